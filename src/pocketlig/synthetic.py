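"""Synthetic fixtures with analytically known ground truth.

Every generator emulates one statistical or geometric feature the analyses
rely on — hollow cages of closed-form cavity volume, solvation frames with
exactly planted first-shell water counts, trajectories with planted
hydrogen-bond schedules or Gaussian displacements, two-charge systems with
closed-form energies, and structure pairs with planted B-factor region
contrasts. Each returns its fixture together with a ground-truth dict; the
CLI writes both through the package's own writers so the I/O path is
exercised end to end.

``make_binding_site_model`` and ``make_lbp_model`` are synthetic stand-ins
for a receptor-ligand crystal structure: they embed the contact geometry,
pocket size and occupancy of a tripartite medium-chain-fatty-acid binding
mode as planted values, so the measurement pipeline can be validated
without any deposited coordinates.
"""

from __future__ import annotations

import json
import math
import os

import numpy as np

from .energetics import COULOMB_CONSTANT, FFParams
from .structure import Atom, AtomSet, Structure, Trajectory, write_structure, write_trajectory

__all__ = [
    "make_cage",
    "make_hydration_frame",
    "make_hydration_trajectory",
    "make_hbond_trajectory",
    "make_displacement_trajectory",
    "make_charge_system",
    "make_random_charge_system",
    "make_bfactor_pair",
    "make_binding_site_model",
    "make_lbp_model",
    "write_fixture",
    "FIXTURE_KINDS",
]


class _Builder:
    """Accumulates Atom records with sequential serials."""

    def __init__(self) -> None:
        self.atoms: list[Atom] = []

    def add(self, name: str, element: str, resname: str, resnum: int, pos,
            chain: str = "A", hetero: bool = False, b: float = 20.0,
            occ: float = 1.0) -> Atom:
        a = Atom(serial=len(self.atoms) + 1, name=name, element=element,
                 residue_name=resname, residue_number=resnum, chain_id=chain,
                 alt_loc="", position=np.asarray(pos, float), occupancy=occ,
                 b_factor=b, is_hetero=hetero)
        self.atoms.append(a)
        return a

    def structure(self, title: str = "") -> Structure:
        return Structure(self.atoms, title=title)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-angle lattice)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + 5 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta), np.cos(phi)])


# ---------------------------------------------------------------------------
# cage / pocket models

def make_cage(inner_radius: float = 8.0, atom_radius: float = 1.5,
              n_shell_atoms: int = 1600, seed: int = 0,
              probe_radius: float = 1.4) -> tuple[Structure, dict]:
    """Hollow spherical shell enclosing a cavity of closed-form volume.

    Atom centers sit on a sphere of radius ``inner_radius``; the probe-
    accessible cavity is the ball of radius
    inner_radius - atom_radius - probe_radius, whose volume is returned as
    ground truth. The shell gap must stay below the blocked diameter
    2*(atom_radius + probe_radius) so the cage is watertight.
    """
    rng = np.random.default_rng(seed)
    pts = _fibonacci_sphere(n_shell_atoms)
    # random (seeded) global rotation so lattice artifacts are not axis-aligned
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    centers = inner_radius * (pts @ rot.T)
    shell_gap = 3.81 * inner_radius / math.sqrt(n_shell_atoms)
    if shell_gap >= 2 * (atom_radius + probe_radius):
        raise ValueError(
            f"shell too sparse: gap {shell_gap:.2f} A >= blocked diameter "
            f"{2 * (atom_radius + probe_radius):.2f} A; increase n_shell_atoms"
        )
    b = _Builder()
    for k, c in enumerate(centers):
        b.add("CA", "C", "GLY", k + 1, c, b=20.0)
    r_acc = inner_radius - atom_radius - probe_radius
    truth = {
        "analytic_volume_A3": 4.0 / 3.0 * math.pi * r_acc ** 3,
        "accessible_radius_A": r_acc,
        "shell_gap_A": shell_gap,
        "probe_radius_A": probe_radius,
        "radii": {"C": atom_radius},
    }
    return b.structure(title="synthetic hollow cage"), truth


def make_lbp_model(total_volume: float = 1300.0, occupied_fraction: float = 0.52,
                   atom_radius: float = 1.5, probe_radius: float = 1.4,
                   n_shell_atoms: int = 2400, n_ligands: int = 3,
                   seed: int = 0) -> tuple[Structure, dict]:
    """Synthetic stand-in for a ligand-binding pocket of known volume/occupancy.

    A watertight cage whose accessible cavity has the requested volume
    (default ~1300 A^3, the size class of the PPAR Y-shaped pocket), with
    ``n_ligands`` pseudo-ligand spheres jointly filling the requested
    fraction of it (default 52%). Ligand radii are planted so the union of
    their (disjoint) spheres has volume fraction x total.
    """
    r_acc = (3.0 * total_volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    inner_radius = r_acc + atom_radius + probe_radius
    cage, cage_truth = make_cage(inner_radius, atom_radius, n_shell_atoms, seed,
                                 probe_radius)
    occupied = occupied_fraction * total_volume

    def lens(ra: float, rb: float, d: float) -> float:
        # intersection volume of two spheres, centers d apart
        if d >= ra + rb:
            return 0.0
        if d <= abs(ra - rb):
            return 4.0 / 3.0 * math.pi * min(ra, rb) ** 3
        return (math.pi * (ra + rb - d) ** 2
                * (d * d + 2 * d * (ra + rb) - 3 * (ra - rb) ** 2)
                / (12.0 * d))

    margin = 0.5  # keep ligand surfaces clear of the cavity wall
    if n_ligands == 1:
        r_lig = (3.0 * occupied / (4.0 * math.pi)) ** (1.0 / 3.0)
        if r_lig >= r_acc - margin:
            raise ValueError("single ligand sphere does not fit inside the cavity")
        spheres = [(np.zeros(3), r_lig)]
    elif n_ligands == 3:
        # central sphere + two overlapping flankers along x; flankers are
        # mutually disjoint, so the union has a closed form
        r_fl = 3.0
        d_fl = r_acc - margin - r_fl
        if 2 * d_fl < 2 * r_fl:
            raise ValueError("cavity too small for the three-sphere layout")

        def union_minus_target(r0: float) -> float:
            u = (4.0 / 3.0 * math.pi * r0 ** 3
                 + 2 * (4.0 / 3.0 * math.pi * r_fl ** 3 - lens(r0, r_fl, d_fl)))
            return u - occupied

        from scipy.optimize import brentq

        r_hi = d_fl + r_fl - 0.05  # flanker centers stay outside the core
        if union_minus_target(r_hi) < 0:
            raise ValueError("requested occupancy too large for this layout")
        r0 = float(brentq(union_minus_target, 1.0, r_hi, xtol=1e-10))
        spheres = [(np.zeros(3), r0),
                   (np.array([d_fl, 0.0, 0.0]), r_fl),
                   (np.array([-d_fl, 0.0, 0.0]), r_fl)]
    else:
        raise ValueError("n_ligands must be 1 or 3")
    b = _Builder()
    for a in cage.atoms:
        b.add(a.name, a.element, a.residue_name, a.residue_number, a.position,
              b=a.b_factor)
    name_overrides = {}
    for k, (off, r_k) in enumerate(spheres):
        nm = f"LQ{k + 1}"
        b.add(nm, "C", "MCA", 601 + k, off, hetero=True, b=30.0)
        name_overrides[nm] = r_k
    truth = {
        "total_volume_A3": total_volume,
        "occupied_volume_A3": occupied,
        "occupancy_fraction": occupied_fraction,
        "ligand_radii_A": [r for _, r in spheres],
        "n_ligands": n_ligands,
        "radii": cage_truth["radii"],
        "name_overrides": name_overrides,
        "probe_radius_A": probe_radius,
    }
    return b.structure(title="synthetic ligand-binding-pocket model"), truth


# ---------------------------------------------------------------------------
# binding-site contact model

def _plant_residue(b: _Builder, resname: str, resnum: int, partner_name: str,
                   partner_element: str, anchor: np.ndarray, direction: np.ndarray,
                   distance: float, b_factor: float = 20.0) -> np.ndarray:
    """Place a partner atom at anchor + distance*direction, backbone behind it."""
    u = _unit(direction)
    pos = anchor + distance * u
    b.add(partner_name, partner_element, resname, resnum, pos, b=b_factor)
    # backbone receding along the same ray; always farther from the anchor
    perp = _unit(np.cross(u, [0.37, 0.61, 0.70] if abs(u[2]) < 0.9 else [1.0, 0, 0]))
    for k, nm_el in enumerate((("CA", "C"), ("N", "N"), ("C", "C"), ("O", "O"))):
        if nm_el[0] == partner_name:
            continue
        b.add(nm_el[0], nm_el[1], resname, resnum,
              pos + (1.6 + 1.1 * k) * u + 0.4 * ((-1) ** k) * perp, b=b_factor)
    return pos


def _carboxylate_dirs(tail_dir, ref_perp=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit directions from C1 to O1 and O2 (flanking, away from the tail)."""
    t = _unit(tail_dir)
    if ref_perp is None:
        ref_perp = [1.0, 0, 0] if abs(t[0]) < 0.9 else [0, 0, 1.0]
    r = np.asarray(ref_perp, float)
    r = _unit(r - (r @ t) * t)
    u = -t
    return _unit(0.5 * u + 0.866 * r), _unit(0.5 * u - 0.866 * r), r


def _fatty_acid(b: _Builder, resnum: int, origin: np.ndarray, tail_dir: np.ndarray,
                n_carbons: int = 9, b_factor: float = 20.0,
                ref_perp=None) -> dict[str, np.ndarray]:
    """A schematic medium-chain fatty acid: carboxylate + zigzag tail."""
    t = _unit(tail_dir)
    d1, d2, perp = _carboxylate_dirs(tail_dir, ref_perp)
    c1 = np.asarray(origin, float)
    o1 = c1 + 1.25 * d1
    o2 = c1 + 1.25 * d2
    b.add("C1", "C", "MCA", resnum, c1, hetero=True, b=b_factor)
    b.add("O1", "O", "MCA", resnum, o1, hetero=True, b=b_factor)
    b.add("O2", "O", "MCA", resnum, o2, hetero=True, b=b_factor)
    pos = {"C1": c1, "O1": o1, "O2": o2}
    for k in range(2, n_carbons + 1):
        p = c1 + 1.3 * (k - 1) * t + 0.45 * ((-1) ** k) * perp
        b.add(f"C{k}", "C", "MCA", resnum, p, hetero=True, b=b_factor)
        pos[f"C{k}"] = p
    return pos


def make_binding_site_model(seed: int = 0) -> tuple[Structure, dict]:
    """Synthetic stand-in for the tripartite fatty-acid binding site.

    Three schematic C9 fatty acids (residues MCA 601/602/603, sites
    I/II/III) with polar partner residues planted at the printed crystal-
    contact distances: site-I carboxylate to Tyr473-OH 2.90 A, His323 2.92,
    His449 2.75, Ser289 3.05; site-II carboxylate to Arg288-NH1 3.2; site-
    III carboxylate to Arg288-NE 3.87 and Leu340 backbone N 3.2. Hydro-
    phobic shell residues sit ~3.9 A from the aliphatic tails. The planted
    distances are the ground truth returned alongside.
    """
    b = _Builder()

    # --- site I ------------------------------------------------------------
    na1 = _fatty_acid(b, 601, np.zeros(3), [0, -1.0, 0], b_factor=15.0)
    o1a, o1b = na1["O1"], na1["O2"]
    _plant_residue(b, "TYR", 473, "OH", "O", o1a, [0.0, 0.25, 0.97], 2.90)
    _plant_residue(b, "HIS", 449, "NE2", "N", o1a, [0.3, 0.2, -0.93], 2.75)
    _plant_residue(b, "HIS", 323, "NE2", "N", o1b, [-0.45, 0.88, 0.16], 2.92)
    _plant_residue(b, "SER", 289, "OG", "O", o1b, [0.1, 0.55, -0.83], 3.05)
    for resname, resnum, cref, direction in (
        ("ILE", 281, "C4", [1.0, 0, 0.2]), ("PHE", 282, "C5", [-1.0, 0, 0.2]),
        ("LEU", 353, "C6", [0.2, 0, 1.0]), ("PHE", 363, "C7", [0.2, 0, -1.0]),
        ("MET", 364, "C8", [1.0, 0, -0.3]), ("LEU", 453, "C9", [-1.0, 0, -0.3]),
    ):
        _plant_residue(b, resname, resnum, "CD1", "C", na1[cref], direction, 3.9)

    # --- sites II and III share Arg288 --------------------------------------
    na2 = _fatty_acid(b, 602, np.array([25.0, 0.0, 0.0]), [0, -1.0, 0], b_factor=40.0)
    p2 = na2["O1"]
    nh1 = p2 + 3.2 * _unit([0.866, 0.5, 0.0])
    cz = nh1 + 1.33 * _unit([0.5, 0.866, 0.0])
    ne = cz + 1.33 * np.array([0.0, 1.0, 0.0])
    p3 = ne + 3.87 * _unit([0.0, 0.917, 0.40])
    b.add("NH1", "N", "ARG", 288, nh1, b=25.0)
    b.add("CZ", "C", "ARG", 288, cz, b=25.0)
    b.add("NE", "N", "ARG", 288, ne, b=25.0)
    b.add("CD", "C", "ARG", 288, ne + 1.5 * _unit([-0.8, 0.3, -0.5]), b=25.0)
    b.add("CA", "C", "ARG", 288, ne + 3.3 * _unit([-0.8, 0.3, -0.5]), b=25.0)
    tail3 = np.array([0.0, 1.0, 0.3])
    d1_3, _, _ = _carboxylate_dirs(tail3)
    na3 = _fatty_acid(b, 603, p3 - 1.25 * d1_3, tail3, b_factor=45.0)
    if np.linalg.norm(na3["O1"] - p3) > 1e-9:
        raise RuntimeError("site-III carboxylate misplaced")
    _plant_residue(b, "LEU", 340, "N", "N", p3, [0.55, 0.1, 0.83], 3.2)
    for resname, resnum, fa, cref, direction in (
        ("ALA", 292, na2, "C4", [1.0, 0, 0.3]), ("ILE", 296, na2, "C6", [-1.0, 0, 0.3]),
        ("MET", 329, na2, "C8", [0.3, 0, 1.0]), ("LEU", 330, na2, "C9", [0.3, 0, -1.0]),
        ("ILE", 341, na3, "C5", [1.0, 0.2, 0]), ("CYS", 285, na3, "C7", [-0.9, 0.2, 0.4]),
    ):
        _plant_residue(b, resname, resnum, "CD1", "C", fa[cref], direction, 3.9)

    st = b.structure(title="synthetic tripartite binding-site model")

    planted = {
        "Y473_OH_site1": (2.90, "resname MCA and resnum 601 and name O1 O2",
                          "resnum 473 and not hetero"),
        "H323_site1": (2.92, "resname MCA and resnum 601 and name O1 O2",
                       "resnum 323 and not hetero"),
        "H449_site1": (2.75, "resname MCA and resnum 601 and name O1 O2",
                       "resnum 449 and not hetero"),
        "S289_site1": (3.05, "resname MCA and resnum 601 and name O1 O2",
                       "resnum 289 and not hetero"),
        "R288_site2": (3.2, "resname MCA and resnum 602 and name O1 O2",
                       "resnum 288 and not hetero"),
        "R288_NE_site3": (3.87, "resname MCA and resnum 603 and name O1 O2",
                          "resnum 288 and name NE"),
        "L340_site3": (3.2, "resname MCA and resnum 603 and name O1 O2",
                       "resnum 340 and not hetero"),
    }
    # construction audit: every planted distance is the true group minimum
    from .contacts import min_group_distance

    for label, (d, expr_a, expr_b) in planted.items():
        got, _ = min_group_distance(st, st.select(expr_a), st.select(expr_b))
        if abs(got - d) > 1e-6:
            raise RuntimeError(f"planted contact {label}: built {got:.4f}, wanted {d}")
    truth = {"planted_distances": {k: v[0] for k, v in planted.items()},
             "selections": {k: {"ligand": v[1], "partner": v[2]}
                            for k, v in planted.items()},
             "hydrophobic_shell": {
                 "site1": [281, 282, 353, 363, 364, 453],
                 "site2": [292, 296, 329, 330],
                 "site3": [341, 285],
             }}
    return st, truth


# ---------------------------------------------------------------------------
# hydration fixtures

def _solute_carboxylate(b: _Builder) -> tuple[np.ndarray, np.ndarray]:
    o1 = np.array([1.25, 0.0, 0.0])
    o2 = np.array([-0.62, 1.06, 0.0])
    b.add("C1", "C", "MCA", 601, np.zeros(3), hetero=True)
    b.add("O1", "O", "MCA", 601, o1, hetero=True)
    b.add("O2", "O", "MCA", 601, o2, hetero=True)
    return o1, o2


def _place_waters(b: _Builder, rng: np.random.Generator, anchors: np.ndarray,
                  n_inside: int, n_outside: int, cutoff: float,
                  first_resnum: int = 1001) -> None:
    resnum = first_resnum
    for _ in range(n_inside):
        while True:
            anchor = anchors[rng.integers(len(anchors))]
            u = _unit(rng.normal(size=3))
            d = rng.uniform(2.5, max(cutoff - 0.05, 2.55))
            pos = anchor + d * u
            if np.linalg.norm(pos - anchors, axis=1).min() >= 2.4:
                break
        b.add("O", "O", "HOH", resnum, pos, chain="W", hetero=True)
        resnum += 1
    for _ in range(n_outside):
        while True:
            u = _unit(rng.normal(size=3))
            d = rng.uniform(cutoff + 0.6, cutoff + 8.0)
            pos = anchors.mean(axis=0) + d * u
            if np.linalg.norm(pos - anchors, axis=1).min() > cutoff + 0.5:
                break
        b.add("O", "O", "HOH", resnum, pos, chain="W", hetero=True)
        resnum += 1


def make_hydration_frame(n_inside: int, n_outside: int, cutoff: float = 3.5,
                         seed: int = 0) -> tuple[Structure, dict]:
    """One frame with exactly ``n_inside`` first-shell waters around a
    carboxylate and ``n_outside`` waters beyond cutoff + 0.5 A."""
    rng = np.random.default_rng(seed)
    b = _Builder()
    o1, o2 = _solute_carboxylate(b)
    _place_waters(b, rng, np.array([o1, o2]), n_inside, n_outside, cutoff)
    truth = {"n_inside": n_inside, "n_outside": n_outside, "cutoff_A": cutoff,
             "solute_selection": "resname MCA and name O1 O2",
             "water_selection": "resname HOH and name O"}
    return b.structure(title="synthetic hydration frame"), truth


def make_hydration_trajectory(counts=None, mean: float = 7.0, n_frames: int = 300,
                              cutoff: float = 3.5, seed: int = 0,
                              site_label: str = "") -> tuple[Trajectory, dict]:
    """Trajectory with a planted per-frame first-shell water count.

    ``counts`` fixes the schedule explicitly; otherwise counts are drawn
    Poisson(``mean``), emulating fluctuating hydration shells around a
    fatty-acid carboxylate.
    """
    rng = np.random.default_rng(seed)
    if counts is None:
        counts = rng.poisson(mean, size=n_frames)
    counts = np.asarray(counts, dtype=int)
    n_water = int(counts.max()) + 2
    b = _Builder()
    o1, o2 = _solute_carboxylate(b)
    anchors = np.array([o1, o2])
    # topology frame: all waters parked far away
    _place_waters(b, rng, anchors, 0, n_water, cutoff)
    top = b.structure(title="synthetic hydration trajectory")
    water_idx = np.array([i for i, a in enumerate(top.atoms) if a.residue_name == "HOH"])
    frames = np.repeat(top.coords[None, :, :], len(counts), axis=0)
    for k, c in enumerate(counts):
        placed = []
        for w in range(int(c)):
            while True:
                anchor = anchors[rng.integers(2)]
                pos = anchor + rng.uniform(2.5, cutoff - 0.05) * _unit(rng.normal(size=3))
                if np.linalg.norm(pos - anchors, axis=1).min() >= 2.4:
                    break
            placed.append(pos)
        for w, pos in enumerate(placed):
            frames[k, water_idx[w]] = pos
    traj = Trajectory(top, frames)
    truth = {"counts": counts.tolist(), "mean": float(counts.mean()),
             "cutoff_A": cutoff, "site_label": site_label,
             "solute_selection": "resname MCA and name O1 O2",
             "water_selection": "resname HOH and name O"}
    return traj, truth


# ---------------------------------------------------------------------------
# hydrogen-bond and displacement trajectories

def make_hbond_trajectory(n_frames: int = 100, persistence_fraction: float = 1.0,
                          d_on: float = 2.8, d_off: float = 4.6, seed: int = 0,
                          schedule: str = "prefix") -> tuple[Trajectory, dict]:
    """Trajectory where a donor-acceptor pair is bonded on a planted schedule.

    The donor (a tyrosine hydroxyl oxygen) sits at ``d_on`` from the ligand
    carboxylate oxygen in exactly round(persistence_fraction * n_frames)
    frames and at ``d_off`` otherwise. ``schedule='prefix'`` keeps the bond
    through the first on-frames then ruptures it (the chain-length-
    dependent rupture pattern); ``'random'`` scatters the on-frames.
    """
    if not 0.0 <= persistence_fraction <= 1.0:
        raise ValueError("persistence_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_on = round(persistence_fraction * n_frames)
    flags = np.zeros(n_frames, dtype=bool)
    if schedule == "prefix":
        flags[:n_on] = True
    elif schedule == "random":
        flags[rng.choice(n_frames, size=n_on, replace=False)] = True
    else:
        raise ValueError(f"unknown schedule {schedule!r}")
    b = _Builder()
    b.add("C1", "C", "MCA", 601, [-1.25, 0, 0], hetero=True)
    b.add("O1", "O", "MCA", 601, [0.0, 0.0, 0.0], hetero=True)
    b.add("OH", "O", "TYR", 473, [0.0, 0.0, d_on])
    b.add("CZ", "C", "TYR", 473, [0.0, 0.0, d_on + 1.4])
    top = b.structure(title="synthetic H-bond trajectory")
    di, ci = 2, 3  # OH donor, CZ rides along
    frames = np.repeat(top.coords[None, :, :], n_frames, axis=0)
    for k in range(n_frames):
        z = d_on if flags[k] else d_off
        frames[k, di, 2] = z
        frames[k, ci, 2] = z + 1.4
    truth = {"schedule": flags.tolist(), "persistence": n_on / n_frames,
             "d_on_A": d_on, "d_off_A": d_off,
             "donor_selection": "resname TYR and name OH",
             "acceptor_selection": "resname MCA and name O1"}
    return Trajectory(top, frames), truth


def make_displacement_trajectory(base: Structure, sigma: float, n_frames: int,
                                 seed: int = 0, displace_sel: AtomSet | None = None,
                                 two_state: bool = False,
                                 state_offset: float = 2.0,
                                 state_fraction: float = 0.5) -> tuple[Trajectory, dict]:
    """Frames with i.i.d. Gaussian per-coordinate displacements (sd ``sigma``).

    Displacements apply to ``displace_sel`` (default: all atoms). With
    ``two_state`` the selection is additionally shifted by ``state_offset``
    along +x in a trailing fraction of frames, planting a biphasic
    (two-average-position) displacement distribution.
    """
    rng = np.random.default_rng(seed)
    idx = displace_sel.indices if displace_sel is not None else np.arange(base.n_atoms)
    frames = np.repeat(base.coords[None, :, :], n_frames, axis=0)
    if sigma > 0:
        frames[:, idx, :] += rng.normal(0.0, sigma, size=(n_frames, len(idx), 3))
    state = np.zeros(n_frames, dtype=bool)
    if two_state:
        n_b = round(state_fraction * n_frames)
        state[n_frames - n_b:] = True
        frames[np.ix_(state, idx)] += np.array([state_offset, 0.0, 0.0])
    truth = {"sigma_A": sigma, "n_frames": n_frames,
             "expected_mean_square_rmsd_A2": 3.0 * sigma * sigma,
             "two_state": two_state, "state_flags": state.tolist(),
             "state_offset_A": state_offset if two_state else 0.0}
    return Trajectory(base, frames), truth


# ---------------------------------------------------------------------------
# energetics fixtures

def make_charge_system(q1: float = 1.0, q2: float = -1.0, r: float = COULOMB_CONSTANT,
                       eps: float = 0.1, rmin: float = 3.5) -> tuple[Structure, FFParams, dict]:
    """Two-atom system with closed-form Coulomb and Lennard-Jones energies."""
    b = _Builder()
    b.add("Q1", "C", "LIG", 1, [0.0, 0.0, 0.0], hetero=True)
    b.add("Q2", "C", "ENV", 2, [r, 0.0, 0.0], hetero=True)
    ff = FFParams()
    ff.add("LIG:Q1", q1, eps, rmin / 2.0, "rmin_half")
    ff.add("ENV:Q2", q2, eps, rmin / 2.0, "rmin_half")
    coulomb = COULOMB_CONSTANT * q1 * q2 / r
    ratio6 = (rmin / r) ** 6
    lj = eps * (ratio6 * ratio6 - 2.0 * ratio6)
    truth = {"r_A": r, "coulomb_kcal": coulomb, "lj_kcal": lj,
             "lj_at_rmin_kcal": -eps}
    return b.structure(title="synthetic two-charge system"), ff, truth


def make_random_charge_system(n_atoms: int = 50, box_size: float = 15.0,
                              n_ligand: int = 5, seed: int = 0,
                              min_sep: float = 1.6) -> tuple[Structure, FFParams, dict]:
    """Random charged LJ particles; first ``n_ligand`` atoms form the ligand.

    Positions are rejection-sampled to keep a minimum separation so no pair
    sits on the LJ singularity. Intended for brute-force oracle checks.
    """
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    while len(pts) < n_atoms:
        p = rng.uniform(0, box_size, size=3)
        if not pts or np.linalg.norm(np.array(pts) - p, axis=1).min() >= min_sep:
            pts.append(p)
    b = _Builder()
    ff = FFParams()
    for k, p in enumerate(pts):
        name = f"Q{k + 1}"
        resname = "LIG" if k < n_ligand else "ENV"
        resnum = 1 if k < n_ligand else 2 + (k - n_ligand)
        b.add(name, "C", resname, resnum, p, hetero=True)
        ff.add(f"{resname}:{name}", float(rng.uniform(-0.8, 0.8)),
               float(rng.uniform(0.02, 0.30)), float(rng.uniform(1.2, 2.2)),
               "rmin_half")
    truth = {"n_atoms": n_atoms, "n_ligand": n_ligand, "box_size_A": box_size,
             "ligand_selection": "resname LIG",
             "environment_selection": "resname ENV"}
    return b.structure(title="synthetic random charge system"), ff, truth


# ---------------------------------------------------------------------------
# B-factor pairs

def make_bfactor_pair(n_res: int = 280, start_resnum: int = 230,
                      regions_a: dict[str, list[tuple[int, int]]] | None = None,
                      regions_b: dict[str, list[tuple[int, int]]] | None = None,
                      delta_sigma: float = 2.0, noise_sd: float = 2.0,
                      idiosyncratic_sd: float = 0.6, baseline: float = 25.0,
                      seed: int = 0) -> tuple[Structure, Structure, dict]:
    """Two structures, identical geometry, planted B-factor region contrasts.

    Both structures share one architecture-driven baseline profile
    (baseline + noise_sd fluctuations), as two crystals of the same
    protein do; each then gets small independent ``idiosyncratic_sd``
    noise, and regions in ``regions_a`` are elevated by ``delta_sigma``
    noise-sds in structure A, ``regions_b`` likewise in B — emulating
    ligand-dependent mobility differences on top of a common profile.
    """
    rng = np.random.default_rng(seed)
    regions_a = regions_a or {}
    regions_b = regions_b or {}
    resnums = np.arange(start_resnum, start_resnum + n_res)
    # CA trace on a gentle helix so geometry is identical and nondegenerate
    t = np.arange(n_res) * 0.45
    coords = np.column_stack([8 * np.cos(t / 3), 8 * np.sin(t / 3), 1.2 * t])
    shared = baseline + rng.normal(0.0, noise_sd, size=n_res)
    base_b = {s: shared + rng.normal(0.0, idiosyncratic_sd, size=n_res) for s in "ab"}

    def elevated(regions: dict) -> np.ndarray:
        bump = np.zeros(n_res)
        for ranges in regions.values():
            for lo, hi in ranges:
                bump[(resnums >= lo) & (resnums <= hi)] += delta_sigma * noise_sd
        return bump

    bumps = {"a": elevated(regions_a), "b": elevated(regions_b)}
    structures = []
    for s in "ab":
        b = _Builder()
        for i, num in enumerate(resnums):
            bv = max(base_b[s][i] + bumps[s][i], 0.0)
            for name, el, off in (("N", "N", [-0.5, 0.3, -0.4]), ("CA", "C", [0, 0, 0]),
                                  ("C", "C", [0.6, -0.3, 0.4]), ("O", "O", [1.1, 0.4, 0.6])):
                b.add(name, el, "ALA", int(num), coords[i] + off, b=bv)
        structures.append(b.structure(title=f"synthetic B-factor structure {s.upper()}"))
    truth = {"regions_elevated_in_a": {k: list(v) for k, v in regions_a.items()},
             "regions_elevated_in_b": {k: list(v) for k, v in regions_b.items()},
             "delta_sigma": delta_sigma, "noise_sd": noise_sd}
    return structures[0], structures[1], truth


# ---------------------------------------------------------------------------
# fixture writing (used by the CLI)

FIXTURE_KINDS = ("cage", "binding_site", "lbp", "hydration_frame", "hbond_traj",
                 "displacement_traj", "charge_system", "bfactor_pair")


def write_fixture(kind: str, outdir: str, seed: int = 0, **params) -> dict:
    """Generate a fixture, write it through the package writers + truth JSON."""
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    if kind == "cage":
        st, truth = make_cage(seed=seed, **params)
        write_structure(st, os.path.join(outdir, "cage.pdb"))
        paths["structure"] = "cage.pdb"
    elif kind == "binding_site":
        st, truth = make_binding_site_model(seed=seed, **params)
        write_structure(st, os.path.join(outdir, "binding_site.pdb"))
        paths["structure"] = "binding_site.pdb"
    elif kind == "lbp":
        st, truth = make_lbp_model(seed=seed, **params)
        write_structure(st, os.path.join(outdir, "lbp.pdb"))
        paths["structure"] = "lbp.pdb"
    elif kind == "hydration_frame":
        st, truth = make_hydration_frame(params.pop("n_inside", 7),
                                         params.pop("n_outside", 20),
                                         seed=seed, **params)
        write_structure(st, os.path.join(outdir, "hydration_frame.pdb"))
        paths["structure"] = "hydration_frame.pdb"
    elif kind == "hbond_traj":
        traj, truth = make_hbond_trajectory(seed=seed, **params)
        write_structure(traj.topology, os.path.join(outdir, "hbond_top.pdb"))
        write_trajectory(traj, os.path.join(outdir, "hbond_frames.xyz"), "xyz-frames")
        paths["topology"] = "hbond_top.pdb"
        paths["trajectory"] = "hbond_frames.xyz"
    elif kind == "displacement_traj":
        base, _ = make_binding_site_model(seed=seed)
        traj, truth = make_displacement_trajectory(base, params.pop("sigma", 0.5),
                                                   params.pop("n_frames", 200),
                                                   seed=seed, **params)
        write_structure(base, os.path.join(outdir, "displacement_top.pdb"))
        write_trajectory(traj, os.path.join(outdir, "displacement_frames.xyz"),
                         "xyz-frames")
        paths["topology"] = "displacement_top.pdb"
        paths["trajectory"] = "displacement_frames.xyz"
    elif kind == "charge_system":
        st, ff, truth = make_charge_system(**params)
        write_structure(st, os.path.join(outdir, "charges.pdb"))
        ff.to_file(os.path.join(outdir, "charges.ff"))
        paths["structure"] = "charges.pdb"
        paths["params"] = "charges.ff"
    elif kind == "bfactor_pair":
        sa, sb, truth = make_bfactor_pair(seed=seed, **params)
        write_structure(sa, os.path.join(outdir, "bfactor_a.pdb"))
        write_structure(sb, os.path.join(outdir, "bfactor_b.pdb"))
        paths["structure_a"] = "bfactor_a.pdb"
        paths["structure_b"] = "bfactor_b.pdb"
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    truth_out = {"kind": kind, "seed": seed, "files": paths, "truth": truth}
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        json.dump(truth_out, fh, indent=1, sort_keys=True)
    return truth_out
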