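"""Cutoff-based nonbonded interaction energies and their decomposition.

Intermolecular ligand-environment energies only: a 12-6 Lennard-Jones term
with Lorentz-Berthelot combining plus a Coulomb term
(k_e = 332.0636 kcal A mol^-1 e^-2), truncated or smoothly switched at a
cutoff (12 A by default, the common van-der-Waals cutoff in biomolecular
force fields). Per-group decomposition is pairwise by construction, so the
complete-system energy equals the sum over disjoint environment groups
exactly. Ewald electrostatics are deliberately not used here — a per-group
split is only well-defined for pairwise sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import neighbor_pairs
from .structure import Atom, AtomSet, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "FFParams",
    "ParameterError",
    "pair_energy",
    "group_interaction_energy",
    "decompose_energy",
    "EnergyTerms",
    "EnergyDecomposition",
]

COULOMB_CONSTANT = 332.0636  # kcal mol^-1 A e^-2
_SIXTH_ROOT_2 = 2.0 ** (1.0 / 6.0)


class ParameterError(KeyError):
    """A required force-field parameter is missing."""


@dataclass(frozen=True)
class LJParams:
    epsilon: float  # kcal/mol, well depth (>= 0)
    rmin: float     # A, distance at the LJ minimum (> 0)


class FFParams:
    """Per-atom partial charges and Lennard-Jones parameters.

    Entries are keyed ``RESNAME:ATOMNAME``; a bare ``ATOMNAME`` key acts as
    a wildcard over residues. The size parameter may be given as sigma or
    as R_min/2 (the CHARMM convention); both are stored internally as the
    full R_min.
    """

    def __init__(self) -> None:
        self._entries: dict[str, tuple[float, LJParams]] = {}

    def add(self, key: str, charge: float, epsilon: float, size: float,
            convention: str = "rmin_half") -> None:
        if epsilon < 0:
            raise ValueError(f"{key}: negative epsilon")
        if size <= 0:
            raise ValueError(f"{key}: nonpositive LJ size")
        if convention == "rmin_half":
            rmin = 2.0 * size
        elif convention == "sigma":
            rmin = _SIXTH_ROOT_2 * size
        else:
            raise ValueError(f"{key}: unknown LJ size convention {convention!r}")
        self._entries[key.upper()] = (charge, LJParams(epsilon, rmin))

    @classmethod
    def from_file(cls, path: str) -> "FFParams":
        """Whitespace table: atom_key charge epsilon size [convention]."""
        ff = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split()
                if len(parts) not in (4, 5):
                    raise ValueError(f"{path}:{lineno}: expected 4 or 5 fields")
                key, q, eps, size = parts[0], float(parts[1]), float(parts[2]), float(parts[3])
                conv = parts[4] if len(parts) == 5 else "rmin_half"
                ff.add(key, q, eps, size, conv)
        return ff

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("# atom_key charge epsilon_kcal rmin_half_A convention\n")
            for key, (q, lj) in sorted(self._entries.items()):
                fh.write(f"{key} {q:.6f} {lj.epsilon:.6f} {lj.rmin / 2:.6f} rmin_half\n")

    def lookup(self, atom: Atom) -> tuple[float, LJParams]:
        for key in (f"{atom.residue_name}:{atom.name}".upper(), atom.name.upper()):
            if key in self._entries:
                return self._entries[key]
        raise ParameterError(
            f"no force-field parameters for atom {atom.name} in residue "
            f"{atom.residue_name} {atom.residue_number}"
        )

    def arrays_for(self, sel: AtomSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(charges, epsilons, rmins) aligned with the selection's atoms."""
        q = np.empty(len(sel))
        eps = np.empty(len(sel))
        rmin = np.empty(len(sel))
        for k, atom in enumerate(sel.atoms):
            charge, lj = self.lookup(atom)
            q[k], eps[k], rmin[k] = charge, lj.epsilon, lj.rmin
        return q, eps, rmin


def _switch_factor(r: np.ndarray, switch_on: float, cutoff: float) -> np.ndarray:
    """CHARMM switching polynomial: 1 below switch_on, 0 at cutoff, C1-smooth."""
    r2, on2, off2 = r * r, switch_on * switch_on, cutoff * cutoff
    s = np.ones_like(r)
    rng = (r > switch_on) & (r < cutoff)
    num = (off2 - r2[rng]) ** 2 * (off2 + 2 * r2[rng] - 3 * on2)
    s[rng] = num / (off2 - on2) ** 3
    s[r >= cutoff] = 0.0
    return s


def pair_energy(q_i: float, q_j: float, lj_i: LJParams, lj_j: LJParams, r: float,
                cutoff: float = 12.0, switching: str = "truncate",
                switch_on: float | None = None) -> tuple[float, float]:
    """(coulomb, lennard_jones) in kcal/mol for one atom pair at distance r.

    ``switching``: ``truncate`` (hard zero beyond cutoff), ``switch``
    (CHARMM ramp on [switch_on, cutoff], default switch_on = cutoff - 2 A),
    or ``none`` (no cutoff).
    """
    if r <= 0:
        raise ValueError("pair distance must be positive (coincident atoms)")
    if switching not in ("truncate", "switch", "none"):
        raise ValueError(f"unknown switching mode {switching!r}")
    if switching != "none" and r >= cutoff:
        return 0.0, 0.0
    coul = COULOMB_CONSTANT * q_i * q_j / r
    eps = math.sqrt(lj_i.epsilon * lj_j.epsilon)
    rmin = 0.5 * (lj_i.rmin + lj_j.rmin)  # Lorentz-Berthelot
    ratio6 = (rmin / r) ** 6
    lj = eps * (ratio6 * ratio6 - 2.0 * ratio6)
    if switching == "switch":
        on = switch_on if switch_on is not None else max(cutoff - 2.0, 0.0)
        s = float(_switch_factor(np.array([r]), on, cutoff)[0])
        coul *= s
        lj *= s
    return coul, lj


@dataclass
class EnergyTerms:
    coulomb: float
    lj: float

    @property
    def total(self) -> float:
        return self.coulomb + self.lj


def group_interaction_energy(frame: np.ndarray, ligand_sel: AtomSet, group_sel: AtomSet,
                             params: FFParams, cutoff: float = 12.0,
                             switching: str = "truncate",
                             switch_on: float | None = None) -> EnergyTerms:
    """Sum of pair energies over all ligand-group cross pairs within cutoff."""
    if not ligand_sel.isdisjoint(group_sel):
        raise ValueError("ligand and group selections overlap")
    frame = np.asarray(frame, dtype=float)
    ql, epsl, rminl = params.arrays_for(ligand_sel)
    qg, epsg, rming = params.arrays_for(group_sel)
    la = frame[ligand_sel.indices]
    ga = frame[group_sel.indices]
    if switching == "none":
        d = np.linalg.norm(la[:, None, :] - ga[None, :, :], axis=2)
        if np.any(d <= 0):
            raise ValueError("coincident ligand/group atoms (r = 0)")
        coul = COULOMB_CONSTANT * (ql[:, None] * qg[None, :]) / d
        eps = np.sqrt(epsl[:, None] * epsg[None, :])
        rmin = 0.5 * (rminl[:, None] + rming[None, :])
        ratio6 = (rmin / d) ** 6
        lj = eps * (ratio6 * ratio6 - 2.0 * ratio6)
        return EnergyTerms(float(coul.sum()), float(lj.sum()))
    pairs = neighbor_pairs(la, ga, cutoff)
    if not pairs:
        return EnergyTerms(0.0, 0.0)
    idx_i = np.array([p[0] for p in pairs])
    idx_j = np.array([p[1] for p in pairs])
    r = np.array([p[2] for p in pairs])
    strict = r < cutoff  # energies are zero at and beyond the cutoff
    idx_i, idx_j, r = idx_i[strict], idx_j[strict], r[strict]
    if r.size == 0:
        return EnergyTerms(0.0, 0.0)
    if np.any(r <= 0):
        raise ValueError("coincident ligand/group atoms (r = 0)")
    coul = COULOMB_CONSTANT * ql[idx_i] * qg[idx_j] / r
    eps = np.sqrt(epsl[idx_i] * epsg[idx_j])
    rmin = 0.5 * (rminl[idx_i] + rming[idx_j])
    ratio6 = (rmin / r) ** 6
    lj = eps * (ratio6 * ratio6 - 2.0 * ratio6)
    if switching == "switch":
        on = switch_on if switch_on is not None else max(cutoff - 2.0, 0.0)
        s = _switch_factor(r, on, cutoff)
        coul = coul * s
        lj = lj * s
    return EnergyTerms(float(coul.sum()), float(lj.sum()))


@dataclass
class EnergyDecomposition:
    """Per-ligand, per-group interaction energy statistics over frames.

    ``series[ligand][group]`` is the per-frame total (Coulomb + LJ) in
    kcal/mol; Coulomb-only and LJ-only breakdowns are kept alongside since
    published interaction-energy tables do not always say which terms they
    include. The ``complete`` column is the row-sum of the disjoint groups
    each frame, exact by construction.
    """

    ligand_labels: list[str]
    group_names: list[str]
    series: dict[str, dict[str, np.ndarray]]
    coulomb_series: dict[str, dict[str, np.ndarray]]
    lj_series: dict[str, dict[str, np.ndarray]]

    def mean_sd(self, ligand: str, group: str, terms: str = "total") -> tuple[float, float]:
        src = {"total": self.series, "coulomb": self.coulomb_series,
               "lj": self.lj_series}[terms]
        s = src[ligand][group]
        mean = float(s.mean())
        sd = float(s.std(ddof=1)) if s.size > 1 else 0.0
        return mean, sd

    def summary_table(self, terms: str = "total") -> pd.DataFrame:
        cols = ["complete"] + self.group_names
        rows = []
        for lig in self.ligand_labels:
            row: dict[str, object] = {"ligand": lig}
            for g in cols:
                m, s = self.mean_sd(lig, g, terms)
                row[g] = f"{m:.1f}±{s:.1f}"
                row[f"{g}_mean"] = m
                row[f"{g}_sd"] = s
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path: str, terms: str = "total") -> None:
        df = self.summary_table(terms)
        df.to_csv(path, sep="\t", index=False)


def decompose_energy(traj: Trajectory, ligand_sels: dict[str, AtomSet],
                     groups: dict[str, AtomSet], params: FFParams,
                     cutoff: float = 12.0, switching: str = "truncate",
                     switch_on: float | None = None) -> EnergyDecomposition:
    """Mean +- sd interaction energy of each ligand with each environment group.

    ``groups`` must partition the non-ligand environment exactly (for each
    ligand, the other ligands count as environment via an automatic
    ``other ligands`` group when not already included).
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    top = traj.topology
    all_idx = np.arange(top.n_atoms)
    lig_union = np.unique(np.concatenate([s.indices for s in ligand_sels.values()]))
    env_idx = np.setdiff1d(all_idx, lig_union)
    group_union = (np.unique(np.concatenate([g.indices for g in groups.values()]))
                   if groups else np.empty(0, dtype=int))
    sizes = sum(len(g) for g in groups.values())
    if sizes != len(group_union) or not np.array_equal(group_union, env_idx):
        raise ValueError("groups must partition the non-ligand environment exactly")

    series: dict[str, dict[str, np.ndarray]] = {}
    cser: dict[str, dict[str, np.ndarray]] = {}
    lser: dict[str, dict[str, np.ndarray]] = {}
    group_names = list(groups)
    for label, lig in ligand_sels.items():
        per_group = dict(groups)
        others = np.setdiff1d(lig_union, lig.indices)
        if others.size:
            per_group = dict(per_group)
            per_group["other ligands"] = AtomSet(top, others)
        g_tot = {g: np.empty(traj.n_frames) for g in per_group}
        g_c = {g: np.empty(traj.n_frames) for g in per_group}
        g_l = {g: np.empty(traj.n_frames) for g in per_group}
        for k, frame in enumerate(traj.frames):
            for g, gsel in per_group.items():
                e = group_interaction_energy(frame, lig, gsel, params, cutoff,
                                             switching, switch_on)
                g_tot[g][k] = e.total
                g_c[g][k] = e.coulomb
                g_l[g][k] = e.lj
        g_tot["complete"] = sum(g_tot[g] for g in per_group)
        g_c["complete"] = sum(g_c[g] for g in per_group)
        g_l["complete"] = sum(g_l[g] for g in per_group)
        series[label], cser[label], lser[label] = g_tot, g_c, g_l
    names = group_names + (["other ligands"] if len(ligand_sels) > 1 else [])
    return EnergyDecomposition(list(ligand_sels), names, series, cser, lser)
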