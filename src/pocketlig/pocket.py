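"""Grid-based binding-pocket detection, vdW volumes and occupancy.

A cavity voxel is one whose center a small probe (default 1.4 A, water)
can occupy — farther than r_vdW + probe from every protein atom — that is
connected (26-neighborhood) to a seed and not part of bulk solvent.
Partly open pockets (the PPAR ligand-binding pocket opens to the domain
surface) are capped with a second, larger probe (default 3.0 A): bulk is
flood-filled on the large-probe-accessible grid from the box boundary, and
only voxels inside the resulting molecular envelope can belong to the
pocket. If the pocket component still reaches the grid boundary it is
flagged open rather than silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .structure import Atom, AtomSet, Structure

__all__ = [
    "BONDI_RADII",
    "CavityRegion",
    "CavityError",
    "vdw_radius",
    "detect_cavity",
    "ligand_grid_volume",
    "occupancy_fraction",
    "OccupancyResult",
]

# Bondi van der Waals radii (Angstrom)
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "ZN": 1.39, "CA": 2.31,
    "FE": 2.00, "SE": 1.90,
}

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class CavityError(ValueError):
    pass


def vdw_radius(atom: Atom, radii: dict[str, float] | None = None,
               name_overrides: dict[str, float] | None = None) -> float:
    """Radius for an atom, by name override first, then element table."""
    if name_overrides and atom.name in name_overrides:
        return name_overrides[atom.name]
    table = radii if radii is not None else BONDI_RADII
    el = atom.element.upper()
    if el not in table:
        raise CavityError(f"no van der Waals radius for element {el!r} (atom {atom.name})")
    return table[el]


@dataclass
class CavityRegion:
    """A voxelized pocket: volume = voxel count x spacing^3."""

    spacing: float
    origin: np.ndarray                  # center of voxel (0,0,0)
    grid_shape: tuple[int, int, int]
    voxels: np.ndarray                  # (n, 3) int indices, one 26-connected component
    volume: float                       # Angstrom^3
    open_pocket: bool = False           # component reached the grid boundary
    seed_description: str = ""

    def mask(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        m[self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]] = True
        return m

    def voxel_centers(self) -> np.ndarray:
        return self.origin + self.voxels * self.spacing

    def to_pdb(self, path: str) -> None:
        """Pseudo-atom dump of voxel centers for visualization."""
        with open(path, "w") as fh:
            for i, c in enumerate(self.voxel_centers(), start=1):
                fh.write(
                    f"HETATM{i % 100000:5d}  DU  CAV X{1:4d}    "
                    f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}  1.00  0.00          XE\n"
                )
            fh.write("END\n")

    def summary(self) -> dict:
        return {
            "volume_A3": self.volume,
            "n_voxels": int(len(self.voxels)),
            "spacing_A": self.spacing,
            "open_pocket": self.open_pocket,
            "seed": self.seed_description,
        }


def _blocked_mask(shape: np.ndarray, lo: np.ndarray, spacing: float,
                  centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Voxels whose centers lie within radii[i] of atom i, unioned."""
    blocked = np.zeros(tuple(shape), dtype=bool)
    for c, r in zip(centers, radii):
        rv = int(np.ceil(r / spacing)) + 1
        cvox = np.floor((c - lo) / spacing).astype(int)
        lo_v = np.maximum(cvox - rv, 0)
        hi_v = np.minimum(cvox + rv + 1, shape)
        if np.any(lo_v >= hi_v):
            continue
        ax = [lo[d] + spacing * (np.arange(lo_v[d], hi_v[d]) + 0.5) - c[d] for d in range(3)]
        d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        sub = blocked[lo_v[0]:hi_v[0], lo_v[1]:hi_v[1], lo_v[2]:hi_v[2]]
        sub |= d2 <= r * r
    return blocked


def _boundary_labels(labels: np.ndarray) -> set[int]:
    faces = [labels[0], labels[-1], labels[:, 0], labels[:, -1],
             labels[:, :, 0], labels[:, :, -1]]
    out: set[int] = set()
    for f in faces:
        out.update(np.unique(f).tolist())
    out.discard(0)
    return out


def detect_cavity(structure: Structure, protein_sel: AtomSet,
                  seed, probe_radius: float = 1.4, spacing: float = 0.5,
                  envelope_probe: float = 3.0,
                  radii: dict[str, float] | None = None,
                  name_overrides: dict[str, float] | None = None) -> CavityRegion:
    """Detect the pocket connected to ``seed`` inside the protein envelope.

    ``seed`` is an AtomSet (e.g. the bound ligands) or a single 3-vector.
    ``envelope_probe`` is the capping probe closing partly open pocket
    mouths; bulk solvent is whatever that probe reaches from outside.
    """
    if not (0 < spacing <= 1.0):
        raise CavityError("spacing must lie in (0, 1] Angstrom")
    if probe_radius < 0:
        raise CavityError("probe_radius must be nonnegative")
    centers = protein_sel.coords
    if centers.size == 0:
        raise CavityError("empty protein selection")
    atom_radii = np.array([vdw_radius(a, radii, name_overrides) for a in protein_sel.atoms])
    margin = atom_radii.max() + envelope_probe + 2 * spacing
    lo = centers.min(axis=0) - margin
    hi = centers.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int)

    free_small = ~_blocked_mask(shape, lo, spacing, centers, atom_radii + probe_radius)
    free_big = ~_blocked_mask(shape, lo, spacing, centers, atom_radii + envelope_probe)

    # bulk solvent: large-probe-accessible region connected to the boundary
    big_labels, _ = ndimage.label(free_big, structure=_CONN26)
    exterior_ids = _boundary_labels(big_labels)
    exterior = np.isin(big_labels, list(exterior_ids)) if exterior_ids else np.zeros_like(free_big)
    envelope_interior = ~exterior

    candidate = free_small & envelope_interior
    labels, _ = ndimage.label(candidate, structure=_CONN26)

    if isinstance(seed, AtomSet):
        seed_pts = seed.coords
        seed_desc = f"AtomSet({len(seed)} atoms)"
    else:
        seed_pts = np.asarray(seed, dtype=float).reshape(-1, 3)
        seed_desc = f"point {seed_pts[0].round(2).tolist()}"
    seed_vox = np.floor((seed_pts - lo) / spacing).astype(int)
    if np.any(seed_vox < 0) or np.any(seed_vox >= shape):
        raise CavityError("seed lies outside the analysis grid")
    seed_ids = set()
    any_free = False
    for v in seed_vox:
        lab = labels[v[0], v[1], v[2]]
        if free_small[v[0], v[1], v[2]]:
            any_free = True
        if lab > 0:
            seed_ids.add(int(lab))
    if not seed_ids:
        if not any_free:
            raise CavityError("seed voxel overlaps protein (no free voxel at seed)")
        raise CavityError("seed voxels lie outside the capped envelope (open pocket?)")
    # a ligand seed may touch several grid components; take their union
    comp = np.isin(labels, list(seed_ids))
    open_pocket = bool(
        comp[0].any() or comp[-1].any() or comp[:, 0].any() or comp[:, -1].any()
        or comp[:, :, 0].any() or comp[:, :, -1].any()
    )
    voxels = np.argwhere(comp)
    volume = float(len(voxels)) * spacing ** 3
    return CavityRegion(
        spacing=spacing, origin=lo + spacing / 2, grid_shape=tuple(shape),
        voxels=voxels, volume=volume, open_pocket=open_pocket,
        seed_description=seed_desc,
    )


def ligand_grid_volume(ligand_sel: AtomSet, spacing: float = 0.2,
                       radii: dict[str, float] | None = None,
                       name_overrides: dict[str, float] | None = None) -> float:
    """Volume (A^3) of the union of ligand vdW spheres on a grid.

    Union semantics: overlapping spheres are counted once.
    """
    if spacing <= 0:
        raise CavityError("spacing must be positive")
    centers = ligand_sel.coords
    if centers.size == 0:
        raise CavityError("empty ligand selection")
    atom_radii = np.array([vdw_radius(a, radii, name_overrides) for a in ligand_sel.atoms])
    margin = atom_radii.max() + 2 * spacing
    lo = centers.min(axis=0) - margin
    hi = centers.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int)
    mask = _blocked_mask(shape, lo, spacing, centers, atom_radii)
    return float(mask.sum()) * spacing ** 3


@dataclass
class OccupancyResult:
    fraction: float
    occupied_volume: float
    total_volume: float
    per_ligand_occupied: list[float] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "total_volume_A3": self.total_volume,
            "occupied_volume_A3": self.occupied_volume,
            "fraction": self.fraction,
            "per_ligand_occupied_A3": self.per_ligand_occupied,
        }


def occupancy_fraction(cavity: CavityRegion, ligands: list[AtomSet],
                       radii: dict[str, float] | None = None,
                       name_overrides: dict[str, float] | None = None) -> OccupancyResult:
    """Fraction of cavity voxels inside the ligands' vdW union.

    Rasterization happens on the cavity's own grid, so
    fraction x total volume = occupied volume exactly.
    """
    shape = np.array(cavity.grid_shape)
    lo = cavity.origin - cavity.spacing / 2
    cav_mask = cavity.mask()
    union = np.zeros(tuple(shape), dtype=bool)
    per_ligand = []
    for lig in ligands:
        if len(lig) == 0:
            per_ligand.append(0.0)
            continue
        rads = np.array([vdw_radius(a, radii, name_overrides) for a in lig.atoms])
        m = _blocked_mask(shape, lo, cavity.spacing, lig.coords, rads)
        per_ligand.append(float((m & cav_mask).sum()) * cavity.spacing ** 3)
        union |= m
    occupied_voxels = int((union & cav_mask).sum())
    total_voxels = int(cav_mask.sum())
    occupied = occupied_voxels * cavity.spacing ** 3
    fraction = occupied_voxels / total_voxels if total_voxels else 0.0
    return OccupancyResult(fraction=float(fraction), occupied_volume=occupied,
                           total_volume=cavity.volume, per_ligand_occupied=per_ligand)
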