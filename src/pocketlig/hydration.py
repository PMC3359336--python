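"""First-shell water counting and time-averaged occupancy density maps.

The hydration number of a solute group (e.g. a fatty-acid carboxylate) is
the count of distinct water molecules whose oxygen lies within a cutoff of
any solute atom; 3.5 A is the conventional first-shell water-oxygen bound
and the default. Density maps record, per voxel, the fraction of frames in
which any selected atom occupies it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure import AtomSet, Trajectory

__all__ = [
    "HydrationSeries",
    "DensityMap",
    "hydration_count",
    "hydration_series",
    "pooled_hydration_mean",
    "occupancy_density",
]


def hydration_count(frame: np.ndarray, solute_sel: AtomSet, water_sel: AtomSet,
                    cutoff: float = 3.5) -> int:
    """Distinct waters with oxygen within ``cutoff`` of any solute atom.

    ``water_sel`` must hold one oxygen per water molecule; a water close to
    several solute atoms counts once.
    """
    if cutoff <= 0:
        return 0
    frame = np.asarray(frame, dtype=float)
    solute = frame[solute_sel.indices]
    waters = frame[water_sel.indices]
    if solute.size == 0 or waters.size == 0:
        return 0
    tree = cKDTree(solute)
    d, _ = tree.query(waters, k=1, distance_upper_bound=cutoff)
    return int(np.sum(np.isfinite(d) & (d <= cutoff)))


@dataclass
class HydrationSeries:
    per_frame_counts: np.ndarray
    mean: float
    site_label: str = ""

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("frame\tcount\n")
            for k, c in enumerate(self.per_frame_counts):
                fh.write(f"{k}\t{int(c)}\n")


def hydration_series(traj: Trajectory, solute_sel: AtomSet, water_sel: AtomSet,
                     cutoff: float = 3.5, site_label: str = "") -> HydrationSeries:
    counts = np.array([
        hydration_count(frame, solute_sel, water_sel, cutoff) for frame in traj.frames
    ])
    return HydrationSeries(counts, float(counts.mean()), site_label)


def pooled_hydration_mean(series: list[HydrationSeries]) -> float:
    """Frame-count-weighted mean over independent trajectories."""
    total = sum(s.per_frame_counts.sum() for s in series)
    n = sum(s.per_frame_counts.size for s in series)
    if n == 0:
        raise ValueError("no frames in any series")
    return float(total / n)


@dataclass
class DensityMap:
    """Per-voxel occupancy fraction in [0, 1] on a regular grid."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # 3-D array of fractions
    n_clipped: int = 0  # atom placements falling outside the given bounds

    def to_dx(self, path: str) -> None:
        nx, ny, nz = self.values.shape
        with open(path, "w") as fh:
            fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
            fh.write(f"origin {self.origin[0]:.4f} {self.origin[1]:.4f} {self.origin[2]:.4f}\n")
            fh.write(f"delta {self.spacing:.4f} 0 0\n")
            fh.write(f"delta 0 {self.spacing:.4f} 0\n")
            fh.write(f"delta 0 0 {self.spacing:.4f}\n")
            fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
            fh.write(f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n")
            flat = self.values.ravel(order="C")
            for i in range(0, flat.size, 3):
                fh.write(" ".join(f"{v:.6f}" for v in flat[i:i + 3]) + "\n")
            fh.write('attribute "dep" string "positions"\n')


def occupancy_density(traj: Trajectory, sel: AtomSet, spacing: float = 0.5,
                      bounds: tuple[np.ndarray, np.ndarray] | None = None,
                      mode: str = "center", dilate_radius: float = 1.4) -> DensityMap:
    """Fraction of frames in which any selected atom occupies each voxel.

    ``mode='center'`` marks the voxel containing each atom center;
    ``mode='vdw'`` marks every voxel within ``dilate_radius`` of it.
    With explicit ``bounds`` atoms outside are counted in ``n_clipped``
    rather than silently dropped.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if mode not in ("center", "vdw"):
        raise ValueError(f"unknown mode {mode!r}")
    pts = traj.frames[:, sel.indices, :]
    if bounds is None:
        lo = pts.reshape(-1, 3).min(axis=0) - spacing
        hi = pts.reshape(-1, 3).max(axis=0) + spacing
    else:
        lo, hi = (np.asarray(bounds[0], float), np.asarray(bounds[1], float))
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    hits = np.zeros(tuple(shape), dtype=np.int64)
    n_clipped = 0
    rad_vox = int(np.ceil(dilate_radius / spacing)) if mode == "vdw" else 0
    for frame_pts in pts:
        vox = np.floor((frame_pts - lo) / spacing).astype(int)
        inside = np.all((vox >= 0) & (vox < shape), axis=1)
        n_clipped += int((~inside).sum())
        marked = np.zeros(tuple(shape), dtype=bool)
        if mode == "center":
            v = vox[inside]
            marked[v[:, 0], v[:, 1], v[:, 2]] = True
        else:
            for p in frame_pts:
                _mark_sphere(marked, p, lo, spacing, dilate_radius, rad_vox)
        hits += marked
    values = hits / traj.n_frames
    return DensityMap(origin=lo + spacing / 2, spacing=spacing, values=values,
                      n_clipped=n_clipped)


def _mark_sphere(marked: np.ndarray, center: np.ndarray, lo: np.ndarray,
                 spacing: float, radius: float, rad_vox: int) -> None:
    shape = np.array(marked.shape)
    cvox = np.floor((center - lo) / spacing).astype(int)
    lo_v = np.maximum(cvox - rad_vox - 1, 0)
    hi_v = np.minimum(cvox + rad_vox + 2, shape)
    if np.any(lo_v >= hi_v):
        return
    ax = [lo[d] + spacing * (np.arange(lo_v[d], hi_v[d]) + 0.5) - center[d] for d in range(3)]
    d2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
          + ax[2][None, None, :] ** 2)
    sub = marked[lo_v[0]:hi_v[0], lo_v[1]:hi_v[1], lo_v[2]:hi_v[2]]
    sub |= d2 <= radius ** 2
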