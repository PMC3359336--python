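"""Rigid-body superposition, RMSD statistics and neighbor search.

These primitives underpin every distance-based analysis in the package:
least-squares (Kabsch) superposition with optional per-atom weights,
fit-one-selection/measure-another RMSD series over trajectories, histogram
plus modality calls for RMSD distributions, and an exact fixed-radius
neighbor search with optional minimum-image periodicity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.mixture import GaussianMixture

from .structure import AtomSet, Structure, Trajectory

__all__ = [
    "SuperpositionResult",
    "RMSDDistribution",
    "kabsch_superpose",
    "rmsd_series",
    "rmsd_distribution",
    "neighbor_pairs",
]


@dataclass
class SuperpositionResult:
    """Least-squares rigid transform mapping mobile onto reference."""

    rotation: np.ndarray   # 3x3 proper orthonormal
    translation: np.ndarray  # Angstrom
    rmsd: float            # Angstrom

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Optimal weighted rigid superposition of ``mobile`` onto ``reference``.

    Reflections are excluded: the returned rotation always has determinant
    +1, so the minimum is over proper rotations only.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3) with equal n")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"superposition underdetermined with {n} < 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be nonnegative with positive sum")
    wsum = w.sum()
    mc = (w[:, None] * mobile).sum(axis=0) / wsum
    rc = (w[:, None] * reference).sum(axis=0) / wsum
    x = mobile - mc
    y = reference - rc
    h = (w[:, None] * x).T @ y
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = x @ rot.T - y
    rmsd = float(np.sqrt((w * np.einsum("ij,ij->i", diff, diff)).sum() / wsum))
    translation = rc - rot @ mc
    return SuperpositionResult(rotation=rot, translation=translation, rmsd=rmsd)


def _plain_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(np.einsum("ij,ij->i", d, d).mean()))


def rmsd_series(traj: Trajectory, analyze_sel: AtomSet, fit_sel: AtomSet,
                reference: Structure) -> np.ndarray:
    """Per-frame RMSD of ``analyze_sel`` after fitting each frame on ``fit_sel``.

    The fit-then-measure convention: each frame is superposed onto the
    reference using the fit selection only, then the RMSD of the analyze
    selection is taken *without refitting* — e.g. fit on protein, measure
    ligand mobility within its site. Pass the same set for both to get the
    conventional fitted RMSD.
    """
    if len(analyze_sel) == 0 or len(fit_sel) == 0:
        raise ValueError("selections must be nonempty")
    if reference.n_atoms != traj.topology.n_atoms:
        raise ValueError(
            f"reference has {reference.n_atoms} atoms but trajectory topology has "
            f"{traj.topology.n_atoms}; atom-matched structures required"
        )
    ref = reference.coords
    ref_fit = ref[fit_sel.indices]
    ref_ana = ref[analyze_sel.indices]
    out = np.empty(traj.n_frames)
    for k, frame in enumerate(traj.frames):
        sup = kabsch_superpose(frame[fit_sel.indices], ref_fit)
        out[k] = _plain_rmsd(sup.apply(frame[analyze_sel.indices]), ref_ana)
    return out


@dataclass
class RMSDDistribution:
    """Histogram plus a uni/multimodality call for an RMSD sample.

    Modality is decided by comparing 1- vs 2-component Gaussian mixtures by
    BIC; the two-component model must win by at least ``bic_margin`` to be
    called multimodal (a biphasic distribution indicating two average
    positions).
    """

    samples: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray
    modality: str                      # "unimodal" | "multimodal"
    component_means: list[float]
    mean: float
    sd: float

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("bin_left\tbin_right\tcount\n")
            for lo, hi, c in zip(self.bin_edges[:-1], self.bin_edges[1:], self.counts):
                fh.write(f"{lo:.6f}\t{hi:.6f}\t{int(c)}\n")

    def summary(self) -> dict:
        return {
            "n": int(len(self.samples)),
            "mean": self.mean,
            "sd": self.sd,
            "modality": self.modality,
            "component_means": self.component_means,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=1)


def rmsd_distribution(samples, n_bins: int = 50, bic_margin: float = 10.0) -> RMSDDistribution:
    """Histogram an RMSD sample over [0, max] and call its modality."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    hi = float(samples.max())
    if hi <= 0:
        hi = 1.0
    counts, edges = np.histogram(samples, bins=n_bins, range=(0.0, hi))
    # sort for order-invariance of the (seeded) mixture fit
    x = np.sort(samples)[:, None]
    fits = {}
    for k in (1, 2):
        gm = GaussianMixture(n_components=k, n_init=3, random_state=0,
                             covariance_type="full", reg_covar=1e-8)
        gm.fit(x)
        fits[k] = (gm.bic(x), gm)
    multimodal = fits[1][0] - fits[2][0] >= bic_margin
    if multimodal:
        means = sorted(float(m) for m in fits[2][1].means_.ravel())
    else:
        means = [float(fits[1][1].means_.ravel()[0])]
    return RMSDDistribution(
        samples=samples,
        bin_edges=edges,
        counts=counts,
        modality="multimodal" if multimodal else "unimodal",
        component_means=means,
        mean=float(samples.mean()),
        sd=float(samples.std(ddof=1)),
    )


def neighbor_pairs(coords_a: np.ndarray, coords_b: np.ndarray, cutoff: float,
                   box: np.ndarray | None = None) -> list[tuple[int, int, float]]:
    """All cross pairs (i from a, j from b) with distance <= cutoff.

    With ``box`` given, distances are minimum-image under an orthorhombic
    box; the cutoff must not exceed half the smallest box length.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if a.size == 0 or b.size == 0:
        return []
    if box is not None:
        box = np.asarray(box, dtype=float)
        if np.any(cutoff > box / 2):
            raise ValueError(
                f"cutoff {cutoff} exceeds half the smallest box length {box.min() / 2}"
            )
        aw = np.mod(a, box)
        bw = np.mod(b, box)
        ta = cKDTree(aw, boxsize=box)
        tb = cKDTree(bw, boxsize=box)
    else:
        ta = cKDTree(a)
        tb = cKDTree(b)
    pairs = []
    for i, js in enumerate(ta.query_ball_tree(tb, cutoff)):
        for j in js:
            delta = a[i] - b[j]
            if box is not None:
                delta -= box * np.round(delta / box)
            d = float(np.sqrt(delta @ delta))
            if d <= cutoff:
                pairs.append((i, int(j), d))
    pairs.sort(key=lambda p: (p[0], p[1]))
    return pairs
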