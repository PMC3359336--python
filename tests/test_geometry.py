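"""Superposition, RMSD statistics and neighbor search against brute force."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import pocketlig as pl
from pocketlig import synthetic as syn


def brute_force_min_rmsd(mobile, reference, n_coarse=24, refinements=4):
    """Independent oracle: grid search over Euler angles, refined locally.

    Centroids are aligned analytically; only the rotation is searched.
    """
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_for(angles):
        rots = Rotation.from_euler("zyz", angles).as_matrix()
        moved = np.einsum("rij,nj->rni", rots, mob)
        d = moved - ref
        return np.sqrt(np.einsum("rni,rni->r", d, d) / mob.shape[0])

    grid1 = np.linspace(0, 2 * np.pi, n_coarse, endpoint=False)
    grid2 = np.linspace(0, np.pi, n_coarse // 2 + 1)
    angles = np.array(np.meshgrid(grid1, grid2, grid1)).reshape(3, -1).T
    vals = rmsd_for(angles)
    best = angles[np.argmin(vals)]
    step = 2 * np.pi / n_coarse
    for _ in range(refinements):
        offs = np.linspace(-step, step, 9)
        local = np.array(np.meshgrid(best[0] + offs, best[1] + offs,
                                     best[2] + offs)).reshape(3, -1).T
        v = rmsd_for(local)
        best = local[np.argmin(v)]
        step /= 4.0
    return float(rmsd_for(best[None, :])[0])


def test_identity_superposition():
    pts = np.random.default_rng(0).normal(size=(6, 3))
    sup = pl.kabsch_superpose(pts, pts)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
    assert sup.rotation == pytest.approx(np.eye(3), abs=1e-10)


def test_exact_recovery_of_rigid_transform():
    pts = np.random.default_rng(1).normal(size=(8, 3))
    rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    shift = np.array([1.0, 2.0, 3.0])
    ref = pts @ rot.T + shift
    sup = pl.kabsch_superpose(pts, ref)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
    assert sup.rotation == pytest.approx(rot, abs=1e-9)
    assert sup.apply(pts) == pytest.approx(ref, abs=1e-9)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_kabsch_matches_rotation_grid_oracle(seed):
    rng = np.random.default_rng(seed)
    mobile = rng.normal(size=(5, 3))
    reference = rng.normal(size=(5, 3))
    analytic = pl.kabsch_superpose(mobile, reference).rmsd
    oracle = brute_force_min_rmsd(mobile, reference)
    assert analytic == pytest.approx(oracle, abs=1e-3)
    assert analytic <= oracle + 1e-9  # the SVD optimum can never be worse


def test_kabsch_underdetermined_and_weights():
    with pytest.raises(ValueError, match="underdetermined"):
        pl.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(6, 3))
    ref = pts.copy()
    ref[0] += 5.0  # one outlier
    w = np.array([0.0, 1, 1, 1, 1, 1.0])
    sup = pl.kabsch_superpose(pts, ref, weights=w)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-10)  # outlier carries no weight


def test_rmsd_symmetry_and_rigid_invariance():
    rng = np.random.default_rng(7)
    a = rng.normal(size=(10, 3))
    b = a + rng.normal(scale=0.3, size=(10, 3))
    r_ab = pl.kabsch_superpose(a, b).rmsd
    r_ba = pl.kabsch_superpose(b, a).rmsd
    assert r_ab == pytest.approx(r_ba, abs=1e-10)
    rot = Rotation.from_euler("xyz", [0.3, -1.2, 2.2]).as_matrix()
    shift = np.array([4.0, -2.0, 9.0])
    r_moved = pl.kabsch_superpose(a @ rot.T + shift, b @ rot.T + shift).rmsd
    assert r_moved == pytest.approx(r_ab, abs=1e-9)


# ---------------------------------------------------------------------------
# rmsd_series

def test_rmsd_series_zero_cases(binding_site):
    st, _ = binding_site
    traj = pl.Trajectory(st, np.repeat(st.coords[None], 5, axis=0))
    lig = st.select("resname MCA and resnum 601")
    prot = st.select("not hetero")
    assert pl.rmsd_series(traj, lig, prot, st) == pytest.approx(np.zeros(5), abs=1e-10)
    # rigid shift removed by fitting when fit_sel == analyze_sel
    shifted = traj.frames + np.array([10.0, 0, 0])
    traj2 = pl.Trajectory(st, shifted)
    assert pl.rmsd_series(traj2, prot, prot, st) == pytest.approx(np.zeros(5), abs=1e-9)


def test_gaussian_displacement_mean_square_rmsd(binding_site):
    """Isotropic sigma displacements give E[RMSD^2] = 3 sigma^2."""
    st, _ = binding_site
    sigma, n_frames = 0.5, 2000
    lig = st.select("resname MCA and resnum 601")
    traj, truth = syn.make_displacement_trajectory(st, sigma, n_frames, seed=11,
                                                   displace_sel=lig)
    series = pl.rmsd_series(traj, lig, st.select("not hetero"), st)
    mean_sq = float((series ** 2).mean())
    assert truth["expected_mean_square_rmsd_A2"] == pytest.approx(0.75)
    # 3 sigma^2 = 0.75 A^2 within Monte-Carlo error (se ~ 0.004 at n=2000)
    assert mean_sq == pytest.approx(0.75, abs=0.02)


# ---------------------------------------------------------------------------
# rmsd_distribution

def test_distribution_unimodal_and_counts(rng):
    samples = np.abs(rng.normal(1.0, 0.1, size=1000))
    dist = pl.rmsd_distribution(samples, n_bins=40)
    assert dist.modality == "unimodal"
    assert dist.counts.sum() == 1000
    assert np.all(np.diff(dist.bin_edges) > 0)


def test_planted_mixture_recovery(rng):
    samples = np.concatenate([rng.normal(0.5, 0.05, 500), rng.normal(2.0, 0.05, 500)])
    dist = pl.rmsd_distribution(samples)
    assert dist.modality == "multimodal"
    lo, hi = dist.component_means
    assert lo == pytest.approx(0.5, abs=0.1)
    assert hi == pytest.approx(2.0, abs=0.1)


def test_modality_call_order_invariant(rng):
    samples = np.concatenate([rng.normal(0.5, 0.05, 300), rng.normal(2.0, 0.05, 300)])
    d1 = pl.rmsd_distribution(samples)
    d2 = pl.rmsd_distribution(rng.permutation(samples))
    assert d1.modality == d2.modality
    assert d1.component_means == pytest.approx(d2.component_means, abs=1e-6)


# ---------------------------------------------------------------------------
# neighbor search

def brute_pairs(a, b, cutoff, box=None):
    out = []
    for i in range(len(a)):
        for j in range(len(b)):
            d = a[i] - b[j]
            if box is not None:
                d = d - box * np.round(d / box)
            dist = np.sqrt(d @ d)
            if dist <= cutoff:
                out.append((i, j, dist))
    return out


def test_neighbor_pairs_simple_cases():
    a = np.array([[0.0, 0, 0]])
    b = np.array([[3.0, 0, 0]])
    assert pl.neighbor_pairs(a, b, 3.5) == [(0, 0, pytest.approx(3.0))]
    assert pl.neighbor_pairs(a, b, 2.5) == []


def test_neighbor_pairs_match_brute_force(rng):
    for trial in range(100):
        n = int(rng.integers(10, 60))
        a = rng.uniform(0, 30, size=(n, 3))
        b = rng.uniform(0, 30, size=(n, 3))
        box = np.array([30.0, 30.0, 30.0]) if trial % 2 else None
        got = pl.neighbor_pairs(a, b, 4.0, box=box)
        want = sorted(brute_pairs(a, b, 4.0, box), key=lambda p: (p[0], p[1]))
        assert [(i, j) for i, j, _ in got] == [(i, j) for i, j, _ in want]
        if got:
            dg = np.array([d for _, _, d in got])
            dw = np.array([d for _, _, d in want])
            assert np.abs(dg - dw).max() < 1e-6


def test_neighbor_pairs_periodic_cutoff_guard():
    with pytest.raises(ValueError, match="half"):
        pl.neighbor_pairs(np.zeros((1, 3)), np.ones((1, 3)), 20.0,
                          box=np.array([30.0, 30.0, 30.0]))
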