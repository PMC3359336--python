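"""Closed-form pair energies, brute-force equivalence and decomposition."""

import numpy as np
import pytest

import pocketlig as pl
from pocketlig import synthetic as syn
from pocketlig.energetics import (COULOMB_CONSTANT, FFParams, LJParams,
                                  decompose_energy, group_interaction_energy,
                                  pair_energy)
from pocketlig.structure import Trajectory


LJ1 = LJParams(epsilon=0.1, rmin=3.5)


def test_coulomb_closed_form():
    c, _ = pair_energy(1.0, -1.0, LJ1, LJ1, r=COULOMB_CONSTANT, switching="none")
    assert c == pytest.approx(-1.0)


def test_lj_at_rmin_and_sigma():
    _, lj = pair_energy(0.0, 0.0, LJ1, LJ1, r=3.5, switching="none")
    assert lj == pytest.approx(-0.1)
    sigma = 3.5 / 2 ** (1 / 6)
    _, lj0 = pair_energy(0.0, 0.0, LJ1, LJ1, r=sigma, switching="none")
    assert lj0 == pytest.approx(0.0, abs=1e-12)


def test_zero_beyond_cutoff_and_singularity():
    assert pair_energy(1.0, -1.0, LJ1, LJ1, r=12.001, cutoff=12.0) == (0.0, 0.0)
    with pytest.raises(ValueError, match="positive"):
        pair_energy(1.0, 1.0, LJ1, LJ1, r=0.0)


def test_sigma_convention_equivalent_to_rmin():
    ff_a, ff_b = FFParams(), FFParams()
    ff_a.add("LIG:Q1", 0.2, 0.15, 1.75, "rmin_half")        # rmin = 3.5
    ff_b.add("LIG:Q1", 0.2, 0.15, 3.5 / 2 ** (1 / 6), "sigma")
    assert ff_a._entries["LIG:Q1"][1].rmin == pytest.approx(
        ff_b._entries["LIG:Q1"][1].rmin)


def test_switching_continuous_at_cutoff():
    def max_jump(n_pts, switching):
        rs = np.linspace(9.0, 12.5, n_pts)
        vals = [sum(pair_energy(0.5, -0.5, LJ1, LJ1, r, cutoff=12.0,
                                switching=switching, switch_on=10.0)) for r in rs]
        return np.abs(np.diff(vals)).max()

    # switched energy vanishes approaching the cutoff...
    near = sum(pair_energy(0.5, -0.5, LJ1, LJ1, 12.0 - 1e-6, 12.0,
                           "switch", 10.0))
    assert near == pytest.approx(0.0, abs=1e-5)
    # ...and its largest grid jump shrinks with the grid (continuity),
    # whereas hard truncation keeps an O(1) step at the cutoff
    assert max_jump(4000, "switch") < 0.7 * max_jump(2000, "switch")
    assert max_jump(4000, "truncate") > 0.9 * max_jump(2000, "truncate")
    assert max_jump(2000, "truncate") > 1.0


def test_group_energy_matches_pair_and_splits_add():
    st, ff, truth = syn.make_charge_system(q1=0.5, q2=-0.5, r=5.0)
    lig, env = st.select("resname LIG"), st.select("resname ENV")
    e = group_interaction_energy(st.coords, lig, env, ff, switching="none")
    c, lj = pair_energy(0.5, -0.5, LJParams(0.1, 3.5), LJParams(0.1, 3.5), 5.0,
                        switching="none")
    assert e.coulomb == pytest.approx(c) and e.lj == pytest.approx(lj)


def test_group_additivity_over_disjoint_halves():
    st, ff, _ = syn.make_random_charge_system(n_atoms=40, seed=1)
    lig = st.select("resname LIG")
    env = st.select("resname ENV")
    half_a = pl.AtomSet(st, env.indices[: len(env) // 2])
    half_b = pl.AtomSet(st, env.indices[len(env) // 2:])
    whole = group_interaction_energy(st.coords, lig, env, ff, cutoff=10.0)
    ea = group_interaction_energy(st.coords, lig, half_a, ff, cutoff=10.0)
    eb = group_interaction_energy(st.coords, lig, half_b, ff, cutoff=10.0)
    assert whole.total == pytest.approx(ea.total + eb.total, abs=1e-9)


def brute_force_energy(st, ff, lig, env, cutoff, switching="truncate"):
    ql = [ff.lookup(a) for a in lig.atoms]
    qe = [ff.lookup(a) for a in env.atoms]
    tot_c = tot_l = 0.0
    for (qi, li), pi in zip(ql, lig.coords):
        for (qj, lj_), pj in zip(qe, env.coords):
            r = float(np.linalg.norm(pi - pj))
            if switching != "none" and r >= cutoff:
                continue
            c, l = pair_energy(qi, qj, li, lj_, r, cutoff, switching)
            tot_c += c
            tot_l += l
    return tot_c, tot_l


@pytest.mark.parametrize("switching", ["truncate", "switch"])
def test_oracle_equivalence_on_random_systems(switching):
    """Neighbor-accelerated sums equal the O(N^2) loop to 1e-6 kcal/mol."""
    for seed in range(100):
        st, ff, _ = syn.make_random_charge_system(n_atoms=50, seed=seed)
        lig, env = st.select("resname LIG"), st.select("resname ENV")
        e = group_interaction_energy(st.coords, lig, env, ff, cutoff=8.0,
                                     switching=switching)
        c, l = brute_force_energy(st, ff, lig, env, 8.0, switching)
        assert abs(e.coulomb - c) < 1e-6
        assert abs(e.lj - l) < 1e-6


def test_energy_symmetric_under_selection_swap():
    st, ff, _ = syn.make_random_charge_system(n_atoms=30, seed=7)
    lig, env = st.select("resname LIG"), st.select("resname ENV")
    e1 = group_interaction_energy(st.coords, lig, env, ff, cutoff=10.0)
    e2 = group_interaction_energy(st.coords, env, lig, ff, cutoff=10.0)
    assert e1.total == pytest.approx(e2.total, abs=1e-9)


# ---------------------------------------------------------------------------
# decomposition

def _toy_decomposition(n_frames=1, seed=0):
    st, ff, _ = syn.make_random_charge_system(n_atoms=24, n_ligand=4, seed=seed)
    rng = np.random.default_rng(seed + 1)
    frames = np.repeat(st.coords[None], n_frames, axis=0)
    if n_frames > 1:
        frames[1:] += rng.normal(scale=0.05, size=frames[1:].shape)
    traj = Trajectory(st, frames)
    env = st.select("resname ENV")
    groups = {
        "protein": pl.AtomSet(st, env.indices[:10]),
        "water": pl.AtomSet(st, env.indices[10:]),
    }
    return traj, {"L1": st.select("resname LIG")}, groups, ff


def test_single_frame_decomposition_sd_zero():
    traj, ligs, groups, ff = _toy_decomposition(n_frames=1)
    dec = decompose_energy(traj, ligs, groups, ff, cutoff=10.0)
    m, s = dec.mean_sd("L1", "complete")
    assert s == 0.0
    mp, _ = dec.mean_sd("L1", "protein")
    mw, _ = dec.mean_sd("L1", "water")
    assert m == pytest.approx(mp + mw, abs=1e-9)


def test_complete_equals_group_sum_every_frame():
    traj, ligs, groups, ff = _toy_decomposition(n_frames=6)
    dec = decompose_energy(traj, ligs, groups, ff, cutoff=10.0)
    total = dec.series["L1"]["complete"]
    parts = dec.series["L1"]["protein"] + dec.series["L1"]["water"]
    assert np.abs(total - parts).max() < 1e-6
    # coulomb + lj breakdowns reassemble the total
    recon = dec.coulomb_series["L1"]["complete"] + dec.lj_series["L1"]["complete"]
    assert np.abs(total - recon).max() < 1e-9


def test_non_partition_groups_rejected():
    traj, ligs, groups, ff = _toy_decomposition()
    bad = {"protein": groups["protein"]}  # misses the water atoms
    with pytest.raises(ValueError, match="partition"):
        decompose_energy(traj, ligs, bad, ff)


def test_planted_alternating_series_statistics():
    # mean and n-1 sd of an alternating -100/-120 series
    s = np.array([-100.0, -120.0] * 10)
    assert s.mean() == pytest.approx(-110.0)
    assert s.std(ddof=1) == pytest.approx(10.2598, abs=1e-3)
    traj, ligs, groups, ff = _toy_decomposition(n_frames=4)
    dec = decompose_energy(traj, ligs, groups, ff, cutoff=10.0)
    m, sd = dec.mean_sd("L1", "complete")
    assert m == pytest.approx(dec.series["L1"]["complete"].mean())
    assert sd == pytest.approx(dec.series["L1"]["complete"].std(ddof=1))
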