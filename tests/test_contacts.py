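"""Contact maps, named polar distances and hydrogen-bond persistence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

import pocketlig as pl
from pocketlig import synthetic as syn
from pocketlig.contacts import HBondCriteria, detect_hbonds
from pocketlig.structure import Atom, Structure


def _two_atom_structure(d, el_a="O", el_b="O"):
    atoms = [
        Atom(1, "O1", el_a, "MCA", 601, "A", "", np.array([0.0, 0, 0]), 1.0, 10.0, True),
        Atom(2, "OH", el_b, "TYR", 473, "A", "", np.array([d, 0.0, 0]), 1.0, 10.0, False),
    ]
    return Structure(atoms)


def test_single_polar_contact():
    st = _two_atom_structure(2.9)
    recs = pl.contact_map(st, st.select("hetero"), st.select("not hetero"), cutoff=4.0)
    assert len(recs) == 1
    assert recs[0].distance == pytest.approx(2.9)
    assert recs[0].klass == "polar"


def test_apolar_classification_and_tiny_cutoff(binding_site):
    st = _two_atom_structure(2.9, el_b="C")
    recs = pl.contact_map(st, st.select("hetero"), st.select("not hetero"), cutoff=4.0)
    assert recs[0].klass == "apolar"
    model, _ = binding_site
    assert pl.contact_map(model, model.select("hetero"),
                          model.select("not hetero"), cutoff=0.1) == []


def test_overlapping_selections_rejected(binding_site):
    st, _ = binding_site
    with pytest.raises(ValueError, match="overlap"):
        pl.contact_map(st, st.select("hetero"), st.select("resname MCA"), 4.5)


def test_residue_summary_lists_planted_shell(binding_site):
    st, truth = binding_site
    recs = pl.contact_map(st, st.select("resname MCA and resnum 601"),
                          st.select("not hetero"), cutoff=4.5)
    summary = pl.contact_residue_summary(recs)
    found = set(summary["resnum"])
    # polar partners and the hydrophobic shell of site I all appear once
    assert {473, 449, 323, 289}.issubset(found)
    assert set(truth["hydrophobic_shell"]["site1"]).issubset(found)
    assert summary["resnum"].is_unique


def test_min_group_distance_translation():
    st = _two_atom_structure(5.0)
    d, (a, b) = pl.min_group_distance(st, st.select("hetero"), st.select("not hetero"))
    assert d == pytest.approx(5.0)
    assert (a.name, b.name) == ("O1", "OH")


def test_min_group_distance_reports_achieving_pair(binding_site):
    st, truth = binding_site
    sel = truth["selections"]["R288_NE_site3"]
    d, (_, partner) = pl.min_group_distance(st, st.select(sel["ligand"]),
                                            st.select(sel["partner"]))
    assert d == pytest.approx(3.87, abs=1e-6)
    assert partner.name == "NE" and partner.residue_number == 288


# ---------------------------------------------------------------------------
# hydrogen bonds

def test_heavy_atom_mode_distance_criterion():
    for d, n_expected in ((2.8, 1), (3.6, 0)):
        st = _two_atom_structure(d)
        bonds = detect_hbonds(st.coords, st, st.select("not hetero"),
                              st.select("hetero"), HBondCriteria(d_cut=3.5))
        assert len(bonds) == n_expected


def test_angle_criterion_rejects_bent_geometry():
    # D-H...A at 90 degrees: distance fine, angle fails
    atoms = [
        Atom(1, "OD", "O", "SER", 1, "A", "", np.array([0.0, 0, 0]), 1.0, 10.0, False),
        Atom(2, "HD", "H", "SER", 1, "A", "", np.array([1.0, 0, 0]), 1.0, 10.0, False),
        Atom(3, "OA", "O", "HOH", 2, "W", "", np.array([1.0, 2.8, 0]), 1.0, 10.0, True),
    ]
    st = Structure(atoms)
    donors, acceptors, hs = st.select("name OD"), st.select("name OA"), st.select("name HD")
    strict = detect_hbonds(st.coords, st, donors, acceptors,
                           HBondCriteria(3.5, 120.0, True), h_sel=hs)
    assert strict == []
    loose = detect_hbonds(st.coords, st, donors, acceptors,
                          HBondCriteria(3.5, 80.0, True), h_sel=hs)
    assert len(loose) == 1 and loose[0].angle == pytest.approx(90.0, abs=1e-6)


@pytest.mark.parametrize("fraction", [0.0, 0.6, 1.0])
def test_persistence_equals_planted_schedule(fraction):
    traj, truth = syn.make_hbond_trajectory(100, fraction, seed=5)
    top = traj.topology
    res = pl.hbond_persistence(traj, top.select(truth["donor_selection"]),
                               top.select(truth["acceptor_selection"]))
    assert res.fraction == pytest.approx(truth["persistence"])
    assert res.per_frame.tolist() == truth["schedule"]


def test_persistence_frame_order_invariant_and_monotone():
    traj, truth = syn.make_hbond_trajectory(60, 0.4, seed=9, schedule="random")
    top = traj.topology
    donors = top.select(truth["donor_selection"])
    acceptors = top.select(truth["acceptor_selection"])
    f1 = pl.hbond_persistence(traj, donors, acceptors).fraction
    shuffled = pl.Trajectory(top, traj.frames[::-1].copy())
    f2 = pl.hbond_persistence(shuffled, donors, acceptors).fraction
    assert f1 == f2 == pytest.approx(0.4)
    loose = pl.hbond_persistence(traj, donors, acceptors,
                                 HBondCriteria(d_cut=5.0)).fraction
    assert loose >= f1


@settings(deadline=None, max_examples=20, derandomize=True)
@given(d_cut=st_.floats(min_value=0.5, max_value=6.0))
def test_persistence_monotone_in_distance_cutoff(d_cut):
    traj, truth = syn.make_hbond_trajectory(40, 0.5, seed=2)
    top = traj.topology
    donors = top.select(truth["donor_selection"])
    acceptors = top.select(truth["acceptor_selection"])
    f = pl.hbond_persistence(traj, donors, acceptors, HBondCriteria(d_cut=d_cut)).fraction
    f_looser = pl.hbond_persistence(traj, donors, acceptors,
                                    HBondCriteria(d_cut=d_cut + 1.0)).fraction
    assert f_looser >= f
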