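"""PDB/xyz reading and writing, alt-loc policy, and the selection language."""

import numpy as np
import pytest

import pocketlig as pl
from pocketlig import synthetic as syn
from pocketlig.selection import SelectionError
from pocketlig.structure import (EmptyStructureError, PDBFormatError,
                                 TrajectoryError)

MINIMAL_ATOM = (
    "ATOM      1  CA  GLY A  12      11.104  13.207   9.005  1.00 23.45"
    "           C\n"
)


def test_single_atom_record_fields(tmp_path):
    p = tmp_path / "one.pdb"
    p.write_text(MINIMAL_ATOM)
    st = pl.read_structure(str(p))
    assert st.n_atoms == 1
    a = st.atoms[0]
    assert a.name == "CA" and a.residue_name == "GLY" and a.chain_id == "A"
    assert a.residue_number == 12
    assert a.b_factor == pytest.approx(23.45)
    assert a.position == pytest.approx([11.104, 13.207, 9.005])


def test_multi_model_count_conservation(tmp_path):
    lines = []
    for m in (1, 2):
        lines.append(f"MODEL     {m:4d}\n")
        for i in range(5):
            lines.append(
                f"ATOM  {i+1:5d}  CA  GLY A{i+1:4d}    "
                f"{float(i):8.3f}{float(m):8.3f}{0.0:8.3f}  1.00 10.00           C\n"
            )
        lines.append("ENDMDL\n")
    p = tmp_path / "mm.pdb"
    p.write_text("".join(lines))
    st = pl.read_structure(str(p))
    assert st.n_models == 2
    assert all(m.shape == (5, 3) for m in st.model_coords)


def test_altloc_keeps_highest_occupancy(tmp_path):
    p = tmp_path / "alt.pdb"
    p.write_text(
        "ATOM      1  CA AGLY A   1       0.000   0.000   0.000  0.60 10.00           C\n"
        "ATOM      2  CA BGLY A   1       1.000   0.000   0.000  0.40 10.00           C\n"
    )
    st = pl.read_structure(str(p))
    assert st.n_atoms == 1
    assert st.atoms[0].position[0] == pytest.approx(0.0)  # conformer A retained
    assert pl.read_structure(str(p), keep_alt="all").n_atoms == 2


def test_empty_and_malformed_inputs(tmp_path):
    empty = tmp_path / "empty.pdb"
    empty.write_text("REMARK nothing here\n")
    with pytest.raises(EmptyStructureError):
        pl.read_structure(str(empty))
    bad = tmp_path / "bad.pdb"
    bad.write_text(MINIMAL_ATOM.replace("11.104", "xx.xxx"))
    with pytest.raises(PDBFormatError, match="line 1"):
        pl.read_structure(str(bad))


def test_write_read_roundtrip(tmp_path, binding_site):
    st, _ = binding_site
    p = tmp_path / "rt.pdb"
    pl.write_structure(st, str(p))
    st2 = pl.read_structure(str(p))
    assert st2.n_atoms == st.n_atoms
    # PDB format precision: 3 decimals on coordinates, 2 on B
    assert np.abs(st2.coords - st.coords).max() <= 5.1e-4
    b1 = [a.b_factor for a in st.atoms]
    b2 = [a.b_factor for a in st2.atoms]
    assert np.abs(np.array(b1) - np.array(b2)).max() <= 5.1e-3


def test_xyz_frames_roundtrip_and_truncation(tmp_path):
    traj, _ = syn.make_hbond_trajectory(n_frames=12, persistence_fraction=0.5)
    p = tmp_path / "t.xyz"
    pl.write_trajectory(traj, str(p), "xyz-frames")
    back = pl.read_trajectory(traj.topology, str(p), "xyz-frames")
    assert back.n_frames == 12
    assert np.abs(back.frames - traj.frames).max() < 1e-9
    # frame 0 equal to topology -> zero RMSD trivially checkable
    text = p.read_text().splitlines()
    truncated = "\n".join(text[:-2])  # drop atoms from the final frame
    p2 = tmp_path / "trunc.xyz"
    p2.write_text(truncated)
    with pytest.raises(TrajectoryError, match="frame 11"):
        pl.read_trajectory(traj.topology, str(p2), "xyz-frames")


def test_trajectory_atom_count_mismatch(tmp_path):
    traj, _ = syn.make_hbond_trajectory(n_frames=3)
    p = tmp_path / "t.xyz"
    pl.write_trajectory(traj, str(p), "xyz-frames")
    smaller = traj.topology.subset(np.arange(traj.topology.n_atoms - 1))
    with pytest.raises(TrajectoryError, match="frame 0"):
        pl.read_trajectory(smaller, str(p), "xyz-frames")


# ---------------------------------------------------------------------------
# selection language

def test_selection_examples(binding_site):
    st, _ = binding_site
    tyr_oh = st.select("resnum 473 and name OH")
    assert len(tyr_oh) == 1 and tyr_oh.atoms[0].residue_name == "TYR"
    waters = st.select("resname HOH")
    assert len(waters) == 0  # no waters in this model
    mca = st.select("resname MCA")
    assert len(mca) == 3 * 11  # three C9 fatty acids: C1..C9 + O1 + O2


def test_selection_partition_and_algebra(binding_site):
    st, _ = binding_site
    het = st.select("hetero")
    not_het = st.select("not hetero")
    assert len(het) + len(not_het) == st.n_atoms
    assert het.isdisjoint(not_het)
    a = st.select("resname TYR")
    b = st.select("resname HIS")
    ab = st.select("resname TYR or resname HIS")
    assert set(a.union(b).indices) == set(ab.indices)
    both = st.select("resname TYR and resname HIS")
    assert len(both) == 0


def test_selection_ranges_and_errors(binding_site):
    st, _ = binding_site
    rng_sel = st.select("resnum 281:289 and not hetero")
    nums = {a.residue_number for a in rng_sel}
    assert nums == {281, 282, 285, 288, 289}
    with pytest.raises(SelectionError, match="position"):
        st.select("resname TYR and")
    with pytest.raises(SelectionError):
        st.select("bogus_keyword 5")
    with pytest.raises(SelectionError):
        st.select("(resname TYR")
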