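"""Protein-ligand contact maps, named polar distances and hydrogen bonds.

Contacts are heavy-atom proximities; a contact is *polar* when both atoms
are N, O or S. Hydrogen bonds default to a heavy-atom donor-acceptor
distance criterion (crystal structures carry no hydrogens); when hydrogens
are available an explicit D-H...A angle criterion is applied on top.
Persistence is the fraction of trajectory frames in which at least one
qualifying bond exists between the selections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import neighbor_pairs
from .structure import Atom, AtomSet, Structure, Trajectory

__all__ = [
    "ContactRecord",
    "HBond",
    "HBondCriteria",
    "PersistenceResult",
    "contact_map",
    "contact_residue_summary",
    "min_group_distance",
    "detect_hbonds",
    "hbond_persistence",
]

POLAR_ELEMENTS = {"N", "O", "S"}


@dataclass
class ContactRecord:
    ligand_atom: Atom
    protein_atom: Atom
    distance: float
    klass: str  # "polar" | "apolar"


@dataclass
class HBond:
    donor_heavy: Atom
    acceptor: Atom
    distance: float
    angle: float | None = None  # degrees; None in heavy-atom mode


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    Defaults are conventional first-shell values: donor-acceptor <= 3.5 A,
    and D-H...A >= 120 degrees when hydrogens are present.
    """

    d_cut: float = 3.5
    angle_cut: float = 120.0
    use_angle: bool = True


def contact_map(structure: Structure, ligand_sel: AtomSet, protein_sel: AtomSet,
                cutoff: float = 4.5) -> list[ContactRecord]:
    """All ligand-protein heavy-atom pairs within ``cutoff`` Angstrom."""
    if len(ligand_sel) == 0 or len(protein_sel) == 0:
        raise ValueError("selections must be nonempty")
    if not ligand_sel.isdisjoint(protein_sel):
        raise ValueError("ligand and protein selections overlap")
    records = []
    lig_atoms = ligand_sel.atoms
    prot_atoms = protein_sel.atoms
    for i, j, d in neighbor_pairs(ligand_sel.coords, protein_sel.coords, cutoff):
        la, pa = lig_atoms[i], prot_atoms[j]
        polar = la.element in POLAR_ELEMENTS and pa.element in POLAR_ELEMENTS
        records.append(ContactRecord(la, pa, d, "polar" if polar else "apolar"))
    return records


def contact_residue_summary(records: list[ContactRecord]) -> pd.DataFrame:
    """One row per contacted protein residue with its closest approach."""
    rows = []
    for r in records:
        p = r.protein_atom
        rows.append({
            "chain": p.chain_id,
            "resnum": p.residue_number,
            "resname": p.residue_name,
            "distance": r.distance,
            "klass": r.klass,
            "ligand_atom": r.ligand_atom.name,
            "protein_atom": p.name,
        })
    if not rows:
        return pd.DataFrame(columns=["chain", "resnum", "resname", "min_distance",
                                     "n_contacts", "any_polar"])
    df = pd.DataFrame(rows)
    grouped = df.groupby(["chain", "resnum", "resname"], as_index=False).agg(
        min_distance=("distance", "min"),
        n_contacts=("distance", "size"),
        any_polar=("klass", lambda s: bool((s == "polar").any())),
    )
    return grouped.sort_values(["chain", "resnum"]).reset_index(drop=True)


def min_group_distance(structure: Structure, sel_a: AtomSet,
                       sel_b: AtomSet) -> tuple[float, tuple[Atom, Atom]]:
    """Minimum cross distance between two selections and the achieving pair."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise ValueError("selections must be nonempty")
    ca, cb = sel_a.coords, sel_b.coords
    d2 = ((ca[:, None, :] - cb[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    return float(np.sqrt(d2[i, j])), (sel_a.atoms[int(i)], sel_b.atoms[int(j)])


def _hydrogens_for_donor(structure: Structure, frame: np.ndarray, donor_idx: int,
                         h_indices: np.ndarray) -> np.ndarray:
    # hydrogens covalently attached to the donor heavy atom (within 1.25 A)
    if h_indices.size == 0:
        return np.empty((0, 3))
    dpos = frame[donor_idx]
    hpos = frame[h_indices]
    dist = np.linalg.norm(hpos - dpos, axis=1)
    return hpos[dist <= 1.25]


def detect_hbonds(frame: np.ndarray, structure: Structure, donor_sel: AtomSet,
                  acceptor_sel: AtomSet, criteria: HBondCriteria | None = None,
                  h_sel: AtomSet | None = None) -> list[HBond]:
    """Hydrogen bonds between donor and acceptor heavy atoms in one frame.

    Heavy-atom mode (``h_sel`` None): a bond exists iff the donor-acceptor
    distance is within ``criteria.d_cut``. With hydrogens supplied and
    ``criteria.use_angle``, at least one attached H must additionally give a
    D-H...A angle >= ``criteria.angle_cut``.
    """
    criteria = criteria or HBondCriteria()
    if criteria.d_cut <= 0:
        raise ValueError("d_cut must be positive")
    frame = np.asarray(frame, dtype=float)
    bonds = []
    d_atoms, a_atoms = donor_sel.atoms, acceptor_sel.atoms
    h_idx = h_sel.indices if h_sel is not None else np.empty(0, dtype=int)
    for i, j, d in neighbor_pairs(frame[donor_sel.indices], frame[acceptor_sel.indices],
                                  criteria.d_cut):
        don_idx = int(donor_sel.indices[i])
        acc_idx = int(acceptor_sel.indices[j])
        if don_idx == acc_idx:
            continue
        angle: float | None = None
        if h_sel is not None and criteria.use_angle:
            hpos = _hydrogens_for_donor(structure, frame, don_idx, h_idx)
            if hpos.size == 0:
                continue
            dvec = frame[don_idx] - hpos
            avec = frame[acc_idx] - hpos
            cosang = np.einsum("ij,ij->i", dvec, avec) / (
                np.linalg.norm(dvec, axis=1) * np.linalg.norm(avec, axis=1))
            angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            best = float(angles.max())
            if best < criteria.angle_cut:
                continue
            angle = best
        bonds.append(HBond(d_atoms[i], a_atoms[j], d, angle))
    return bonds


@dataclass
class PersistenceResult:
    fraction: float
    per_frame: np.ndarray  # bool per frame

    def summary(self) -> dict:
        return {"fraction": self.fraction, "n_frames": int(self.per_frame.size),
                "n_bonded": int(self.per_frame.sum())}


def hbond_persistence(traj: Trajectory, donor_sel: AtomSet, acceptor_sel: AtomSet,
                      criteria: HBondCriteria | None = None,
                      h_sel: AtomSet | None = None) -> PersistenceResult:
    """Fraction of frames with >= 1 qualifying H-bond between the selections."""
    criteria = criteria or HBondCriteria()
    flags = np.zeros(traj.n_frames, dtype=bool)
    for k, frame in enumerate(traj.frames):
        flags[k] = bool(detect_hbonds(frame, traj.topology, donor_sel, acceptor_sel,
                                      criteria, h_sel))
    frac = float(flags.mean()) if flags.size else 0.0
    return PersistenceResult(fraction=frac, per_frame=flags)


def contacts_to_tsv(records: list[ContactRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("lig_chain\tlig_resnum\tlig_resname\tlig_atom\t"
                 "prot_chain\tprot_resnum\tprot_resname\tprot_atom\tdistance\tklass\n")
        for r in records:
            la, pa = r.ligand_atom, r.protein_atom
            fh.write(f"{la.chain_id}\t{la.residue_number}\t{la.residue_name}\t{la.name}\t"
                     f"{pa.chain_id}\t{pa.residue_number}\t{pa.residue_name}\t{pa.name}\t"
                     f"{r.distance:.3f}\t{r.klass}\n")
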