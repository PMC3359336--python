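"""Macromolecular structures, trajectories and atom sets.

Coordinates are in Angstrom throughout; residue numbering is author
numbering (the numbering crystallographers print, e.g. Tyr473 of the
PPARgamma ligand-binding domain). Structures may lack hydrogens — every
downstream analysis runs heavy-atom-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "AtomSet",
    "StructureError",
    "PDBFormatError",
    "EmptyStructureError",
    "TrajectoryError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
]

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL"}


class StructureError(Exception):
    """Base class for structure-handling failures."""


class PDBFormatError(StructureError):
    """A mandatory fixed-column PDB field could not be parsed."""


class EmptyStructureError(StructureError):
    """The file contained no ATOM/HETATM records."""


class TrajectoryError(StructureError):
    """Frame-level inconsistency while reading coordinate frames."""


@dataclass(eq=False)
class Atom:
    """One atom record (author numbering, Angstrom, B in A^2)."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    alt_loc: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(
                f"atom {self.serial} {self.name}: position must be a finite 3-vector"
            )
        if not (0.0 <= self.occupancy <= 1.0):
            raise StructureError(
                f"atom {self.serial} {self.name}: occupancy {self.occupancy} outside [0, 1]"
            )
        if self.b_factor < 0:
            raise StructureError(
                f"atom {self.serial} {self.name}: negative B-factor {self.b_factor}"
            )

    @property
    def key(self) -> tuple:
        return (self.chain_id, self.residue_number, self.name, self.alt_loc)


class Structure:
    """An ordered atom collection with one or more coordinate models.

    ``atoms`` carries the identity (names, residues, B-factors); model 0
    coordinates live on the atoms themselves, further models in
    ``model_coords``. When used as a trajectory topology all models share
    the atom ordering and count.
    """

    def __init__(self, atoms: list[Atom], model_coords: list[np.ndarray] | None = None,
                 title: str = "", resolution: float | None = None):
        self.atoms = list(atoms)
        base = np.array([a.position for a in self.atoms], dtype=float).reshape(-1, 3)
        if model_coords is None:
            model_coords = [base]
        self.model_coords = [np.asarray(m, dtype=float) for m in model_coords]
        for i, m in enumerate(self.model_coords):
            if m.shape != (len(self.atoms), 3):
                raise StructureError(
                    f"model {i}: expected {len(self.atoms)} atoms, got {m.shape[0]}"
                )
        self.title = title
        self.resolution = resolution
        seen: set[tuple] = set()
        for a in self.atoms:
            if a.key in seen:
                raise StructureError(f"duplicate atom key {a.key} within model")
            seen.add(a.key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_models(self) -> int:
        return len(self.model_coords)

    @property
    def coords(self) -> np.ndarray:
        """Model-0 coordinates, shape (n_atoms, 3)."""
        return self.model_coords[0]

    def select(self, expr: str) -> "AtomSet":
        from .selection import select_atoms

        return select_atoms(self, expr)

    def subset(self, indices: np.ndarray) -> "Structure":
        """New single-model Structure containing only the given atoms."""
        idx = np.asarray(indices, dtype=int)
        atoms = [replace(self.atoms[i], position=self.coords[i].copy()) for i in idx]
        return Structure(atoms, [self.coords[idx]], title=self.title,
                         resolution=self.resolution)

    def copy(self) -> "Structure":
        atoms = [replace(a, position=a.position.copy()) for a in self.atoms]
        return Structure(atoms, [m.copy() for m in self.model_coords],
                         title=self.title, resolution=self.resolution)


@dataclass
class AtomSet:
    """Ordered, unique atom indices into a parent Structure."""

    parent: Structure
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.parent.n_atoms):
            raise StructureError("AtomSet indices out of range")
        if len(np.unique(idx)) != len(idx):
            raise StructureError("AtomSet indices must be unique")
        self.indices = np.sort(idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return (self.parent.atoms[i] for i in self.indices)

    @property
    def atoms(self) -> list[Atom]:
        return [self.parent.atoms[i] for i in self.indices]

    @property
    def coords(self) -> np.ndarray:
        return self.parent.coords[self.indices]

    def coords_in(self, frame: np.ndarray) -> np.ndarray:
        return np.asarray(frame)[self.indices]

    def union(self, other: "AtomSet") -> "AtomSet":
        self._check_parent(other)
        return AtomSet(self.parent, np.union1d(self.indices, other.indices))

    def intersection(self, other: "AtomSet") -> "AtomSet":
        self._check_parent(other)
        return AtomSet(self.parent, np.intersect1d(self.indices, other.indices))

    def difference(self, other: "AtomSet") -> "AtomSet":
        self._check_parent(other)
        return AtomSet(self.parent, np.setdiff1d(self.indices, other.indices))

    def isdisjoint(self, other: "AtomSet") -> bool:
        return len(np.intersect1d(self.indices, other.indices)) == 0

    __or__ = union
    __and__ = intersection
    __sub__ = difference

    def _check_parent(self, other: "AtomSet") -> None:
        if other.parent is not self.parent:
            raise StructureError("AtomSet operands belong to different structures")


@dataclass
class Trajectory:
    """Coordinate frames over a fixed topology.

    ``frames`` has shape (n_frames, n_atoms, 3) in Angstrom; ``box`` is an
    optional orthorhombic box (3 positive lengths) enabling minimum-image
    distances downstream.
    """

    topology: Structure
    frames: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise TrajectoryError(
                f"frames shape {self.frames.shape} does not match topology "
                f"({self.topology.n_atoms} atoms)"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise TrajectoryError("box must be 3 positive lengths")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def __iter__(self):
        return iter(self.frames)


# ---------------------------------------------------------------------------
# PDB reading (gemmi-backed) and writing

def _validate_pdb_lines(path: str) -> int:
    """Cheap fixed-column validation so format errors name the line."""
    n_records = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            n_records += 1
            if len(line.rstrip("\n")) < 54:
                raise PDBFormatError(f"line {lineno}: record shorter than coordinate columns")
            for lo, hi, caster, what in (
                (6, 11, int, "serial"),
                (22, 26, int, "residue number"),
                (30, 38, float, "x"),
                (38, 46, float, "y"),
                (46, 54, float, "z"),
            ):
                text = line[lo:hi].strip()
                try:
                    caster(text)
                except ValueError:
                    raise PDBFormatError(
                        f"line {lineno}: unparseable {what} field {text!r}"
                    ) from None
            for lo, hi, what in ((54, 60, "occupancy"), (60, 66, "b-factor")):
                text = line[lo:hi].strip()
                if text:
                    try:
                        float(text)
                    except ValueError:
                        raise PDBFormatError(
                            f"line {lineno}: unparseable {what} field {text!r}"
                        ) from None
    return n_records


def _apply_altloc_policy(atoms: list[Atom], keep_alt: str) -> list[Atom]:
    if keep_alt == "all":
        return atoms
    groups: dict[tuple, list[Atom]] = {}
    order: list[tuple] = []
    for a in atoms:
        k = (a.chain_id, a.residue_number, a.residue_name, a.name)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(a)
    kept: list[Atom] = []
    for k in order:
        cands = groups[k]
        if len(cands) == 1:
            kept.append(cands[0])
            continue
        if keep_alt == "highest_occupancy":
            # highest occupancy wins; alphabetical alt_loc breaks ties
            best = min(cands, key=lambda a: (-a.occupancy, a.alt_loc))
        elif keep_alt == "first":
            best = cands[0]
        elif len(keep_alt) == 1:
            matching = [a for a in cands if a.alt_loc in ("", keep_alt)]
            best = matching[0] if matching else min(cands, key=lambda a: (-a.occupancy, a.alt_loc))
        else:
            raise ValueError(f"unknown alt-loc policy {keep_alt!r}")
        best = replace(best, alt_loc="", position=best.position.copy())
        kept.append(best)
    return kept


def read_structure(path: str, keep_alt: str = "highest_occupancy") -> Structure:
    """Read a PDB file into a Structure.

    ``keep_alt`` controls alternate-location handling: ``highest_occupancy``
    (default; ties broken alphabetically), ``first``, ``all``, or a single
    conformer letter.
    """
    n_records = _validate_pdb_lines(path)
    if n_records == 0:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
    st = gemmi.read_pdb(str(path))
    models: list[list[Atom]] = []
    for model in st:
        atoms: list[Atom] = []
        for chain in model:
            for res in chain:
                het = res.het_flag == "H"
                for ga in res:
                    atoms.append(Atom(
                        serial=ga.serial,
                        name=ga.name,
                        element=ga.element.name.upper(),
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        alt_loc=ga.altloc if ga.altloc != "\x00" else "",
                        position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(max(ga.occ, 0.0), 1.0),
                        b_factor=max(ga.b_iso, 0.0),
                        is_hetero=het,
                    ))
        models.append(_apply_altloc_policy(atoms, keep_alt))
    if not models or not models[0]:
        raise EmptyStructureError(f"{path}: no atoms survived parsing")
    base = models[0]
    coords = [np.array([a.position for a in m]) for m in models]
    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    return Structure(base, coords, title=st.name or "", resolution=resolution)


def _pdb_atom_name(name: str, element: str) -> str:
    # PDB alignment: 1-char elements start in column 14 unless 4 chars long
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3s}"
    return f"{name:<4s}"


def write_structure(structure: Structure, path: str) -> None:
    """Write fixed-column PDB (coordinates to 3 decimals, B to 2)."""
    multi = structure.n_models > 1
    with open(path, "w") as fh:
        if structure.title:
            fh.write(f"TITLE     {structure.title[:60]}\n")
        for m, coords in enumerate(structure.model_coords):
            if multi:
                fh.write(f"MODEL     {m + 1:4d}\n")
            for a, pos in zip(structure.atoms, coords):
                record = "HETATM" if a.is_hetero else "ATOM  "
                fh.write(
                    f"{record}{a.serial % 100000:5d} {_pdb_atom_name(a.name, a.element)}"
                    f"{a.alt_loc or ' '}{a.residue_name:>3s} {a.chain_id[:1]}"
                    f"{a.residue_number % 10000:4d}    "
                    f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}"
                    f"{a.occupancy:6.2f}{a.b_factor:6.2f}          "
                    f"{a.element:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectories

def _read_xyz_frames(path: str, n_atoms: int) -> np.ndarray:
    frames: list[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError:
            raise TrajectoryError(
                f"frame {frame_idx}: expected atom count, got {lines[pos]!r}"
            ) from None
        if count != n_atoms:
            raise TrajectoryError(
                f"frame {frame_idx}: atom count {count} does not match topology ({n_atoms})"
            )
        if pos + 2 + count > len(lines):
            raise TrajectoryError(f"frame {frame_idx}: truncated (expected {count} atom lines)")
        block = lines[pos + 2: pos + 2 + count]
        coords = np.empty((count, 3))
        for i, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise TrajectoryError(f"frame {frame_idx}: malformed atom line {line!r}")
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(coords)
        pos += 2 + count
        frame_idx += 1
    if not frames:
        raise TrajectoryError(f"{path}: no frames found")
    return np.array(frames)


def read_trajectory(topology: Structure, path: str, format: str = "multimodel-pdb",
                    box: np.ndarray | None = None) -> Trajectory:
    """Read coordinate frames against a fixed topology.

    ``format`` is ``multimodel-pdb`` (MODEL/ENDMDL blocks) or ``xyz-frames``
    (repeated ``N\\ncomment\\nelement x y z`` blocks).
    """
    if format == "multimodel-pdb":
        st = read_structure(path, keep_alt="all")
        for k, m in enumerate(st.model_coords):
            if m.shape[0] != topology.n_atoms:
                raise TrajectoryError(
                    f"frame {k}: atom count {m.shape[0]} does not match topology "
                    f"({topology.n_atoms})"
                )
        frames = np.array(st.model_coords)
    elif format == "xyz-frames":
        frames = _read_xyz_frames(path, topology.n_atoms)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return Trajectory(topology, frames, box=box)


def write_trajectory(traj: Trajectory, path: str, format: str = "xyz-frames") -> None:
    if format == "xyz-frames":
        with open(path, "w") as fh:
            for k, frame in enumerate(traj.frames):
                fh.write(f"{traj.topology.n_atoms}\n")
                fh.write(f"frame {k}\n")
                for a, pos in zip(traj.topology.atoms, frame):
                    fh.write(f"{a.element:<2s} {pos[0]:12.6f} {pos[1]:12.6f} {pos[2]:12.6f}\n")
    elif format == "multimodel-pdb":
        st = Structure(traj.topology.atoms, list(traj.frames), title=traj.topology.title)
        write_structure(st, path)
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
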