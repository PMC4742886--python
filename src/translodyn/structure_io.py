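"""Structures, atom groups and trajectories.

All coordinates are Cartesian, in Angstrom. Structures are ordered atom
tables; trajectories are stacks of coordinate frames sharing a parent
structure's atom order. PDB reading/writing is delegated to biotite; the
native trajectory format is a columnar TSV (frame, time, atom_index,
x, y, z) chosen for exactness and diffability at desk scale.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile


class StructureError(ValueError):
    """Malformed structure, file or selection."""


class SelectionError(StructureError):
    """A selection expression resolved to no atoms or failed to parse."""


@dataclass
class Structure:
    """An ordered set of atoms with identities and coordinates.

    Attributes
    ----------
    atom_names, elements, res_names, chain_ids : object ndarray of str
    res_ids : int ndarray
        Residue numbering is taken verbatim from the input file.
    coords : (n_atoms, 3) float ndarray, Angstrom
    model_id : int
    """

    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    coords: np.ndarray
    model_id: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        for arr_name in ("elements", "res_ids", "res_names", "chain_ids"):
            if len(getattr(self, arr_name)) != n:
                raise StructureError(f"{arr_name} length != atom count {n}")
        if self.coords.shape != (n, 3):
            raise StructureError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        keys = list(zip(self.chain_ids, self.res_ids, self.atom_names))
        if len(set(keys)) != n:
            raise StructureError("duplicate (chain, residue, atom name) triple")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure carrying new coordinates."""
        return Structure(self.atom_names, self.elements, self.res_ids,
                         self.res_names, self.chain_ids,
                         np.array(coords, dtype=float), self.model_id)

    def same_atoms(self, other: "Structure") -> bool:
        return (self.n_atoms == other.n_atoms
                and all(np.array_equal(getattr(self, f), getattr(other, f))
                        for f in ("atom_names", "res_ids", "res_names", "chain_ids")))


@dataclass
class AtomGroup:
    """A named, ordered, duplicate-free list of atom indices into a Structure."""

    name: str
    members: np.ndarray

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=int)
        if len(np.unique(self.members)) != len(self.members):
            raise StructureError(f"group {self.name!r} has duplicate indices")
        if len(self.members) and self.members.min() < 0:
            raise StructureError(f"group {self.name!r} has negative indices")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Trajectory:
    """Coordinate frames over a fixed atom set, with reduced-time stamps."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    times: np.ndarray   # (n_frames,), strictly increasing

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructureError("frames must have shape (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.frames):
            raise StructureError("times length != frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise StructureError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# PDB I/O


def _scan_pdb_lines(path: Path) -> None:
    """Pre-validate coordinate fields of ATOM/HETATM records.

    Gives a parse error that names the offending line, which biotite's
    vectorised reader does not.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fieldtxt = line[lo:hi].strip()
                    try:
                        float(fieldtxt)
                    except ValueError:
                        raise StructureError(
                            f"{path}: malformed coordinate field {fieldtxt!r} "
                            f"on line {lineno}") from None


def _atom_array_to_structure(arr: bst.AtomArray, model_id: int) -> Structure:
    return Structure(
        atom_names=np.asarray(arr.atom_name, dtype=object),
        elements=np.asarray(arr.element, dtype=object),
        res_ids=np.asarray(arr.res_id, dtype=int),
        res_names=np.asarray(arr.res_name, dtype=object),
        chain_ids=np.asarray(arr.chain_id, dtype=object),
        coords=np.asarray(arr.coord, dtype=float),
        model_id=model_id,
    )


def read_pdb_models(path: str | Path) -> list[Structure]:
    """Read every MODEL of a PDB file as a separate :class:`Structure`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise StructureError(f"{path}: empty file")
    _scan_pdb_lines(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise StructureError(f"{path}: no ATOM/HETATM records")
    out = []
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m, altloc="first")
        out.append(_atom_array_to_structure(arr, model_id=m))
    return out


def read_pdb(path: str | Path) -> Structure:
    """Read the first model of a PDB file."""
    return read_pdb_models(path)[0]


def write_pdb(structure: Structure | list[Structure], path: str | Path) -> None:
    """Write one structure (or a list, as MODEL blocks) in fixed-column PDB v3."""
    structures = [structure] if isinstance(structure, Structure) else list(structure)
    arrays = []
    for s in structures:
        for nm, width, what in ((s.atom_names, 4, "atom name"),
                                (s.res_names, 4, "residue name"),
                                (s.chain_ids, 1, "chain id")):
            too_long = [str(v) for v in nm if len(str(v)) > width]
            if too_long:
                raise StructureError(
                    f"{what} {too_long[0]!r} exceeds PDB column width {width}")
        arr = bst.AtomArray(s.n_atoms)
        arr.atom_name = np.asarray(s.atom_names, dtype="U6")
        arr.element = np.asarray(s.elements, dtype="U2")
        arr.res_id = np.asarray(s.res_ids, dtype=int)
        arr.res_name = np.asarray(s.res_names, dtype="U5")
        arr.chain_id = np.asarray(s.chain_ids, dtype="U4")
        arr.coord = np.asarray(s.coords, dtype=np.float32)
        arr.hetero = np.zeros(s.n_atoms, dtype=bool)
        arrays.append(arr)
    pdb = PDBFile()
    if len(arrays) == 1:
        pdb.set_structure(arrays[0])
    else:
        pdb.set_structure(bst.stack(arrays))
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Selections
#
# Grammar (whitespace-separated, case-sensitive values):
#   expr    := term ("or" term)*
#   term    := factor ("and" factor)*
#   factor  := "chain" ID | "resname" NAME | "name" NAME | "resid" RANGES
#   RANGES  := R ("," R)*      R := INT | INT "-" INT
# "or" of terms concatenates index sets in first-appearance order.

_KEYWORDS = {"chain", "resname", "name", "resid"}


def _factor_mask(structure: Structure, keyword: str, value: str) -> np.ndarray:
    if keyword == "chain":
        return structure.chain_ids == value
    if keyword == "resname":
        return structure.res_names == value
    if keyword == "name":
        return structure.atom_names == value
    if keyword == "resid":
        mask = np.zeros(structure.n_atoms, dtype=bool)
        for part in value.split(","):
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", part)
            if not m:
                raise SelectionError(f"bad resid range {part!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            mask |= (structure.res_ids >= lo) & (structure.res_ids <= hi)
        return mask
    raise SelectionError(f"unknown selection keyword {keyword!r}")


def select(structure: Structure, spec: str, name: str | None = None) -> AtomGroup:
    """Resolve a selection expression to an :class:`AtomGroup`.

    Raises :class:`SelectionError` on an empty result: a silent empty
    selection would hide residue-misnumbering mistakes.
    """
    tokens = spec.split()
    if not tokens:
        raise SelectionError("empty selection expression")
    or_masks: list[np.ndarray] = []
    mask = np.ones(structure.n_atoms, dtype=bool)
    i = 0
    expect_factor = True
    while i < len(tokens):
        tok = tokens[i]
        if tok == "or":
            if expect_factor:
                raise SelectionError(f"misplaced 'or' in {spec!r}")
            or_masks.append(mask)
            mask = np.ones(structure.n_atoms, dtype=bool)
            expect_factor = True
            i += 1
        elif tok == "and":
            if expect_factor:
                raise SelectionError(f"misplaced 'and' in {spec!r}")
            expect_factor = True
            i += 1
        else:
            if tok not in _KEYWORDS:
                raise SelectionError(f"unknown token {tok!r} in {spec!r}")
            if i + 1 >= len(tokens):
                raise SelectionError(f"keyword {tok!r} missing its value in {spec!r}")
            mask &= _factor_mask(structure, tok, tokens[i + 1])
            expect_factor = False
            i += 2
    if expect_factor:
        raise SelectionError(f"trailing operator in {spec!r}")
    or_masks.append(mask)
    # union in first-appearance order
    seen = np.zeros(structure.n_atoms, dtype=bool)
    indices: list[np.ndarray] = []
    for m in or_masks:
        new = m & ~seen
        indices.append(np.nonzero(new)[0])
        seen |= m
    members = np.concatenate(indices) if indices else np.array([], dtype=int)
    if len(members) == 0:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return AtomGroup(name=name if name is not None else spec, members=members)


def resolve_groups(structure: Structure, group_specs: dict[str, str]) -> dict[str, AtomGroup]:
    """Resolve a mapping of group name -> selection expression."""
    return {nm: select(structure, expr, name=nm) for nm, expr in group_specs.items()}


# ---------------------------------------------------------------------------
# Trajectory I/O

_TRAJ_COLUMNS = ["frame", "time", "atom_index", "x", "y", "z"]


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory in the columnar TSV format (full float precision)."""
    n_f, n_a = trajectory.n_frames, trajectory.n_atoms
    frame_col = np.repeat(np.arange(n_f), n_a)
    df = pd.DataFrame({
        "frame": frame_col,
        "time": np.repeat(trajectory.times, n_a),
        "atom_index": np.tile(np.arange(n_a), n_f),
        "x": trajectory.frames[:, :, 0].ravel(),
        "y": trajectory.frames[:, :, 1].ravel(),
        "z": trajectory.frames[:, :, 2].ravel(),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_trajectory(path: str | Path, parent: Structure) -> Trajectory:
    """Read a trajectory (columnar TSV or multi-model PDB) aligned to ``parent``.

    Raises :class:`StructureError` naming the first frame whose atom count
    does not match the parent structure.
    """
    path = Path(path)
    if path.suffix.lower() in {".pdb", ".ent"}:
        models = read_pdb_models(path)
        for k, s in enumerate(models):
            if s.n_atoms != parent.n_atoms:
                raise StructureError(
                    f"frame {k}: {s.n_atoms} atoms, parent has {parent.n_atoms}")
        frames = np.stack([s.coords for s in models])
        return Trajectory(frames=frames, times=np.arange(len(models), dtype=float))
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise StructureError(f"{path}: missing trajectory columns {sorted(missing)}")
    frames, times = [], []
    for k, (fid, sub) in enumerate(df.groupby("frame", sort=True)):
        if len(sub) != parent.n_atoms:
            raise StructureError(
                f"frame {k} (id {fid}): {len(sub)} atoms, "
                f"parent has {parent.n_atoms}")
        sub = sub.sort_values("atom_index")
        if not np.array_equal(sub["atom_index"].to_numpy(), np.arange(parent.n_atoms)):
            raise StructureError(f"frame {k} (id {fid}): atom indices not 0..N-1")
        frames.append(sub[["x", "y", "z"]].to_numpy())
        times.append(sub["time"].iloc[0])
    return Trajectory(frames=np.stack(frames), times=np.asarray(times))
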