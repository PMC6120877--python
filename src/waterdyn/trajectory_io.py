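"""Coordinate file I/O and the in-memory trajectory model.

Units are fixed package-wide: coordinates in Angstrom, times in picoseconds.
Multi-model PDB is the canonical trajectory interchange format; a plain XYZ
reader (with a sidecar PDB topology, since XYZ carries no residue
information) is provided for synthetic data.  Only orthorhombic boxes are
supported: a CRYST1 record populates ``Frame.box``, otherwise no periodic
imaging is applied downstream.

Hydrogen and deuterium are not distinguished chemically; both carry an
"H"-like element field (the underlying study used D2O waters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "AtomSelection",
    "PDBParseError",
    "WATER_RESIDUE_NAMES",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_structure_pdb",
    "write_structure_pdb",
    "read_xyz",
    "write_xyz",
    "select",
    "select_water_oxygens",
]

#: Residue names recognised as water (configurable at each call site).
WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "SOL", "DOD"})

_TIME_TOL = 1e-6  # ps; tolerance on timestep regularity


class PDBParseError(ValueError):
    """Raised when a coordinate file violates the format contract."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.

    ``altloc`` is a single-character alternate-location code or ``""``;
    alternate conformers are retained as distinct records with their
    refined occupancies.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain: str
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"occupancy must lie in [0, 1], got {self.occupancy} "
                f"for atom {self.name}"
            )
        if len(self.altloc) > 1:
            raise ValueError(f"altloc must be one character or blank: {self.altloc!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity within a topology: (chain, residue_number, name, altloc)."""
        return (self.chain, self.residue_number, self.name, self.altloc)

    @property
    def is_hydrogen_like(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Frame:
    """One time point: coordinates (n_atoms, 3) in Angstrom, time in ps.

    ``box`` holds orthorhombic edge lengths (3,) in Angstrom, or ``None``.
    """

    index: int
    time: float
    coordinates: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if self.index < 0:
            raise ValueError("frame index must be non-negative")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or not np.all(self.box > 0):
                raise ValueError("box must be three positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Ordered topology plus time-ordered frames with a constant timestep."""

    topology: list[AtomRecord]
    frames: list[Frame]
    timestep: float

    def __post_init__(self) -> None:
        n_top = len(self.topology)
        seen: set[tuple[str, int, str, str]] = set()
        for rec in self.topology:
            if rec.key in seen:
                raise ValueError(f"duplicate atom {rec.key} in topology")
            seen.add(rec.key)
        times = np.array([f.time for f in self.frames])
        for f in self.frames:
            if f.n_atoms != n_top:
                raise ValueError(
                    f"frame {f.index} has {f.n_atoms} atoms, topology has {n_top}"
                )
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValueError("frame times must be strictly increasing")
            if np.any(np.abs(dt - self.timestep) > _TIME_TOL):
                raise ValueError(
                    "successive frame times must differ by the timestep "
                    f"({self.timestep} ps) within {_TIME_TOL} ps"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.topology)

    def coordinate_array(self) -> np.ndarray:
        """All coordinates stacked to shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, unique topology positions."""

    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")
        if any(i < 0 for i in self.indices):
            raise ValueError("selection indices must be non-negative")

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


# ---------------------------------------------------------------------------
# PDB reading
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, np.ndarray]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        residue_name = line[17:20].strip()
        chain = line[21].strip()
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise PDBParseError(
            f"unreadable coordinate record at line {lineno}: {line.rstrip()!r}"
        ) from exc
    occ_field = line[54:60].strip()
    occupancy = float(occ_field) if occ_field else 1.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # PDB v2 files may omit the element; fall back on the name convention.
        element = "".join(c for c in name if c.isalpha())[:1]
    rec = AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_number=residue_number,
        chain=chain,
        altloc=altloc,
        occupancy=occupancy,
    )
    return rec, np.array([x, y, z])


def _parse_cryst1(line: str) -> np.ndarray | None:
    try:
        edges = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
    except (ValueError, IndexError):
        return None
    if np.all(edges > 0):
        return edges
    return None


def _read_pdb_models(path: str | Path) -> tuple[
    list[AtomRecord], list[np.ndarray], np.ndarray | None
]:
    """Parse a PDB file into a topology, per-model coordinate blocks and box."""
    path = Path(path)
    topology: list[AtomRecord] = []
    models: list[list[np.ndarray]] = []
    current: list[np.ndarray] = []
    box: np.ndarray | None = None
    in_model = False
    model_id = 0
    first_model_done = False
    atom_cursor = 0

    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            record = line[:6]
            if record == "CRYST1":
                box = _parse_cryst1(line)
            elif record == "MODEL ":
                in_model = True
                model_id += 1
                current = []
            elif record == "ENDMDL":
                in_model = False
                if first_model_done and len(current) != len(topology):
                    raise PDBParseError(
                        f"model {model_id} has {len(current)} atoms, "
                        f"expected {len(topology)}"
                    )
                models.append(current)
                first_model_done = True
                atom_cursor = 0
                current = []
            elif record in ("ATOM  ", "HETATM"):
                rec, xyz = _parse_atom_line(line, lineno)
                if not first_model_done:
                    topology.append(rec)
                else:
                    expected = topology[atom_cursor] if atom_cursor < len(topology) else None
                    if expected is not None and (
                        rec.name != expected.name
                        or rec.residue_number != expected.residue_number
                        or rec.chain != expected.chain
                    ):
                        raise PDBParseError(
                            f"model {model_id} atom ordering differs from model 1 "
                            f"at line {lineno} (got {rec.name}, expected {expected.name})"
                        )
                    atom_cursor += 1
                current.append(xyz)

    if in_model:
        raise PDBParseError(f"model {model_id} not terminated by ENDMDL")
    if current and not models:
        models.append(current)  # single-model file without MODEL records
    elif current:
        if len(current) != len(topology):
            raise PDBParseError(
                f"model {model_id + 1} has {len(current)} atoms, "
                f"expected {len(topology)}"
            )
        models.append(current)
    if not topology:
        raise PDBParseError(f"no atoms found in {path}")
    return topology, [np.array(m) for m in models], box


def read_multimodel_pdb(path: str | Path, timestep: float = 1.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    Frame times are assigned 0, dt, 2 dt, ... from ``timestep`` (ps); the
    format itself carries no time information.  All MODEL blocks must share
    the topology of the first.
    """
    topology, models, box = _read_pdb_models(path)
    frames = [
        Frame(index=i, time=i * timestep, coordinates=coords, box=box)
        for i, coords in enumerate(models)
    ]
    return Trajectory(topology=topology, frames=frames, timestep=timestep)


def read_structure_pdb(path: str | Path) -> tuple[list[AtomRecord], Frame]:
    """Read a single-model structure, retaining all altloc copies.

    Duplicate (chain, residue_number, name, altloc) records are a parse
    error: they would be indistinguishable in the topology.
    """
    topology, models, box = _read_pdb_models(path)
    seen: set[tuple[str, int, str, str]] = set()
    for rec in topology:
        if rec.key in seen:
            raise PDBParseError(f"duplicate atom record {rec.key}")
        seen.add(rec.key)
    return topology, Frame(index=0, time=0.0, coordinates=models[0], box=box)


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_line(rec: AtomRecord, xyz: np.ndarray) -> str:
    name = rec.name
    # PDB convention: 1-letter element names start in column 14.
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {rec.serial % 100000:5d} {padded:<4s}{rec.altloc or ' ':1s}"
        f"{rec.residue_name:<3s} {rec.chain or 'A':1s}{rec.residue_number:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{rec.occupancy:6.2f}{0.0:6.2f}"
        f"          {rec.element:>2s}\n"
    )


def _write_model(fh, topology: Sequence[AtomRecord], coords: np.ndarray) -> None:
    for rec, xyz in zip(topology, coords):
        fh.write(_format_atom_line(rec, xyz))


def write_structure_pdb(
    path: str | Path, topology: Sequence[AtomRecord], frame: Frame
) -> None:
    with Path(path).open("w") as fh:
        if frame.box is not None:
            a, b, c = frame.box
            fh.write(
                f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1\n"
            )
        _write_model(fh, topology, frame.coordinates)
        fh.write("END\n")


def write_multimodel_pdb(path: str | Path, traj: Trajectory) -> None:
    with Path(path).open("w") as fh:
        box = traj.frames[0].box if traj.frames else None
        if box is not None:
            a, b, c = box
            fh.write(
                f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1\n"
            )
        for i, frame in enumerate(traj.frames, start=1):
            fh.write(f"MODEL     {i:4d}\n")
            _write_model(fh, traj.topology, frame.coordinates)
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# XYZ trajectory (synthetic-data interchange; topology from a sidecar PDB)
# ---------------------------------------------------------------------------

def read_xyz(
    path: str | Path, topology_path: str | Path, timestep: float = 1.0
) -> Trajectory:
    """Read a concatenated-frame XYZ file with topology from a sidecar PDB."""
    topology, _ = read_structure_pdb(topology_path)
    n_atoms = len(topology)
    frames: list[Frame] = []
    with Path(path).open() as fh:
        lines = fh.read().splitlines()
    pos = 0
    index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError as exc:
            raise PDBParseError(
                f"bad XYZ atom count at line {pos + 1}: {lines[pos]!r}"
            ) from exc
        if count != n_atoms:
            raise PDBParseError(
                f"XYZ frame {index} has {count} atoms, topology has {n_atoms}"
            )
        block = lines[pos + 2 : pos + 2 + count]
        if len(block) < count:
            raise PDBParseError(f"truncated XYZ frame {index}")
        coords = np.empty((count, 3))
        for i, ln in enumerate(block):
            parts = ln.split()
            try:
                coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except (IndexError, ValueError) as exc:
                raise PDBParseError(
                    f"unreadable XYZ coordinate at line {pos + 3 + i}"
                ) from exc
        frames.append(
            Frame(index=index, time=index * timestep, coordinates=coords)
        )
        index += 1
        pos += 2 + count
    if not frames:
        raise PDBParseError(f"no frames found in {path}")
    return Trajectory(topology=topology, frames=frames, timestep=timestep)


def write_xyz(path: str | Path, traj: Trajectory) -> None:
    with Path(path).open("w") as fh:
        for frame in traj.frames:
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"t = {frame.time:.6f} ps\n")
            for rec, xyz in zip(traj.topology, frame.coordinates):
                fh.write(
                    f"{rec.element:<2s} {xyz[0]:12.6f} {xyz[1]:12.6f} {xyz[2]:12.6f}\n"
                )


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select(
    topology: Sequence[AtomRecord],
    chain: str | None = None,
    residue_number: int | None = None,
    residue_numbers: Iterable[int] | None = None,
    names: Iterable[str] | None = None,
    residue_names: Iterable[str] | None = None,
    element: str | None = None,
) -> AtomSelection:
    """Select atoms by residue/name/chain predicates; topology-ordered.

    A query matching nothing returns an empty selection.  All criteria are
    combined with AND; iterable criteria match any member.
    """
    name_set = frozenset(names) if names is not None else None
    resname_set = frozenset(residue_names) if residue_names is not None else None
    resnum_set = frozenset(residue_numbers) if residue_numbers is not None else None
    if residue_number is not None:
        resnum_set = (resnum_set or frozenset()) | {residue_number}

    hits = []
    for i, rec in enumerate(topology):
        if chain is not None and rec.chain != chain:
            continue
        if resnum_set is not None and rec.residue_number not in resnum_set:
            continue
        if name_set is not None and rec.name not in name_set:
            continue
        if resname_set is not None and rec.residue_name not in resname_set:
            continue
        if element is not None and rec.element.upper() != element.upper():
            continue
        hits.append(i)
    return AtomSelection(indices=tuple(hits))


def select_water_oxygens(
    topology: Sequence[AtomRecord],
    water_residues: Iterable[str] = WATER_RESIDUE_NAMES,
) -> AtomSelection:
    """Oxygen atoms of water residues (default names HOH/WAT/SOL/DOD)."""
    return select(topology, residue_names=water_residues, element="O")
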