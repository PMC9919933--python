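"""Data model and I/O for periodic-box structures and trajectories.

Coordinates are stored exactly as read (possibly outside the box); periodic
wrapping is applied only inside distance computations, so mean-square
displacements can be computed from unwrapped coordinates without corruption.

Supported formats
-----------------
``xyz``
    Single- or multi-frame XYZ. The comment line may carry metadata of the
    form ``time=<ps> cell=<a,b,c>``; absent metadata yields an open cell and
    times ``i * timestep``.
``pdb``
    Minimal PDB: ATOM/HETATM coordinates and element columns, CRYST1 for the
    cell (orthorhombic only). Parsed with :mod:`gemmi`.
``csv``
    Native table dialect with columns ``frame, time_ps, atom, element, x, y,
    z, charge, molecule_id, role`` and optionally ``class_label`` — the only
    dialect that carries partial charges, molecule roles and atom-class
    labels. An optional first line ``# cell: a b c`` sets the periodic cell.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError

__all__ = [
    "AtomRecord",
    "PeriodicCell",
    "Frame",
    "Trajectory",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
    "minimum_image_distance",
    "minimum_image_displacement",
]

_ROLES = ("host", "guest", "other")


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, partial charge and molecule membership.

    ``class_label`` carries the charge-class tag (e.g. ``O1`` … ``O8``,
    ``H1``, ``H2``) used by hydrogen-bond typing; ``None`` when untagged.
    """

    index: int
    element: str
    partial_charge: float = 0.0
    molecule_id: int = 0
    molecule_role: str = "other"
    class_label: str | None = None

    def __post_init__(self):
        if not self.element:
            raise InvalidInputError("element symbol must be non-empty")
        if self.molecule_role not in _ROLES:
            raise InvalidInputError(
                f"molecule_role must be one of {_ROLES}, got {self.molecule_role!r}"
            )
        object.__setattr__(self, "element", self.element.capitalize())


@dataclass(frozen=True)
class PeriodicCell:
    """Orthorhombic periodic cell (edge lengths in Å) or an open boundary."""

    edges: tuple[float, float, float] | None = None

    def __post_init__(self):
        if self.edges is not None:
            e = tuple(float(x) for x in self.edges)
            if len(e) != 3 or any(x <= 0 for x in e):
                raise InvalidInputError(f"cell edges must be 3 positive lengths, got {self.edges}")
            object.__setattr__(self, "edges", e)

    @classmethod
    def cubic(cls, edge: float) -> "PeriodicCell":
        return cls((edge, edge, edge))

    @classmethod
    def open(cls) -> "PeriodicCell":
        return cls(None)

    @property
    def periodic(self) -> bool:
        return self.edges is not None

    @property
    def volume(self) -> float:
        """Cell volume in Å³ (raises for an open cell)."""
        if self.edges is None:
            raise InvalidInputError("open cell has no volume")
        return self.edges[0] * self.edges[1] * self.edges[2]

    @property
    def min_edge(self) -> float:
        if self.edges is None:
            raise InvalidInputError("open cell has no edges")
        return min(self.edges)


@dataclass
class Frame:
    """One snapshot: atoms plus an (n, 3) Å coordinate array and a cell."""

    atoms: list[AtomRecord]
    coordinates: np.ndarray
    cell: PeriodicCell = field(default_factory=PeriodicCell.open)
    time: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.atoms), 3):
            raise InvalidInputError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise InvalidInputError("coordinates must be finite")
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise InvalidInputError("atom indices must be unique within a frame")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def select(self, **criteria) -> np.ndarray:
        """Indices of atoms matching all keyword criteria.

        Keys are AtomRecord field names, e.g. ``element="O"``,
        ``molecule_role="guest"``, ``class_label="O1"``.
        """
        mask = np.ones(self.n_atoms, dtype=bool)
        for key, value in criteria.items():
            mask &= np.array([getattr(a, key) == value for a in self.atoms])
        return np.nonzero(mask)[0]


@dataclass
class Trajectory:
    """Time-ordered frames with constant atom count and ordering.

    ``energies`` optionally maps a component name (e.g. ``total``) to a
    per-frame kcal/mol array.
    """

    frames: list[Frame]
    timestep: float = 1.0
    energies: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.frames:
            raise InvalidInputError("trajectory needs at least one frame")
        n = self.frames[0].n_atoms
        for i, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise InvalidInputError(
                    f"frame {i} has {f.n_atoms} atoms, expected {n}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise InvalidInputError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def coordinates(self) -> np.ndarray:
        """Stacked (n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.coordinates for f in self.frames])


# ---------------------------------------------------------------------------
# minimum image


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, cell: PeriodicCell
) -> np.ndarray:
    """Displacement b − a under the minimum-image convention (broadcasts)."""
    delta = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    if cell.periodic:
        edges = np.asarray(cell.edges)
        delta = delta - edges * np.round(delta / edges)
    return delta


def minimum_image_distance(a, b, cell: PeriodicCell) -> float:
    """Euclidean distance between two points, wrapped for periodic cells.

    For an orthorhombic periodic cell each Cartesian component is reduced to
    the nearest image; for an open cell this is the plain Euclidean distance.
    """
    delta = minimum_image_displacement(a, b, cell)
    return float(np.sqrt(np.sum(delta * delta, axis=-1)))


# ---------------------------------------------------------------------------
# XYZ dialect

_CELL_RE = re.compile(r"cell=([\d.eE+-]+),([\d.eE+-]+),([\d.eE+-]+)")
_TIME_RE = re.compile(r"time=([\d.eE+-]+)")


def _parse_xyz_frames(path: Path) -> list[tuple[list[str], np.ndarray, PeriodicCell, float | None]]:
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise ParseError(f"{path}: empty file")
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}: expected atom count", line=i + 1)
        if i + 1 + n >= len(lines) + 1 and n > 0 and i + 1 + n > len(lines):
            raise ParseError(f"{path}: truncated frame of {n} atoms", line=i + 1)
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        cell = PeriodicCell.open()
        m = _CELL_RE.search(comment)
        if m:
            cell = PeriodicCell(tuple(float(g) for g in m.groups()))
        t = _TIME_RE.search(comment)
        time = float(t.group(1)) if t else None
        elements, coords = [], []
        for j in range(i + 2, i + 2 + n):
            if j >= len(lines):
                raise ParseError(f"{path}: truncated frame", line=j + 1)
            parts = lines[j].split()
            if len(parts) < 4:
                raise ParseError(f"{path}: malformed atom record {lines[j]!r}", line=j + 1)
            elements.append(parts[0])
            try:
                coords.append([float(x) for x in parts[1:4]])
            except ValueError:
                raise ParseError(f"{path}: non-numeric coordinate", line=j + 1)
        frames.append((elements, np.array(coords), cell, time))
        i += 2 + n
    return frames


def _frame_from_xyz(elements, coords, cell, time) -> Frame:
    atoms = [AtomRecord(index=k, element=e) for k, e in enumerate(elements)]
    return Frame(atoms=atoms, coordinates=coords, cell=cell, time=time or 0.0)


# ---------------------------------------------------------------------------
# PDB via gemmi

def _read_pdb(path: Path) -> Frame:
    import gemmi

    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    cell = PeriodicCell.open()
    c = structure.cell
    if c.a > 0 and c.b > 0 and c.c > 0 and not c.is_crystal():
        # gemmi keeps a dummy 1x1x1 cell when CRYST1 is absent
        pass
    if c.a > 1 and c.b > 1 and c.c > 1:
        if not (abs(c.alpha - 90) < 1e-6 and abs(c.beta - 90) < 1e-6 and abs(c.gamma - 90) < 1e-6):
            raise ParseError(f"{path}: only orthorhombic cells are supported")
        cell = PeriodicCell((c.a, c.b, c.c))
    atoms: list[AtomRecord] = []
    coords: list[list[float]] = []
    k = 0
    for model in structure:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    element = atom.element.name or atom.name[:1]
                    atoms.append(AtomRecord(index=k, element=element))
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                    k += 1
        break  # first model only
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records")
    return Frame(atoms=atoms, coordinates=np.array(coords), cell=cell)


# ---------------------------------------------------------------------------
# native CSV dialect

_CSV_COLUMNS = ["frame", "time_ps", "atom", "element", "x", "y", "z",
                "charge", "molecule_id", "role"]


def _read_csv_cell(path: Path) -> PeriodicCell:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        m = re.search(r"cell:\s*([\d.eE+-]+)[,\s]+([\d.eE+-]+)[,\s]+([\d.eE+-]+)", first)
        if m:
            return PeriodicCell(tuple(float(g) for g in m.groups()))
    return PeriodicCell.open()


def _read_csv_frames(path: Path) -> list[Frame]:
    cell = _read_csv_cell(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises several parse error types
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    has_label = "class_label" in df.columns
    frames = []
    for _, group in df.groupby("frame", sort=True):
        group = group.sort_values("atom")
        atoms = [
            AtomRecord(
                index=int(r.atom),
                element=str(r.element),
                partial_charge=float(r.charge),
                molecule_id=int(r.molecule_id),
                molecule_role=str(r.role),
                class_label=(None if not has_label or pd.isna(r.class_label)
                             else str(r.class_label)),
            )
            for r in group.itertuples()
        ]
        coords = group[["x", "y", "z"]].to_numpy(dtype=float)
        frames.append(Frame(atoms=atoms, coordinates=coords, cell=cell,
                            time=float(group["time_ps"].iloc[0])))
    if not frames:
        raise ParseError(f"{path}: no frames")
    return frames


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("xyz", "pdb", "csv"):
        return suffix
    raise InvalidInputError(f"cannot infer format from {path.name!r}; pass format=")


def read_structure(path, format: str | None = None) -> Frame:
    """Read a single structure (first frame of multi-frame files)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        return _frame_from_xyz(*_parse_xyz_frames(path)[0])
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "csv":
        return _read_csv_frames(path)[0]
    raise InvalidInputError(f"unknown structure format {fmt!r}")


def read_trajectory(path, format: str | None = None, timestep: float = 1.0) -> Trajectory:
    """Read a multi-frame trajectory from XYZ or native CSV.

    When the file carries no time metadata, frame times are ``i * timestep``
    (ps). Atom counts must be consistent across frames.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        raw = _parse_xyz_frames(path)
        frames = []
        for i, (elements, coords, cell, time) in enumerate(raw):
            frames.append(_frame_from_xyz(
                elements, coords, cell, time if time is not None else i * timestep))
    elif fmt == "csv":
        frames = _read_csv_frames(path)
    else:
        raise InvalidInputError(f"unknown trajectory format {fmt!r}")
    return Trajectory(frames=frames, timestep=timestep)


def write_trajectory(traj: Trajectory, path, format: str | None = None) -> None:
    """Write a trajectory as multi-frame XYZ or native CSV (lossless dialect)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "xyz":
        with open(path, "w") as fh:
            for frame in traj.frames:
                fh.write(f"{frame.n_atoms}\n")
                comment = f"time={frame.time:.10g}"
                if frame.cell.periodic:
                    a, b, c = frame.cell.edges
                    comment += f" cell={a:.10g},{b:.10g},{c:.10g}"
                fh.write(comment + "\n")
                for atom, xyz in zip(frame.atoms, frame.coordinates):
                    fh.write(f"{atom.element} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")
    elif fmt == "csv":
        rows = []
        for i, frame in enumerate(traj.frames):
            for atom, xyz in zip(frame.atoms, frame.coordinates):
                rows.append({
                    "frame": i, "time_ps": frame.time, "atom": atom.index,
                    "element": atom.element, "x": xyz[0], "y": xyz[1], "z": xyz[2],
                    "charge": atom.partial_charge, "molecule_id": atom.molecule_id,
                    "role": atom.molecule_role, "class_label": atom.class_label or "",
                })
        df = pd.DataFrame(rows)
        with open(path, "w") as fh:
            cell = traj.frames[0].cell
            if cell.periodic:
                a, b, c = cell.edges
                fh.write(f"# cell: {a:.10g} {b:.10g} {c:.10g}\n")
            df.to_csv(fh, index=False)
    else:
        raise InvalidInputError(f"unknown trajectory format {fmt!r}")


def read_energy_table(path) -> dict[str, np.ndarray]:
    """Read a per-frame energy table CSV (frame, component, value_kcal_mol)."""
    df = pd.read_csv(path, comment="#")
    needed = {"frame", "component", "value_kcal_mol"}
    if not needed.issubset(df.columns):
        raise ParseError(f"{path}: energy table needs columns {sorted(needed)}")
    out = {}
    for name, group in df.groupby("component"):
        out[str(name)] = group.sort_values("frame")["value_kcal_mol"].to_numpy(dtype=float)
    return out
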