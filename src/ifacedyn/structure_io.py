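"""Multi-model structure I/O, atom addressing, and the trajectory abstraction.

The trajectory interchange format is plain multi-model PDB: one MODEL/ENDMDL
block per frame over a fixed atom topology.  Residue numbering is author (PDB)
numbering, 1-based, and all residue ranges are inclusive on both ends.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Residue names recognized as water (PDB dialects differ).
WATER_RESIDUE_NAMES = frozenset({"HOH", "TIP3", "TIP3P", "WAT", "SOL"})

#: Valid atom-class selectors.
ATOM_CLASSES = ("all", "heavy", "hydrogen", "water_oxygen")


class StructureError(Exception):
    """Base class for structure I/O and selection failures."""


class PDBParseError(StructureError):
    """A malformed record was encountered; the message names the line."""


class TopologyError(StructureError):
    """MODEL blocks of one file disagree in atom count or ordering."""


class SelectionError(StructureError):
    """A selection references chains absent from the frame."""


def _element_from_name(atom_name: str) -> str:
    """Infer the element from an atom name (crystal PDBs often lack col 77-78).

    The first alphabetic character wins, so ``1HG1`` is hydrogen and ``OD1``
    is oxygen.
    """
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return ""


@dataclass
class AtomRecord:
    """One atom of one frame, addressed by author chain/residue numbering."""

    serial: int
    atom_name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    position: np.ndarray
    is_hydrogen: bool = False
    is_water: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")

    @property
    def key(self) -> tuple[str, int, str]:
        """Stable identity within a topology: (chain, residue_seq, atom name)."""
        return (self.chain_id, self.residue_seq, self.atom_name)


@dataclass
class Frame:
    """One coordinate snapshot over a fixed atom topology."""

    atoms: list[AtomRecord]
    frame_index: int = 0
    time_ps: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time_ps < 0:
            raise ValueError("time_ps must be >= 0")
        self._coords: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å; cached, do not mutate."""
        if self._coords is None:
            self._coords = np.array([a.position for a in self.atoms], dtype=float)
        return self._coords

    def with_coords(self, coords: np.ndarray, **kwargs) -> "Frame":
        """New frame sharing this topology with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        out = Frame(
            atoms,
            frame_index=kwargs.get("frame_index", self.frame_index),
            time_ps=kwargs.get("time_ps", self.time_ps),
            metadata=dict(self.metadata),
        )
        return out

    def chains(self) -> set[str]:
        return {a.chain_id for a in self.atoms}

    def topology_keys(self) -> list[tuple[str, int, str]]:
        return [a.key for a in self.atoms]


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, labelled by replica."""

    frames: list[Frame]
    replica_label: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a trajectory needs at least one frame")
        times = [f.time_ps for f in self.frames]
        if any(t1 > t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be monotone non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


@dataclass(frozen=True)
class ResidueRange:
    """Inclusive author-numbered residue range on one chain.

    ``start``/``end`` of ``None`` leave that side unbounded, so
    ``ResidueRange("H")`` addresses the whole chain.
    """

    chain_id: str
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"range start {self.start} > end {self.end}")

    def contains(self, chain_id: str, residue_seq: int) -> bool:
        if chain_id != self.chain_id:
            return False
        if self.start is not None and residue_seq < self.start:
            return False
        if self.end is not None and residue_seq > self.end:
            return False
        return True

    @classmethod
    def parse(cls, text: str) -> "ResidueRange":
        """Parse ``"P:25-34"`` or bare ``"H"`` (whole chain)."""
        if ":" not in text:
            return cls(text.strip())
        chain, _, span = text.partition(":")
        lo, _, hi = span.partition("-")
        return cls(chain.strip(), int(lo), int(hi) if hi else int(lo))


@dataclass(frozen=True)
class SelectionSpec:
    """Deterministic, order-stable atom subset of a frame.

    Empty ``ranges`` match every chain.  ``name_patterns`` are shell-style
    globs against the atom name (e.g. ``["O*", "N*"]``).
    """

    ranges: tuple[ResidueRange, ...] = ()
    atom_class: str = "all"
    name_patterns: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranges", tuple(self.ranges))
        if self.name_patterns is not None:
            object.__setattr__(self, "name_patterns", tuple(self.name_patterns))
        if self.atom_class not in ATOM_CLASSES:
            raise ValueError(f"atom_class must be one of {ATOM_CLASSES}")

    @classmethod
    def chains(cls, *chain_ids: str, atom_class: str = "all") -> "SelectionSpec":
        return cls(tuple(ResidueRange(c) for c in chain_ids), atom_class=atom_class)

    def matches(self, atom: AtomRecord) -> bool:
        if self.ranges and not any(
            r.contains(atom.chain_id, atom.residue_seq) for r in self.ranges
        ):
            return False
        if self.atom_class == "heavy" and atom.is_hydrogen:
            return False
        if self.atom_class == "hydrogen" and not atom.is_hydrogen:
            return False
        if self.atom_class == "water_oxygen" and not (
            atom.is_water and atom.element == "O"
        ):
            return False
        if self.name_patterns is not None and not any(
            fnmatch.fnmatchcase(atom.atom_name, pat) for pat in self.name_patterns
        ):
            return False
        return True


def select_indices(frame: Frame, spec: SelectionSpec) -> np.ndarray:
    """Indices (frame order) of atoms matching ``spec``.

    Raises
    ------
    SelectionError
        If a range names a chain not present in the frame.
    """
    present = frame.chains()
    missing = {r.chain_id for r in spec.ranges} - present
    if missing:
        raise SelectionError(
            f"selection references unknown chain(s) {sorted(missing)}; "
            f"frame has {sorted(present)}"
        )
    return np.array(
        [i for i, a in enumerate(frame.atoms) if spec.matches(a)], dtype=int
    )


def select_atoms(frame: Frame, spec: SelectionSpec) -> list[AtomRecord]:
    """Atoms matching ``spec`` in frame order (may be empty)."""
    return [frame.atoms[i] for i in select_indices(frame, spec)]


def residue_range_size(rng: ResidueRange, frame: Frame) -> int:
    """Number of distinct residues of the chain present within the range."""
    seen = {
        a.residue_seq
        for a in frame.atoms
        if rng.contains(a.chain_id, a.residue_seq)
    }
    return len(seen)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

_TIME_REMARK = "REMARK 100 TIME_PS"


def _parse_atom_line(line: str, lineno: int, water_names: frozenset[str]) -> tuple:
    try:
        serial = int(line[6:11])
        atom_name = line[12:16].strip()
        altloc = line[16]
        residue_name = line[17:21].strip()
        chain_id = line[21].strip() or " "
        residue_seq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip().upper() if len(line) >= 77 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {exc}") from exc
    if not element:
        element = _element_from_name(atom_name)
    record = AtomRecord(
        serial=serial,
        atom_name=atom_name,
        element=element,
        residue_name=residue_name,
        residue_seq=residue_seq,
        chain_id=chain_id,
        position=np.array([x, y, z]),
        is_hydrogen=(element == "H"),
        is_water=(residue_name in water_names),
    )
    return record, altloc, occupancy


def _resolve_altlocs(parsed: list[tuple]) -> list[AtomRecord]:
    """Keep the highest-occupancy altloc per atom; ties prefer altloc 'A'."""
    best: dict[tuple, tuple] = {}
    order: list[tuple] = []
    for record, altloc, occupancy in parsed:
        k = record.key
        if k not in best:
            best[k] = (record, altloc, occupancy)
            order.append(k)
        else:
            _, cur_alt, cur_occ = best[k]
            if altloc == cur_alt:
                raise PDBParseError(
                    f"duplicate atom {k} with identical altloc {altloc!r}"
                )
            if occupancy > cur_occ or (occupancy == cur_occ and altloc < cur_alt):
                best[k] = (record, altloc, occupancy)
    return [best[k][0] for k in order]


def read_structure(
    path: str | Path,
    water_names: Iterable[str] = WATER_RESIDUE_NAMES,
) -> Trajectory:
    """Read a (possibly multi-model) PDB file into a :class:`Trajectory`.

    One frame per MODEL block; a file without MODEL records yields a single
    frame.  All MODEL blocks must share atom count and ordering.
    """
    path = Path(path)
    water_names = frozenset(water_names)
    frames: list[Frame] = []
    current: list[tuple] = []
    current_time: float | None = None
    in_model = False
    saw_model = False

    def flush() -> None:
        nonlocal current, current_time
        if not current:
            current_time = None
            return
        atoms = _resolve_altlocs(current)
        idx = len(frames)
        t = current_time if current_time is not None else float(idx)
        frames.append(Frame(atoms, frame_index=idx, time_ps=t))
        current = []
        current_time = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                saw_model = True
                in_model = True
                current = []
                current_time = None
            elif rec == "ENDMDL":
                flush()
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current.append(_parse_atom_line(line, lineno, water_names))
            elif line.startswith(_TIME_REMARK):
                try:
                    current_time = float(line[len(_TIME_REMARK):])
                except ValueError as exc:
                    raise PDBParseError(f"bad time remark at line {lineno}") from exc
            # TER / END / headers are ignored
    if current:
        if saw_model and in_model:
            raise PDBParseError(f"{path}: MODEL block without ENDMDL")
        flush()

    if not frames:
        raise PDBParseError(f"{path}: no atoms found")

    ref_keys = frames[0].topology_keys()
    for fr in frames[1:]:
        if fr.topology_keys() != ref_keys:
            raise TopologyError(
                f"{path}: MODEL {fr.frame_index + 1} disagrees with MODEL 1 "
                f"in atom count or ordering"
            )
    if len(ref_keys) != len(set(ref_keys)):
        dupes = sorted({k for k in ref_keys if ref_keys.count(k) > 1})[:5]
        raise PDBParseError(f"{path}: duplicate atom keys after altloc resolution: {dupes}")
    return Trajectory(frames)


def _format_atom_line(atom: AtomRecord) -> str:
    name = atom.atom_name
    # conventional alignment: 1-letter elements start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    record = "HETATM" if atom.is_water else "ATOM  "
    x, y, z = atom.position
    return (
        f"{record}{atom.serial % 100000:5d} {name:<4s} {atom.residue_name:<4s}"
        f"{atom.chain_id:1s}{atom.residue_seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2s}"
    )


def write_structure(traj: Trajectory | Frame, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (single frame → no MODEL records).

    ``read_structure(write_structure(t))`` is the identity up to the 3-decimal
    PDB coordinate precision; frame times survive via a REMARK line.
    """
    if isinstance(traj, Frame):
        traj = Trajectory([traj])
    path = Path(path)
    multi = len(traj.frames) > 1
    lines: list[str] = []
    for i, frame in enumerate(traj.frames):
        if multi:
            lines.append(f"MODEL {i + 1:8d}")
        lines.append(f"{_TIME_REMARK} {frame.time_ps:.6f}")
        for atom in frame.atoms:
            lines.append(_format_atom_line(atom))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def read_trajectories(paths: Sequence[str | Path], labels: Sequence[str] | None = None) -> list[Trajectory]:
    """Read several replica files, attaching ``Equ1..EquN``-style labels."""
    trajs = []
    for i, p in enumerate(paths):
        t = read_structure(p)
        t.replica_label = labels[i] if labels else f"Equ{i + 1}"
        trajs.append(t)
    return trajs
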