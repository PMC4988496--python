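"""Core domain types and I/O: structures, trajectories, selections, windows.

Units: lengths are Å, times are ns throughout the package (persistence-length
results are reported in nm by the :mod:`mdflex.persistence` module).
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MDFlexError",
    "SelectionError",
    "TopologyError",
    "Structure",
    "Trajectory",
    "AtomSelection",
    "WindowSpec",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "select",
    "concat_windows",
]


class MDFlexError(Exception):
    """Base class for errors raised by mdflex."""


class SelectionError(MDFlexError):
    """Malformed selection expression or invalid selection target."""


class TopologyError(MDFlexError):
    """Structure/trajectory inconsistency (atom counts, identities, ...)."""


@dataclass
class Structure:
    """A molecular topology with one set of coordinates.

    Parameters
    ----------
    atom_names, elements, chain_ids, res_names
        Per-atom string annotations, length ``n_atoms``.
    res_ids
        Author residue numbers (int) per atom.
    masses
        Atomic masses in Da.
    coords
        Cartesian coordinates in Å, shape ``(n_atoms, 3)``.
    """

    atom_names: np.ndarray
    elements: np.ndarray
    chain_ids: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    masses: np.ndarray
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        self.masses = np.asarray(self.masses, dtype=float)
        for name in ("atom_names", "elements", "chain_ids", "res_names"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        n = self.coords.shape[0]
        if n == 0:
            raise TopologyError("structure has no atoms")
        if self.coords.shape != (n, 3) or not np.all(np.isfinite(self.coords)):
            raise TopologyError("coordinates must be finite with shape (n, 3)")
        ids = list(zip(self.chain_ids, self.res_ids, self.atom_names))
        if len(set(ids)) != n:
            raise TopologyError(
                "duplicate (chain, resid, atom name) after alt-location resolution"
            )

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def same_topology(self, other: "Structure") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.chain_ids, other.chain_ids)
            and np.array_equal(self.res_ids, other.res_ids)
            and np.array_equal(self.atom_names, other.atom_names)
        )

    def select(self, expression: str) -> "AtomSelection":
        return select(self, expression)


@dataclass
class Trajectory:
    """Ordered coordinate frames bound to a :class:`Structure` topology."""

    structure: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3) Å
    times: np.ndarray  # ns, strictly increasing
    label: str = ""
    #: nominal total duration in ns (sum of window lengths for unions);
    #: defaults to n_frames × median frame spacing.
    duration_ns: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise TopologyError("trajectory needs >= 1 frame of (n_atoms, 3) coords")
        if self.frames.shape[1] != self.structure.n_atoms:
            raise TopologyError(
                f"frame atom count {self.frames.shape[1]} != topology "
                f"atom count {self.structure.n_atoms}"
            )
        if self.times.shape != (self.frames.shape[0],):
            raise TopologyError("times length must equal number of frames")
        if self.frames.shape[0] > 1 and not np.all(np.diff(self.times) > 0):
            raise TopologyError("frame times must be strictly increasing")
        if self.duration_ns is None:
            dt = self.frame_spacing
            self.duration_ns = float(self.frames.shape[0] * dt)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def frame_spacing(self) -> float:
        """Median time between frames (ns); 1.0 for single-frame trajectories."""
        if self.n_frames < 2:
            return 1.0
        return float(np.median(np.diff(self.times)))


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, duplicate-free atom indices with their source expression."""

    indices: np.ndarray
    expression: str
    n_atoms_structure: int

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms_structure):
            raise SelectionError("selection indices out of range for structure")
        if len(np.unique(idx)) != idx.size:
            raise SelectionError("selection contains duplicate indices")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def is_empty(self) -> bool:
        return self.indices.size == 0

    def minus(self, other: "AtomSelection | None") -> "AtomSelection":
        if other is None:
            return self
        keep = ~np.isin(self.indices, other.indices)
        return AtomSelection(
            self.indices[keep],
            f"({self.expression}) minus ({other.expression})",
            self.n_atoms_structure,
        )


@dataclass(frozen=True)
class WindowSpec:
    """Half-open time window ``[start, end)`` (ns) of a source trajectory.

    ``source`` is an index into the source list or a trajectory label.
    """

    source: int | str
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"window start {self.start} must be < end {self.end}")

    @property
    def length(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# structure I/O (PDB via biotite)
# ---------------------------------------------------------------------------

def _element_mass(element: str, atom_name: str) -> float:
    import biotite.structure.info as info

    el = element.strip()
    if not el:  # infer from atom name: first alphabetic char
        m = re.search(r"[A-Za-z]", atom_name)
        el = m.group(0) if m else "C"
    try:
        mass = info.mass(el.capitalize())
    except KeyError:
        mass = None
    return float(mass) if mass is not None else 12.011


def read_structure(path: str | Path, format: str = "pdb") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Alternate locations are resolved by keeping the highest-occupancy variant
    (ties broken by file order). Hydrogens are retained when present.
    """
    if format.lower() != "pdb":
        raise ValueError(f"unsupported structure format: {format}")
    import biotite.structure.io.pdb as pdbio

    pdb_file = pdbio.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(
        model=1, altloc="all", extra_fields=["occupancy"]
    )
    if atoms.array_length() == 0:
        raise TopologyError(f"no ATOM/HETATM records in {path}")

    altloc = atoms.get_annotation("altloc_id")
    occ = atoms.occupancy
    keep = np.ones(atoms.array_length(), dtype=bool)
    seen: dict[tuple, int] = {}
    for i in range(atoms.array_length()):
        key = (atoms.chain_id[i], int(atoms.res_id[i]), atoms.atom_name[i])
        if altloc[i] in (" ", "", "."):
            continue
        if key in seen:
            j = seen[key]
            # keep highest occupancy; tie -> first listed
            if occ[i] > occ[j]:
                keep[j] = False
                seen[key] = i
            else:
                keep[i] = False
        else:
            seen[key] = i
    atoms = atoms[keep]

    masses = np.array(
        [_element_mass(e, n) for e, n in zip(atoms.element, atoms.atom_name)]
    )
    return Structure(
        atom_names=atoms.atom_name,
        elements=atoms.element,
        chain_ids=atoms.chain_id,
        res_ids=atoms.res_id,
        res_names=atoms.res_name,
        masses=masses,
        coords=np.asarray(atoms.coord, dtype=float),
        label=Path(path).stem,
    )


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as PDB (coordinates rounded to 10⁻³ Å)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.round(structure.coords, 3).astype(np.float32)
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.res_id = structure.res_ids
    arr.res_name = structure.res_names.astype("U5")
    arr.atom_name = structure.atom_names.astype("U6")
    arr.element = structure.elements.astype("U2")
    f = pdbio.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


# ---------------------------------------------------------------------------
# trajectory I/O (DCD / XTC via MDAnalysis)
# ---------------------------------------------------------------------------

_PS_PER_NS = 1000.0


def read_trajectory(
    path: str | Path,
    topology: Structure,
    format: str | None = None,
    timestep: float | None = None,
) -> Trajectory:
    """Read a DCD or XTC trajectory bound to ``topology``.

    Frame times are ``frame_index × timestep`` (ns) when ``timestep`` is
    given, otherwise embedded times (ps, converted to ns) are used.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "dcd":
        from MDAnalysis.coordinates.DCD import DCDReader as Reader
    elif fmt == "xtc":
        from MDAnalysis.coordinates.XTC import XTCReader as Reader
    else:
        raise ValueError(f"unsupported trajectory format: {fmt}")

    frames, times = [], []
    with Reader(str(path)) as reader:
        if reader.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"trajectory has {reader.n_atoms} atoms, topology has "
                f"{topology.n_atoms}"
            )
        for ts in reader:
            frames.append(ts.positions.astype(float).copy())
            times.append(float(ts.time) / _PS_PER_NS)
    if not frames:
        raise TopologyError(f"no frames in {path}")
    arr = np.asarray(frames)
    if timestep is not None:
        t = np.arange(len(frames), dtype=float) * timestep
    else:
        t = np.asarray(times)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            # no usable embedded times: fall back to unit frame index
            t = np.arange(len(frames), dtype=float)
    return Trajectory(structure=topology, frames=arr, times=t, label=path.stem)


def write_trajectory(traj: Trajectory, path: str | Path, format: str | None = None) -> None:
    """Write a trajectory as DCD or XTC (frame times stored in ps)."""
    import warnings

    import MDAnalysis as mda

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("dcd", "xtc"):
        raise ValueError(f"unsupported trajectory format: {fmt}")
    u = mda.Universe.empty(traj.n_atoms, trajectory=True)
    u.load_new(traj.frames.astype(np.float32), order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
            for i, ts in enumerate(u.trajectory):
                ts.time = traj.times[i] * _PS_PER_NS
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# selection mini-grammar
# ---------------------------------------------------------------------------
#
#   expr    := or_expr
#   or_expr := and_expr ("or" and_expr)*
#   and_expr:= unary ("and" unary)*
#   unary   := "not" unary | "(" expr ")" | predicate
#   predicate := "all"
#              | "chain" ID[,ID...]
#              | "resid" RANGES          (e.g. 123-150 or 5,7,9-12)
#              | "name" NAME[,NAME...]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _SelParser:
    def __init__(self, structure: Structure, expression: str):
        self.s = structure
        self.tokens = _TOKEN_RE.findall(expression)
        self.pos = 0
        if not self.tokens:
            raise SelectionError("empty selection expression")

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek() == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.next()
            return ~self.unary()
        if tok == "(":
            self.next()
            mask = self.or_expr()
            if self.next() != ")":
                raise SelectionError("unbalanced parentheses in selection")
            return mask
        return self.predicate()

    def predicate(self) -> np.ndarray:
        kw = self.next().lower()
        if kw == "all":
            return np.ones(self.s.n_atoms, dtype=bool)
        if kw == "chain":
            values = self._values()
            known = set(self.s.chain_ids)
            missing = [v for v in values if v not in known]
            if missing:
                raise SelectionError(f"unknown chain(s): {missing}")
            return np.isin(self.s.chain_ids.astype(str), values)
        if kw == "name":
            values = self._values()
            return np.isin(self.s.atom_names.astype(str), values)
        if kw == "resid":
            mask = np.zeros(self.s.n_atoms, dtype=bool)
            for part in self._values():
                m = re.fullmatch(r"(-?\d+)(?:[-:](-?\d+))?", part)
                if m is None:
                    raise SelectionError(f"malformed resid range {part!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                if hi < lo:
                    raise SelectionError(f"descending resid range {part!r}")
                mask |= (self.s.res_ids >= lo) & (self.s.res_ids <= hi)
            return mask
        raise SelectionError(f"unknown selection keyword {kw!r}")

    def _values(self) -> list[str]:
        """Collect one or more comma-separated value tokens."""
        values: list[str] = []
        while True:
            tok = self.peek()
            if tok is None or tok in ("and", "or", "not", "(", ")"):
                break
            values.extend(v for v in self.next().split(",") if v)
            # only keep consuming if the previous token ended with a comma
            if not self.tokens[self.pos - 1].endswith(","):
                break
        if not values:
            raise SelectionError("selection keyword requires at least one value")
        return values


def select(structure: Structure, expression: str) -> AtomSelection:
    """Evaluate a selection expression against a structure.

    The grammar supports ``chain``, ``resid`` (single values and inclusive
    ranges like ``123-150``), ``name``, ``all`` and the combinators ``and``,
    ``or``, ``not`` with parentheses. Returns atom indices in structure
    order (deterministic and idempotent).
    """
    mask = _SelParser(structure, expression).parse()
    return AtomSelection(np.flatnonzero(mask), expression, structure.n_atoms)


# ---------------------------------------------------------------------------
# window assembly
# ---------------------------------------------------------------------------

def concat_windows(
    sources: Sequence[Trajectory],
    windows: Sequence[WindowSpec],
    label: str = "union",
) -> Trajectory:
    """Concatenate half-open ``[start, end)`` time windows into one trajectory.

    All sources must share one topology. Output frame times are re-indexed
    contiguously (window k starts where window k-1 ended) and the reported
    ``duration_ns`` equals the sum of window lengths.
    """
    if not sources:
        raise ValueError("no source trajectories")
    if not windows:
        raise ValueError("no windows")
    ref = sources[0].structure
    for tr in sources[1:]:
        if not tr.structure.same_topology(ref):
            raise TopologyError("source trajectories have mismatched topologies")

    by_label = {tr.label: tr for tr in sources}
    frames, times = [], []
    offset = 0.0
    for w in windows:
        if isinstance(w.source, str):
            if w.source not in by_label:
                raise KeyError(f"no source trajectory labelled {w.source!r}")
            tr = by_label[w.source]
        else:
            tr = sources[w.source]
        dt = tr.frame_spacing
        span_lo, span_hi = tr.times[0], tr.times[-1] + dt
        if w.start < span_lo - 1e-9 or w.end > span_hi + 1e-9:
            raise ValueError(
                f"window [{w.start}, {w.end}) outside source span "
                f"[{span_lo}, {span_hi})"
            )
        mask = (tr.times >= w.start - 1e-12) & (tr.times < w.end - 1e-12)
        if not mask.any():
            raise ValueError(f"window [{w.start}, {w.end}) selects no frames")
        frames.append(tr.frames[mask])
        times.append(offset + tr.times[mask] - w.start)
        offset += w.length
    return Trajectory(
        structure=ref,
        frames=np.concatenate(frames, axis=0),
        times=np.concatenate(times),
        label=label,
        duration_ns=float(sum(w.length for w in windows)),
    )
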