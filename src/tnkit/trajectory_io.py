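"""Reading, writing and atom selection for molecular trajectories.

All coordinates are Ångström internally; frame spacing ``dt`` is in
picoseconds.  Periodic boxes are orthorhombic (three edge lengths) and all
distance helpers use the minimum-image convention when a box is present.

Supported formats
-----------------
``pdb``
    Standard PDB files, multi-frame via MODEL/ENDMDL blocks (parsed and
    written through :mod:`biotite`).  Residue numbering is preserved.
``xyz``
    Plain XYZ; the comment line may carry ``dt_ps=<float>`` and
    ``box=<a>,<b>,<c>`` metadata written by this package.
``csv``
    A whitespace table ``frame atom x y z`` with ``#``-prefixed header lines
    recording units, ``dt_ps`` and optionally the box.  This is the
    canonical desk-scale test format: exact round-trips, no fixed-width
    records.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("tnkit")

DEFAULT_DT_PS = 1.0

__all__ = [
    "Atom",
    "Topology",
    "TrajectoryEnsemble",
    "ParseError",
    "SelectionError",
    "read_structure",
    "write_trajectory",
    "select_atoms",
    "minimum_image_displacements",
    "pair_distances",
]


class ParseError(ValueError):
    """A file did not parse under the named standard.

    Carries ``path`` and (1-based) ``line`` when they are known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f", line {line}"
        super().__init__(f"{message} ({loc})" if loc else message)
        self.path = path
        self.line = line


class SelectionError(ValueError):
    """A selection query violated the grammar; ``position`` is the
    character offset of the offending token."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_name: str
    residue_index: int  # 1-based, as in PDB files
    molecule_id: str = "A"


@dataclass
class Topology:
    """Atom identities and optional bonds.

    Atom indices are 0-based and implicit (position in ``atoms``);
    residue indices are 1-based, matching PDB conventions.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]] | None = None

    def __post_init__(self):
        n = len(self.atoms)
        if self.bonds is not None:
            for i, j in self.bonds:
                if not (0 <= i < n and 0 <= j < n):
                    raise ValueError(f"bond ({i},{j}) references atom outside 0..{n - 1}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def residue_ids(self) -> list[tuple[str, int]]:
        """Distinct (molecule_id, residue_index) pairs in order of appearance."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.molecule_id, a.residue_index), None)
        return list(seen)

    def atoms_of_residue(self, molecule_id: str, residue_index: int) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.molecule_id == molecule_id and a.residue_index == residue_index
        ]


@dataclass
class TrajectoryEnsemble:
    """Frames × atoms coordinates plus topology and bookkeeping.

    ``segments`` marks independent trajectory pieces as half-open frame
    ranges ``(start, end)``; transitions are never counted across a
    segment boundary.
    """

    topology: Topology
    frames: np.ndarray  # (n_frames, n_atoms, 3), Å
    dt: float = DEFAULT_DT_PS  # ps
    box: np.ndarray | None = None  # orthorhombic edges, Å
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"{self.frames.shape[1]} coordinates per frame for "
                f"{self.topology.n_atoms} topology atoms"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,) or np.any(self.box <= 0):
                raise ValueError("box must be three positive orthorhombic edge lengths")
        if not self.segments:
            self.segments = [(0, self.n_frames)]
        self._check_segments()

    def _check_segments(self):
        covered = 0
        prev_end = 0
        for start, end in self.segments:
            if start != prev_end or end <= start:
                raise ValueError(f"segments must partition 0..{self.n_frames} without gaps")
            covered += end - start
            prev_end = end
        if covered != self.n_frames:
            raise ValueError("segment lengths must sum to the number of frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


# ---------------------------------------------------------------------------
# minimum-image helpers
# ---------------------------------------------------------------------------

def minimum_image_displacements(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the central orthorhombic image."""
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def pair_distances(a: np.ndarray, b: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """All minimum-image distances between rows of ``a`` (m,3) and ``b`` (n,3) → (m,n)."""
    delta = a[:, None, :] - b[None, :, :]
    delta = minimum_image_displacements(delta, box)
    return np.sqrt((delta**2).sum(axis=-1))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_structure(
    path,
    format: str | None = None,
    *,
    topology: Topology | None = None,
    dt: float | None = None,
) -> TrajectoryEnsemble:
    """Read a topology + trajectory from ``path``.

    Parameters
    ----------
    path : str or Path
    format : {"pdb", "xyz", "csv"}, optional
        Inferred from the file suffix when omitted.
    topology : Topology, optional
        Supplies atom identities for the coordinate-only csv dialect.
    dt : float, optional
        Frame interval in ps; overrides any value found in file headers.
        When neither is available, 1.0 ps is used and a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if format == "pdb":
        ens = _read_pdb(path)
    elif format == "xyz":
        ens = _read_xyz(path)
    elif format == "csv":
        ens = _read_csv(path, topology)
    else:
        raise ValueError(f"unsupported trajectory format: {format!r}")
    if dt is not None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        ens.dt = dt
    return ens


def _warn_default_dt(path):
    logger.warning(
        "no frame interval found in %s; defaulting dt to %.1f ps "
        "(pass dt= explicitly for kinetic analyses)",
        path,
        DEFAULT_DT_PS,
    )


def _read_pdb(path: Path) -> TrajectoryEnsemble:
    from biotite.structure.io.pdb import PDBFile

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pdb = PDBFile.read(str(path))
            stack = pdb.get_structure(model=None)
    except Exception as exc:  # locate the offending record for the message
        raise ParseError(
            f"malformed PDB record: {exc}", path=path, line=_find_bad_pdb_line(path)
        ) from exc
    # AtomArrayStack: (models, atoms); AtomArray for a single model
    if stack.stack_depth() == 0 or stack.array_length() == 0:
        raise ParseError("PDB file contains no atoms", path=path)
    atoms = [
        Atom(
            name=str(stack.atom_name[i]),
            element=str(stack.element[i]).capitalize() or "X",
            residue_name=str(stack.res_name[i]),
            residue_index=int(stack.res_id[i]),
            molecule_id=str(stack.chain_id[i]) or "A",
        )
        for i in range(stack.array_length())
    ]
    box = None
    if stack.box is not None:
        b = np.asarray(stack.box)
        if b.ndim == 3:
            b = b[0]
        diag = np.diag(b)
        if np.all(diag > 0):
            box = diag
    dt = _pdb_header_dt(path)
    if dt is None:
        _warn_default_dt(path)
        dt = DEFAULT_DT_PS
    return TrajectoryEnsemble(
        Topology(atoms), np.asarray(stack.coord, dtype=float), dt=dt, box=box
    )


def _pdb_header_dt(path: Path) -> float | None:
    """Frame interval recorded by this package's writer (REMARK 250)."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("REMARK 250 UNITS ANGSTROM DT_PS"):
                try:
                    return float(line.split()[-1])
                except ValueError:
                    return None
            if line.startswith(("ATOM", "HETATM", "MODEL")):
                break
    return None


def _find_bad_pdb_line(path: Path) -> int | None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except (ValueError, IndexError):
                    return lineno
    return None


def _read_xyz(path: Path) -> TrajectoryEnsemble:
    frames: list[np.ndarray] = []
    elements: list[str] | None = None
    dt = None
    box = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            raise ParseError("expected atom count", path=path, line=i + 1)
        if i + 1 + n >= len(lines) + 1:
            raise ParseError(f"truncated frame: expected {n} atom lines", path=path, line=i + 1)
        comment = lines[i + 1]
        for token in comment.split():
            if token.startswith("dt_ps="):
                dt = float(token.split("=", 1)[1])
            elif token.startswith("box="):
                box = np.array([float(v) for v in token.split("=", 1)[1].split(",")])
        frame_elems, coords = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise ParseError("XYZ atom line needs 'element x y z'", path=path, line=i + 3 + j)
            frame_elems.append(parts[0])
            try:
                coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError:
                raise ParseError("non-numeric coordinate", path=path, line=i + 3 + j)
        if elements is None:
            elements = frame_elems
        elif frame_elems != elements:
            raise ParseError("inconsistent atom list between frames", path=path, line=i + 1)
        frames.append(np.array(coords))
        i += 2 + n
    if not frames:
        raise ParseError("no frames found", path=path)
    atoms = [
        Atom(name=e, element=e.capitalize(), residue_name="UNK", residue_index=1)
        for e in elements
    ]
    if dt is None:
        _warn_default_dt(path)
        dt = DEFAULT_DT_PS
    return TrajectoryEnsemble(Topology(atoms), np.stack(frames), dt=dt, box=box)


def _read_csv(path: Path, topology: Topology | None) -> TrajectoryEnsemble:
    dt = None
    box = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("dt_ps:"):
                    dt = float(body.split(":", 1)[1])
                elif body.startswith("box:"):
                    box = np.array([float(v) for v in body.split(":", 1)[1].split(",")])
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ParseError("expected 'frame atom x y z'", path=path, line=lineno)
            try:
                rows.append(
                    (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]), float(parts[4]))
                )
            except ValueError:
                raise ParseError("non-numeric field", path=path, line=lineno)
    if not rows:
        raise ParseError("no coordinate rows found", path=path)
    n_frames = max(r[0] for r in rows) + 1
    n_atoms = max(r[1] for r in rows) + 1
    coords = np.full((n_frames, n_atoms, 3), np.nan)
    for f, a, x, y, z in rows:
        coords[f, a] = (x, y, z)
    if np.isnan(coords).any():
        raise ParseError("missing (frame, atom) entries: coordinate table is not dense", path=path)
    if topology is None:
        topology = Topology(
            [Atom(name="X", element="X", residue_name="UNK", residue_index=1) for _ in range(n_atoms)]
        )
    elif topology.n_atoms != n_atoms:
        raise ParseError(
            f"topology has {topology.n_atoms} atoms but file has {n_atoms}", path=path
        )
    if dt is None:
        _warn_default_dt(path)
        dt = DEFAULT_DT_PS
    return TrajectoryEnsemble(topology, coords, dt=dt, box=box)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_trajectory(ens: TrajectoryEnsemble, path, format: str | None = None) -> None:
    """Write ``ens`` to ``path``; every writer records units and dt in a header."""
    if ens.n_frames == 0:
        raise ValueError("refusing to write an empty ensemble")
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if format == "pdb":
        _write_pdb(ens, path)
    elif format == "xyz":
        _write_xyz(ens, path)
    elif format == "csv":
        _write_csv(ens, path)
    else:
        raise ValueError(f"unsupported trajectory format: {format!r}")


def _write_pdb(ens: TrajectoryEnsemble, path: Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = ens.n_atoms
    stack = struc.AtomArrayStack(ens.n_frames, n)
    stack.coord = ens.frames
    stack.atom_name = np.array([a.name for a in ens.topology.atoms])
    stack.element = np.array([a.element.upper() for a in ens.topology.atoms])
    stack.res_name = np.array([a.residue_name for a in ens.topology.atoms])
    stack.res_id = np.array([a.residue_index for a in ens.topology.atoms])
    stack.chain_id = np.array([a.molecule_id[:1] or "A" for a in ens.topology.atoms])
    stack.hetero = np.zeros(n, dtype=bool)
    if ens.box is not None:
        stack.box = np.repeat(np.diag(ens.box)[None], ens.n_frames, axis=0)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.lines.insert(0, f"REMARK 250 UNITS ANGSTROM DT_PS {ens.dt:g}")
    pdb.write(str(path))


def _write_xyz(ens: TrajectoryEnsemble, path: Path) -> None:
    meta = f"units=angstrom dt_ps={ens.dt:g}"
    if ens.box is not None:
        meta += " box=" + ",".join(f"{b:.6f}" for b in ens.box)
    with open(path, "w") as fh:
        for frame in ens.frames:
            fh.write(f"{ens.n_atoms}\n{meta}\n")
            for atom, (x, y, z) in zip(ens.topology.atoms, frame):
                fh.write(f"{atom.element:<3s} {x:13.6f} {y:13.6f} {z:13.6f}\n")


def _write_csv(ens: TrajectoryEnsemble, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# units: angstrom\n")
        fh.write(f"# dt_ps: {ens.dt:g}\n")
        if ens.box is not None:
            fh.write("# box: " + ",".join(repr(float(b)) for b in ens.box) + "\n")
        fh.write("# columns: frame atom x y z\n")
        for f, frame in enumerate(ens.frames):
            for a, (x, y, z) in enumerate(frame):
                fh.write(f"{f} {a} {float(x)!r} {float(y)!r} {float(z)!r}\n")


# ---------------------------------------------------------------------------
# atom selection
# ---------------------------------------------------------------------------
#
# Grammar (whitespace-tokenized, case-insensitive keywords):
#   expr      := term ("or" term)*
#   term      := factor ("and" factor)*
#   factor    := "not" factor | "(" expr ")" | primitive
#   primitive := "all"
#              | "name" VALUE+ | "resname" VALUE+ | "element" VALUE+
#              | "molid" VALUE+ | "resid" RANGE+       (alias: residue_index)
#   RANGE     := INT | INT-INT          (1-based residue indices, inclusive)

_KEYWORDS = {"and", "or", "not", "(", ")", "all", "name", "resname", "element", "molid", "resid", "residue_index"}


def _tokenize(query: str) -> list[tuple[str, int]]:
    tokens = []
    i = 0
    while i < len(query):
        c = query[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(query) and not query[j].isspace() and query[j] not in "()":
            j += 1
        tokens.append((query[i:j], i))
        i = j
    return tokens


class _SelParser:
    def __init__(self, topology: Topology, query: str):
        self.top = topology
        self.tokens = _tokenize(query)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse(self) -> set[int]:
        if not self.tokens:
            raise SelectionError("empty selection query")
        result = self.expr()
        if self.pos < len(self.tokens):
            tok, at = self.tokens[self.pos]
            raise SelectionError(f"unexpected token {tok!r}", position=at)
        return result

    def expr(self) -> set[int]:
        result = self.term()
        while self.peek() == "or":
            self.next()
            result = result | self.term()
        return result

    def term(self) -> set[int]:
        result = self.factor()
        while self.peek() == "and":
            self.next()
            result = result & self.factor()
        return result

    def factor(self) -> set[int]:
        tok = self.peek()
        if tok is None:
            raise SelectionError("query ended unexpectedly", position=len(self.tokens))
        if tok == "not":
            self.next()
            return set(range(self.top.n_atoms)) - self.factor()
        if tok == "(":
            _, at = self.next()
            inner = self.expr()
            if self.peek() != ")":
                raise SelectionError("unbalanced parenthesis", position=at)
            self.next()
            return inner
        return self.primitive()

    def _values(self, keyword_at: int) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS:
            vals.append(self.next()[0])
        if not vals:
            raise SelectionError("keyword needs at least one value", position=keyword_at)
        return vals

    def primitive(self) -> set[int]:
        tok, at = self.next()
        atoms = self.top.atoms
        if tok == "all":
            return set(range(len(atoms)))
        if tok == "name":
            vals = set(self._values(at))
            return {i for i, a in enumerate(atoms) if a.name in vals}
        if tok == "resname":
            vals = set(self._values(at))
            return {i for i, a in enumerate(atoms) if a.residue_name in vals}
        if tok == "element":
            vals = {v.capitalize() for v in self._values(at)}
            return {i for i, a in enumerate(atoms) if a.element.capitalize() in vals}
        if tok == "molid":
            vals = set(self._values(at))
            return {i for i, a in enumerate(atoms) if a.molecule_id in vals}
        if tok in ("resid", "residue_index"):
            selected: set[int] = set()
            for val in self._values(at):
                val = val.replace("–", "-")  # tolerate en-dash ranges
                try:
                    if "-" in val.lstrip("-")[0:] and val.count("-") >= 1 and not val.lstrip("-").isdigit():
                        lo, hi = val.split("-", 1)
                        lo_i, hi_i = int(lo), int(hi)
                    else:
                        lo_i = hi_i = int(val)
                except ValueError:
                    raise SelectionError(f"bad residue range {val!r}", position=at)
                selected |= {
                    i for i, a in enumerate(atoms) if lo_i <= a.residue_index <= hi_i
                }
            return selected
        raise SelectionError(f"unknown selection keyword {tok!r}", position=at)


def select_atoms(ens_or_topology, query: str) -> list[int]:
    """Evaluate a selection expression; returns a sorted (possibly empty) 0-based index list."""
    top = ens_or_topology.topology if isinstance(ens_or_topology, TrajectoryEnsemble) else ens_or_topology
    return sorted(_SelParser(top, query).parse())
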