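"""Reading and writing docking output tables.

A rigid-body docking run produces one row per candidate pose ("solution"):
three rotation angles, three translation components and an interaction
score.  The reference on-disk format is a plain TSV dialect::

    solution_id<TAB>rot1<TAB>rot2<TAB>rot3<TAB>tx<TAB>ty<TAB>tz<TAB>score

with a single header line, UTF-8 text, '.' decimal separator and optional
comment lines starting with ``#``.  Docking engines print their own layouts;
those are supported as pluggable dialect reader functions registered with
:func:`register_dialect`.

Internal conventions, applied at parse time regardless of dialect:

* angles are stored in radians, reduced modulo 2*pi into ``[0, 2*pi)``;
* scores are stored so that larger always means a better (stronger)
  interaction; tables whose engine prints "lower is better" are negated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import ConfigError, FormatError, InputError, ParseError

TWO_PI = 2.0 * math.pi

GENERIC_COLUMNS = (
    "solution_id",
    "rot1",
    "rot2",
    "rot3",
    "tx",
    "ty",
    "tz",
    "score",
)


def wrap_angle(a: float) -> float:
    """Reduce an angle in radians into ``[0, 2*pi)``."""
    if not math.isfinite(a):
        raise InputError(f"non-finite angle: {a!r}")
    w = math.fmod(a, TWO_PI)
    if w < 0.0:
        w += TWO_PI
    # fmod can land exactly on 2*pi after the correction for tiny negatives
    if w >= TWO_PI:
        w = 0.0
    return w


@dataclass(frozen=True)
class DockingSolution:
    """One docking pose: identifier, rotation-angle triple (rad), translation
    triple (angstrom) and interaction score (larger = better)."""

    id: int
    angles: tuple[float, float, float]
    translation: tuple[float, float, float]
    score: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "angles", tuple(wrap_angle(a) for a in self.angles))
        if not all(math.isfinite(t) for t in self.translation):
            raise InputError(f"solution {self.id}: non-finite translation")
        if not math.isfinite(self.score):
            raise InputError(f"solution {self.id}: non-finite score")


@dataclass
class DockingTable:
    """Ordered collection of docking solutions plus its on-disk provenance."""

    solutions: list[DockingSolution]
    dialect: str = "generic"
    angle_units_on_disk: str = "deg"
    score_direction_on_disk: str = "higher_better"

    def __post_init__(self) -> None:
        if len(self.solutions) < 2:
            raise InputError(
                f"a docking table needs at least 2 solutions, got {len(self.solutions)}"
            )
        ids = [s.id for s in self.solutions]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate solution ids: {dup}")

    def __len__(self) -> int:
        return len(self.solutions)

    @property
    def n(self) -> int:
        return len(self.solutions)

    def ids(self) -> np.ndarray:
        return np.array([s.id for s in self.solutions], dtype=int)

    def angles(self) -> np.ndarray:
        """(n, 3) array of rotation angles in radians, row order preserved."""
        return np.array([s.angles for s in self.solutions], dtype=float)

    def translations(self) -> np.ndarray:
        """(n, 3) array of translations in angstrom."""
        return np.array([s.translation for s in self.solutions], dtype=float)

    def scores(self) -> np.ndarray:
        return np.array([s.score for s in self.solutions], dtype=float)

    def index_of(self, solution_id: int) -> int:
        for i, s in enumerate(self.solutions):
            if s.id == solution_id:
                return i
        raise InputError(f"unknown solution id: {solution_id}")


DialectReader = Callable[[Path, str, str], DockingTable]

_DIALECTS: dict[str, DialectReader] = {}


def register_dialect(name: str, reader: DialectReader) -> None:
    """Register a reader function for a docking-engine-specific table layout.

    The reader receives ``(path, angle_units, score_direction)`` and must
    return a :class:`DockingTable` obeying the internal conventions.
    """
    _DIALECTS[name] = reader


def _parse_float(text: str, row: int, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(
            f"row {row}: non-numeric value {text!r} in column '{column}'"
        ) from None


def _read_generic(path: Path, angle_units: str, score_direction: str) -> DockingTable:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = [
        (i + 1, line) for i, line in enumerate(lines)
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not rows:
        raise FormatError(f"{path}: empty table")
    header_no, header = rows[0]
    cols = tuple(header.rstrip("\n").split("\t"))
    missing = [c for c in GENERIC_COLUMNS if c not in cols]
    extra = [c for c in cols if c not in GENERIC_COLUMNS]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if extra:
        raise FormatError(f"{path}: unexpected column(s) {extra}")
    if cols != GENERIC_COLUMNS:
        raise FormatError(f"{path}: columns out of order: {cols}")

    to_rad = math.pi / 180.0 if angle_units == "deg" else 1.0
    sign = -1.0 if score_direction == "lower_better" else 1.0
    solutions = []
    for line_no, line in rows[1:]:
        fields = line.split("\t")
        if len(fields) != len(GENERIC_COLUMNS):
            raise FormatError(
                f"{path}: row {line_no}: expected {len(GENERIC_COLUMNS)} fields, "
                f"got {len(fields)}"
            )
        try:
            sid = int(fields[0])
        except ValueError:
            raise ParseError(
                f"row {line_no}: non-integer solution_id {fields[0]!r}"
            ) from None
        vals = [
            _parse_float(f, line_no, c)
            for f, c in zip(fields[1:], GENERIC_COLUMNS[1:])
        ]
        solutions.append(
            DockingSolution(
                id=sid,
                angles=(vals[0] * to_rad, vals[1] * to_rad, vals[2] * to_rad),
                translation=(vals[3], vals[4], vals[5]),
                score=sign * vals[6],
            )
        )
    return DockingTable(
        solutions,
        dialect="generic",
        angle_units_on_disk=angle_units,
        score_direction_on_disk=score_direction,
    )


def read_docking_table(
    path: str | Path,
    dialect: str = "generic",
    angle_units: str = "deg",
    score_direction: str = "higher_better",
) -> DockingTable:
    """Read a docking output table.

    Parameters
    ----------
    path
        Table file.
    dialect
        Registered dialect name; ``"generic"`` is the built-in reference TSV.
    angle_units
        ``"deg"`` or ``"rad"`` — units of the angle columns on disk.
    score_direction
        ``"higher_better"`` or ``"lower_better"``; scores are negated on read
        in the latter case so that internally larger is always better.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if angle_units not in ("deg", "rad"):
        raise ConfigError(f"angle_units must be 'deg' or 'rad', got {angle_units!r}")
    if score_direction not in ("higher_better", "lower_better"):
        raise ConfigError(f"invalid score_direction: {score_direction!r}")
    if dialect == "generic":
        return _read_generic(path, angle_units, score_direction)
    if dialect not in _DIALECTS:
        raise ConfigError(
            f"unknown dialect {dialect!r}; registered: {sorted(_DIALECTS)}"
        )
    table = _DIALECTS[dialect](path, angle_units, score_direction)
    return replace(table, dialect=dialect)


def _fmt(x: float) -> str:
    return format(x, ".17g")


def write_docking_table(
    table: DockingTable, path: str | Path, angle_units: str = "deg"
) -> Path:
    """Write a table in the generic TSV dialect (angles converted to
    ``angle_units`` on disk; scores kept in the internal larger-is-better
    orientation)."""
    if angle_units not in ("deg", "rad"):
        raise ConfigError(f"angle_units must be 'deg' or 'rad', got {angle_units!r}")
    from_rad = 180.0 / math.pi if angle_units == "deg" else 1.0
    path = Path(path)
    lines = ["\t".join(GENERIC_COLUMNS)]
    for s in table.solutions:
        lines.append(
            "\t".join(
                [str(s.id)]
                + [_fmt(a * from_rad) for a in s.angles]
                + [_fmt(t) for t in s.translation]
                + [_fmt(s.score)]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_assignments(
    table: DockingTable,
    labels: np.ndarray,
    path: str | Path,
    representative_ids: Iterable[int] = (),
) -> Path:
    """Write per-solution cluster assignments (input row order preserved)."""
    labels = np.asarray(labels)
    if len(labels) != table.n:
        raise InputError(
            f"labels length {len(labels)} != table size {table.n}"
        )
    reps = set(representative_ids)
    path = Path(path)
    lines = ["id\tcluster\tscore\tis_representative"]
    for s, lab in zip(table.solutions, labels):
        lines.append(f"{s.id}\t{int(lab)}\t{_fmt(s.score)}\t{int(s.id in reps)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_assignments(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an assignments file back; returns (ids, labels, is_representative)."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    ids, labels, reps = [], [], []
    for line in lines[1:]:
        f = line.split("\t")
        ids.append(int(f[0]))
        labels.append(int(f[1]))
        reps.append(int(f[3]))
    return np.array(ids), np.array(labels), np.array(reps)
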