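"""Typed per-contig property table.

The table is the central in-memory container of the toolkit. Each contig
(identified by an exact, case-sensitive string ID) carries values in typed
columns of four kinds:

``numeric``
    finite floats; missing values are ``NaN``.
``categorical``
    strings (e.g. a taxonomic assignment); missing is ``None``.
``feature_set``
    a multiset of feature identifiers (e.g. KO numbers or marker genes)
    stored as a :class:`collections.Counter`; copy number is significant.
    Missing is ``None``; an empty multiset is a valid, present value.
``descriptive``
    free-text strings; missing is ``None``.

Two per-contig flags sit outside the columns: a boolean *mask* (masked
contigs are excluded from summaries, metrics, selections and exports) and
an integer *highlight* slot (0 = not highlighted, 1-8 = a color slot; color
assignment itself is presentation-layer).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "ColumnKind",
    "ColumnSpec",
    "FeatureGroup",
    "ContigTable",
    "AppendReport",
    "TableError",
    "build_table",
    "append_columns",
    "set_flag",
    "focus",
]


class TableError(ValueError):
    """Raised on invariant violations in table construction or editing."""


class ColumnKind(str, Enum):
    NUMERIC = "numeric"
    CATEGORICAL = "categorical"
    FEATURE_SET = "feature_set"
    DESCRIPTIVE = "descriptive"

    @classmethod
    def coerce(cls, value: "ColumnKind | str") -> "ColumnKind":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise TableError(f"unknown column kind: {value!r}") from None


@dataclass(frozen=True)
class ColumnSpec:
    """Name and kind of one table column."""

    name: str
    kind: ColumnKind

    def __post_init__(self) -> None:
        if not self.name:
            raise TableError("column name must be non-empty")
        object.__setattr__(self, "kind", ColumnKind.coerce(self.kind))


@dataclass(frozen=True)
class FeatureGroup:
    """A named set of member features (e.g. single-copy marker genes)."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        members = list(members)
        if not members:
            raise TableError(f"feature group {name!r} has no members")
        if len(members) != len(set(members)):
            dupes = sorted({m for m in members if members.count(m) > 1})
            raise TableError(f"feature group {name!r} has duplicate members: {dupes}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members


@dataclass
class AppendReport:
    """Outcome of appending rows/columns: nothing is dropped silently."""

    n_updated: int = 0
    skipped_ids: list[str] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.skipped_ids)


_MISSING_STRINGS = frozenset({"", "na", "nan", "n/a", "none", "null"})


def parse_value(value, kind: ColumnKind, *, where: str = "value"):
    """Parse a raw cell into the internal representation for *kind*.

    ``None`` and blank/NA-like strings become missing. Raises
    :class:`TableError` naming *where* when the value cannot be parsed.
    """
    kind = ColumnKind.coerce(kind)
    if value is None:
        return _missing(kind)
    if isinstance(value, float) and math.isnan(value):
        return _missing(kind)
    if isinstance(value, str) and value.strip().lower() in _MISSING_STRINGS:
        return _missing(kind)

    if kind is ColumnKind.NUMERIC:
        try:
            x = float(value)
        except (TypeError, ValueError):
            raise TableError(f"cannot parse {value!r} as numeric at {where}") from None
        if math.isinf(x):
            raise TableError(f"non-finite numeric value {value!r} at {where}")
        return x
    if kind is ColumnKind.FEATURE_SET:
        if isinstance(value, Counter):
            return Counter({str(k): int(v) for k, v in value.items() if v > 0})
        if isinstance(value, Mapping):
            return Counter({str(k): int(v) for k, v in value.items() if int(v) > 0})
        if isinstance(value, str):
            items = [tok.strip() for tok in value.split(",")]
            return Counter(tok for tok in items if tok)
        if isinstance(value, Iterable):
            return Counter(str(tok) for tok in value)
        raise TableError(f"cannot parse {value!r} as feature set at {where}")
    # categorical / descriptive
    return str(value)


def join_feature_set(fs: Counter | None) -> str:
    """Render a feature multiset as the canonical comma-joined string."""
    if fs is None:
        return ""
    return ",".join(k for k in sorted(fs) for _ in range(fs[k]))


def _missing(kind: ColumnKind):
    return math.nan if kind is ColumnKind.NUMERIC else None


def _is_missing(value) -> bool:
    if value is None:
        return True
    return isinstance(value, float) and math.isnan(value)


class ContigTable:
    """Ordered collection of contigs with typed columns and flags.

    Values are stored column-major: each column is a Python list aligned
    with :attr:`ids`. Numeric access as a float array (NaN for missing) is
    provided by :meth:`numeric`.
    """

    def __init__(self, ids: Sequence[str]):
        ids = [str(i) for i in ids]
        seen: set[str] = set()
        for cid in ids:
            if cid in seen:
                raise TableError(f"duplicate contig ID: {cid!r}")
            seen.add(cid)
        self.ids: list[str] = ids
        self._index: dict[str, int] = {cid: i for i, cid in enumerate(ids)}
        self._specs: dict[str, ColumnSpec] = {}
        self._values: dict[str, list] = {}
        self.mask: np.ndarray = np.zeros(len(ids), dtype=bool)
        self.highlight: np.ndarray = np.zeros(len(ids), dtype=np.int64)

    # -- introspection -------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, cid: str) -> bool:
        return cid in self._index

    @property
    def columns(self) -> list[str]:
        return list(self._specs)

    def spec(self, name: str) -> ColumnSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise TableError(f"no such column: {name!r}") from None

    def index(self, cid: str) -> int:
        try:
            return self._index[cid]
        except KeyError:
            raise TableError(f"unknown contig ID: {cid!r}") from None

    def values(self, name: str) -> list:
        self.spec(name)
        return self._values[name]

    def value(self, cid: str, name: str):
        return self._values[name][self.index(cid)]

    def numeric(self, name: str) -> np.ndarray:
        """Column as float array (NaN = missing); requires a numeric column."""
        spec = self.spec(name)
        if spec.kind is not ColumnKind.NUMERIC:
            raise TableError(f"column {name!r} is {spec.kind.value}, not numeric")
        return np.asarray(self._values[name], dtype=float)

    def unmasked_ids(self) -> list[str]:
        return [cid for cid, m in zip(self.ids, self.mask) if not m]

    def is_masked(self, cid: str) -> bool:
        return bool(self.mask[self.index(cid)])

    # -- construction / editing ----------------------------------------

    def add_column(self, spec: ColumnSpec, values: list | None = None) -> None:
        if spec.name in self._specs:
            raise TableError(f"column {spec.name!r} already exists")
        if values is None:
            values = [_missing(spec.kind)] * len(self)
        if len(values) != len(self):
            raise TableError(
                f"column {spec.name!r} has {len(values)} values for {len(self)} contigs"
            )
        self._specs[spec.name] = spec
        self._values[spec.name] = values

    def drop_column(self, name: str) -> None:
        self.spec(name)
        del self._specs[name]
        del self._values[name]

    def append_columns(
        self,
        rows: Mapping[str, Mapping[str, object]] | Iterable[tuple[str, Mapping[str, object]]],
        specs: Sequence[ColumnSpec],
        *,
        overwrite: bool = False,
    ) -> AppendReport:
        """Merge new columns/values into the table.

        Rows referencing unknown contig IDs are skipped and reported (never
        silently dropped); contigs absent from *rows* keep missing values in
        the new columns. Colliding column names raise unless *overwrite*.
        """
        specs = list(specs)
        names = [s.name for s in specs]
        if len(names) != len(set(names)):
            raise TableError(f"duplicate column names in specs: {names}")
        for spec in specs:
            if spec.name in self._specs:
                if not overwrite:
                    raise TableError(
                        f"column {spec.name!r} already exists (pass overwrite=True to replace)"
                    )
                self.drop_column(spec.name)
            self.add_column(spec)
        report = AppendReport()
        for cid, record in _iter_rows(rows):
            if cid not in self._index:
                report.skipped_ids.append(cid)
                continue
            idx = self._index[cid]
            for col in record:
                if col not in names:
                    raise TableError(f"row {cid!r} has field {col!r} not covered by specs")
            for spec in specs:
                if spec.name in record:
                    self._values[spec.name][idx] = parse_value(
                        record[spec.name], spec.kind, where=f"row {cid!r}, column {spec.name!r}"
                    )
            report.n_updated += 1
        return report

    # -- flags ---------------------------------------------------------

    def set_mask(self, ids: Iterable[str], value: bool = True) -> None:
        for cid in ids:
            self.mask[self.index(cid)] = value

    def set_highlight(self, ids: Iterable[str], slot: int) -> None:
        slot = int(slot)
        if not 0 <= slot <= 8:
            raise TableError(f"highlight slot must be in 0..8, got {slot}")
        for cid in ids:
            self.highlight[self.index(cid)] = slot

    def focus(self, ids: Iterable[str]) -> None:
        """Mask every contig *not* in *ids* (show only the focused set)."""
        keep = {cid for cid in ids}
        for cid in keep:
            self.index(cid)  # validate
        self.mask = np.array([cid not in keep for cid in self.ids], dtype=bool)

    # -- comparison ----------------------------------------------------

    def equals(self, other: "ContigTable", *, check_flags: bool = True) -> bool:
        if self.ids != other.ids or self.columns != other.columns:
            return False
        for name in self.columns:
            if self._specs[name] != other._specs[name]:
                return False
            for a, b in zip(self._values[name], other._values[name]):
                if _is_missing(a) != _is_missing(b):
                    return False
                if not _is_missing(a) and a != b:
                    return False
        if check_flags:
            if not np.array_equal(self.mask, other.mask):
                return False
            if not np.array_equal(self.highlight, other.highlight):
                return False
        return True

    def copy(self) -> "ContigTable":
        out = ContigTable(self.ids)
        for name, spec in self._specs.items():
            out.add_column(spec, [_copy_value(v) for v in self._values[name]])
        out.mask = self.mask.copy()
        out.highlight = self.highlight.copy()
        return out

    def __repr__(self) -> str:
        return (
            f"<ContigTable: {len(self)} contigs, {len(self._specs)} columns, "
            f"{int(self.mask.sum())} masked>"
        )


def _copy_value(v):
    return Counter(v) if isinstance(v, Counter) else v


def _iter_rows(rows) -> Iterator[tuple[str, Mapping[str, object]]]:
    if isinstance(rows, Mapping):
        yield from ((str(k), v) for k, v in rows.items())
    else:
        for item in rows:
            cid, record = item
            yield str(cid), record


def build_table(
    rows: Mapping[str, Mapping[str, object]] | Iterable[tuple[str, Mapping[str, object]]],
    specs: Sequence[ColumnSpec],
) -> ContigTable:
    """Construct a table from per-contig records and column specs.

    Duplicate IDs and fields not covered by *specs* are errors; feature-set
    cells given as comma-joined strings are split into multisets. All flags
    start cleared (mask False, highlight 0).
    """
    pairs = list(_iter_rows(rows))
    ids = []
    seen: set[str] = set()
    for cid, _ in pairs:
        if cid in seen:
            raise TableError(f"duplicate contig ID: {cid!r}")
        seen.add(cid)
        ids.append(cid)
    table = ContigTable(ids)
    by_name = {s.name: s for s in specs}
    if len(by_name) != len(specs):
        raise TableError("duplicate column names in specs")
    for spec in specs:
        table.add_column(spec)
    for cid, record in pairs:
        idx = table.index(cid)
        for col, raw in record.items():
            if col not in by_name:
                raise TableError(f"row {cid!r} has field {col!r} not covered by specs")
            table._values[col][idx] = parse_value(
                raw, by_name[col].kind, where=f"row {cid!r}, column {col!r}"
            )
    return table


def append_columns(table: ContigTable, rows, specs, *, overwrite: bool = False):
    """Functional wrapper over :meth:`ContigTable.append_columns`."""
    report = table.append_columns(rows, specs, overwrite=overwrite)
    return table, report


def set_flag(table: ContigTable, ids: Iterable[str], flag: str, value) -> ContigTable:
    """Set the mask or highlight flag on *ids*; unknown IDs are errors."""
    if flag == "mask":
        table.set_mask(ids, bool(value))
    elif flag == "highlight":
        table.set_highlight(ids, int(value))
    else:
        raise TableError(f"unknown flag: {flag!r} (expected 'mask' or 'highlight')")
    return table


def focus(table: ContigTable, ids: Iterable[str]) -> ContigTable:
    table.focus(ids)
    return table
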