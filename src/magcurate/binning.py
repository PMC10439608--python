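"""Binning-plan editing with undo, contig selection, and per-bin summaries.

A :class:`BinningPlan` is a named, *partial* assignment of contigs to
bins: a contig is in at most one bin, and may be in none. Every edit
appends a reversible record to the plan's history, so any sequence of
edits can be undone step by step — moving a contig between bins is a
single atomic record, which is what guarantees undo can never create a
double membership.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .table import ColumnKind, ContigTable, TableError

__all__ = [
    "BinningPlan",
    "BinSummary",
    "PlanError",
    "edit_plan",
    "select_polygon",
    "search_contigs",
    "summarize_plan",
    "read_plan_tsv",
    "write_plan_tsv",
]


class PlanError(ValueError):
    """Raised on invalid binning-plan edits."""


@dataclass
class BinningPlan:
    """Partial contig -> bin assignment with an undoable edit history."""

    name: str = "plan"
    assignment: dict[str, str] = field(default_factory=dict)
    bins: set[str] = field(default_factory=set)
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.bins |= set(self.assignment.values())

    @classmethod
    def from_assignment(cls, assignment: Mapping[str, str], name: str = "plan") -> "BinningPlan":
        return cls(name=name, assignment=dict(assignment))

    def members(self, bin_name: str) -> set[str]:
        if bin_name not in self.bins:
            raise PlanError(f"unknown bin: {bin_name!r}")
        return {cid for cid, b in self.assignment.items() if b == bin_name}

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def copy(self) -> "BinningPlan":
        return BinningPlan(
            name=self.name,
            assignment=dict(self.assignment),
            bins=set(self.bins),
            history=[dict(rec) for rec in self.history],
        )

    def same_assignment(self, other: "BinningPlan") -> bool:
        return self.assignment == other.assignment and self.bins == other.bins

    # -- edits (each appends exactly one reversible history record) ----

    def create_bin(self, bin_name: str) -> None:
        if not bin_name:
            raise PlanError("bin name must be non-empty")
        if bin_name in self.bins:
            raise PlanError(f"bin {bin_name!r} already exists")
        self.bins.add(bin_name)
        self.history.append({"action": "create", "bin": bin_name})

    def assign(self, ids: Iterable[str], bin_name: str) -> None:
        """Assign contigs to an existing bin, moving them out of any other."""
        if bin_name not in self.bins:
            raise PlanError(f"unknown bin: {bin_name!r}")
        ids = list(ids)
        prior = {cid: self.assignment.get(cid) for cid in ids}
        for cid in ids:
            self.assignment[cid] = bin_name
        self.history.append({"action": "assign", "bin": bin_name, "prior": prior})

    def unassign(self, ids: Iterable[str]) -> None:
        ids = list(ids)
        prior = {cid: self.assignment.get(cid) for cid in ids}
        for cid in ids:
            self.assignment.pop(cid, None)
        self.history.append({"action": "unassign", "prior": prior})

    def merge(self, sources: Sequence[str], into: str) -> None:
        """Merge >= 2 bins into one of them (the others disappear)."""
        sources = list(sources)
        if len(sources) < 2:
            raise PlanError("merge needs at least 2 bins")
        if into not in sources:
            raise PlanError(f"target bin {into!r} must be one of the merged bins")
        for b in sources:
            if b not in self.bins:
                raise PlanError(f"unknown bin: {b!r}")
        moved = {cid: b for cid, b in self.assignment.items() if b in sources and b != into}
        for cid in moved:
            self.assignment[cid] = into
        removed = [b for b in sources if b != into]
        self.bins -= set(removed)
        self.history.append(
            {"action": "merge", "into": into, "removed": removed, "moved": moved}
        )

    def delete_bin(self, bin_name: str) -> None:
        if bin_name not in self.bins:
            raise PlanError(f"unknown bin: {bin_name!r}")
        removed = {cid for cid, b in self.assignment.items() if b == bin_name}
        for cid in removed:
            del self.assignment[cid]
        self.bins.discard(bin_name)
        self.history.append({"action": "delete", "bin": bin_name, "members": removed})

    def rename_bin(self, old: str, new: str) -> None:
        if old not in self.bins:
            raise PlanError(f"unknown bin: {old!r}")
        if not new:
            raise PlanError("bin name must be non-empty")
        if new in self.bins:
            raise PlanError(f"bin {new!r} already exists")
        for cid, b in self.assignment.items():
            if b == old:
                self.assignment[cid] = new
        self.bins.discard(old)
        self.bins.add(new)
        self.history.append({"action": "rename", "old": old, "new": new})

    def undo(self) -> None:
        """Revert exactly the most recent edit."""
        if not self.history:
            raise PlanError("nothing to undo")
        rec = self.history.pop()
        action = rec["action"]
        if action == "create":
            self.bins.discard(rec["bin"])
        elif action == "assign" or action == "unassign":
            for cid, prev in rec["prior"].items():
                if prev is None:
                    self.assignment.pop(cid, None)
                else:
                    self.assignment[cid] = prev
        elif action == "merge":
            self.bins |= set(rec["removed"])
            for cid, prev in rec["moved"].items():
                self.assignment[cid] = prev
        elif action == "delete":
            self.bins.add(rec["bin"])
            for cid in rec["members"]:
                self.assignment[cid] = rec["bin"]
        elif action == "rename":
            old, new = rec["old"], rec["new"]
            for cid, b in self.assignment.items():
                if b == new:
                    self.assignment[cid] = old
            self.bins.discard(new)
            self.bins.add(old)
        else:  # pragma: no cover
            raise PlanError(f"corrupt history record: {rec}")


def edit_plan(plan: BinningPlan, action: str, **args) -> BinningPlan:
    """Dispatch one named edit onto *plan* (mutates and returns it)."""
    dispatch = {
        "create": lambda: plan.create_bin(args["bin"]),
        "assign": lambda: plan.assign(args["ids"], args["bin"]),
        "unassign": lambda: plan.unassign(args["ids"]),
        "merge": lambda: plan.merge(args["bins"], args["into"]),
        "delete": lambda: plan.delete_bin(args["bin"]),
        "rename": lambda: plan.rename_bin(args["old"], args["new"]),
        "undo": plan.undo,
    }
    if action not in dispatch:
        raise PlanError(f"unknown plan action: {action!r}")
    dispatch[action]()
    return plan


# -- geometric selection ----------------------------------------------


def _on_segment(px: float, py: float, ax: float, ay: float, bx: float, by: float) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if cross != 0.0:
        return False
    return min(ax, bx) <= px <= max(ax, bx) and min(ay, by) <= py <= max(ay, by)


def point_in_polygon(x: float, y: float, polygon: Sequence[tuple[float, float]]) -> bool:
    """Even-odd (ray casting) membership; boundary points are inside.

    The polygon is implicitly closed and may be listed in either winding
    order; self-intersecting polygons follow the even-odd rule.
    """
    n = len(polygon)
    inside = False
    for i in range(n):
        ax, ay = polygon[i]
        bx, by = polygon[(i + 1) % n]
        if _on_segment(x, y, ax, ay, bx, by):
            return True
        # count crossings of a horizontal ray to the right of (x, y)
        if (ay > y) != (by > y):
            x_int = ax + (y - ay) * (bx - ax) / (by - ay)
            if x_int > x:
                inside = not inside
    return inside


def select_polygon(
    coords: Mapping[str, tuple[float, float]],
    polygon: Sequence[tuple[float, float]],
    *,
    table: ContigTable | None = None,
) -> list[str]:
    """Contigs whose (x, y) coordinates fall inside a drawn polygon.

    Masked contigs are excluded when *table* is given. Points exactly on
    an edge count as selected.
    """
    if len(polygon) < 3:
        raise ValueError(f"polygon needs >= 3 vertices, got {len(polygon)}")
    out = []
    for cid, (x, y) in coords.items():
        if table is not None and cid in table and table.is_masked(cid):
            continue
        if point_in_polygon(float(x), float(y), polygon):
            out.append(cid)
    return out


# -- attribute search --------------------------------------------------

_NUMERIC_OPS = ("<", "<=", "=", ">=", ">", "between")
_CATEGORICAL_OPS = ("equals", "contains", "regex")
_FEATURE_OPS = ("has",)


def search_contigs(table: ContigTable, query, *more_queries) -> list[str]:
    """Unmasked contigs matching one or more predicates (conjunction).

    Each query is a ``{"column": ..., "op": ..., "value": ...}`` mapping.
    Supported ops by column kind: numeric ``< <= = >= > between`` (value
    of ``between`` is a (lo, hi) pair, inclusive); categorical ``equals
    contains regex``; feature_set ``has`` (multiset membership). Missing
    values never match.
    """
    queries = [query, *more_queries]
    matchers = []
    for q in queries:
        column, op, value = q["column"], q["op"], q["value"]
        spec = table.spec(column)
        if spec.kind is ColumnKind.NUMERIC:
            if op not in _NUMERIC_OPS:
                raise TableError(f"op {op!r} invalid for numeric column {column!r}")
            vals = table.numeric(column)
            if op == "between":
                lo, hi = value
                fn = lambda i, v=vals, lo=lo, hi=hi: lo <= v[i] <= hi
            else:
                cmp = {
                    "<": np.less,
                    "<=": np.less_equal,
                    "=": np.equal,
                    ">=": np.greater_equal,
                    ">": np.greater,
                }[op]
                fn = lambda i, v=vals, c=cmp, t=float(value): not np.isnan(v[i]) and bool(
                    c(v[i], t)
                )
        elif spec.kind in (ColumnKind.CATEGORICAL, ColumnKind.DESCRIPTIVE):
            if op not in _CATEGORICAL_OPS:
                raise TableError(f"op {op!r} invalid for {spec.kind.value} column {column!r}")
            vals = table.values(column)
            if op == "equals":
                fn = lambda i, v=vals, t=str(value): v[i] == t
            elif op == "contains":
                fn = lambda i, v=vals, t=str(value): v[i] is not None and t in v[i]
            else:
                pat = re.compile(str(value))
                fn = lambda i, v=vals, p=pat: v[i] is not None and p.search(v[i]) is not None
        elif spec.kind is ColumnKind.FEATURE_SET:
            if op not in _FEATURE_OPS:
                raise TableError(f"op {op!r} invalid for feature_set column {column!r}")
            vals = table.values(column)
            fn = lambda i, v=vals, t=str(value): v[i] is not None and v[i][t] > 0
        matchers.append(fn)
    return [
        cid
        for i, cid in enumerate(table.ids)
        if not table.mask[i] and all(fn(i) for fn in matchers)
    ]


# -- per-bin summaries -------------------------------------------------


@dataclass(frozen=True)
class BinSummary:
    """Totals of one bin over its unmasked members.

    ``abundance`` maps each coverage column (one per sample) to the
    length-weighted mean depth of the bin's members (or the summed
    length x depth "mass" under ``mode='mass'``); NaN for empty bins.
    """

    bin: str
    n_contigs: int
    total_length: float
    abundance: dict[str, float]


def summarize_plan(
    plan: BinningPlan,
    table: ContigTable,
    coverage_columns: Sequence[str] = (),
    *,
    length_column: str = "length",
    mode: str = "mean",
) -> list[BinSummary]:
    """Per-bin contig count, total length, and per-sample abundance."""
    if mode not in ("mean", "mass"):
        raise ValueError(f"unknown abundance mode: {mode!r}")
    lengths = table.numeric(length_column)
    covs = {c: table.numeric(c) for c in coverage_columns}
    out = []
    for bin_name in sorted(plan.bins):
        idx = [
            table.index(cid)
            for cid in plan.members(bin_name)
            if cid in table and not table.is_masked(cid)
        ]
        lens = np.array([lengths[i] for i in idx])
        ok = ~np.isnan(lens)
        total_length = float(lens[ok].sum()) if idx else 0.0
        abundance = {}
        for cname, cov in covs.items():
            c = np.array([cov[i] for i in idx])
            keep = ok & ~np.isnan(c) if idx else np.array([], dtype=bool)
            if not idx or not keep.any():
                abundance[cname] = float("nan")
            elif mode == "mass":
                abundance[cname] = float(np.sum(lens[keep] * c[keep]))
            else:
                abundance[cname] = float(
                    np.sum(lens[keep] * c[keep]) / np.sum(lens[keep])
                )
        out.append(
            BinSummary(
                bin=bin_name,
                n_contigs=len(idx),
                total_length=total_length,
                abundance=abundance,
            )
        )
    return out


# -- plan I/O ----------------------------------------------------------


def write_plan_tsv(plan: BinningPlan, path) -> None:
    """Write the 2-column plan format: ``#contig<TAB>bin``, one binned
    contig per row, unbinned contigs omitted."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#contig\tbin\n")
        for cid in sorted(plan.assignment):
            fh.write(f"{cid}\t{plan.assignment[cid]}\n")


def read_plan_tsv(path, *, shape: str = "auto", name: str | None = None) -> BinningPlan:
    """Read a binning plan from TSV.

    Two shapes are accepted: ``contig_bin`` (two columns, contig then
    bin) and ``members`` (bin name then a comma-joined member list).
    ``auto`` picks ``members`` when the header comment says ``#bin`` or
    any second field contains a comma.
    """
    path = Path(path)
    lines = []
    header = None
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if header is None:
                    header = line
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise PlanError(f"{path.name}:{lineno}: expected 2 tab-separated fields")
            lines.append((lineno, fields))
    if shape == "auto":
        if header is not None and header.lower().startswith("#bin"):
            shape = "members"
        elif any("," in fields[1] for _, fields in lines):
            shape = "members"
        else:
            shape = "contig_bin"
    assignment: dict[str, str] = {}
    bins: set[str] = set()
    if shape == "contig_bin":
        for lineno, (cid, bin_name) in lines:
            if cid in assignment:
                raise PlanError(f"{path.name}:{lineno}: contig {cid!r} assigned twice")
            assignment[cid] = bin_name
            bins.add(bin_name)
    elif shape == "members":
        for lineno, (bin_name, members) in lines:
            bins.add(bin_name)
            for cid in (tok.strip() for tok in members.split(",")):
                if not cid:
                    continue
                if cid in assignment:
                    raise PlanError(f"{path.name}:{lineno}: contig {cid!r} assigned twice")
                assignment[cid] = bin_name
    else:
        raise ValueError(f"unknown plan shape: {shape!r}")
    return BinningPlan(name=name or path.stem, assignment=assignment, bins=bins)
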