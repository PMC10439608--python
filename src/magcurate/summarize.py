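"""Selection summaries, histograms and range filtering.

All operations honor the table mask (masked contigs are excluded) and
skip missing values; an empty effective selection yields a missing
result, not an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .table import ColumnKind, ContigTable, TableError
from .transforms import transform_values

__all__ = [
    "CategorySummary",
    "HistogramResult",
    "summarize_numeric",
    "summarize_category",
    "histogram",
    "select_range",
]

NUMERIC_SUMMARY_METHODS = ("sum", "mean", "weighted_mean", "min", "max", "median")


@dataclass(frozen=True)
class CategorySummary:
    """Majority category of a selection, with its share of annotated contigs.

    Rendered as ``"label (NN%)"`` — e.g. a selection whose length-weighted
    majority is Firmicutes at 80% prints as ``"Firmicutes (80%)"``.
    """

    label: str
    fraction: float
    weighted: bool

    def __str__(self) -> str:
        return f"{self.label} ({round(self.fraction * 100):.0f}%)"


@dataclass(frozen=True)
class HistogramResult:
    """Equal-width histogram of a (transformed) numeric column.

    Bins are half-open ``[lo, hi)`` except the last, which is closed, so
    counts conserve the number of unmasked contigs with non-missing
    transformed values.
    """

    edges: np.ndarray
    counts: np.ndarray
    transform: str
    column: str

    @property
    def n_bins(self) -> int:
        return len(self.counts)


def _selection_indices(table: ContigTable, ids: Iterable[str] | None) -> list[int]:
    """Indices of unmasked selected contigs (all contigs when ids is None)."""
    if ids is None:
        return [i for i in range(len(table)) if not table.mask[i]]
    out = []
    for cid in ids:
        i = table.index(cid)
        if not table.mask[i]:
            out.append(i)
    return out


def _numeric_selection(table, ids, column, transform="none"):
    spec = table.spec(column)
    if spec.kind is not ColumnKind.NUMERIC:
        raise TableError(f"column {column!r} is {spec.kind.value}, not numeric")
    idx = _selection_indices(table, ids)
    vals = table.numeric(column)[idx]
    if transform != "none":
        vals, _ = transform_values(vals, transform)
    return np.asarray(idx, dtype=int), vals


def summarize_numeric(
    table: ContigTable,
    ids: Iterable[str] | None,
    column: str,
    method: str = "mean",
    weight_column: str | None = None,
) -> float:
    """Summarize a numeric column over a selection.

    ``weighted_mean`` computes sum(w*x)/sum(w) with weights from
    *weight_column* (e.g. GC content weighted by contig length). Masked
    contigs and missing values are excluded; an empty effective selection
    returns NaN.
    """
    if method not in NUMERIC_SUMMARY_METHODS:
        raise ValueError(f"unknown summary method: {method!r}")
    idx, vals = _numeric_selection(table, ids, column)
    if method == "weighted_mean":
        if weight_column is None:
            raise TableError("weighted_mean requires a weight_column")
        w = table.numeric(weight_column)[idx]
        keep = ~np.isnan(vals) & ~np.isnan(w)
        vals, w = vals[keep], w[keep]
        if vals.size == 0:
            return float("nan")
        if np.any(w < 0):
            raise TableError(f"negative weights in column {weight_column!r}")
        if not np.any(w > 0):
            raise TableError(f"all-zero weights in column {weight_column!r}")
        return float(np.sum(w * vals) / np.sum(w))
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    fn = {
        "sum": np.sum,
        "mean": np.mean,
        "min": np.min,
        "max": np.max,
        "median": np.median,
    }[method]
    return float(fn(vals))


def summarize_category(
    table: ContigTable,
    ids: Iterable[str] | None,
    column: str,
    weighted: bool = False,
    weight_column: str | None = None,
) -> CategorySummary | None:
    """Majority-rule category of a selection, optionally weighted.

    The fraction is the winner's share among *annotated* (non-missing)
    contigs of the selection; ties break lexicographically by label.
    Returns None when no contig in the selection is annotated.
    """
    spec = table.spec(column)
    if spec.kind is not ColumnKind.CATEGORICAL:
        raise TableError(f"column {column!r} is {spec.kind.value}, not categorical")
    idx = _selection_indices(table, ids)
    values = table.values(column)
    if weighted:
        if weight_column is None:
            raise TableError("weighted summary requires a weight_column")
        w = table.numeric(weight_column)
        weights = {i: w[i] for i in idx if not np.isnan(w[i])}
    else:
        weights = {i: 1.0 for i in idx}
    shares: dict[str, float] = {}
    for i in idx:
        v = values[i]
        if v is None or i not in weights:
            continue
        shares[v] = shares.get(v, 0.0) + weights[i]
    total = sum(shares.values())
    if not shares or total <= 0:
        return None
    winner = min(shares, key=lambda lab: (-shares[lab], lab))
    return CategorySummary(winner, shares[winner] / total, weighted)


def histogram(
    table: ContigTable,
    ids: Iterable[str] | None,
    column: str,
    n_bins: int = 20,
    transform: str = "none",
) -> HistogramResult:
    """Equal-width histogram over the transformed values of a selection.

    A constant-valued selection gets its range widened by 0.5 on each side
    so bins remain well-defined. Raises when the selection has no finite
    transformed values.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    _, vals = _numeric_selection(table, ids, column, transform)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise TableError(f"no finite values in column {column!r} for histogram")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    return HistogramResult(edges=edges, counts=counts, transform=transform, column=column)


def select_range(
    table: ContigTable,
    ids: Iterable[str] | None,
    column: str,
    lo: float,
    hi: float,
    transform: str = "none",
) -> list[str]:
    """Contigs whose transformed value falls in the closed range [lo, hi].

    Mirrors dragging a range on the interactive histogram: masked contigs
    and missing values never match; bounds are inclusive.
    """
    if lo > hi:
        raise ValueError(f"lo ({lo}) must be <= hi ({hi})")
    idx, vals = _numeric_selection(table, ids, column, transform)
    keep = ~np.isnan(vals) & (vals >= lo) & (vals <= hi)
    return [table.ids[i] for i, k in zip(idx, keep) if k]
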