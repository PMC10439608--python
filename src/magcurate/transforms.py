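"""Numeric value transformations.

Metagenomic properties span wildly different scales and shapes (contig
lengths and depths are heavy-tailed, GC and breadth are proportions), so a
small toolbox of monotone transforms is applied before histogramming,
range selection, display scaling, or distance computation:

====== ==========================================
method definition
====== ==========================================
none   identity
square x^2
cube   x^3
sqrt   sqrt(x), defined for x >= 0
cbrt   sign-preserving cube root (cbrt(-8) = -2)
log    log10(x), defined for x > 0
exp    10^x (inverse of ``log``)
logit  ln(x / (1 - x)), defined for 0 < x < 1
arcsine asin(sqrt(x)), defined for 0 <= x <= 1
rank   1-based ranks, ties averaged
====== ==========================================

Out-of-domain inputs (e.g. log of a zero-coverage contig) are soft
failures: they become missing and are counted in the returned report, so
that interactively toggling transforms never aborts on a few bad values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["TRANSFORM_METHODS", "TransformReport", "transform_values"]

TRANSFORM_METHODS = (
    "none",
    "square",
    "cube",
    "sqrt",
    "cbrt",
    "log",
    "exp",
    "logit",
    "arcsine",
    "rank",
)


@dataclass(frozen=True)
class TransformReport:
    """Bookkeeping for one transform application."""

    method: str
    n_missing_in: int
    n_out_of_domain: int

    @property
    def n_missing_out(self) -> int:
        return self.n_missing_in + self.n_out_of_domain


def transform_values(values, method: str = "none"):
    """Apply *method* element-wise to a numeric vector with missing values.

    Parameters
    ----------
    values
        Sequence of floats; NaN marks missing.
    method
        One of :data:`TRANSFORM_METHODS`.

    Returns
    -------
    (numpy.ndarray, TransformReport)
        Transformed vector of the same length (NaN where the input was
        missing or out of the transform's domain) and a report counting
        domain violations.
    """
    if method not in TRANSFORM_METHODS:
        raise ValueError(f"unknown transform: {method!r} (choose from {TRANSFORM_METHODS})")
    x = np.asarray(values, dtype=float)
    missing_in = np.isnan(x)

    if method == "rank":
        out = np.full(x.shape, np.nan)
        finite = ~missing_in
        if finite.any():
            out[finite] = rankdata(x[finite], method="average")
        return out, TransformReport(method, int(missing_in.sum()), 0)

    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        if method == "none":
            out, bad = x.copy(), np.zeros_like(missing_in)
        elif method == "square":
            out, bad = x**2, np.zeros_like(missing_in)
        elif method == "cube":
            out, bad = x**3, np.zeros_like(missing_in)
        elif method == "sqrt":
            bad = x < 0
            out = np.sqrt(np.where(bad, np.nan, x))
        elif method == "cbrt":
            out, bad = np.cbrt(x), np.zeros_like(missing_in)
        elif method == "log":
            bad = x <= 0
            out = np.log10(np.where(bad, np.nan, x))
        elif method == "exp":
            out, bad = 10.0**x, np.zeros_like(missing_in)
        elif method == "logit":
            bad = (x <= 0) | (x >= 1)
            safe = np.where(bad, np.nan, x)
            out = np.log(safe / (1.0 - safe))
        elif method == "arcsine":
            bad = (x < 0) | (x > 1)
            out = np.arcsin(np.sqrt(np.where(bad, np.nan, x)))

    bad = bad & ~missing_in
    out[bad] = np.nan
    if not np.all(np.isfinite(out) | np.isnan(out)):
        # overflow in square/cube/exp on extreme inputs counts as out-of-domain
        overflow = ~np.isfinite(out) & ~np.isnan(out)
        out[overflow] = np.nan
        bad = bad | overflow
    return out, TransformReport(method, int(missing_in.sum()), int(bad.sum()))
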