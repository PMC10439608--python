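"""Quantitative evaluation of binning plans and contig selections.

Four families of metrics support interactive curation:

* **Silhouette coefficient** — per-contig confidence of its bin assignment
  in a numeric feature space (typically the 2D embedding). For contig *i*
  with mean intra-bin distance ``a(i)`` and smallest mean distance to any
  other bin ``b(i)``, ``s(i) = (b(i) - a(i)) / max(a(i), b(i))``; members
  of singleton bins get ``s = 0`` (Rousseeuw's convention).
* **Adjusted Rand index** — chance-corrected agreement between two binning
  plans via pair counting over the contingency table ``n_ij``:
  ``ARI = (Index - Expected) / (Max - Expected)`` with
  ``Index = sum_ij C(n_ij, 2)``,
  ``Expected = sum_i C(a_i, 2) * sum_j C(b_j, 2) / C(n, 2)`` and
  ``Max = (sum_i C(a_i, 2) + sum_j C(b_j, 2)) / 2``.
* **Completeness / redundancy** — marker-gene presence over a selection:
  completeness is the percentage of a feature group's members found at
  least once; redundancy (a.k.a. contamination) is the percentage of
  excess copies relative to the group size and may exceed 100%. Marker
  collocation is deliberately not modeled; this is a first-pass check,
  not a replacement for a lineage-aware post-binning assessment.
* **Quality tiers** — the community-standard MAG catalog classes:
  high (>= 90% complete, < 5% contaminated), medium (>= 50%, < 10%),
  low (< 50%, < 10%); anything >= 10% contaminated is excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb

from .table import ColumnKind, ContigTable, FeatureGroup, TableError

__all__ = [
    "SilhouetteResult",
    "ARIResult",
    "QualityTier",
    "BinComparison",
    "MetricError",
    "silhouette_scores",
    "silhouette_from_table",
    "adjusted_rand",
    "completeness_redundancy",
    "classify_quality",
    "compare_bins",
]


class MetricError(ValueError):
    """Raised when a metric's preconditions are violated."""


@dataclass(frozen=True)
class SilhouetteResult:
    per_contig: dict[str, float]
    per_bin_mean: dict[str, float]
    overall_mean: float
    n_used: int


@dataclass(frozen=True)
class ARIResult:
    ari: float
    n_shared: int
    contingency: pd.DataFrame


class QualityTier(str, Enum):
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class BinComparison:
    jaccard: float
    containment_a_in_b: float
    containment_b_in_a: float


def _as_assignment(plan) -> Mapping[str, str]:
    """Accept a BinningPlan or a plain contig->bin mapping."""
    return getattr(plan, "assignment", plan)


def silhouette_scores(
    coords: Mapping[str, Sequence[float]],
    labels: Mapping[str, str],
    *,
    standardize: bool = True,
    sample_size: int | None = None,
    seed: int | None = None,
) -> SilhouetteResult:
    """Exact all-pairs Euclidean silhouette of a binning over coordinates.

    Parameters
    ----------
    coords
        Per-contig feature vectors (all the same dimension d >= 1).
    labels
        Partial contig -> bin assignment; only contigs present in both
        *coords* and *labels* are scored (n_used reports how many).
    standardize
        Scale each feature to zero mean / unit variance before computing
        distances, so no single raw axis (e.g. coverage) dominates.
        Constant features are left unscaled.
    sample_size
        If given and smaller than the number of scorable contigs, a
        random subsample of that size (seeded by *seed*) is scored
        instead; intended for very large assemblies.

    Raises on fewer than 2 bins or any non-finite coordinate.
    """
    ids = [cid for cid in coords if cid in labels]
    if sample_size is not None and len(ids) > sample_size:
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(ids), size=sample_size, replace=False)
        ids = [ids[i] for i in sorted(keep)]
    if len(ids) < 2:
        raise MetricError("silhouette needs at least 2 labeled contigs")
    X = np.asarray([coords[cid] for cid in ids], dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    bad = ~np.all(np.isfinite(X), axis=1)
    if bad.any():
        names = [ids[i] for i in np.flatnonzero(bad)[:5]]
        raise MetricError(f"non-finite coordinates for contigs: {names}")
    bins = [labels[cid] for cid in ids]
    uniq = sorted(set(bins))
    if len(uniq) < 2:
        raise MetricError("silhouette needs at least 2 bins")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    D = squareform(pdist(X, metric="euclidean"))
    bin_index = {b: j for j, b in enumerate(uniq)}
    member = np.zeros((len(ids), len(uniq)))
    for i, b in enumerate(bins):
        member[i, bin_index[b]] = 1.0
    counts = member.sum(axis=0)            # contigs per bin
    sums = D @ member                      # sums[i, j] = sum of d(i, bin j)

    s = np.zeros(len(ids))
    for i, b in enumerate(bins):
        j = bin_index[b]
        if counts[j] <= 1:
            continue  # singleton bin: s = 0 by convention
        a = sums[i, j] / (counts[j] - 1)
        others = [sums[i, k] / counts[k] for k in range(len(uniq)) if k != j]
        bmin = min(others)
        denom = max(a, bmin)
        s[i] = 0.0 if denom == 0 else (bmin - a) / denom

    per_contig = {cid: float(v) for cid, v in zip(ids, s)}
    per_bin = {
        b: float(np.mean([s[i] for i, bb in enumerate(bins) if bb == b])) for b in uniq
    }
    return SilhouetteResult(
        per_contig=per_contig,
        per_bin_mean=per_bin,
        overall_mean=float(s.mean()),
        n_used=len(ids),
    )


def silhouette_from_table(
    table: ContigTable,
    plan,
    columns: Sequence[str],
    **kwargs,
) -> SilhouetteResult:
    """Silhouette over designated numeric table columns, mask-aware.

    Masked and unbinned contigs, and contigs with any missing value in the
    designated columns, are excluded before scoring.
    """
    assignment = _as_assignment(plan)
    mats = [table.numeric(c) for c in columns]
    coords = {}
    for i, cid in enumerate(table.ids):
        if table.mask[i] or cid not in assignment:
            continue
        vec = [m[i] for m in mats]
        if all(math.isfinite(v) for v in vec):
            coords[cid] = vec
    return silhouette_scores(coords, assignment, **kwargs)


def adjusted_rand(
    plan_a,
    plan_b,
    *,
    exclude: Iterable[str] = (),
) -> ARIResult:
    """Adjusted Rand index between two binning plans.

    Computed over the intersection of contigs binned in both plans
    (optionally minus *exclude*, e.g. masked contigs); ``n_shared``
    reports the subset size so the restriction is auditable. ARI is 1
    exactly when the plans agree on the shared contigs.
    """
    a = _as_assignment(plan_a)
    b = _as_assignment(plan_b)
    excluded = set(exclude)
    shared = [cid for cid in a if cid in b and cid not in excluded]
    if len(shared) < 2:
        raise MetricError(
            f"adjusted Rand index needs >= 2 contigs binned in both plans (got {len(shared)})"
        )
    la = pd.Categorical([a[cid] for cid in shared])
    lb = pd.Categorical([b[cid] for cid in shared])
    cont = pd.crosstab(la, lb)
    nij = cont.to_numpy(dtype=np.int64)
    n = len(shared)
    index = comb(nij, 2).sum()
    sum_a = comb(nij.sum(axis=1), 2).sum()
    sum_b = comb(nij.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:
        # both partitions trivial (all-in-one vs all-in-one, or all singletons)
        ari = 1.0 if index == maximum else 0.0
    else:
        ari = float((index - expected) / (maximum - expected))
    return ARIResult(ari=ari, n_shared=n, contingency=cont)


def completeness_redundancy(
    table: ContigTable,
    ids: Iterable[str] | None,
    group: FeatureGroup,
    feature_column: str,
) -> tuple[float, float]:
    """Marker completeness and redundancy (%) of a contig selection.

    Over the unmasked selected contigs, with ``found`` the distinct group
    members present and ``total`` the summed copy count of group members:
    ``completeness = 100 * |found| / |group|`` and
    ``redundancy = 100 * (total - |found|) / |group|``.
    """
    spec = table.spec(feature_column)
    if spec.kind is not ColumnKind.FEATURE_SET:
        raise TableError(f"column {feature_column!r} is {spec.kind.value}, not feature_set")
    if len(group) == 0:
        raise MetricError("empty feature group")
    values = table.values(feature_column)
    if ids is None:
        ids = table.ids
    found: set[str] = set()
    total = 0
    for cid in ids:
        i = table.index(cid)
        if table.mask[i]:
            continue
        fs = values[i]
        if fs is None:
            continue
        for feat, count in fs.items():
            if feat in group:
                found.add(feat)
                total += count
    completeness = 100.0 * len(found) / len(group)
    redundancy = 100.0 * (total - len(found)) / len(group)
    return completeness, redundancy


def classify_quality(completeness: float, contamination: float) -> QualityTier:
    """MAG catalog tier from completeness and contamination percentages."""
    if completeness < 0 or contamination < 0:
        raise MetricError(
            f"completeness/contamination must be non-negative, got "
            f"({completeness}, {contamination})"
        )
    if contamination >= 10:
        return QualityTier.EXCLUDED
    if completeness >= 90 and contamination < 5:
        return QualityTier.HIGH
    if completeness >= 50:
        return QualityTier.MEDIUM
    return QualityTier.LOW


def compare_bins(
    bin_a: Iterable[str],
    bin_b: Iterable[str],
    lengths: Mapping[str, float],
    *,
    weighted: bool = True,
) -> BinComparison:
    """Length-weighted Jaccard index and mutual containment of two bins.

    ``jaccard = len(A & B) / len(A | B)`` and
    ``containment_X = len(A & B) / len(X)``, with ``len`` the summed
    contig length (or the contig count when ``weighted=False``).
    """
    a, b = set(bin_a), set(bin_b)
    union = a | b
    if not union:
        raise MetricError("both bins are empty")
    if weighted:
        missing = [cid for cid in union if cid not in lengths]
        if missing:
            raise MetricError(f"no length for contigs: {sorted(missing)[:5]}")
        size = lambda s: float(sum(lengths[cid] for cid in s))
    else:
        size = lambda s: float(len(s))
    shared = size(a & b)
    size_a, size_b = size(a), size(b)
    return BinComparison(
        jaccard=shared / size(union),
        containment_a_in_b=shared / size_a if size_a else 0.0,
        containment_b_in_a=shared / size_b if size_b else 0.0,
    )
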