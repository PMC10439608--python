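"""k-mer composition profiles and 2D embedding of contigs.

Oligonucleotide composition (tetranucleotide frequencies by default) is a
genome signature: contigs from the same genome cluster together in k-mer
frequency space. The pipeline here is

1. count k-mers per contig with a sliding window of stride 1, skipping
   windows containing non-ACGT characters; by default each k-mer is
   collapsed onto its *canonical* form (the lexicographic minimum of the
   k-mer and its reverse complement), making the signature
   strand-insensitive;
2. normalize counts to per-contig frequencies (rows sum to 1), removing
   the contig-length effect;
3. reduce to 2D with PCA, t-SNE (Barnes-Hut, after a PCA pre-reduction to
   50 dimensions) or UMAP (same pre-reduction), producing the scatter
   coordinates the curation operators work on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "KmerMatrix",
    "EmbeddingResult",
    "count_kmers",
    "kmer_freq_matrix",
    "embed",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


@dataclass
class KmerMatrix:
    """Row-stochastic k-mer frequency matrix over contigs.

    Rows of contigs with zero valid windows are all-NaN and listed in
    ``invalid_ids``. Columns are labeled by k-mer string in lexicographic
    order; under canonical counting only canonical k-mers appear.
    """

    contig_ids: list[str]
    k: int
    canonical: bool
    kmers: list[str]
    freqs: np.ndarray
    invalid_ids: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.freqs.shape


@dataclass(frozen=True)
class EmbeddingResult:
    """2D coordinates per contig; reproducible given (method, params, seed)."""

    contig_ids: list[str]
    coords: np.ndarray
    method: str
    seed: int
    params: dict

    def as_mapping(self) -> dict[str, tuple[float, float]]:
        return {cid: (float(x), float(y)) for cid, (x, y) in zip(self.contig_ids, self.coords)}


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to base codes 0-3; anything non-ACGT becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    return codes


def _window_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all valid (ACGT-only) k-windows of *seq*."""
    codes = _encode(seq)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = np.all(win >= 0, axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win[valid] @ powers


def _revcomp_codes(k: int) -> np.ndarray:
    """Lookup table mapping every k-mer code to its reverse complement's code."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    rest = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - rest % 4)
        rest //= 4
    return rc


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_CODE_BASE[code % 4])
        code //= 4
    return "".join(reversed(out))


def count_kmers(seq: str, k: int, canonical: bool = True) -> dict[str, int]:
    """Count k-mers in a DNA string.

    Sliding window of stride 1; windows containing non-ACGT characters
    are skipped. With ``canonical=True`` each k-mer is counted as the
    lexicographic minimum of itself and its reverse complement. A
    sequence shorter than k yields an empty map.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    codes = _window_codes(seq, k)
    if codes.size == 0:
        return {}
    if canonical:
        rc = _revcomp_codes(k)
        codes = np.minimum(codes, rc[codes])
    uniq, counts = np.unique(codes, return_counts=True)
    return {_decode(int(c), k): int(n) for c, n in zip(uniq, counts)}


def kmer_freq_matrix(
    seqs: Mapping[str, str], k: int = 4, canonical: bool = True
) -> KmerMatrix:
    """Per-contig k-mer frequency matrix (rows sum to 1).

    Column order is lexicographic over the k-mers observed anywhere in the
    input. Contigs with no valid window (e.g. all-N sequences) get an
    all-NaN row and are listed in the result's ``invalid_ids``.
    """
    if not seqs:
        raise ValueError("no sequences given")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > 8:
        import warnings

        warnings.warn(f"k={k} allocates 4^{k} columns; expect heavy memory use")
    rc = _revcomp_codes(k) if canonical else None
    ids = list(seqs)
    per_contig: list[np.ndarray] = []
    per_counts: list[np.ndarray] = []
    observed: set[int] = set()
    for cid in ids:
        codes = _window_codes(seqs[cid], k)
        if canonical and codes.size:
            codes = np.minimum(codes, rc[codes])
        uniq, counts = np.unique(codes, return_counts=True)
        per_contig.append(uniq)
        per_counts.append(counts)
        observed.update(int(c) for c in uniq)
    cols = sorted(observed)
    col_index = {c: j for j, c in enumerate(cols)}
    freqs = np.zeros((len(ids), len(cols)))
    invalid: list[str] = []
    for i, (uniq, counts) in enumerate(zip(per_contig, per_counts)):
        total = counts.sum()
        if total == 0:
            freqs[i, :] = np.nan
            invalid.append(ids[i])
            continue
        for c, n in zip(uniq, counts):
            freqs[i, col_index[int(c)]] = n / total
    return KmerMatrix(
        contig_ids=ids,
        k=k,
        canonical=canonical,
        kmers=[_decode(c, k) for c in cols],
        freqs=freqs,
        invalid_ids=invalid,
    )


def embed(
    matrix: KmerMatrix,
    method: str = "pca",
    *,
    pca_pre_dims: int = 50,
    perplexity: float = 30.0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 42,
) -> EmbeddingResult:
    """Reduce a k-mer frequency matrix to 2D contig coordinates.

    ``pca`` projects onto the first two principal components. ``tsne``
    (Barnes-Hut) and ``umap`` both operate on a PCA pre-reduction of the
    frequency matrix to at most *pca_pre_dims* dimensions, which bounds
    their cost on wide inputs. Re-running with identical inputs, method,
    parameters and seed reproduces the coordinates exactly.
    """
    from sklearn.decomposition import PCA

    if method not in ("pca", "tsne", "umap"):
        raise ValueError(f"unknown embedding method: {method!r}")
    X = matrix.freqs
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"embedding needs >= 3 contigs, got {n}")
    bad = ~np.all(np.isfinite(X), axis=1)
    if bad.any():
        names = [matrix.contig_ids[i] for i in np.flatnonzero(bad)[:5]]
        raise ValueError(
            f"non-finite frequency rows for contigs {names}; "
            "drop invalid contigs before embedding"
        )
    X = X[:, X.any(axis=0)]  # zero columns carry no signal

    params: dict = {"pca_pre_dims": pca_pre_dims}
    if method == "pca":
        coords = PCA(n_components=2, svd_solver="full", random_state=seed).fit_transform(X)
    else:
        d = min(pca_pre_dims, n - 1, X.shape[1])
        reduced = PCA(n_components=d, svd_solver="full", random_state=seed).fit_transform(X)
        if method == "tsne":
            from sklearn.manifold import TSNE

            perp = min(perplexity, (n - 1) / 3.0)
            params["perplexity"] = perp
            coords = TSNE(
                n_components=2,
                perplexity=perp,
                method="barnes_hut",
                init="pca",
                random_state=seed,
            ).fit_transform(reduced)
        else:
            import umap

            nn = min(n_neighbors, n - 1)
            params.update(n_neighbors=nn, min_dist=min_dist)
            coords = umap.UMAP(
                n_components=2,
                n_neighbors=nn,
                min_dist=min_dist,
                random_state=seed,
            ).fit_transform(reduced)
    return EmbeddingResult(
        contig_ids=list(matrix.contig_ids),
        coords=np.asarray(coords, dtype=float),
        method=method,
        seed=seed,
        params=params,
    )
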