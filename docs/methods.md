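# Methods

This note records how `magcurate` defines its quantities, the defaults
it ships, and the choices made where more than one reasonable convention
exists. Nothing here states a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A curation session operates on an ordered table of contigs with typed
columns. The four kinds mirror what curation actually consumes:

* **numeric** — finite floats; missing is NaN. Missing values are
  *excluded* from transforms, summaries and metrics, never treated as 0:
  annotations are routinely partial, and zero-imputation would bias
  every length/coverage statistic.
* **categorical** — strings (taxon names, sources).
* **feature set** — a multiset of feature identifiers (KO numbers,
  marker genes). Copy number is significant because redundancy is
  computed from excess copies; order is not. On disk these are
  comma-joined strings; an empty cell is *missing*, an annotated contig
  with no features is an *empty set* — the distinction matters for
  completeness denominators.
* **descriptive** — free text, never computed on.

Contig IDs compare case-sensitively and exactly. Two flags sit outside
the columns: `mask` (a masked contig is invisible to every summary,
metric, selection and export; *focus* on a set is masking its
complement) and `highlight` (an integer slot 0–8; mapping slots to
colors is presentation-layer, and eight slots comfortably exceeds what a
human distinguishes in one view).

Tables serialize as TSV with a `|n|c|f|d` suffix on each header naming
its kind. The suffix convention is this package's own: it makes round
trips independent of inference. Unsuffixed columns are inferred
(all-numeric → numeric, any comma → feature set, else categorical).
Floats are written with `repr` (shortest exact form), so read∘write is
the identity bit for bit.

## Transforms

Ten monotone element-wise transforms (`none, square, cube, sqrt, cbrt,
log, exp, logit, arcsine, rank`) precede histogramming, range selection
and display scaling. Conventions:

* `log` is base 10 and `exp` is 10^x — depth and length span orders of
  magnitude and decimal ticks read naturally. Zeros and negatives under
  `log` (e.g. zero-coverage contigs) become *missing and are counted in
  the returned report* rather than raising or being offset: exploratory
  toggling across transforms must not abort, and an arbitrary
  pseudo-count would silently distort the low end.
* `cbrt` preserves sign (cbrt(−8) = −2).
* `rank` assigns 1-based ranks with ties averaged — deterministic and
  weight-free.

## Summaries, histograms, range selection

Numeric summaries support sum, mean, weighted mean (Σwx/Σw, e.g. GC
weighted by length), min, max, median. An empty effective selection
yields missing, not an error; all-zero weights are an error because the
quotient is undefined.

The categorical majority summary reports the winning label and its share
*among annotated contigs* (missing values leave the denominator —
documented prominently since "80 % Firmicutes" could otherwise mean two
different things), optionally length-weighted, ties broken
lexicographically, rendered `"label (NN%)"` with the percent rounded to
an integer.

Histograms use `n_bins` equal-width bins (default 20) over the
transformed values, half-open `[lo, hi)` except the last bin, closed, so
counts conserve n. A constant-valued selection widens its range by 0.5
on each side. Range selection is boundary-inclusive on the transformed
scale, matching the drag-to-filter idiom it replaces.

## Plan metrics

**Silhouette.** Exact all-pairs Euclidean silhouette over user-designated
numeric columns (typically the 2D embedding). Each column is
standardized to zero mean/unit variance by default (disable with
`standardize=False`): without it a raw axis like coverage dominates the
distances. Singleton-bin members score 0 (Rousseeuw's convention);
unbinned and masked contigs are excluded and `n_used` reports how many
were scored. An optional seeded subsample bounds the O(n²) cost on large
assemblies.

**Adjusted Rand index.** Pair-counting form over the contingency table,
restricted to contigs binned in *both* plans (masked contigs excludable)
— treating unbinned contigs as a pseudo-bin would let a binner score
points for what it refused to bin. `n_shared` makes the restriction
auditable. Degenerate cases (both partitions trivial) return 1 for
identical, 0 otherwise.

**Completeness/redundancy.** Over the unmasked selection, with `found`
the distinct marker-group members present and `copies` their summed copy
count: completeness = 100·|found|/|group|, redundancy =
100·(copies − |found|)/|group|, which may exceed 100. The flat member
list is deliberate — no collocated marker-set model — so this is a
real-time first-pass check; both quantities are monotone non-decreasing
as the selection grows.

**Quality tiers.** high ⇔ comp ≥ 90 ∧ cont < 5; medium ⇔ comp ≥ 50 ∧
cont < 10 ∧ ¬high; low ⇔ comp < 50 ∧ cont < 10; excluded ⇔ cont ≥ 10.
These four cells partition the domain; the boundary grid is tested
exhaustively.

**Bin comparison.** Length-weighted by default — shared length over
union length (Jaccard) and over each bin's length (containment) — since
bin size is biologically a length, not a contig count; an unweighted
variant sits behind `weighted=False`.

## k-mer embedding

Counting slides a stride-1 window, skips windows containing non-ACGT
characters, and by default collapses each k-mer onto the lexicographic
minimum of itself and its reverse complement (canonical form) — contig
orientation is arbitrary post-assembly, so the signature should be
strand-insensitive. Frequencies (not counts) feed dimensionality
reduction, removing the length effect; all-invalid rows are NaN and
flagged, and must be dropped before embedding (the error names them).

Defaults: k = 4 (tetranucleotides; 5 and 6 supported), PCA
pre-reduction to 50 dimensions before Barnes-Hut t-SNE
(perplexity 30, capped at (n−1)/3) and UMAP (15 neighbors,
min_dist 0.1), seed 42. All parameters and the seed are recorded in the
result, and identical inputs + seed reproduce coordinates exactly.
Zero columns are dropped before PCA; when the pre-reduction retains the
matrix rank, the PCA map is an isometry (verified against an explicit
eigen-decomposition oracle).

## Plans, selection, editing

A binning plan is a *partial* map contig → bin (a contig is in at most
one bin). Every edit — create, assign, unassign, merge, delete, rename —
appends one reversible history record; `undo()` reverts exactly one.
Moving a contig between bins is a single atomic record, which is what
makes undo unable to create double membership.

Polygon selection uses the even-odd (ray casting) rule with boundary
points *included* — interactive selection should err inclusive — and
accepts either winding order and self-intersecting polygons. The
implementation is validated against an exact-rational crossing-number
oracle on 10⁴ random pairs plus constructed on-edge cases.

Per-bin abundance is the length-weighted mean coverage of unmasked
members per sample (a depth, commensurate with the input columns); a
Σ(length·coverage) "mass" variant is available via `mode="mass"` for
users who want totals.

## Ingest conventions

GC is computed over unambiguous A/C/G/T only (an all-N contig has
missing GC) so scaffolding gaps cannot skew it. The MegaHit `multi`
token is used as an approximate depth proxy. Kraken parsing keeps the
assignment string only; GTDB lineages split into seven rank columns with
empty ranks missing. GFF features attach to contigs by column 1;
coordinates are retained but unused. Marker maps are consumed as a flat
`marker<TAB>contig` TSV, one row per hit. The assembly filter keeps
contigs with length ≥ min_len, coverage strictly > min_cov, and (when a
breadth column is supplied) breadth ≥ min_breadth; defaults 2000 bp,
1×, 0.9.

## Checkpointing and exports

Checkpoints are versioned JSON (`format_version: 1`) containing the full
table (values, kinds, flags), every plan with its history, view
settings and the operation log; loading a higher version refuses rather
than guesses. The log is structured (timestamp, operation, parameters)
and replaying its plan edits on the initial plans reproduces the final
assignments. Figure export draws contigs in ascending ID order and pins
the SVG hash salt, so identical sessions produce byte-identical SVGs.

## Synthetic communities

The generator emulates the *structure* curation consumes, not
sequencing physics. Each genome draws base frequencies from a
Dirichlet(α = 1/composition_divergence per base, lightly smoothed toward
uniform); contig sequences are sampled i.i.d. from them (order-0
Markov), which suffices to produce separable tetranucleotide clusters.
Defaults, chosen once as a realistic desk-scale community: 5 genomes,
20–40 contigs each, lognormal lengths (median ≈ 5 kb, σ = 0.5, floor
500 bp), 3 samples with lognormal per-genome depths (median ≈ 10×,
σ = 1) plus 10 % per-contig noise, 40 single-copy markers placed
uniformly per genome, divergence 5. `contamination_rate` injects label
noise into the truth; `marker_duplication` injects redundancy;
`perturb_plan` (random swaps, splits, merges) emulates imperfect
automatic binning.

What passing tests on these communities shows — and does not. They
verify the operators' algebra (metrics, selections, round trips) and
that the pipeline separates genomes whose composition differs strongly.
They do not show performance on real assemblies: real contigs share
k-mer statistics across related taxa, have correlated coverage,
repeats, chimeras and strain variation, none of which order-0 sampling
produces. Absolute silhouette/ARI values on fixtures are therefore
optimistic; only the relative comparisons (curated vs corrupted) carry
over as a sanity check of the workflow.

## Problem sizes and numerical notes

The shipped test and acceptance runs use desk-scale sizes — communities
of ~120–160 contigs, oracle sweeps of 100–200 random instances (n ≤ 200
for silhouette, n ≤ 50 for ARI), 10⁴ polygon pairs, 50 serialization
round trips, 10 curation-rehearsal seeds — sized so the whole suite
completes in well under a minute of metric computation plus the one-off
UMAP import cost. Silhouette agreement with the brute-force oracle is
asserted at 1e-9 absolute; ARI agreement is exact (both sides are
ratios of small integers); PCA isometry at 1e-9. Ties in the categorical
majority break lexicographically; histogram degeneracy widens by ±0.5;
standardization leaves constant features unscaled rather than dividing
by zero.

## Known limitations

* Silhouette is O(n²) memory and time; use the seeded subsample above
  ~10⁴ binned contigs.
* No BAM/SAM depth computation: coverage and breadth come in as columns
  from upstream tools.
* The marker model ignores collocation and lineage-specific sets; its
  completeness/redundancy correlate with, but do not equal, a full
  marker-set analysis.
* t-SNE/UMAP determinism is per-environment: fixed seeds reproduce
  coordinates on the same library versions and thread count, not across
  versions.
* Checkpoints are this package's own schema; no compatibility with any
  external tool's session files is promised.
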