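"""Synthetic metagenomic communities with ground truth.

The generator emulates the *structure* a curation session consumes —
composition-separable contig clusters, per-sample depth profiles,
single-copy marker placements and a ground-truth contig-to-genome plan —
without simulating reads or assembly. Each genome draws its own base
composition from a Dirichlet distribution; contig sequences are sampled
i.i.d. from that composition (an order-0 Markov model), which is enough
to give genomes distinct, separable tetranucleotide signatures. Contig
lengths are lognormal, per-genome per-sample depths are lognormal, and
each of a catalog of marker genes is placed once per genome on a random
contig (optionally duplicated, to inject testable redundancy).
Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .binning import BinningPlan
from .table import ColumnKind, ColumnSpec, ContigTable, FeatureGroup, build_table

__all__ = ["CommunitySpec", "Community", "generate_community", "perturb_plan", "write_community"]


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic community.

    Defaults describe a small, clearly structured community: 5 genomes of
    20-40 contigs each, lognormal contig lengths with median ~5 kb,
    3 samples with lognormal per-genome depths (median ~10x), 40
    single-copy markers per genome, and strongly divergent genome base
    compositions (Dirichlet concentration 1/composition_divergence per
    base, so larger divergence spreads the genome signatures further
    apart).
    """

    n_genomes: int = 5
    contigs_per_genome: tuple[int, int] = (20, 40)
    length_log_mu: float = math.log(5000.0)
    length_log_sigma: float = 0.5
    min_length: int = 500
    composition_divergence: float = 5.0
    n_samples: int = 3
    coverage_log_mu: float = math.log(10.0)
    coverage_log_sigma: float = 1.0
    coverage_noise_sigma: float = 0.1
    n_markers: int = 40
    marker_duplication: float = 0.0
    contamination_rate: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        lo, hi = self.contigs_per_genome
        if lo < 1 or hi < lo:
            raise ValueError("contigs_per_genome must be a valid positive range")
        if not 0 <= self.contamination_rate < 1:
            raise ValueError("contamination_rate must be in [0, 1)")
        if self.min_length < 8:
            raise ValueError("min_length too short for k-mer profiling")
        if self.n_samples < 1 or self.n_markers < 1:
            raise ValueError("n_samples and n_markers must be >= 1")


@dataclass
class Community:
    spec: CommunitySpec
    sequences: dict[str, str]
    table: ContigTable
    truth: BinningPlan
    markers: FeatureGroup
    genome_names: list[str] = field(default_factory=list)


def generate_community(spec: CommunitySpec = CommunitySpec()) -> Community:
    """Generate a ground-truth-labeled synthetic community.

    The returned table carries ``length``, ``gc``, one ``cov_<sample>``
    column per sample, a categorical ``genome`` column (the true origin,
    playing the role of a taxonomy column), and a ``markers`` feature-set
    column. The truth plan assigns every contig to its genome's bin.
    ``contamination_rate`` relabels that fraction of contigs to a wrong
    genome in the *truth plan and genome column* (label noise), which is
    how redundant marker content arises in truth bins.
    """
    rng = np.random.default_rng(spec.seed)
    alpha = np.full(4, 1.0 / spec.composition_divergence)
    bases = np.array(list("ACGT"))

    sequences: dict[str, str] = {}
    rows: dict[str, dict] = {}
    assignment: dict[str, str] = {}
    genome_names = [f"genome_{g + 1}" for g in range(spec.n_genomes)]
    marker_names = [f"marker_{m + 1:03d}" for m in range(spec.n_markers)]
    genome_contigs: dict[str, list[str]] = {}

    for g, genome in enumerate(genome_names):
        probs = rng.dirichlet(alpha)
        # avoid fully degenerate compositions (sequence of one letter)
        probs = 0.95 * probs + 0.05 / 4
        n_contigs = int(rng.integers(spec.contigs_per_genome[0], spec.contigs_per_genome[1] + 1))
        depths = np.exp(rng.normal(spec.coverage_log_mu, spec.coverage_log_sigma, spec.n_samples))
        contigs = []
        for c in range(n_contigs):
            cid = f"{genome}_c{c + 1:03d}"
            length = max(
                spec.min_length,
                int(np.exp(rng.normal(spec.length_log_mu, spec.length_log_sigma))),
            )
            seq = "".join(rng.choice(bases, size=length, p=probs))
            sequences[cid] = seq
            gc = 100.0 * (seq.count("G") + seq.count("C")) / length
            row: dict = {"length": float(length), "gc": gc, "genome": genome}
            for s in range(spec.n_samples):
                noise = np.exp(rng.normal(0.0, spec.coverage_noise_sigma))
                row[f"cov_s{s + 1}"] = float(depths[s] * noise)
            rows[cid] = row
            assignment[cid] = genome
            contigs.append(cid)
        genome_contigs[genome] = contigs
        # single-copy marker placement, optional duplication
        for marker in marker_names:
            host = contigs[int(rng.integers(len(contigs)))]
            rows[host].setdefault("markers", []).append(marker)
            if spec.marker_duplication > 0 and rng.random() < spec.marker_duplication:
                extra = contigs[int(rng.integers(len(contigs)))]
                rows[extra].setdefault("markers", []).append(marker)

    all_ids = list(rows)
    if spec.contamination_rate > 0:
        n_flip = int(round(spec.contamination_rate * len(all_ids)))
        flip = rng.choice(len(all_ids), size=n_flip, replace=False)
        for i in flip:
            cid = all_ids[i]
            others = [g for g in genome_names if g != assignment[cid]]
            new = others[int(rng.integers(len(others)))]
            assignment[cid] = new
            rows[cid]["genome"] = new

    specs = [
        ColumnSpec("length", ColumnKind.NUMERIC),
        ColumnSpec("gc", ColumnKind.NUMERIC),
        *[ColumnSpec(f"cov_s{s + 1}", ColumnKind.NUMERIC) for s in range(spec.n_samples)],
        ColumnSpec("genome", ColumnKind.CATEGORICAL),
        ColumnSpec("markers", ColumnKind.FEATURE_SET),
    ]
    table = build_table(rows, specs)
    truth = BinningPlan(name="truth", assignment=assignment, bins=set(genome_names))
    markers = FeatureGroup(name="core_markers", members=marker_names)
    return Community(
        spec=spec,
        sequences=sequences,
        table=table,
        truth=truth,
        markers=markers,
        genome_names=genome_names,
    )


def perturb_plan(
    truth: BinningPlan, mode: str = "random_swap", intensity: float = 0.3, seed: int = 0
) -> BinningPlan:
    """Degrade a plan to emulate an imperfect automatic binning.

    ``random_swap`` moves a fraction *intensity* of binned contigs (at
    least one when intensity > 0) to a different, random bin; ``split``
    cuts a fraction of bins in two; ``merge`` fuses pairs of bins.
    ``intensity = 0`` returns an identical plan.
    """
    if not 0 <= intensity <= 1:
        raise ValueError("intensity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    plan = truth.copy()
    plan.name = f"{truth.name}_{mode}"
    plan.history = []
    if intensity == 0:
        return plan
    bins = sorted(plan.bins)
    if mode == "random_swap":
        if len(bins) < 2:
            return plan
        ids = sorted(plan.assignment)
        n_swap = max(1, int(round(intensity * len(ids))))
        chosen = rng.choice(len(ids), size=n_swap, replace=False)
        for i in chosen:
            cid = ids[i]
            others = [b for b in bins if b != plan.assignment[cid]]
            plan.assignment[cid] = others[int(rng.integers(len(others)))]
    elif mode == "split":
        n_split = max(1, int(round(intensity * len(bins))))
        chosen = rng.choice(len(bins), size=min(n_split, len(bins)), replace=False)
        for i in chosen:
            b = bins[i]
            members = sorted(plan.members(b))
            if len(members) < 2:
                continue
            half = rng.choice(len(members), size=len(members) // 2, replace=False)
            new = f"{b}_split"
            plan.bins.add(new)
            for j in half:
                plan.assignment[members[j]] = new
    elif mode == "merge":
        n_merge = max(1, int(round(intensity * len(bins))))
        candidates = list(bins)
        rng.shuffle(candidates)
        for _ in range(n_merge):
            if len(candidates) < 2:
                break
            a, b = candidates.pop(), candidates.pop()
            for cid, bn in plan.assignment.items():
                if bn == b:
                    plan.assignment[cid] = a
            plan.bins.discard(b)
            candidates.append(a)
    else:
        raise ValueError(f"unknown perturbation mode: {mode!r}")
    return plan


def write_community(community: Community, out_dir) -> dict[str, Path]:
    """Write FASTA + table TSV + truth plan TSV for CLI / end-to-end use."""
    from .binning import write_plan_tsv
    from .ingest import write_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "community.fasta"
    with fasta.open("w", encoding="utf-8") as fh:
        for cid, seq in community.sequences.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    table_path = out_dir / "community.tsv"
    write_table(community.table, table_path)
    plan_path = out_dir / "truth_plan.tsv"
    write_plan_tsv(community.truth, plan_path)
    return {"fasta": fasta, "table": table_path, "plan": plan_path}
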