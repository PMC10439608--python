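"""Readers and writers for assemblies, annotations and contig tables.

Supported inputs mirror what a binning workflow produces upstream:
assembly FASTA in three header dialects (SPAdes ``NODE_i_length_L_cov_x``,
MegaHit ``flag= multi= len=`` tokens, or plain headers), Kraken-style
classification output, GTDB lineage strings, GFF3 annotations, and
flat marker-gene-to-contig maps. The native table format is a UTF-8 TSV
with a header row whose column names may carry a one-letter dtype suffix
(``|n`` numeric, ``|c`` categorical, ``|f`` feature set, ``|d``
descriptive); tables written here always emit the suffixes, so round
trips never depend on type inference.
"""

from __future__ import annotations

import csv
import math
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .table import (
    ColumnKind,
    ColumnSpec,
    ContigTable,
    FeatureGroup,
    TableError,
    build_table,
    join_feature_set,
)

__all__ = [
    "AssemblyRecord",
    "IngestError",
    "parse_assembly_fasta",
    "assembly_to_rows",
    "parse_taxonomy",
    "parse_features_gff",
    "parse_checkm_markers",
    "read_table",
    "write_table",
    "filter_contigs",
]

GTDB_RANKS = {
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}


class IngestError(ValueError):
    """Raised on malformed input files."""


@dataclass(frozen=True)
class AssemblyRecord:
    """Length, GC and (when the header carries it) depth of one contig.

    GC is computed over unambiguous A/C/G/T bases only, so scaffolding
    gaps (N runs) do not skew it; a contig with no unambiguous base has
    missing GC.
    """

    id: str
    length: int
    gc: float  # percent; NaN when no unambiguous base
    coverage: float | None = None


_SPADES_RE = re.compile(r"^NODE_(\d+)_length_(\d+)_cov_([0-9.eE+-]+)")
_MEGAHIT_TOKEN_RE = re.compile(r"(\w+)=([^\s]+)")


def _gc_percent(seq: str) -> float:
    up = seq.upper()
    gc = up.count("G") + up.count("C")
    at = up.count("A") + up.count("T")
    if gc + at == 0:
        return math.nan
    return 100.0 * gc / (gc + at)


def parse_assembly_fasta(path, dialect: str = "plain") -> list[AssemblyRecord]:
    """Parse an assembly FASTA into per-contig records.

    ``spades`` extracts depth from ``NODE_<i>_length_<L>_cov_<x>``
    headers; ``megahit`` from the ``multi=`` token (an approximate depth
    proxy); ``plain`` reports no coverage. Under a strict dialect a
    non-conforming header is an error naming the record, as is an empty
    sequence.
    """
    if dialect not in ("spades", "megahit", "plain"):
        raise ValueError(f"unknown FASTA dialect: {dialect!r}")
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise IngestError(f"empty sequence for record {rec.id!r}")
        coverage = None
        if dialect == "spades":
            m = _SPADES_RE.match(rec.id)
            if not m:
                raise IngestError(f"record {rec.id!r} does not match the SPAdes header format")
            coverage = float(m.group(3))
        elif dialect == "megahit":
            tokens = dict(_MEGAHIT_TOKEN_RE.findall(rec.description))
            if "multi" not in tokens:
                raise IngestError(
                    f"record {rec.id!r} does not match the MegaHit header format (no multi=)"
                )
            coverage = float(tokens["multi"])
        out.append(
            AssemblyRecord(id=rec.id, length=len(seq), gc=_gc_percent(seq), coverage=coverage)
        )
    return out


def assembly_to_rows(records: Iterable[AssemblyRecord]):
    """Rows + specs for loading assembly records into a ContigTable."""
    has_cov = any(r.coverage is not None for r in records)
    specs = [
        ColumnSpec("length", ColumnKind.NUMERIC),
        ColumnSpec("gc", ColumnKind.NUMERIC),
    ]
    if has_cov:
        specs.append(ColumnSpec("coverage", ColumnKind.NUMERIC))
    rows = {}
    for r in records:
        row = {"length": float(r.length), "gc": r.gc}
        if has_cov:
            row["coverage"] = math.nan if r.coverage is None else r.coverage
        rows[r.id] = row
    return rows, specs


def parse_taxonomy(path, format: str = "kraken"):
    """Parse taxonomy assignments into (rows, specs) for a ContigTable.

    ``kraken``: tab-separated lines starting with the classification flag
    (``C``/``U``), contig ID, then the taxon; unclassified lines yield a
    missing assignment in a single ``taxon`` column.

    ``gtdb_lineage``: two-column TSV (ID, then a
    ``d__...;p__...;...;s__...`` lineage string; a header line whose
    second column is named ``classification`` is also accepted). The
    lineage is split into seven rank columns, empty ranks becoming
    missing.
    """
    path = Path(path)
    if format == "kraken":
        rows: dict[str, dict] = {}
        with path.open("r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise IngestError(
                        f"{path.name}:{lineno}: expected >= 3 tab-separated fields"
                    )
                flag, cid, taxon = fields[0], fields[1], fields[2]
                if flag == "U":
                    rows[cid] = {"taxon": None}
                elif flag == "C":
                    rows[cid] = {"taxon": taxon}
                else:
                    raise IngestError(
                        f"{path.name}:{lineno}: unknown classification flag {flag!r}"
                    )
        return rows, [ColumnSpec("taxon", ColumnKind.CATEGORICAL)]
    if format == "gtdb_lineage":
        rank_names = list(GTDB_RANKS.values())
        rows = {}
        with path.open("r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise IngestError(
                        f"{path.name}:{lineno}: expected >= 2 tab-separated fields"
                    )
                cid, lineage = fields[0], fields[1]
                if lineno == 1 and lineage.lower() == "classification":
                    continue  # GTDB-Tk summary header
                row = dict.fromkeys(rank_names)
                for part in lineage.split(";"):
                    part = part.strip()
                    if not part:
                        continue
                    if len(part) < 3 or part[1:3] != "__":
                        raise IngestError(
                            f"{path.name}:{lineno}: malformed rank field {part!r}"
                        )
                    prefix, value = part[0], part[3:]
                    if prefix not in GTDB_RANKS:
                        raise IngestError(
                            f"{path.name}:{lineno}: unknown rank prefix {prefix!r}"
                        )
                    row[GTDB_RANKS[prefix]] = value or None
                rows[cid] = row
        return rows, [ColumnSpec(r, ColumnKind.CATEGORICAL) for r in rank_names]
    raise ValueError(f"unknown taxonomy format: {format!r}")


def parse_features_gff(path, attribute_key: str):
    """Per-contig feature multisets from a GFF3 file.

    For each contig (GFF column 1) collects the multiset of values of
    *attribute_key* over its features; features lacking the key are
    skipped and counted. Returns ``(rows, specs, n_skipped)`` where the
    single column is named after *attribute_key*.
    """
    from gffutils.iterators import DataIterator

    rows: dict[str, dict] = {}
    n_skipped = 0
    for feature in DataIterator(str(path)):
        values = feature.attributes.get(attribute_key)
        if not values:
            n_skipped += 1
            continue
        fs = rows.setdefault(feature.seqid, {attribute_key: Counter()})[attribute_key]
        for v in values:
            fs[v] += 1
    return rows, [ColumnSpec(attribute_key, ColumnKind.FEATURE_SET)], n_skipped


def parse_checkm_markers(path):
    """Read a flat marker-gene map: TSV rows of ``marker<TAB>contig``.

    One row per hit (a marker hitting a contig twice appears on two
    rows). Returns the group of all distinct markers plus per-contig
    feature-set rows for a ``markers`` column. An empty map is an error.
    """
    path = Path(path)
    markers: set[str] = set()
    rows: dict[str, dict] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise IngestError(f"{path.name}:{lineno}: expected 2 tab-separated fields")
            marker, cid = fields
            if lineno == 1 and marker.lower() == "marker":
                continue
            markers.add(marker)
            rows.setdefault(cid, {"markers": Counter()})["markers"][marker] += 1
    if not markers:
        raise IngestError(f"{path.name}: no markers found")
    group = FeatureGroup(name=path.stem, members=markers)
    return group, rows, [ColumnSpec("markers", ColumnKind.FEATURE_SET)]


# -- native table TSV --------------------------------------------------

_SUFFIX_TO_KIND = {
    "n": ColumnKind.NUMERIC,
    "c": ColumnKind.CATEGORICAL,
    "f": ColumnKind.FEATURE_SET,
    "d": ColumnKind.DESCRIPTIVE,
}
_KIND_TO_SUFFIX = {v: k for k, v in _SUFFIX_TO_KIND.items()}


def _infer_kind(cells: list[str]) -> ColumnKind:
    """Dtype inference for unsuffixed columns: all-numeric -> numeric;
    any comma-containing cell -> feature_set; else categorical."""
    non_empty = [c for c in cells if c.strip() != ""]
    if non_empty:
        try:
            for c in non_empty:
                float(c)
            return ColumnKind.NUMERIC
        except ValueError:
            pass
        if any("," in c for c in non_empty):
            return ColumnKind.FEATURE_SET
    return ColumnKind.CATEGORICAL


def read_table(path) -> ContigTable:
    """Read a contig table TSV (first column = contig ID, header row).

    Column dtypes come from ``|n|c|f|d`` header suffixes; columns without
    a suffix are inferred from their cells. Duplicate IDs and ragged rows
    are errors naming the offending line.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise IngestError(f"{path.name}: empty file") from None
        data = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise IngestError(
                    f"{path.name}:{lineno}: ragged row ({len(row)} fields, "
                    f"expected {len(header)})"
                )
            data.append(row)
    names: list[str] = []
    kinds: list[ColumnKind | None] = []
    for col in header[1:]:
        if len(col) > 2 and col[-2] == "|" and col[-1] in _SUFFIX_TO_KIND:
            names.append(col[:-2])
            kinds.append(_SUFFIX_TO_KIND[col[-1]])
        else:
            names.append(col)
            kinds.append(None)
    for j, kind in enumerate(kinds):
        if kind is None:
            kinds[j] = _infer_kind([row[j + 1] for row in data])
    specs = [ColumnSpec(n, k) for n, k in zip(names, kinds)]
    pairs = []
    seen: set[str] = set()
    for lineno, row in zip(range(2, len(data) + 2), data):
        cid = row[0]
        if cid in seen:
            raise IngestError(f"{path.name}:{lineno}: duplicate contig ID {cid!r}")
        seen.add(cid)
        pairs.append((cid, {n: row[j + 1] for j, n in enumerate(names)}))
    return build_table(pairs, specs)


def _format_cell(value, kind: ColumnKind) -> str:
    if value is None:
        return ""
    if kind is ColumnKind.NUMERIC:
        if math.isnan(value):
            return ""
        return repr(value) if value != int(value) else str(int(value))
    if kind is ColumnKind.FEATURE_SET:
        return join_feature_set(value)
    return str(value)


def write_table(table: ContigTable, path, *, ids: Sequence[str] | None = None) -> None:
    """Write a contig table as TSV with dtype-suffixed headers.

    Floats are rendered shortest-exact (via ``repr``), so a read of the
    written file reproduces the table's values bit for bit. *ids* limits
    the output to a subset of contigs (e.g. one bin's members).
    """
    path = Path(path)
    cols = table.columns
    specs = [table.spec(c) for c in cols]
    if ids is None:
        ids = table.ids
    with path.open("w", encoding="utf-8") as fh:
        header = ["id"] + [f"{s.name}|{_KIND_TO_SUFFIX[s.kind]}" for s in specs]
        fh.write("\t".join(header) + "\n")
        for cid in ids:
            i = table.index(cid)
            cells = [cid] + [
                _format_cell(table.values(c)[i], s.kind) for c, s in zip(cols, specs)
            ]
            fh.write("\t".join(cells) + "\n")


def filter_contigs(
    source,
    min_len: float = 2000,
    min_cov: float = 1.0,
    min_breadth: float = 0.0,
    *,
    length_column: str = "length",
    coverage_column: str = "coverage",
    breadth_column: str | None = None,
) -> list[str]:
    """Assembly quality filter: keep contigs with ``length >= min_len``,
    ``coverage > min_cov`` (strict), and ``breadth >= min_breadth``.

    *source* is a list of :class:`AssemblyRecord` or a
    :class:`~magcurate.table.ContigTable`. Breadth (the covered fraction
    of the contig, from an upstream depth tool) must be supplied as a
    column when ``min_breadth > 0``. Raising any threshold can only
    shrink the surviving set.
    """
    if isinstance(source, ContigTable):
        lengths = source.numeric(length_column)
        covs = source.numeric(coverage_column)
        if min_breadth > 0:
            if breadth_column is None:
                raise IngestError("min_breadth > 0 requires a breadth_column")
            breadths = source.numeric(breadth_column)
        else:
            breadths = None
        out = []
        for i, cid in enumerate(source.ids):
            if math.isnan(lengths[i]) or lengths[i] < min_len:
                continue
            if math.isnan(covs[i]) or covs[i] <= min_cov:
                continue
            if breadths is not None and (
                math.isnan(breadths[i]) or breadths[i] < min_breadth
            ):
                continue
            out.append(cid)
        return out
    if min_breadth > 0:
        raise IngestError(
            "min_breadth > 0 requires a ContigTable with a breadth_column"
        )
    return [
        r.id
        for r in source
        if r.length >= min_len and r.coverage is not None and r.coverage > min_cov
    ]
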