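"""Readers, writers, and shared domain types.

Internal coordinates are 1-based inclusive (GFF3-native).  BED input is
0-based half-open and is converted at the boundary, so ``chr1 99 250``
becomes ``start=100, end=250``.  All writers emit files their paired
readers parse back to equal values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

CONFIDENCE_CLASSES = ("HC", "LC")
ORTHOLOG_CLASSES = ("orthologous", "paralogous", "uncertain", "undetected")

#: outfmt-6 column order (qseqid sseqid pident length mismatch gapopen
#: qstart qend sstart send evalue bitscore); extra columns are ignored.
HIT_COLUMNS = [
    "query_id", "target_id", "pident", "align_len", "mismatches", "gapopens",
    "qstart", "qend", "tstart", "tend", "evalue", "bitscore",
]

MAX_HIT_RANK = 3


class ParseError(ValueError):
    """A line of an input file could not be parsed; the message names the line."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


@dataclass(frozen=True)
class Gene:
    """A gene model: 1-based inclusive coordinates plus a confidence class.

    ``rank`` is the ordinal position of the gene along its chromosome
    (1-based) and is assigned by :func:`rank_genes`, not by the readers.
    """

    id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    confidence: str = "HC"
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"gene {self.id}: start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError(
                f"gene {self.id}: end {self.end} < start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"gene {self.id}: bad strand {self.strand!r}")
        if self.confidence not in CONFIDENCE_CLASSES:
            raise ValidationError(
                f"gene {self.id}: confidence {self.confidence!r} not in "
                f"{CONFIDENCE_CLASSES}")


@dataclass(frozen=True)
class HitRecord:
    """One BLAST tabular (outfmt 6) row with an assigned per-query hit rank."""

    query_id: str
    target_id: str
    pident: float
    align_len: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    tstart: int
    tend: int
    evalue: float
    bitscore: float
    hit_rank: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValidationError(
                f"hit {self.query_id}->{self.target_id}: pident "
                f"{self.pident} outside [0, 100]")
        if self.evalue < 0:
            raise ValidationError(
                f"hit {self.query_id}->{self.target_id}: negative e-value")


@dataclass(frozen=True)
class OrthologRecord:
    """One classified query gene, mirroring the ortholog-table TSV schema.

    ``target_id`` is empty for undetected queries; ``block_id`` is empty for
    genes that are not members of a collinear block.  ``flags`` carries
    annotations such as the spurious-duplicate marker ``!``.
    """

    query_id: str
    query_chrom: str
    query_start: int
    query_end: int
    confidence: str
    target_id: str = ""
    target_chrom: str = ""
    target_start: int = 0
    target_end: int = 0
    pident: float = 0.0
    align_len: int = 0
    klass: str = "undetected"
    block_id: str = ""
    flags: str = ""

    def __post_init__(self) -> None:
        if self.klass not in ORTHOLOG_CLASSES:
            raise ValidationError(f"unknown ortholog class {self.klass!r}")
        if self.klass == "undetected" and self.target_id:
            raise ValidationError(
                f"{self.query_id}: undetected record carries a target")


ORTHOLOG_TABLE_COLUMNS = [
    "query_id", "query_chrom", "query_start", "query_end", "confidence",
    "target_id", "target_chrom", "target_start", "target_end",
    "pident", "align_len", "klass", "block_id", "flags",
]


# ---------------------------------------------------------------------------
# gene models

def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gene_models(
    path: str | Path,
    format: str | None = None,
    confidence_key: str = "confidence",
    feature_types: Sequence[str] = ("gene",),
) -> list[Gene]:
    """Read gene models from GFF3 or BED into :class:`Gene` records.

    ``format`` is inferred from the file suffix when omitted.  The HC/LC
    confidence class is read from the GFF3 attribute named by
    ``confidence_key``; when absent (always, for BED) the gene defaults to
    HC and a warning is logged once per file.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        format = "bed" if suffix == ".bed" else "gff3"
    if format not in ("gff3", "bed"):
        raise ValueError(f"unknown gene-model format {format!r}")

    genes: list[Gene] = []
    missing_confidence = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if format == "gff3":
                cols = line.split("\t")
                if len(cols) != 9:
                    raise ParseError(
                        f"{path}: line {lineno}: expected 9 tab-separated "
                        f"GFF3 columns, found {len(cols)}")
                chrom, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = cols
                if ftype not in feature_types:
                    continue
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: non-integer coordinate") from exc
                attrs = _parse_gff3_attributes(attr_s)
                gene_id = attrs.get("ID") or attrs.get("Name")
                if not gene_id:
                    raise ParseError(
                        f"{path}: line {lineno}: gene row without ID attribute")
                confidence = attrs.get(confidence_key)
                if confidence is None:
                    confidence = "HC"
                    missing_confidence += 1
            else:
                cols = line.split()
                if len(cols) < 3:
                    raise ParseError(
                        f"{path}: line {lineno}: BED needs >= 3 columns")
                chrom = cols[0]
                try:
                    start = int(cols[1]) + 1  # 0-based half-open -> 1-based inclusive
                    end = int(cols[2])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}: line {lineno}: non-integer coordinate") from exc
                gene_id = cols[3] if len(cols) >= 4 else f"{chrom}:{start}-{end}"
                strand = cols[5] if len(cols) >= 6 else "."
                confidence = "HC"
                missing_confidence += 1
            try:
                genes.append(Gene(id=gene_id, chromosome=chrom, start=start,
                                  end=end, strand=strand, confidence=confidence))
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    if missing_confidence:
        log.warning("%s: %d gene(s) without a %r attribute; defaulted to HC",
                    path, missing_confidence, confidence_key)
    return genes


def write_gene_models(genes: Iterable[Gene], path: str | Path,
                      format: str = "gff3",
                      confidence_key: str = "confidence") -> None:
    """Write genes as GFF3 (lossless) or BED6 (drops the confidence class)."""
    path = Path(path)
    with open(path, "w") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                attrs = f"ID={g.id};{confidence_key}={g.confidence}"
                fh.write("\t".join([g.chromosome, "cgnkit", "gene",
                                    str(g.start), str(g.end), ".",
                                    g.strand, ".", attrs]) + "\n")
        elif format == "bed":
            for g in genes:
                fh.write("\t".join([g.chromosome, str(g.start - 1), str(g.end),
                                    g.id, "0", g.strand]) + "\n")
        else:
            raise ValueError(f"unknown gene-model format {format!r}")


def rank_genes(genes: Sequence[Gene]) -> list[Gene]:
    """Assign per-chromosome ordinal ranks 1..n by ascending (start, end, id).

    Returns new records sorted by (chromosome, rank).  Duplicate gene ids
    are a validation error.
    """
    seen: set[str] = set()
    for g in genes:
        if g.id in seen:
            raise ValidationError(f"duplicate gene id {g.id!r}")
        seen.add(g.id)
    ranked: list[Gene] = []
    by_chrom: dict[str, list[Gene]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end, g.id))
        ranked.extend(replace(g, rank=i) for i, g in enumerate(ordered, start=1))
    return ranked


# ---------------------------------------------------------------------------
# hit tables

def read_hit_table(path: str | Path, max_rank: int = MAX_HIT_RANK) -> list[HitRecord]:
    """Read a 12-column BLAST tabular file and assign per-query hit ranks.

    Ranks are assigned per query by descending bitscore, breaking ties by
    descending pident then lexicographic target id.  Rows beyond
    ``max_rank`` are dropped (the count is logged).  Columns beyond the
    twelfth are ignored.
    """
    path = Path(path)
    rows: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 12 tab-separated "
                    f"columns, found {len(cols)}")
            try:
                rec = HitRecord(
                    query_id=cols[0], target_id=cols[1],
                    pident=float(cols[2]), align_len=int(cols[3]),
                    mismatches=int(cols[4]), gapopens=int(cols[5]),
                    qstart=int(cols[6]), qend=int(cols[7]),
                    tstart=int(cols[8]), tend=int(cols[9]),
                    evalue=float(cols[10]), bitscore=float(cols[11]),
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric field ({exc})") from exc
            rows.append(rec)
    return assign_hit_ranks(rows, max_rank=max_rank)


def assign_hit_ranks(rows: Sequence[HitRecord],
                     max_rank: int = MAX_HIT_RANK) -> list[HitRecord]:
    """Rank hits 1..min(max_rank, n) per query; drop the rest."""
    by_query: dict[str, list[HitRecord]] = {}
    for rec in rows:
        by_query.setdefault(rec.query_id, []).append(rec)
    out: list[HitRecord] = []
    dropped = 0
    for query_id in by_query:
        hits = sorted(by_query[query_id],
                      key=lambda h: (-h.bitscore, -h.pident, h.target_id))
        dropped += max(0, len(hits) - max_rank)
        out.extend(replace(h, hit_rank=i)
                   for i, h in enumerate(hits[:max_rank], start=1))
    if dropped:
        log.info("dropped %d hit row(s) beyond rank %d", dropped, max_rank)
    return out


def write_hit_table(rows: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits as 12-column BLAST tabular (hit_rank is not a column)."""
    with open(path, "w") as fh:
        for h in rows:
            fh.write("\t".join([
                h.query_id, h.target_id, f"{h.pident:.2f}", str(h.align_len),
                str(h.mismatches), str(h.gapopens), str(h.qstart), str(h.qend),
                str(h.tstart), str(h.tend), f"{h.evalue:.2g}",
                f"{h.bitscore:.1f}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# ortholog tables

def write_ortholog_table(records: Iterable[OrthologRecord],
                         path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in ORTHOLOG_TABLE_COLUMNS}
                       for r in records], columns=ORTHOLOG_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_ortholog_table(path: str | Path) -> list[OrthologRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(ORTHOLOG_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        if row.klass not in ORTHOLOG_CLASSES:
            raise ValidationError(
                f"{path}: unknown klass token {row.klass!r} "
                f"for query {row.query_id}")
        records.append(OrthologRecord(
            query_id=row.query_id, query_chrom=row.query_chrom,
            query_start=int(row.query_start), query_end=int(row.query_end),
            confidence=row.confidence, target_id=row.target_id,
            target_chrom=row.target_chrom,
            target_start=int(row.target_start) if row.target_start else 0,
            target_end=int(row.target_end) if row.target_end else 0,
            pident=float(row.pident), align_len=int(row.align_len),
            klass=row.klass, block_id=row.block_id, flags=row.flags))
    return records


# ---------------------------------------------------------------------------
# assembly statistics

STATS_COLUMNS = ["chromosome", "total_length", "gap_length",
                 "effective_length", "gap_count", "n_count"]


def assembly_stats(sequences: Mapping[str, str],
                   totals_label: str = "Total") -> pd.DataFrame:
    """Per-chromosome length/gap statistics plus a totals row.

    A gap is a maximal run of ``N`` (case-insensitive); gap_length equals
    n_count by construction and effective_length = total_length - gap_length.
    """
    rows = []
    for name in sequences:
        seq = sequences[name].upper()
        gap_count = 0
        n_count = 0
        in_gap = False
        for base in seq:
            if base == "N":
                n_count += 1
                if not in_gap:
                    gap_count += 1
                    in_gap = True
            else:
                in_gap = False
        rows.append({"chromosome": name, "total_length": len(seq),
                     "gap_length": n_count,
                     "effective_length": len(seq) - n_count,
                     "gap_count": gap_count, "n_count": n_count})
    df = pd.DataFrame(rows, columns=STATS_COLUMNS)
    totals = {"chromosome": totals_label}
    for col in STATS_COLUMNS[1:]:
        totals[col] = int(df[col].sum()) if len(df) else 0
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def write_assembly_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def read_assembly_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(STATS_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def published_stats(version: str) -> pd.DataFrame:
    """Bundled per-chromosome summary rows for the two published AL8/78
    assembly versions (``"v5"`` or ``"v6"``)."""
    from importlib.resources import files
    if version not in ("v5", "v6"):
        raise ValueError("version must be 'v5' or 'v6'")
    path = files("cgnkit").joinpath(
        f"data/aet_{version}_chromosome_stats.tsv")
    return pd.read_csv(str(path), sep="\t")


def compare_assembly_stats(
    new: pd.DataFrame, old: pd.DataFrame, totals_label: str = "Total",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-chromosome new-minus-old differences, a recomputed totals row,
    and paired t-test p-values per column.

    Rows are matched by chromosome name; any totals rows in the inputs are
    dropped and the totals-difference row is recomputed as column sums.
    """
    from scipy import stats as _st
    cols = ["total_length", "gap_length", "effective_length", "gap_count"]
    a = new[new["chromosome"] != totals_label].set_index("chromosome")
    b = old[old["chromosome"] != totals_label].set_index("chromosome")
    shared = [c for c in a.index if c in b.index]
    if not shared:
        raise ValidationError("no shared chromosome rows to compare")
    diff = (a.loc[shared, cols] - b.loc[shared, cols]).astype(int)
    diff.loc[totals_label] = diff.sum()
    pvalues = {}
    for col in cols:
        if len(shared) >= 2:
            res = _st.ttest_rel(a.loc[shared, col], b.loc[shared, col])
            pvalues[col] = float(res.pvalue)
        else:
            pvalues[col] = float("nan")
    return diff.reset_index(), pvalues
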