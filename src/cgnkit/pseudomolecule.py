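"""Genetic-map anchoring, pseudomolecule construction, and optical-map tools.

Scaffolds are assigned to chromosomes by marker plurality, ordered by mean
genetic position (cM), and oriented by the sign of the rank correlation
between cM and scaffold bp.  Pseudomolecules are built by concatenating
oriented scaffolds with N-filled junctions: a known gap of k bp becomes k
Ns and an AGP "N" row; an unknown gap becomes exactly 100 Ns and an AGP
"U 100" row (gap_type scaffold, linkage yes, evidence map).  Sequences can
be digested in silico at a labeling-enzyme motif (DLE-1, CTTAAG, by
default) into ordered label sets, written as CMAP v0.2, and two label sets
can be compared by an interval-matching dynamic program.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .io import ParseError, ValidationError, assembly_stats

log = logging.getLogger(__name__)

UNKNOWN_GAP_LENGTH = 100
DLE1_MOTIF = "CTTAAG"


@dataclass(frozen=True)
class MarkerPlacement:
    """A genetic-map marker located on a scaffold by sequence alignment."""

    marker_id: str
    map_chrom: str
    cm: float
    scaffold_id: str
    scaffold_pos: int  # bp, 1-based
    pident: float = 100.0
    evalue: float = 0.0


@dataclass
class ScaffoldAssignment:
    """A scaffold's place in a pseudomolecule."""

    scaffold_id: str
    chromosome: str
    order_index: int
    orientation: str  # "+" or "-"
    oriented: bool
    n_markers: int
    mean_cm: float
    conflict_flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CmapLabelSet:
    """Ordered in-silico label positions along one sequence."""

    map_id: str
    length: int
    positions: tuple[int, ...]  # 1-based, strictly increasing
    channel: int = 1

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValidationError(
                f"map {self.map_id}: label positions not strictly increasing")
        if self.positions and self.positions[-1] > self.length:
            raise ValidationError(
                f"map {self.map_id}: label beyond sequence end")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(np.asarray(self.positions, dtype=float))


# ---------------------------------------------------------------------------
# marker tables

def read_marker_map(path: str | Path) -> pd.DataFrame:
    """TSV with columns marker, chromosome, cM."""
    df = pd.read_csv(path, sep="\t")
    need = {"marker", "chromosome", "cM"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: marker map needs columns {sorted(need)}")
    return df


def read_placements(path: str | Path) -> list[MarkerPlacement]:
    """TSV with columns marker, chromosome, cM, scaffold, position, pident, evalue."""
    df = pd.read_csv(path, sep="\t")
    need = {"marker", "chromosome", "cM", "scaffold", "position",
            "pident", "evalue"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: placements need columns {sorted(need)}")
    return [MarkerPlacement(marker_id=r.marker, map_chrom=r.chromosome,
                            cm=float(r.cM), scaffold_id=r.scaffold,
                            scaffold_pos=int(r.position),
                            pident=float(r.pident), evalue=float(r.evalue))
            for r in df.itertuples(index=False)]


def write_placements(placements: Iterable[MarkerPlacement],
                     path: str | Path) -> None:
    pd.DataFrame([{"marker": p.marker_id, "chromosome": p.map_chrom,
                   "cM": p.cm, "scaffold": p.scaffold_id,
                   "position": p.scaffold_pos, "pident": p.pident,
                   "evalue": p.evalue} for p in placements]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# anchoring

def anchor_scaffolds(
    placements: Sequence[MarkerPlacement],
    min_pident: float = 99.0,
    max_evalue: float = 1e-5,
) -> list[ScaffoldAssignment]:
    """Assign retained scaffolds to chromosomes, order and orient them.

    Placements are filtered at ``min_pident`` / ``max_evalue`` (strong-hit
    filter).  Chromosome: marker plurality (ties: lexicographic).  Order:
    ascending mean cM of retained markers (ties: min cM, then scaffold id).
    Orientation: sign of the Spearman correlation between cM and scaffold
    bp; scaffolds with fewer than two distinct markers are unoriented and
    reported as "+".  Conflicts (scaffold with markers on more than one
    chromosome; marker hitting more than one scaffold) are flagged.
    """
    kept = [p for p in placements
            if p.pident >= min_pident and p.evalue <= max_evalue]
    if not kept:
        log.warning("no marker placements passed the filters "
                    "(min_pident=%s, max_evalue=%s)", min_pident, max_evalue)
        return []
    by_scaffold: dict[str, list[MarkerPlacement]] = {}
    scaffolds_of_marker: dict[str, set[str]] = {}
    for p in kept:
        by_scaffold.setdefault(p.scaffold_id, []).append(p)
        scaffolds_of_marker.setdefault(p.marker_id, set()).add(p.scaffold_id)
    multi_scaffold_markers = {m for m, s in scaffolds_of_marker.items()
                              if len(s) > 1}

    rows: list[tuple[str, float, float, str, ScaffoldAssignment]] = []
    for sid in sorted(by_scaffold):
        ps = by_scaffold[sid]
        chrom_counts: dict[str, int] = {}
        for p in ps:
            chrom_counts[p.map_chrom] = chrom_counts.get(p.map_chrom, 0) + 1
        top = max(chrom_counts.values())
        chrom = min(c for c, k in chrom_counts.items() if k == top)
        flags = []
        if len(chrom_counts) > 1:
            flags.append("multi_chromosome")
        shared = sorted(p.marker_id for p in ps
                        if p.marker_id in multi_scaffold_markers)
        if shared:
            flags.append("shared_markers:" + ",".join(shared))
        on_chrom = [p for p in ps if p.map_chrom == chrom]
        cms = np.array([p.cm for p in on_chrom], dtype=float)
        bps = np.array([p.scaffold_pos for p in on_chrom], dtype=float)
        oriented = len(on_chrom) >= 2 and len(set(cms)) > 1 and len(set(bps)) > 1
        orientation = "+"
        if oriented:
            rho = stats.spearmanr(cms, bps).statistic
            if np.isnan(rho) or rho == 0:
                oriented = False
            elif rho < 0:
                orientation = "-"
        rows.append((chrom, float(cms.mean()), float(cms.min()), sid,
                     ScaffoldAssignment(
                         scaffold_id=sid, chromosome=chrom, order_index=0,
                         orientation=orientation, oriented=oriented,
                         n_markers=len(on_chrom), mean_cm=float(cms.mean()),
                         conflict_flags=flags)))
    out: list[ScaffoldAssignment] = []
    for chrom in sorted({r[0] for r in rows}):
        chrom_rows = sorted((r for r in rows if r[0] == chrom),
                            key=lambda r: (r[1], r[2], r[3]))
        for idx, (_, _, _, _, asg) in enumerate(chrom_rows, start=1):
            asg.order_index = idx
            out.append(asg)
    return out


# ---------------------------------------------------------------------------
# pseudomolecule construction (FASTA + AGP)

AGP_COLUMNS = ["object", "object_beg", "object_end", "part_number",
               "component_type", "component_id", "component_beg",
               "component_end", "orientation"]


def build_pseudomolecules(
    assignments: Sequence[ScaffoldAssignment],
    sequences: Mapping[str, str],
    junction_gaps: Mapping[tuple[str, str], int | None] | None = None,
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Concatenate ordered, oriented scaffolds into pseudomolecules.

    ``junction_gaps`` maps (left_scaffold, right_scaffold) to a known gap
    length in bp, or None / absent for an unknown gap (100 Ns, AGP "U"
    row).  Returns (pseudomolecule sequences, AGP table, assembly stats).
    """
    junction_gaps = junction_gaps or {}
    by_chrom: dict[str, list[ScaffoldAssignment]] = {}
    for a in assignments:
        if a.scaffold_id not in sequences:
            raise ValidationError(
                f"assigned scaffold {a.scaffold_id!r} has no sequence")
        by_chrom.setdefault(a.chromosome, []).append(a)
    pseudos: dict[str, str] = {}
    agp_rows: list[dict] = []
    for chrom in sorted(by_chrom):
        ordered = sorted(by_chrom[chrom], key=lambda a: a.order_index)
        parts: list[str] = []
        pos = 0
        part_number = 0
        for i, asg in enumerate(ordered):
            if i > 0:
                key = (ordered[i - 1].scaffold_id, asg.scaffold_id)
                gap = junction_gaps.get(key)
                if gap is not None and gap <= 0:
                    raise ValidationError(
                        f"junction {key}: gap length must be positive")
                length = gap if gap is not None else UNKNOWN_GAP_LENGTH
                part_number += 1
                agp_rows.append({
                    "object": chrom, "object_beg": pos + 1,
                    "object_end": pos + length, "part_number": part_number,
                    "component_type": "N" if gap is not None else "U",
                    "component_id": str(length),  # gap_length column
                    "component_beg": "scaffold", "component_end": "yes",
                    "orientation": "map"})
                parts.append("N" * length)
                pos += length
            seq = sequences[asg.scaffold_id]
            if asg.orientation == "-":
                seq = str(Seq(seq).reverse_complement())
            part_number += 1
            agp_rows.append({
                "object": chrom, "object_beg": pos + 1,
                "object_end": pos + len(seq), "part_number": part_number,
                "component_type": "W", "component_id": asg.scaffold_id,
                "component_beg": 1, "component_end": len(seq),
                "orientation": asg.orientation if asg.oriented else "+"})
            parts.append(seq)
            pos += len(seq)
        pseudos[chrom] = "".join(parts)
    agp = pd.DataFrame(agp_rows, columns=AGP_COLUMNS)
    stats_df = assembly_stats(pseudos)
    return pseudos, agp, stats_df


def write_agp(agp: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for row in agp.itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_agp(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: line {lineno}: AGP needs 9 columns")
            rows.append(dict(zip(AGP_COLUMNS, cols)))
    agp = pd.DataFrame(rows, columns=AGP_COLUMNS)
    for col in ("object_beg", "object_end", "part_number"):
        agp[col] = agp[col].astype(int)
    return agp


def reconstruct_from_agp(agp: pd.DataFrame,
                         sequences: Mapping[str, str]) -> dict[str, str]:
    """Rebuild object sequences from an AGP table and component sequences."""
    out: dict[str, list[str]] = {}
    for row in agp.itertuples(index=False):
        parts = out.setdefault(row.object, [])
        if row.component_type in ("N", "U"):
            parts.append("N" * int(row.component_id))
        else:
            seq = sequences[row.component_id]
            seq = seq[int(row.component_beg) - 1:int(row.component_end)]
            if row.orientation == "-":
                seq = str(Seq(seq).reverse_complement())
            parts.append(seq)
    return {k: "".join(v) for k, v in out.items()}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# in-silico digestion and CMAP

def insilico_digest(sequence: str, motif: str = DLE1_MOTIF,
                    map_id: str = "1") -> CmapLabelSet:
    """Label positions (1-based, motif start) of every motif occurrence.

    Matching is case-insensitive and overlapping occurrences are all
    reported; windows containing non-ACGT characters never match (the
    motif itself is plain ACGT, so any N or ambiguity code breaks it).
    """
    if not motif:
        raise ValidationError("empty digestion motif")
    seq = sequence.upper()
    pattern = re.compile("(?=" + re.escape(motif.upper()) + ")")
    positions = tuple(m.start() + 1 for m in pattern.finditer(seq))
    return CmapLabelSet(map_id=map_id, length=len(seq), positions=positions)


CMAP_HEADER = [
    "CMapId", "ContigLength", "NumSites", "SiteID", "LabelChannel",
    "Position", "StdDev", "Coverage", "Occurrence",
]


def write_cmap(label_sets: Sequence[CmapLabelSet], path: str | Path,
               motif: str = DLE1_MOTIF) -> None:
    """Emit CMAP v0.2 (one channel-1 row per label plus a channel-0 end row)."""
    with open(path, "w") as fh:
        fh.write("# CMAP File Version:\t0.2\n")
        fh.write("# Label Channels:\t1\n")
        fh.write(f"# Nickase Recognition Site 1:\t{motif}\n")
        fh.write("#h " + "\t".join(CMAP_HEADER) + "\n")
        fh.write("#f int\tfloat\tint\tint\tint\tfloat\tfloat\tfloat\tfloat\n")
        for ls in label_sets:
            n = len(ls.positions)
            for site_id, pos in enumerate(ls.positions, start=1):
                fh.write(f"{ls.map_id}\t{float(ls.length):.1f}\t{n}\t"
                         f"{site_id}\t{ls.channel}\t{float(pos):.1f}\t"
                         f"1.0\t1.0\t1.0\n")
            fh.write(f"{ls.map_id}\t{float(ls.length):.1f}\t{n}\t{n + 1}\t0\t"
                     f"{float(ls.length):.1f}\t0.0\t1.0\t0.0\n")


def read_cmap(path: str | Path) -> list[CmapLabelSet]:
    by_id: dict[str, dict] = {}
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            cols = raw.split("\t")
            map_id, length, channel, pos = (cols[0], float(cols[1]),
                                            int(cols[4]), float(cols[5]))
            entry = by_id.setdefault(map_id, {"length": int(length),
                                              "positions": []})
            if channel == 1:
                entry["positions"].append(int(pos))
    return [CmapLabelSet(map_id=k, length=v["length"],
                         positions=tuple(sorted(v["positions"])))
            for k, v in by_id.items()]


# ---------------------------------------------------------------------------
# CMAP comparison

@dataclass
class CmapAlignment:
    """Result of the interval-matching comparison of two label maps."""

    orientation: str  # "+" or "-"
    matched_pairs: list[tuple[int, int]]  # (ref label index, qry label index), 0-based
    unmatched_qry_runs: list[tuple[int, int]]  # [start, end] label-index runs
    n_matched_intervals: int
    undetermined: bool = False


def _interval_dp(ref_iv: np.ndarray, qry_iv: np.ndarray,
                 rel_tol: float) -> list[tuple[int, int]]:
    """LCS-style DP over interval sequences; two intervals match when their
    lengths agree within rel_tol of the larger."""
    n, m = len(ref_iv), len(qry_iv)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(1, n + 1):
        a = ref_iv[i - 1]
        for j in range(1, m + 1):
            b = qry_iv[j - 1]
            match = abs(a - b) <= rel_tol * max(a, b)
            dp[i, j] = max(dp[i - 1, j], dp[i, j - 1],
                           dp[i - 1, j - 1] + (1 if match else 0))
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        if (abs(ref_iv[i - 1] - qry_iv[j - 1])
                <= rel_tol * max(ref_iv[i - 1], qry_iv[j - 1])
                and dp[i, j] == dp[i - 1, j - 1] + 1):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif dp[i - 1, j] >= dp[i, j - 1]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def align_cmaps(ref: CmapLabelSet, qry: CmapLabelSet,
                rel_tol: float = 0.1, min_match: int = 5) -> CmapAlignment:
    """Compare two label maps by matching consecutive inter-label intervals.

    The query is tried in both orientations; the one matching more
    intervals wins.  Matched label pairs are reported in original (not
    flipped) query label indices, and maximal runs of unmatched query
    labels are returned as candidate discordances.
    """
    if len(ref.positions) < min_match or len(qry.positions) < min_match:
        return CmapAlignment(orientation="+", matched_pairs=[],
                             unmatched_qry_runs=[], n_matched_intervals=0,
                             undetermined=True)
    ref_iv = ref.intervals
    fwd = _interval_dp(ref_iv, qry.intervals, rel_tol)
    rev = _interval_dp(ref_iv, qry.intervals[::-1], rel_tol)
    m = len(qry.positions)
    if len(rev) > len(fwd):
        orientation, interval_pairs = "-", rev
        label_pairs = sorted({(i + d, m - 1 - (j + d))
                              for i, j in interval_pairs for d in (0, 1)})
    else:
        orientation, interval_pairs = "+", fwd
        label_pairs = sorted({(i + d, j + d)
                              for i, j in interval_pairs for d in (0, 1)})
    matched_qry = {j for _, j in label_pairs}
    runs: list[tuple[int, int]] = []
    start = None
    for j in range(m):
        if j not in matched_qry:
            if start is None:
                start = j
        elif start is not None:
            runs.append((start, j - 1))
            start = None
    if start is not None:
        runs.append((start, m - 1))
    return CmapAlignment(orientation=orientation, matched_pairs=label_pairs,
                         unmatched_qry_runs=runs,
                         n_matched_intervals=len(interval_pairs))
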