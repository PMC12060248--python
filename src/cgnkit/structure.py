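"""Structural-difference taxonomy from collinear blocks.

Non-backbone collinear blocks are converted into the two-way taxonomy used
to compare closely related assemblies: differences in *orientation*
(descending blocks sitting in place on the homologous chromosome, binned
by gene-pair count into 2 / 3 / >3 classes) and differences in *location*
(blocks of three or more pairs that are displaced within the homologous
chromosome or land on a non-homologous chromosome).  A block that is both
moved and flipped is tallied once, as a location difference with its
orientation recorded, so no block is double-counted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import fmean
from typing import Iterable, Sequence

import pandas as pd

from .orthology import CollinearBlock
from .io import OrthologRecord

log = logging.getLogger(__name__)

DIFF_KINDS = ("orientation", "intra_location", "inter_location")
VERDICTS = ("unset", "real", "assembly_error", "undetermined")


@dataclass
class StructuralDifference:
    """One orientation or location difference between the two assemblies."""

    diff_id: str
    kind: str  # orientation | intra_location | inter_location
    query_chrom: str
    target_chrom: str
    block: CollinearBlock
    size: int
    size_class: str = ""  # "2" | "3" | ">3" (orientation only)
    orientation_attr: str = "ascending"
    mean_pident: float = 0.0
    verdict: str = "unset"
    p_value: float | None = None

    @property
    def member_ids(self) -> list[str]:
        return [p.query.id for p in self.block.members]

    @property
    def identities(self) -> list[float]:
        return [p.pident for p in self.block.members]


def _size_class(n: int) -> str:
    return "2" if n == 2 else ("3" if n == 3 else ">3")


def detect_orientation_differences(
    blocks: Sequence[CollinearBlock],
) -> list[StructuralDifference]:
    """Every descending, in-place block on the homologous chromosome is one
    orientation difference (a putative inversion)."""
    diffs: list[StructuralDifference] = []
    for b in blocks:
        if b.is_backbone or not b.on_homologue:
            continue
        if b.direction == "descending" and b.placement == "in_place":
            diffs.append(StructuralDifference(
                diff_id=f"OD{len(diffs):04d}", kind="orientation",
                query_chrom=b.query_chrom, target_chrom=b.target_chrom,
                block=b, size=b.size, size_class=_size_class(b.size),
                orientation_attr="descending",
                mean_pident=fmean(p.pident for p in b.members)))
    return diffs


def detect_location_differences(
    blocks: Sequence[CollinearBlock],
    min_genes: int = 3,
) -> list[StructuralDifference]:
    """Displaced blocks of >= ``min_genes`` pairs on the homologous
    chromosome are intrachromosomal location differences; blocks of that
    size on any other chromosome are interchromosomal ones.  A displaced
    descending block counts once, here, with its orientation recorded."""
    diffs: list[StructuralDifference] = []
    for b in blocks:
        if b.is_backbone or b.size < min_genes:
            continue
        if b.on_homologue and b.placement == "displaced":
            kind = "intra_location"
        elif not b.on_homologue:
            kind = "inter_location"
        else:
            continue
        diffs.append(StructuralDifference(
            diff_id=f"LD{len(diffs):04d}", kind=kind,
            query_chrom=b.query_chrom, target_chrom=b.target_chrom,
            block=b, size=b.size, orientation_attr=b.direction,
            mean_pident=fmean(p.pident for p in b.members)))
    return diffs


def detect_differences(blocks: Sequence[CollinearBlock],
                       min_location_genes: int = 3) -> list[StructuralDifference]:
    """Full taxonomy; location differences subsume moved-and-flipped blocks."""
    location = detect_location_differences(blocks, min_location_genes)
    located = {id(d.block) for d in location}
    orientation = [d for d in detect_orientation_differences(blocks)
                   if id(d.block) not in located]
    ignored = sum(1 for b in blocks
                  if not b.is_backbone and b.on_homologue
                  and b.placement == "in_place" and b.direction == "ascending")
    if ignored:
        log.warning("%d in-place ascending off-backbone block(s) treated as "
                    "chaining artifacts, not differences", ignored)
    out = orientation + location
    for i, d in enumerate(out):
        d.diff_id = f"SD{i:04d}"
    return out


ORIENTATION_COLS = ["orient_2", "orient_3", "orient_gt3"]
LOCATION_COLS = ["intra_location", "inter_location"]


def summarize_differences(
    differences: Sequence[StructuralDifference],
    records: Sequence[OrthologRecord] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-chromosome difference matrix plus (optionally) class counts.

    Returns ``{"differences": ..., "classes": ...}``; the differences table
    has one row per query chromosome with orientation counts by size class
    and location counts by intra/inter, plus a totals row.
    """
    chroms = sorted({d.query_chrom for d in differences}
                    | ({r.query_chrom for r in records} if records else set()))
    table = pd.DataFrame(0, index=pd.Index(chroms, name="chromosome"),
                         columns=ORIENTATION_COLS + LOCATION_COLS)
    for d in differences:
        if d.kind == "orientation":
            col = {"2": "orient_2", "3": "orient_3", ">3": "orient_gt3"}[d.size_class]
        else:
            col = d.kind
        table.loc[d.query_chrom, col] += 1
    table.loc["Total"] = table.sum()

    out = {"differences": table}
    if records is not None:
        from .orthology import class_counts
        out["classes"] = class_counts(records)
    return out


def differences_to_frame(diffs: Sequence[StructuralDifference]) -> pd.DataFrame:
    """Flat table for the diffs TSV (one row per difference)."""
    rows = []
    for d in diffs:
        rows.append({
            "diff_id": d.diff_id, "kind": d.kind, "size": d.size,
            "size_class": d.size_class or "", "query_chrom": d.query_chrom,
            "target_chrom": d.target_chrom,
            "orientation": d.orientation_attr,
            "gene_ids": ",".join(d.member_ids),
            "mean_pident": round(d.mean_pident, 3),
            "verdict": d.verdict,
            "p_value": "" if d.p_value is None else f"{d.p_value:.4g}",
        })
    return pd.DataFrame(rows, columns=[
        "diff_id", "kind", "size", "size_class", "query_chrom",
        "target_chrom", "orientation", "gene_ids", "mean_pident", "verdict",
        "p_value"])
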