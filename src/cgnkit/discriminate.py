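"""Assembly-error vs real-rearrangement discrimination from sequence identity.

The signal: a *real* segmental relocation arises from segmental duplication,
so its gene pairs are paralogous and diverge well below the genome-wide
orthologue identity distribution; a relocation that is an *assembly error*
is an orthologous segment put in the wrong place, so identity stays at
orthologue level.  Location differences are therefore judged by a
one-sided z-test of the segment mean against Normal(mean, sd/sqrt(n)) of
the fitted orthologue distribution.

A *real* inversion spends time as a heterozygous polymorphism, suppressing
recombination and purifying selection inside the segment, so genes within
it diverge faster than genes flanking it; an orientation difference is
called real only when the segment mean is significantly below *both*
flanking segments (one-sided Welch tests), an assembly error when it is
significantly below neither, and undetermined otherwise.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .orthology import CollinearBlock
from .structure import StructuralDifference

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """A Welch (unequal-variance) t-test result with Satterthwaite df."""

    statistic: float
    df: float
    p_value: float
    sidedness: str  # one_sided_less | two_sided
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    undetermined: bool = False


@dataclass
class IdentityContext:
    """Genome-wide orthologue identity distribution plus test parameters.

    ``alpha_loc`` governs the one-sided z-test for location differences,
    ``alpha_inv`` the one-sided Welch tests for orientation differences
    (significance inclusive, p <= alpha); ``flank_cap`` bounds how many
    collinear pairs are taken per flanking side.
    """

    identities: np.ndarray
    mean: float
    sd: float
    alpha_loc: float = 0.01
    alpha_inv: float = 0.05
    flank_cap: int = 15

    @classmethod
    def from_identities(cls, identities: Sequence[float],
                        alpha_loc: float = 0.01, alpha_inv: float = 0.05,
                        flank_cap: int = 15) -> "IdentityContext":
        arr = np.asarray(list(identities), dtype=float)
        if arr.size == 0:
            raise ValueError("cannot build an identity context from no pairs")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(identities=arr, mean=float(arr.mean()), sd=sd,
                   alpha_loc=alpha_loc, alpha_inv=alpha_inv,
                   flank_cap=flank_cap)


def segment_identity_stats(identities: Sequence[float]) -> tuple[float, float, int]:
    """Arithmetic mean, sample sd, and n of a segment's pair identities.

    For n = 1 the sd is returned as nan (flagged undefined).
    """
    arr = np.asarray(list(identities), dtype=float)
    if arr.size == 0:
        raise ValueError("segment with no identities")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
    return float(arr.mean()), sd, int(arr.size)


def welch_t(group_a: Sequence[float], group_b: Sequence[float],
            sidedness: str = "two_sided") -> TestResult:
    """Welch's unequal-variance t-test; the one-sided variant tests
    mean(a) < mean(b).  Groups below n = 2 yield an undetermined result
    (flagged, not raised)."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        log.info("welch_t: group too small (n=%d, %d); undetermined",
                 a.size, b.size)
        return TestResult(statistic=float("nan"), df=float("nan"),
                          p_value=float("nan"), sidedness=sidedness,
                          n_a=a.size, n_b=b.size,
                          mean_a=float(a.mean()) if a.size else float("nan"),
                          mean_b=float(b.mean()) if b.size else float("nan"),
                          undetermined=True)
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate: both groups constant
        df = float(a.size + b.size - 2)
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = float("-inf") if a.mean() < b.mean() else float("inf")
            if sidedness == "one_sided_less":
                p = 0.0 if a.mean() < b.mean() else 1.0
            else:
                p = 0.0
        return TestResult(statistic=t, df=df, p_value=p, sidedness=sidedness,
                          n_a=a.size, n_b=b.size, mean_a=float(a.mean()),
                          mean_b=float(b.mean()))
    alternative = "less" if sidedness == "one_sided_less" else "two-sided"
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return TestResult(statistic=float(res.statistic), df=float(res.df),
                      p_value=float(res.pvalue), sidedness=sidedness,
                      n_a=a.size, n_b=b.size, mean_a=float(a.mean()),
                      mean_b=float(b.mean()))


def classify_location_difference(diff: StructuralDifference,
                                 ctx: IdentityContext) -> str:
    """Verdict for an intra-/inter-chromosomal location difference.

    One-sided z-test of the segment mean against
    Normal(ctx.mean, ctx.sd/sqrt(n)): significantly below at alpha_loc
    means paralog-level divergence (real segmental duplication); otherwise
    the segment is an orthologous block in the wrong place (assembly
    error).  Segments below three pairs are undetermined.
    """
    if diff.kind not in ("intra_location", "inter_location"):
        raise ValueError(f"{diff.diff_id}: not a location difference")
    mean, _sd, n = segment_identity_stats(diff.identities)
    if n < 3:
        diff.verdict = "undetermined"
        return diff.verdict
    if ctx.sd <= 0:
        p = 0.5 if mean >= ctx.mean else 0.0
    else:
        z = (mean - ctx.mean) / (ctx.sd / math.sqrt(n))
        p = float(stats.norm.cdf(z))
    diff.p_value = p
    diff.verdict = "real" if p <= ctx.alpha_loc else "assembly_error"
    return diff.verdict


def classify_orientation_difference(
    diff: StructuralDifference,
    distal_flank: Sequence[float],
    proximal_flank: Sequence[float],
    ctx: IdentityContext,
) -> str:
    """Verdict for an orientation difference via the flanking-segment test.

    One-sided Welch tests (segment < flank) against each flank at
    alpha_inv, significance inclusive: significant versus both flanks is a
    real inversion; versus neither, an assembly error; mixed evidence,
    a missing flank, or a segment below three pairs is undetermined.
    """
    if diff.kind != "orientation":
        raise ValueError(f"{diff.diff_id}: not an orientation difference")
    seg = list(diff.identities)
    if len(seg) < 3:
        diff.verdict = "undetermined"
        return diff.verdict
    distal = list(distal_flank)[:ctx.flank_cap]
    proximal = list(proximal_flank)[:ctx.flank_cap]
    results = [welch_t(seg, fl, "one_sided_less") for fl in (distal, proximal)]
    if any(r.undetermined for r in results):
        diff.verdict = "undetermined"
        return diff.verdict
    significant = [r.p_value <= ctx.alpha_inv for r in results]
    diff.p_value = max(r.p_value for r in results)
    if all(significant):
        diff.verdict = "real"
    elif not any(significant):
        diff.verdict = "assembly_error"
    else:
        diff.verdict = "undetermined"
    return diff.verdict


def compare_verdict_groups(real_means: Sequence[float],
                           error_means: Sequence[float]) -> TestResult:
    """Two-sided Welch t-test between per-segment mean identities of the
    real-verdict and error-verdict groups."""
    return welch_t(real_means, error_means, "two_sided")


# ---------------------------------------------------------------------------
# flank extraction and the full discrimination pass

def extract_flanks(diff: StructuralDifference,
                   blocks: Sequence[CollinearBlock],
                   cap: int = 15) -> tuple[list[float], list[float]]:
    """Identities of the collinear orthologous pairs flanking a segment.

    Flanks are taken from backbone members of the same query chromosome:
    the ``cap`` nearest pairs below the segment's query span (left flank)
    and above it (right flank).
    """
    lo, hi = diff.block.query_rank_span
    backbone_pairs = [p for b in blocks
                      if b.is_backbone and b.query_chrom == diff.query_chrom
                      for p in b.members]
    backbone_pairs.sort(key=lambda p: p.query_rank)
    left = [p.pident for p in backbone_pairs if p.query_rank < lo][-cap:]
    right = [p.pident for p in backbone_pairs if p.query_rank > hi][:cap]
    return left, right


def discriminate_differences(
    diffs: Sequence[StructuralDifference],
    blocks: Sequence[CollinearBlock],
    ctx: IdentityContext,
) -> list[StructuralDifference]:
    """Assign a verdict to every difference in place and return them."""
    for d in diffs:
        if d.kind == "orientation":
            left, right = extract_flanks(d, blocks, ctx.flank_cap)
            classify_orientation_difference(d, left, right, ctx)
        else:
            classify_location_difference(d, ctx)
    return list(diffs)
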