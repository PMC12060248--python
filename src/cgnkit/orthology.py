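"""Conserved-gene-neighborhood (CGN) orthology classification.

A query gene and its top BLAST hit are called putative orthologues when
they sit in a collinear (ascending or descending) order inside a conserved
gene neighborhood shared by the two assemblies; non-collinear top hits are
putative paralogues.  Collinearity is established per query chromosome by

1. finding the *dominant* target chromosome (plurality of rank-1 hits),
2. chaining a *backbone*: the maximum-cardinality ascending run (a
   gap-constrained longest increasing subsequence of target ranks) on the
   dominant chromosome, and
3. grouping the remaining pairs into maximal monotone runs (ascending or
   descending) under the same rank-gap limits; runs of two or more genes
   become collinear blocks, leftovers stay singletons (paralogues).

Step 3 solves small independent groups exactly (an exhaustive partition
over bitmasks, maximizing the number of genes placed in blocks) and falls
back to a greedy left-to-right scan for groups too large to enumerate.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from math import inf
from typing import Iterable, Sequence

from scipy.stats import norm

from .io import (Gene, HitRecord, OrthologRecord, ValidationError, rank_genes)

log = logging.getLogger(__name__)

#: largest leftover group solved by exhaustive chain-partition enumeration
EXACT_PARTITION_LIMIT = 12


@dataclass(frozen=True)
class ThresholdSpec:
    """Identity threshold used when juxtaposed duplicated queries share a target.

    The working threshold is the configured constant ``threshold`` (97.0 %);
    :func:`derive_identity_threshold` exposes the one-sided normal-quantile
    derivation from the orthologue identity distribution (mu, sigma, alpha)
    for comparison.
    """

    mu: float = 99.4
    sigma: float = 1.65
    alpha: float = 0.01
    threshold: float = 97.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError(f"alpha {self.alpha} outside (0, 1)")
        if not 0.0 <= self.threshold <= 100.0:
            raise ValidationError(f"threshold {self.threshold} outside [0, 100]")
        if self.sigma < 0:
            raise ValidationError(f"negative sigma {self.sigma}")


def derive_identity_threshold(spec: ThresholdSpec) -> float:
    """Lower identity bound mu - z(1-alpha)*sigma of the orthologue model."""
    return float(spec.mu - norm.ppf(1.0 - spec.alpha) * spec.sigma)


@dataclass(frozen=True)
class RankedPair:
    """A query gene paired with its rank-1 target, both with ordinal ranks."""

    query: Gene
    target_id: str
    target_chrom: str
    target_rank: int
    pident: float
    align_len: int = 0
    target_start: int = 0
    target_end: int = 0

    @property
    def query_rank(self) -> int:
        assert self.query.rank is not None
        return self.query.rank


@dataclass
class CollinearBlock:
    """A monotone run of two or more collinear gene pairs."""

    block_id: str
    query_chrom: str
    target_chrom: str
    members: list[RankedPair]
    direction: str  # ascending | descending
    placement: str = "in_place"  # in_place | displaced
    on_homologue: bool = True
    is_backbone: bool = False

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def query_rank_span(self) -> tuple[int, int]:
        ranks = [p.query_rank for p in self.members]
        return min(ranks), max(ranks)

    @property
    def target_rank_span(self) -> tuple[int, int]:
        ranks = [p.target_rank for p in self.members]
        return min(ranks), max(ranks)


# ---------------------------------------------------------------------------
# shared-target adjudication

def resolve_shared_targets(
    pairs: Sequence[RankedPair],
    spec: ThresholdSpec | None = None,
    juxtapose_distance: int = 2,
) -> dict[str, str]:
    """Adjudicate juxtaposed duplicated queries that hit the same target.

    Returns ``query_id -> {"candidate", "paralogous", "uncertain"}`` for
    every query involved in a juxtaposed shared-target group.  When exactly
    one of the juxtaposed queries reaches the identity threshold it stays
    the orthologue candidate and the others are paralogous; when all or
    none reach it, no decision is made and all become uncertain (and are
    excluded from chaining).
    """
    spec = spec or ThresholdSpec()
    by_target: dict[str, list[RankedPair]] = {}
    for p in pairs:
        by_target.setdefault(p.target_id, []).append(p)
    verdicts: dict[str, str] = {}
    for target_id, group in by_target.items():
        if len(group) < 2:
            continue
        # cluster queries on the same chromosome within the rank distance
        by_chrom: dict[str, list[RankedPair]] = {}
        for p in group:
            by_chrom.setdefault(p.query.chromosome, []).append(p)
        for chrom_group in by_chrom.values():
            chrom_group.sort(key=lambda p: p.query_rank)
            cluster = [chrom_group[0]]
            clusters = [cluster]
            for p in chrom_group[1:]:
                if p.query_rank - cluster[-1].query_rank <= juxtapose_distance:
                    cluster.append(p)
                else:
                    cluster = [p]
                    clusters.append(cluster)
            for cl in clusters:
                if len(cl) < 2:
                    continue
                above = [p for p in cl if p.pident >= spec.threshold]
                if len(above) == 1:
                    for p in cl:
                        verdicts[p.query.id] = (
                            "candidate" if p is above[0] else "paralogous")
                else:
                    for p in cl:
                        verdicts[p.query.id] = "uncertain"
    return verdicts


# ---------------------------------------------------------------------------
# chaining

def _lis_table(pairs: list[RankedPair], max_target_gap: int,
               max_query_gap: int) -> list[int]:
    """dp[i] = length of the longest gap-constrained ascending chain ending
    at query-sorted index i."""
    n = len(pairs)
    dp = [1] * n
    for i in range(n):
        qi, ti = pairs[i].query_rank, pairs[i].target_rank
        for j in range(i - 1, -1, -1):
            qj, tj = pairs[j].query_rank, pairs[j].target_rank
            if qi - qj > max_query_gap:
                break  # pairs are query-sorted; earlier j only farther
            if 0 < ti - tj <= max_target_gap and dp[j] + 1 > dp[i]:
                dp[i] = dp[j] + 1
    return dp


def _constrained_lis(pairs: list[RankedPair], max_target_gap: int,
                     max_query_gap: int) -> list[RankedPair]:
    """One maximum-cardinality ascending chain of target ranks (query-ordered,
    consecutive-member rank gaps bounded on both axes), deterministic."""
    n = len(pairs)
    if n == 0:
        return []
    dp = _lis_table(pairs, max_target_gap, max_query_gap)
    best = max(range(n), key=lambda i: (dp[i], -i))
    chain = [pairs[best]]
    i = best
    while dp[i] > 1:
        qi, ti = pairs[i].query_rank, pairs[i].target_rank
        for j in range(i - 1, -1, -1):
            qj, tj = pairs[j].query_rank, pairs[j].target_rank
            if qi - qj > max_query_gap:
                break
            if 0 < ti - tj <= max_target_gap and dp[j] == dp[i] - 1:
                chain.append(pairs[j])
                i = j
                break
    chain.reverse()
    return chain


def _all_max_ascending_chains(pairs: list[RankedPair], max_target_gap: int,
                              max_query_gap: int,
                              cap: int = 2000) -> list[list[RankedPair]]:
    """Every maximum-cardinality ascending chain (up to ``cap`` of them)."""
    n = len(pairs)
    if n == 0:
        return []
    dp = _lis_table(pairs, max_target_gap, max_query_gap)
    best_len = max(dp)
    chains: list[list[RankedPair]] = []

    def backtrack(i: int, suffix: list[RankedPair]) -> None:
        if len(chains) >= cap:
            return
        suffix = [pairs[i]] + suffix
        if dp[i] == 1:
            chains.append(suffix)
            return
        qi, ti = pairs[i].query_rank, pairs[i].target_rank
        for j in range(i - 1, -1, -1):
            qj, tj = pairs[j].query_rank, pairs[j].target_rank
            if qi - qj > max_query_gap:
                break
            if 0 < ti - tj <= max_target_gap and dp[j] == dp[i] - 1:
                backtrack(j, suffix)

    for i in range(n):
        if dp[i] == best_len:
            backtrack(i, [])
    return chains


def _chain_valid_extension(t_last: int, t_next: int, direction: int,
                           max_target_gap: int) -> int | None:
    """Direction after appending, or None if the step is not monotone/in gap."""
    step = t_next - t_last
    if step == 0 or abs(step) > max_target_gap:
        return None
    sign = 1 if step > 0 else -1
    if direction != 0 and sign != direction:
        return None
    return sign


def _enumerate_chains(q: list[int], t: list[int], max_target_gap: int,
                      max_query_gap: int) -> dict[int, list[int]]:
    """All valid monotone chains (size >= 2) as bitmasks, keyed by lowest bit."""
    n = len(q)
    chains: dict[int, list[int]] = {i: [] for i in range(n)}

    def extend(start: int, last: int, direction: int, mask: int) -> None:
        for j in range(last + 1, n):
            if q[j] - q[last] > max_query_gap:
                break
            d = _chain_valid_extension(t[last], t[j], direction, max_target_gap)
            if d is None:
                continue
            new_mask = mask | (1 << j)
            chains[start].append(new_mask)
            extend(start, j, d, new_mask)

    for i in range(n):
        extend(i, i, 0, 1 << i)
    return chains


def _partition_exact(pairs: list[RankedPair], max_target_gap: int,
                     max_query_gap: int) -> tuple[list[list[RankedPair]], list[RankedPair]]:
    """Partition into monotone chains maximizing genes covered by chains of
    size >= 2 (then fewest chains); exhaustive over subsets."""
    n = len(pairs)
    q = [p.query_rank for p in pairs]
    t = [p.target_rank for p in pairs]
    chains = _enumerate_chains(q, t, max_target_gap, max_query_gap)
    size = [bin(m).count("1") for m in range(1 << n)] if n <= 16 else None
    # dp[mask] = (covered, -n_chains, choice_mask) over elements in mask
    dp: list[tuple[int, int, int]] = [(0, 0, 0)] * (1 << n)
    for mask in range(1, 1 << n):
        i = (mask & -mask).bit_length() - 1
        rest = mask ^ (1 << i)
        c, nc, _ = dp[rest]
        best = (c, nc, 0)  # leave i as a singleton
        for cm in chains[i]:
            if cm & mask != cm:
                continue
            c2, nc2, _ = dp[mask ^ cm]
            cand = (c2 + size[cm], nc2 - 1, cm)
            if (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
        dp[mask] = best
    out_chains: list[list[RankedPair]] = []
    singletons: list[RankedPair] = []
    mask = (1 << n) - 1
    while mask:
        i = (mask & -mask).bit_length() - 1
        _, _, cm = dp[mask]
        if cm == 0:
            singletons.append(pairs[i])
            mask ^= 1 << i
        else:
            out_chains.append([pairs[j] for j in range(n) if cm >> j & 1])
            mask ^= cm
    out_chains.reverse()
    singletons.reverse()
    return out_chains, singletons


def _partition_greedy(pairs: list[RankedPair], max_target_gap: int,
                      max_query_gap: int) -> tuple[list[list[RankedPair]], list[RankedPair]]:
    """Left-to-right grouping into maximal query-consecutive monotone runs."""
    chains: list[list[RankedPair]] = []
    singletons: list[RankedPair] = []
    run: list[RankedPair] = []
    direction = 0

    def close() -> None:
        nonlocal run, direction
        if len(run) >= 2:
            chains.append(run)
        else:
            singletons.extend(run)
        run = []
        direction = 0

    for p in pairs:
        if not run:
            run = [p]
            continue
        last = run[-1]
        if p.query_rank - last.query_rank > max_query_gap:
            close()
            run = [p]
            continue
        d = _chain_valid_extension(last.target_rank, p.target_rank,
                                   direction, max_target_gap)
        if d is None:
            close()
            run = [p]
        else:
            direction = d
            run.append(p)
    close()
    return chains, singletons


def _partition_group(group: list[RankedPair], max_target_gap: int,
                     max_query_gap: int) -> tuple[list[list[RankedPair]], list[RankedPair]]:
    """Partition same-target-chromosome leftovers into monotone chains.

    The group is first split into independent components at query-rank gaps
    exceeding the limit (no chain can span them); small components are
    solved exactly, large ones greedily.
    """
    chains: list[list[RankedPair]] = []
    singletons: list[RankedPair] = []
    comp: list[RankedPair] = []
    comps: list[list[RankedPair]] = []
    for p in sorted(group, key=lambda p: p.query_rank):
        if comp and p.query_rank - comp[-1].query_rank > max_query_gap:
            comps.append(comp)
            comp = []
        comp.append(p)
    if comp:
        comps.append(comp)
    for comp in comps:
        if len(comp) == 1:
            singletons.append(comp[0])
        elif len(comp) <= EXACT_PARTITION_LIMIT:
            ch, si = _partition_exact(comp, max_target_gap, max_query_gap)
            chains.extend(ch)
            singletons.extend(si)
        else:
            ch, si = _partition_greedy(comp, max_target_gap, max_query_gap)
            chains.extend(ch)
            singletons.extend(si)
    return chains, singletons


def chain_collinear_blocks(
    pairs: Sequence[RankedPair],
    max_target_gap: int = 5,
    max_query_gap: int = 5,
    block_id_prefix: str = "",
) -> tuple[list[CollinearBlock], list[RankedPair]]:
    """Chain the rank-1 pairs of one query chromosome into collinear blocks.

    Returns ``(blocks, singletons)``.  The first block, when present, is the
    ascending backbone on the dominant target chromosome; every other block
    carries ``placement`` (in_place vs displaced relative to the backbone
    flanks extended by ``max_target_gap``) and ``on_homologue``.
    """
    if not pairs:
        return [], []
    ordered = sorted(pairs, key=lambda p: p.query_rank)
    qchrom = ordered[0].query.chromosome
    counts = Counter(p.target_chrom for p in ordered)
    top = max(counts.values())
    dominant = min(c for c, k in counts.items() if k == top)

    dom_pairs = [p for p in ordered if p.target_chrom == dominant]
    chains: list[list[RankedPair]] = []
    singletons: list[RankedPair] = []

    # pairs hitting non-dominant chromosomes: independent of backbone choice
    by_chrom: dict[str, list[RankedPair]] = {}
    for p in ordered:
        if p.target_chrom != dominant:
            by_chrom.setdefault(p.target_chrom, []).append(p)
    for chrom in sorted(by_chrom):
        ch, si = _partition_group(by_chrom[chrom], max_target_gap, max_query_gap)
        chains.extend(ch)
        singletons.extend(si)

    # dominant chromosome: reserve a maximum ascending backbone, then chain
    # the leftovers.  For small inputs every maximum ascending chain is tried
    # and the one admitting the best leftover coverage wins.
    if len(dom_pairs) <= EXACT_PARTITION_LIMIT:
        candidates = _all_max_ascending_chains(dom_pairs, max_target_gap,
                                               max_query_gap)
        if candidates and len(candidates[0]) < 2:
            candidates = [[]]
        best: tuple | None = None
        for cand in (candidates or [[]]):
            cand_ids = {id(p) for p in cand}
            left = [p for p in dom_pairs if id(p) not in cand_ids]
            ch, si = _partition_group(left, max_target_gap, max_query_gap)
            cov = len(cand) + sum(len(c) for c in ch)
            if best is None or cov > best[0]:
                best = (cov, cand, ch, si)
        _, backbone, dom_chains, dom_singles = best
    else:
        backbone = _constrained_lis(dom_pairs, max_target_gap, max_query_gap)
        if len(backbone) < 2:
            backbone = []
        in_backbone = {id(p) for p in backbone}
        left = [p for p in dom_pairs if id(p) not in in_backbone]
        dom_chains, dom_singles = _partition_group(left, max_target_gap,
                                                   max_query_gap)
    chains.extend(dom_chains)
    singletons.extend(dom_singles)

    blocks: list[CollinearBlock] = []
    counter = 0
    if backbone:
        blocks.append(CollinearBlock(
            block_id=f"{block_id_prefix}{qchrom}.B{counter}",
            query_chrom=qchrom, target_chrom=dominant, members=list(backbone),
            direction="ascending", placement="in_place", on_homologue=True,
            is_backbone=True))
        counter += 1
    chains.sort(key=lambda ch: ch[0].query_rank)
    bb_q = [p.query_rank for p in backbone]
    bb_t = [p.target_rank for p in backbone]
    for ch in chains:
        direction = ("ascending" if ch[-1].target_rank > ch[0].target_rank
                     else "descending")
        on_hom = ch[0].target_chrom == dominant
        placement = "displaced"
        if on_hom:
            placement = _placement(ch, bb_q, bb_t, max_target_gap)
        blocks.append(CollinearBlock(
            block_id=f"{block_id_prefix}{qchrom}.B{counter}",
            query_chrom=qchrom, target_chrom=ch[0].target_chrom,
            members=ch, direction=direction, placement=placement,
            on_homologue=on_hom))
        counter += 1
    singletons.sort(key=lambda p: p.query_rank)
    return blocks, singletons


def _placement(chain: list[RankedPair], bb_q: list[int], bb_t: list[int],
               max_target_gap: int) -> str:
    """in_place iff the chain's target ranks fall between the target ranks of
    the backbone members flanking it in query order (widened by the gap)."""
    if not bb_q:
        return "in_place"
    import bisect
    lo_q = chain[0].query_rank
    hi_q = chain[-1].query_rank
    i = bisect.bisect_left(bb_q, lo_q)
    j = bisect.bisect_right(bb_q, hi_q)
    prev_t = bb_t[i - 1] if i > 0 else None
    next_t = bb_t[j] if j < len(bb_t) else None
    bounds = [t for t in (prev_t, next_t) if t is not None]
    lo = (min(bounds) - max_target_gap) if bounds else -inf
    hi = (max(bounds) + max_target_gap) if bounds else inf
    if prev_t is None:
        lo = -inf
    if next_t is None:
        hi = inf
    return ("in_place"
            if all(lo <= p.target_rank <= hi for p in chain) else "displaced")


# ---------------------------------------------------------------------------
# backbone refinement
#
# Gap-capped chaining leaves three artifacts on noisy input: the backbone
# fragments wherever interleaved paralogues/undetected genes open a rank
# gap beyond the cap; collinear genes stranded between fragments fall out
# as singletons; and the edge genes of an inverted segment are absorbed
# into the ascending backbone (the backbone "jumps over" the flip using
# its ends).  The refinement pass below repairs all three without touching
# the chaining primitive itself: in-place ascending blocks and singletons
# whose insertion keeps the backbone doubly (query and target) strictly
# increasing are merged into it; backbone members that monotonically extend
# an adjacent descending block are reclaimed by it; and a leftover
# singleton forming a local descending pair with an adjacent backbone
# member becomes a 2-gene block (the smallest orientation-difference
# class).  Placement of the remaining blocks is then recomputed against
# the consolidated backbone.


def _is_doubly_increasing(members: list[RankedPair]) -> bool:
    return all(b.query_rank > a.query_rank and b.target_rank > a.target_rank
               for a, b in zip(members, members[1:]))


def refine_blocks(
    blocks: list[CollinearBlock],
    singletons: list[RankedPair],
    max_target_gap: int = 5,
    max_query_gap: int = 5,
) -> tuple[list[CollinearBlock], list[RankedPair]]:
    """Consolidate the backbone of one query chromosome's chaining result.

    Returns new ``(blocks, singletons)``; input lists are not mutated.
    No-op when the chromosome has no backbone.
    """
    backbone_block = next((b for b in blocks if b.is_backbone), None)
    if backbone_block is None:
        return list(blocks), list(singletons)
    qchrom = backbone_block.query_chrom
    dominant = backbone_block.target_chrom
    backbone = sorted(backbone_block.members, key=lambda p: p.query_rank)
    others = [b for b in blocks if not b.is_backbone]
    free = sorted(singletons, key=lambda p: p.query_rank)

    # 1. merge ascending dominant-chromosome blocks and singletons whose
    #    insertion keeps the backbone doubly strictly increasing
    merged_away: set[int] = set()
    candidates: list[tuple[int, list[RankedPair], object]] = []
    for b in others:
        if b.target_chrom == dominant and b.direction == "ascending":
            candidates.append((b.members[0].query_rank, list(b.members), b))
    for s in free:
        if s.target_chrom == dominant:
            candidates.append((s.query_rank, [s], s))
    # larger fragments first: genuine backbone fragments are long, while
    # relocated or scattered leftovers are short and must not fill a
    # backbone hole before the true fragment reclaims it
    for _, members, obj in sorted(candidates,
                                  key=lambda c: (-len(c[1]), c[0])):
        trial = sorted(backbone + members, key=lambda p: p.query_rank)
        if _is_doubly_increasing(trial):
            backbone = trial
            merged_away.add(id(obj))
    others = [b for b in others if id(b) not in merged_away]
    free = [s for s in free if id(s) not in merged_away]

    # 2. descending blocks reclaim adjacent backbone members that extend
    #    their run (inverted-segment edges absorbed by the LIS)
    for b in others:
        if (b.target_chrom != dominant or b.direction != "descending"
                or len(backbone) <= 2):
            continue
        members = sorted(b.members, key=lambda p: p.query_rank)
        changed = True
        while changed and len(backbone) > 2:
            changed = False
            first, last = members[0], members[-1]
            import bisect
            qs = [p.query_rank for p in backbone]
            i = bisect.bisect_left(qs, first.query_rank) - 1
            if i >= 0:
                m = backbone[i]
                if (first.query_rank - m.query_rank <= max_query_gap
                        and 0 < m.target_rank - first.target_rank
                        <= max_target_gap):
                    members.insert(0, m)
                    backbone.pop(i)
                    changed = True
                    continue
            qs = [p.query_rank for p in backbone]
            j = bisect.bisect_right(qs, last.query_rank)
            if j < len(backbone):
                m = backbone[j]
                if (m.query_rank - last.query_rank <= max_query_gap
                        and 0 < last.target_rank - m.target_rank
                        <= max_target_gap):
                    members.append(m)
                    backbone.pop(j)
                    changed = True
        b.members = members

    # 3. leftover singletons forming a local descending pair with an
    #    adjacent backbone member become 2-gene blocks
    new_blocks: list[CollinearBlock] = []
    remaining: list[RankedPair] = []
    import bisect
    for s in free:
        if s.target_chrom != dominant or len(backbone) <= 2:
            remaining.append(s)
            continue
        qs = [p.query_rank for p in backbone]
        i = bisect.bisect_left(qs, s.query_rank)
        pair = None
        before = backbone[i - 1] if i > 0 else None
        after = backbone[i] if i < len(backbone) else None

        def _local_swap(m: RankedPair, idx: int) -> bool:
            # the pair must sit between the surrounding backbone targets,
            # i.e. look like a local order swap, not a long-range jump
            prev_t = backbone[idx - 1].target_rank if idx > 0 else -inf
            next_t = (backbone[idx + 1].target_rank
                      if idx + 1 < len(backbone) else inf)
            lo, hi = sorted((s.target_rank, m.target_rank))
            return prev_t < lo and hi < next_t

        if (before is not None
                and s.query_rank - before.query_rank <= max_query_gap
                and 0 < before.target_rank - s.target_rank <= max_target_gap
                and _local_swap(before, i - 1)):
            pair = (before, [before, s], i - 1)
        elif (after is not None
                and after.query_rank - s.query_rank <= max_query_gap
                and 0 < s.target_rank - after.target_rank <= max_target_gap
                and _local_swap(after, i)):
            pair = (after, [s, after], i)
        if pair is None:
            remaining.append(s)
            continue
        _, members, idx = pair
        backbone.pop(idx)
        new_blocks.append(CollinearBlock(
            block_id=f"{qchrom}.R{len(new_blocks)}", query_chrom=qchrom,
            target_chrom=dominant, members=members, direction="descending",
            placement="in_place", on_homologue=True))

    backbone_block.members = backbone
    out = [backbone_block] + others + new_blocks
    bb_q = [p.query_rank for p in backbone]
    bb_t = [p.target_rank for p in backbone]
    for b in out:
        if b.is_backbone:
            continue
        if b.on_homologue:
            b.placement = _placement(
                sorted(b.members, key=lambda p: p.query_rank),
                bb_q, bb_t, max_target_gap)
        else:
            b.placement = "displaced"
    return out, remaining


# ---------------------------------------------------------------------------
# full classification

def flag_spurious_duplicates(genes: Sequence[Gene]) -> set[str]:
    """Gene ids of query pairs sharing chromosome and start but differing in
    end coordinate: the fingerprint of gene-transfer duplication artifacts."""
    by_start: dict[tuple[str, int], list[Gene]] = {}
    for g in genes:
        by_start.setdefault((g.chromosome, g.start), []).append(g)
    flagged: set[str] = set()
    for group in by_start.values():
        if len(group) > 1 and len({g.end for g in group}) > 1:
            flagged.update(g.id for g in group)
    return flagged


def classify_genes(
    genes_query: Sequence[Gene],
    genes_target: Sequence[Gene],
    hits: Sequence[HitRecord],
    spec: ThresholdSpec | None = None,
    max_target_gap: int = 5,
    max_query_gap: int = 5,
    juxtapose_distance: int = 2,
) -> tuple[list[OrthologRecord], list[CollinearBlock]]:
    """Classify every query gene as orthologous / paralogous / uncertain /
    undetected and return the collinear blocks supporting the calls.

    Every query gene appears in exactly one class: queries without hits are
    undetected; juxtaposed shared-target duplicates are adjudicated by the
    identity threshold; members of collinear blocks (size >= 2) are putative
    orthologues; remaining singletons are putative paralogues.
    """
    spec = spec or ThresholdSpec()
    q_ranked = rank_genes(genes_query)
    t_ranked = rank_genes(genes_target)
    q_by_id = {g.id: g for g in q_ranked}
    t_by_id = {g.id: g for g in t_ranked}

    top_hits: dict[str, HitRecord] = {}
    for h in hits:
        if h.query_id not in q_by_id:
            raise ValidationError(
                f"hit references unknown query gene {h.query_id!r}")
        if h.target_id not in t_by_id:
            raise ValidationError(
                f"hit references unknown target gene {h.target_id!r}")
        if h.hit_rank == 1:
            top_hits[h.query_id] = h

    pairs: list[RankedPair] = []
    for qid, h in top_hits.items():
        tg = t_by_id[h.target_id]
        pairs.append(RankedPair(
            query=q_by_id[qid], target_id=tg.id, target_chrom=tg.chromosome,
            target_rank=tg.rank, pident=h.pident, align_len=h.align_len,
            target_start=tg.start, target_end=tg.end))

    adjudications = resolve_shared_targets(pairs, spec, juxtapose_distance)
    chainable = [p for p in pairs
                 if adjudications.get(p.query.id, "candidate") == "candidate"]

    blocks: list[CollinearBlock] = []
    singleton_pairs: list[RankedPair] = []
    by_qchrom: dict[str, list[RankedPair]] = {}
    for p in chainable:
        by_qchrom.setdefault(p.query.chromosome, []).append(p)
    for chrom in sorted(by_qchrom):
        bl, si = chain_collinear_blocks(
            by_qchrom[chrom], max_target_gap, max_query_gap)
        bl, si = refine_blocks(bl, si, max_target_gap, max_query_gap)
        blocks.extend(bl)
        singleton_pairs.extend(si)

    block_of: dict[str, str] = {}
    for b in blocks:
        for p in b.members:
            block_of[p.query.id] = b.block_id

    spurious = flag_spurious_duplicates(q_ranked)
    pair_of = {p.query.id: p for p in pairs}

    records: list[OrthologRecord] = []
    for g in q_ranked:
        flags = "!" if g.id in spurious else ""
        p = pair_of.get(g.id)
        if p is None:
            records.append(OrthologRecord(
                query_id=g.id, query_chrom=g.chromosome, query_start=g.start,
                query_end=g.end, confidence=g.confidence, klass="undetected",
                flags=flags))
            continue
        verdict = adjudications.get(g.id, "candidate")
        if verdict == "uncertain":
            klass, block_id = "uncertain", ""
        elif verdict == "paralogous":
            klass, block_id = "paralogous", ""
        elif g.id in block_of:
            klass, block_id = "orthologous", block_of[g.id]
        else:
            klass, block_id = "paralogous", ""
        records.append(OrthologRecord(
            query_id=g.id, query_chrom=g.chromosome, query_start=g.start,
            query_end=g.end, confidence=g.confidence, target_id=p.target_id,
            target_chrom=p.target_chrom, target_start=p.target_start,
            target_end=p.target_end, pident=p.pident, align_len=p.align_len,
            klass=klass, block_id=block_id, flags=flags))
    return records, blocks


def blocks_from_records(records: Sequence[OrthologRecord]) -> list[CollinearBlock]:
    """Rebuild collinear blocks from a classified ortholog table.

    Ranks are recomputed from the coordinates present in the table (query
    genes are complete; target ranks are over the targets that appear), so
    rank *order* is exact while rank *distances* are compressed relative
    to the full target annotation.  The block whose id ends in ``.B0`` is
    the backbone of its chromosome.  Placement and on_homologue are
    recomputed against the backbone.
    """
    q_genes = rank_genes([Gene(id=r.query_id, chromosome=r.query_chrom,
                               start=r.query_start, end=r.query_end,
                               confidence=r.confidence) for r in records])
    seen_targets: dict[str, Gene] = {}
    for r in records:
        if r.target_id and r.target_id not in seen_targets:
            seen_targets[r.target_id] = Gene(
                id=r.target_id, chromosome=r.target_chrom,
                start=r.target_start, end=r.target_end)
    t_genes = rank_genes(list(seen_targets.values()))
    q_by_id = {g.id: g for g in q_genes}
    t_by_id = {g.id: g for g in t_genes}

    grouped: dict[str, list[OrthologRecord]] = {}
    for r in records:
        if r.klass == "orthologous" and r.block_id:
            grouped.setdefault(r.block_id, []).append(r)
    blocks: list[CollinearBlock] = []
    for block_id in sorted(grouped):
        rs = grouped[block_id]
        members = [RankedPair(
            query=q_by_id[r.query_id], target_id=r.target_id,
            target_chrom=r.target_chrom,
            target_rank=t_by_id[r.target_id].rank, pident=r.pident,
            align_len=r.align_len, target_start=r.target_start,
            target_end=r.target_end) for r in rs]
        members.sort(key=lambda p: p.query_rank)
        direction = ("descending" if len(members) >= 2
                     and members[-1].target_rank < members[0].target_rank
                     else "ascending")
        blocks.append(CollinearBlock(
            block_id=block_id, query_chrom=members[0].query.chromosome,
            target_chrom=members[0].target_chrom, members=members,
            direction=direction, is_backbone=block_id.endswith(".B0")))
    for chrom in {b.query_chrom for b in blocks}:
        chrom_blocks = [b for b in blocks if b.query_chrom == chrom]
        bb = next((b for b in chrom_blocks if b.is_backbone), None)
        dominant = bb.target_chrom if bb else None
        bb_q = [p.query_rank for p in bb.members] if bb else []
        bb_t = [p.target_rank for p in bb.members] if bb else []
        for b in chrom_blocks:
            b.on_homologue = (dominant is None
                              or b.target_chrom == dominant)
            if b.is_backbone:
                continue
            if b.on_homologue:
                b.placement = _placement(b.members, bb_q, bb_t, 5)
            else:
                b.placement = "displaced"
    return blocks


def class_counts(records: Iterable[OrthologRecord]):
    """Per-chromosome class-by-confidence counts (Table-4-style layout)."""
    import pandas as pd
    rows = [{"chromosome": r.query_chrom, "confidence": r.confidence,
             "klass": r.klass} for r in records]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    table = (df.value_counts(["chromosome", "klass", "confidence"])
             .unstack(["klass", "confidence"], fill_value=0)
             .sort_index(axis=1))
    table.loc["Total"] = table.sum()
    return table
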