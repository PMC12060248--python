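"""Seeded simulator of paired annotated genomes with truth labels.

Genome B is derived from genome A's gene order; each A gene has a partner
whose identity is drawn from the orthologue model N(99.4, 1.65) truncated
to (50, 100].  Per-gene fates emulate the study conditions: a fraction of
queries per confidence class is undetected (HC 1.7 %, LC 15.5 %) and a
fraction has a scattered paralogous top hit drawn from the paralogue
models (HC N(93.3, 6.7), LC N(95.2, 4.5)).  Structural events are injected
on the B side:

* real inversions   — flip a segment AND redraw identities from N(94, 2)
  (recombination-suppressed divergence of a real polymorphic inversion);
* error inversions  — flip only, identities stay at orthologue level;
* segmental dups    — relocate a segment (intra or inter chromosome) and
  redraw identities from the paralogue model (a real location difference);
* error relocations — relocate only, identities stay at orthologue level;
* transpositions    — move one gene without duplication (its top hit
  becomes non-collinear, hence a putative paralogue);
* tandem dup/loss   — the in-paralogue scenario: the pair stays collinear
  but its identity is paralogue-level, and the putative call remains
  orthologous;
* shared-target dups — juxtaposed duplicated queries hitting one target,
  exercising the identity-threshold adjudication.

Truth labels record the *putative* (collinearity-level) class each gene
should receive plus every event with its member genes and the verdict a
correct discriminator should assign.  The same seed yields byte-identical
outputs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Gene, HitRecord, ValidationError, assign_hit_ranks
from .structure import StructuralDifference

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the paired-genome simulator."""

    n_chromosomes: int = 4
    genes_per_chromosome: int = 500
    fraction_lc: float = 0.522
    ortho_mu: float = 99.4
    ortho_sigma: float = 1.65
    paralog_hc: tuple[float, float] = (93.3, 6.7)
    paralog_lc: tuple[float, float] = (95.2, 4.5)
    inversion_mu: float = 94.0
    inversion_sigma: float = 2.0
    undetected_hc: float = 0.017
    undetected_lc: float = 0.155
    paralog_fraction_hc: float = 0.084
    paralog_fraction_lc: float = 0.473
    n_transpositions: int = 5
    n_tandem_dup_loss: int = 8
    n_shared_target_dups: int = 4
    segdup_intra_sizes: tuple[int, ...] = (4, 5)
    segdup_inter_sizes: tuple[int, ...] = (4,)
    real_inversion_sizes: tuple[int, ...] = (4, 5, 6, 8)
    error_inversion_sizes: tuple[int, ...] = (2, 3, 4, 6, 10)
    error_reloc_intra_sizes: tuple[int, ...] = (3, 4, 5)
    error_reloc_inter_sizes: tuple[int, ...] = (3, 4)
    decoy_rate: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("fraction_lc", "undetected_hc", "undetected_lc",
                     "paralog_fraction_hc", "paralog_fraction_lc",
                     "decoy_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class TruthEvent:
    event_id: str
    kind: str    # real_inversion | error_inversion | real_translocation |
                 # error_relocation | transposition | duplication
    scope: str   # intra | inter | ""
    query_chrom: str
    member_query_ids: tuple[str, ...]  # collinear member pairs
    size: int
    expected_verdict: str  # real | assembly_error | ""


@dataclass
class Truth:
    """Per-gene putative classes (both genomes) and the injected events."""

    gene_class: dict[str, str]
    events: list[TruthEvent]


@dataclass
class GenomePair:
    genes_a: list[Gene]
    genes_b: list[Gene]
    hits: list[HitRecord]
    truth: Truth
    config: SimConfig


_MU_CACHE: dict[tuple[float, float], float] = {}


def _calibrated_mu(target_mean: float, sigma: float,
                   ceiling: float = 100.0) -> float:
    """Underlying normal location whose ceiling-censored mean equals the
    configured mean.

    Identities cannot exceed 100 %, so draws are censored at the ceiling;
    the published means were measured on such ceiling-limited values, and
    naively drawing N(mean, sigma) and clipping would bias the realized
    mean low by E[(X - 100)+].
    """
    key = (target_mean, sigma)
    if key not in _MU_CACHE:
        from scipy.optimize import brentq
        from scipy.stats import norm

        def censored_mean(mu: float) -> float:
            a = (ceiling - mu) / sigma
            excess = sigma * norm.pdf(a) + (mu - ceiling) * norm.sf(a)
            return mu - excess

        if censored_mean(target_mean) >= target_mean - 1e-9:
            _MU_CACHE[key] = target_mean
        else:
            _MU_CACHE[key] = float(brentq(
                lambda m: censored_mean(m) - target_mean,
                target_mean, target_mean + 6 * sigma))
    return _MU_CACHE[key]


def _trunc_normal(rng: np.random.Generator, mu: float, sigma: float,
                  lo: float = 50.0, hi: float = 100.0) -> float:
    x = rng.normal(_calibrated_mu(mu, sigma, hi), sigma)
    return float(min(hi, max(lo + 1e-4, x)))


def simulate_genome_pair(config: SimConfig | None = None) -> GenomePair:
    """Generate (genes A, genes B, hit table, truth) under ``config``."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.genes_per_chromosome
    margin = 25
    min_sep = 12

    # per-chromosome gene scaffolding --------------------------------------
    chrom_a = [f"A{c + 1:02d}" for c in range(cfg.n_chromosomes)]
    chrom_b = [f"B{c + 1:02d}" for c in range(cfg.n_chromosomes)]
    a_ids = [[f"A{c + 1:02d}G{i:04d}" for i in range(n)]
             for c in range(cfg.n_chromosomes)]
    b_of = {a_ids[c][i]: f"B{c + 1:02d}G{i:04d}"
            for c in range(cfg.n_chromosomes) for i in range(n)}
    confidence = {g: ("LC" if rng.random() < cfg.fraction_lc else "HC")
                  for c in range(cfg.n_chromosomes) for g in a_ids[c]}

    def _frac(g: str, hc: float, lc: float) -> float:
        return hc if confidence[g] == "HC" else lc

    fate: dict[str, str] = {}
    for c in range(cfg.n_chromosomes):
        for g in a_ids[c]:
            u = rng.random()
            undet = _frac(g, cfg.undetected_hc, cfg.undetected_lc)
            para = _frac(g, cfg.paralog_fraction_hc, cfg.paralog_fraction_lc)
            if u < undet:
                fate[g] = "undetected"
            elif u < undet + para:
                fate[g] = "scattered"
            else:
                fate[g] = "collinear"

    # event-site selection -------------------------------------------------
    event_list: list[tuple[str, str, int]] = []
    event_list += [("real_inversion", "", s) for s in cfg.real_inversion_sizes]
    event_list += [("error_inversion", "", s) for s in cfg.error_inversion_sizes]
    event_list += [("real_translocation", "intra", s)
                   for s in cfg.segdup_intra_sizes]
    event_list += [("real_translocation", "inter", s)
                   for s in cfg.segdup_inter_sizes]
    event_list += [("error_relocation", "intra", s)
                   for s in cfg.error_reloc_intra_sizes]
    event_list += [("error_relocation", "inter", s)
                   for s in cfg.error_reloc_inter_sizes]

    used: dict[int, list[tuple[int, int]]] = {c: [] for c in range(cfg.n_chromosomes)}

    def _clear(c: int, lo: int, hi: int, sep: int) -> bool:
        return (lo >= margin and hi < n - margin
                and all(lo - sep > b or hi + sep < a for a, b in used[c]))

    def _pick_window(c: int, size: int) -> tuple[int, int] | None:
        coll = [i for i, g in enumerate(a_ids[c]) if fate[g] == "collinear"]
        for _ in range(300):
            k = int(rng.integers(0, max(1, len(coll) - size)))
            members = coll[k:k + size]
            if len(members) < size:
                continue
            lo, hi = members[0], members[-1]
            if hi - lo + 1 > 3 * size:
                continue
            if _clear(c, lo, hi, min_sep):
                used[c].append((lo, hi))
                return lo, hi
        return None

    placed: list[tuple[str, str, int, int, int, int]] = []  # kind, scope, chrom, lo, hi, size
    c_cycle = 0
    for kind, scope, size in event_list:
        if size >= n - 2 * margin:
            raise ValidationError(
                f"event of size {size} exceeds usable chromosome size")
        window = None
        for attempt in range(cfg.n_chromosomes):
            c = (c_cycle + attempt) % cfg.n_chromosomes
            window = _pick_window(c, size)
            if window:
                placed.append((kind, scope, c, window[0], window[1], size))
                break
        if window is None:
            raise ValidationError(
                f"could not place event {kind}/{size}: genome too small "
                f"for the configured events")
        c_cycle += 1

    def _pick_single(c: int) -> int | None:
        coll = [i for i, g in enumerate(a_ids[c]) if fate[g] == "collinear"]
        for _ in range(300):
            i = coll[int(rng.integers(0, len(coll)))]
            if _clear(c, i, i, 6):
                used[c].append((i, i))
                return i
        return None

    singles: list[tuple[str, int, int]] = []  # kind, chrom, index
    for kind, count in (("transposition", cfg.n_transpositions),
                        ("duplication", cfg.n_tandem_dup_loss)):
        for k in range(count):
            c = c_cycle % cfg.n_chromosomes
            i = _pick_single(c)
            if i is None:
                raise ValidationError(f"could not place {kind} event")
            singles.append((kind, c, i))
            c_cycle += 1

    shared_pairs: list[tuple[int, int, bool]] = []  # chrom, index, decidable
    for k in range(cfg.n_shared_target_dups):
        c = c_cycle % cfg.n_chromosomes
        placed_at = None
        coll = [i for i, g in enumerate(a_ids[c]) if fate[g] == "collinear"]
        for _ in range(300):
            i = coll[int(rng.integers(0, len(coll) - 1))]
            if (fate[a_ids[c][i + 1]] == "collinear"
                    and _clear(c, i, i + 1, 6)):
                used[c].append((i, i + 1))
                placed_at = i
                break
        if placed_at is None:
            raise ValidationError("could not place shared-target duplication")
        shared_pairs.append((c, placed_at, k % 2 == 0))
        c_cycle += 1

    # apply events to the B gene order ------------------------------------
    b_order: list[list[str]] = [[b_of[g] for g in a_ids[c]]
                                for c in range(cfg.n_chromosomes)]
    window_ids = {(c, lo, hi): [b_of[g] for g in a_ids[c][lo:hi + 1]]
                  for _, _, c, lo, hi, _ in placed}

    for kind, scope, c, lo, hi, size in placed:
        ids = window_ids[(c, lo, hi)]
        order = b_order[c]
        start = order.index(ids[0])
        if kind in ("real_inversion", "error_inversion"):
            order[start:start + len(ids)] = ids[::-1]
        else:
            del order[start:start + len(ids)]
            dest_c = c
            if scope == "inter":
                dest_c = (c + 1 + int(rng.integers(0, cfg.n_chromosomes - 1))) \
                    % cfg.n_chromosomes
            dest = b_order[dest_c]
            for _ in range(300):
                j = int(rng.integers(margin, len(dest) - margin))
                if scope == "inter" or abs(j - start) >= 15:
                    if all(not (a - min_sep <= j <= b + min_sep)
                           for a, b in used[dest_c]) or scope == "inter":
                        break
            dest[j:j] = ids

    for kind, c, i in singles:
        if kind == "transposition":
            bid = b_of[a_ids[c][i]]
            order = b_order[c]
            pos = order.index(bid)
            order.remove(bid)
            for _ in range(300):
                j = int(rng.integers(margin, len(order) - margin))
                if abs(j - pos) >= 20:
                    break
            order.insert(j, bid)

    shared_target_losers: dict[str, tuple[str, bool]] = {}
    for c, i, decidable in shared_pairs:
        keeper, loser = a_ids[c][i], a_ids[c][i + 1]
        b_order[c].remove(b_of[loser])  # reciprocal loss of the B copy
        shared_target_losers[loser] = (b_of[keeper], decidable)

    # materialize gene records ---------------------------------------------
    genes_a: list[Gene] = []
    for c in range(cfg.n_chromosomes):
        for i, g in enumerate(a_ids[c]):
            start = 1 + i * 2000
            genes_a.append(Gene(id=g, chromosome=chrom_a[c], start=start,
                                end=start + 999, strand="+",
                                confidence=confidence[g]))
    genes_b: list[Gene] = []
    b_gene: dict[str, Gene] = {}
    for c in range(cfg.n_chromosomes):
        for i, bid in enumerate(b_order[c]):
            start = 1 + i * 2000
            gb = Gene(id=bid, chromosome=chrom_b[c], start=start,
                      end=start + 999, strand="+", confidence="HC")
            genes_b.append(gb)
            b_gene[bid] = gb

    # identities ------------------------------------------------------------
    in_window: dict[str, tuple[str, str]] = {}
    for kind, scope, c, lo, hi, size in placed:
        for g in a_ids[c][lo:hi + 1]:
            if fate[g] == "collinear":
                in_window[g] = (kind, scope)
    tandem_genes = {a_ids[c][i] for kind, c, i in singles
                    if kind == "duplication"}

    def _paralog_draw(g: str) -> float:
        mu, sd = (cfg.paralog_hc if confidence[g] == "HC" else cfg.paralog_lc)
        return _trunc_normal(rng, mu, sd)

    raw_hits: list[HitRecord] = []
    all_b_ids = [bid for c in range(cfg.n_chromosomes) for bid in b_order[c]]
    b_rank: dict[str, tuple[int, int]] = {
        bid: (c, i) for c in range(cfg.n_chromosomes)
        for i, bid in enumerate(b_order[c])}
    truth_class: dict[str, str] = {}

    # scattered paralogue targets must be non-collinear, as their truth
    # label asserts: redraw any target that would sit in the gene's own
    # collinear slot or continue a monotone run with a nearby scattered
    # assignment (such a draw would be a putative orthologue by the CGN
    # definition, not a paralogue)
    recent_scatter: dict[int, list[tuple[int, int, int]]] = {
        c: [] for c in range(cfg.n_chromosomes)}

    def _scatter_target(g: str, c: int, i: int) -> str:
        partner_loc = b_rank.get(b_of.get(g, ""), None)
        for _ in range(100):
            tid = all_b_ids[int(rng.integers(0, len(all_b_ids)))]
            tc_, tr_ = b_rank[tid]
            if tid == b_of.get(g):
                continue
            if (partner_loc is not None and tc_ == partner_loc[0]
                    and abs(tr_ - partner_loc[1]) <= 8):
                continue
            if any(abs(i - j) <= 5 and tc_ == jc and 0 < abs(tr_ - jt) <= 6
                   for j, jc, jt in recent_scatter[c]):
                continue
            recent_scatter[c].append((i, tc_, tr_))
            if len(recent_scatter[c]) > 8:
                recent_scatter[c].pop(0)
            return tid
        return all_b_ids[int(rng.integers(0, len(all_b_ids)))]

    def _emit(qid: str, tid: str, pident: float,
              below_bitscore: float | None = None) -> None:
        alen = int(rng.integers(300, 3000))
        bs = round(alen * pident / 50.0, 1)
        if below_bitscore is not None:
            # decoy: strictly below the true partner's bitscore
            bs = round(below_bitscore * (0.3 + 0.4 * rng.random())
                       - float(rng.integers(1, 20)), 1)
            if bs <= 0:
                bs = 1.0
        raw_hits.append(HitRecord(
            query_id=qid, target_id=tid, pident=round(pident, 2),
            align_len=alen,
            mismatches=int(alen * (100.0 - pident) / 100.0),
            gapopens=int(rng.integers(0, 4)), qstart=1, qend=alen,
            tstart=1, tend=alen,
            evalue=float(10.0 ** -float(rng.integers(30, 180))), bitscore=bs))

    for c in range(cfg.n_chromosomes):
        for gi, g in enumerate(a_ids[c]):
            if g in shared_target_losers:
                target, decidable = shared_target_losers[g]
                if decidable:
                    pident = min(96.9, _paralog_draw(g))
                    truth_class[g] = "paralogous"
                else:
                    pident = _trunc_normal(rng, 98.5, 0.5)
                    truth_class[g] = "paralogous"
                _emit(g, target, pident)
                continue
            if fate[g] == "undetected":
                truth_class[g] = "undetected"
                continue
            if fate[g] == "scattered":
                truth_class[g] = "paralogous"
                target = _scatter_target(g, c, gi)
                pident = _paralog_draw(g)
                _emit(g, target, pident)
            else:
                kind, _scope = in_window.get(g, ("", ""))
                if kind == "real_inversion":
                    pident = _trunc_normal(rng, cfg.inversion_mu,
                                           cfg.inversion_sigma)
                elif kind == "real_translocation" or g in tandem_genes:
                    pident = _paralog_draw(g)
                else:
                    pident = _trunc_normal(rng, cfg.ortho_mu, cfg.ortho_sigma)
                is_transposed = any(k == "transposition" and a_ids[cc][i] == g
                                    for k, cc, i in singles)
                truth_class[g] = ("paralogous" if is_transposed
                                  else "orthologous")
                _emit(g, b_of[g], pident)
            if rng.random() < cfg.decoy_rate:
                rank1_pident = raw_hits[-1].pident
                rank1_bs = raw_hits[-1].bitscore
                for _ in range(int(rng.integers(1, 3))):
                    decoy = all_b_ids[int(rng.integers(0, len(all_b_ids)))]
                    dp = min(_paralog_draw(g) - 4.0, rank1_pident - 0.5)
                    dp = max(50.01, dp)
                    _emit(g, decoy, dp, below_bitscore=rank1_bs)

    a_of = {b: a for a, b in b_of.items()}
    for bid in b_gene:
        # mirror the partner's putative class onto the B copy
        truth_class[bid] = truth_class.get(a_of.get(bid, ""), "undetected")

    # truth events ----------------------------------------------------------
    events: list[TruthEvent] = []
    verdict_of = {"real_inversion": "real", "error_inversion": "assembly_error",
                  "real_translocation": "real",
                  "error_relocation": "assembly_error"}
    for idx, (kind, scope, c, lo, hi, size) in enumerate(placed):
        members = tuple(g for g in a_ids[c][lo:hi + 1]
                        if fate[g] == "collinear")
        events.append(TruthEvent(
            event_id=f"E{idx:03d}", kind=kind, scope=scope,
            query_chrom=chrom_a[c], member_query_ids=members,
            size=len(members), expected_verdict=verdict_of[kind]))
    for k, (kind, c, i) in enumerate(singles):
        events.append(TruthEvent(
            event_id=f"S{k:03d}", kind=kind, scope="",
            query_chrom=chrom_a[c], member_query_ids=(a_ids[c][i],),
            size=1, expected_verdict=""))

    hits = assign_hit_ranks(raw_hits)
    return GenomePair(genes_a=genes_a, genes_b=genes_b, hits=hits,
                      truth=Truth(gene_class=truth_class, events=events),
                      config=cfg)


# ---------------------------------------------------------------------------
# scaffold-set simulator

@dataclass(frozen=True)
class ScaffoldSimConfig:
    """Fixture parameters for the anchoring/pseudomolecule test genome."""

    n_chromosomes: int = 2
    scaffolds_per_chromosome: int = 25
    scaffold_length_range: tuple[int, int] = (4000, 12000)
    markers_per_scaffold: int = 10
    motifs_per_scaffold: int = 5
    known_gap_range: tuple[int, int] = (23, 5000)
    unknown_gap_fraction: float = 0.25
    reverse_fraction: float = 0.4
    cm_per_mb: float = 20.0
    motif: str = "CTTAAG"
    seed: int = 1


@dataclass
class ScaffoldSim:
    scaffolds: dict[str, str]
    marker_map: pd.DataFrame
    placements: list
    truth_agp: pd.DataFrame
    truth_pseudomolecules: dict[str, str]
    junction_gaps: dict[tuple[str, str], int | None]
    planted_motifs: dict[str, int]  # scaffold id -> planted site count


def _random_sequence(rng: np.random.Generator, length: int,
                     forbidden: str) -> str:
    bases = np.array(list("ACGT"))
    seq = list(bases[rng.integers(0, 4, size=length)])
    text = "".join(seq)
    guard = 0
    while forbidden in text and guard < 200:
        i = text.index(forbidden)
        mid = i + len(forbidden) // 2
        old = text[mid]
        new = "ACGT"[(("ACGT".index(old)) + 1 + int(rng.integers(0, 3))) % 4]
        text = text[:mid] + new + text[mid + 1:]
        guard += 1
    return text


def _plant_motifs(rng: np.random.Generator, seq: str, motif: str,
                  count: int) -> tuple[str, int]:
    """Write ``count`` motif copies at spaced positions; returns the sequence
    and the exact number of occurrences after planting."""
    m = len(motif)
    if len(seq) < count * (m + 10) + 20:
        raise ValidationError("scaffold too short for requested motif count")
    positions: list[int] = []
    guard = 0
    while len(positions) < count and guard < 1000:
        guard += 1
        p = int(rng.integers(5, len(seq) - m - 5))
        if all(abs(p - q) >= m + 4 for q in positions):
            positions.append(p)
    for p in positions:
        seq = seq[:p] + motif + seq[p + m:]
    # scrub accidental occurrences created across plant boundaries
    planted = set(positions)
    for _ in range(100):
        found = [i for i in range(len(seq) - m + 1)
                 if seq[i:i + m] == motif and i not in planted]
        if not found:
            break
        i = found[0]
        for j in range(i, i + m):
            if all(not (p <= j < p + m) for p in planted):
                old = seq[j]
                new = "ACGT"[("ACGT".index(old) + 1) % 4]
                seq = seq[:j] + new + seq[j + 1:]
                break
    n_sites = sum(1 for i in range(len(seq) - m + 1) if seq[i:i + m] == motif)
    return seq, n_sites


def simulate_scaffold_set(config: ScaffoldSimConfig | None = None) -> ScaffoldSim:
    """Generate a scaffold FASTA, marker map, placements, and truth AGP.

    Chromosome sequences carry planted labeling-motif sites and are split
    into scaffolds separated by known- or unknown-length gaps; scaffolds
    are stored reverse-complemented with configured probability, and
    markers (with map cM positions linear in chromosome bp) are reported
    in scaffold-local coordinates, so anchoring must recover both order
    and orientation.
    """
    from Bio.Seq import Seq
    from .pseudomolecule import MarkerPlacement

    cfg = config or ScaffoldSimConfig()
    rng = np.random.default_rng(cfg.seed)
    scaffolds: dict[str, str] = {}
    markers = []
    placements = []
    agp_rows = []
    pseudos: dict[str, str] = {}
    gaps: dict[tuple[str, str], int | None] = {}
    planted: dict[str, int] = {}
    sid_pool = rng.permutation(
        cfg.n_chromosomes * cfg.scaffolds_per_chromosome * 7)

    k = 0
    marker_no = 0
    for c in range(cfg.n_chromosomes):
        chrom = f"P{c + 1:02d}"
        parts: list[str] = []
        pos = 0
        part_number = 0
        prev_sid = None
        for s in range(cfg.scaffolds_per_chromosome):
            sid = f"SC{int(sid_pool[k]):05d}"
            k += 1
            length = int(rng.integers(*cfg.scaffold_length_range))
            forward = _random_sequence(rng, length, cfg.motif)
            forward, n_sites = _plant_motifs(rng, forward, cfg.motif,
                                             cfg.motifs_per_scaffold)
            reverse = rng.random() < cfg.reverse_fraction
            stored = (str(Seq(forward).reverse_complement())
                      if reverse else forward)
            scaffolds[sid] = stored
            planted[sid] = n_sites
            if s > 0:
                unknown = rng.random() < cfg.unknown_gap_fraction
                gap = None if unknown else int(rng.integers(*cfg.known_gap_range))
                gaps[(prev_sid, sid)] = gap
                glen = gap if gap is not None else 100
                part_number += 1
                agp_rows.append({
                    "object": chrom, "object_beg": pos + 1,
                    "object_end": pos + glen, "part_number": part_number,
                    "component_type": "N" if gap is not None else "U",
                    "component_id": str(glen), "component_beg": "scaffold",
                    "component_end": "yes", "orientation": "map"})
                parts.append("N" * glen)
                pos += glen
            part_number += 1
            agp_rows.append({
                "object": chrom, "object_beg": pos + 1,
                "object_end": pos + length, "part_number": part_number,
                "component_type": "W", "component_id": sid,
                "component_beg": 1, "component_end": length,
                "orientation": "-" if reverse else "+"})
            offsets = sorted(int(x) for x in rng.choice(
                np.arange(10, length - 10), size=cfg.markers_per_scaffold,
                replace=False))
            for off in offsets:
                marker_no += 1
                mid = f"M{marker_no:05d}"
                forward_bp = pos + off + 1
                cm = round(forward_bp * cfg.cm_per_mb / 1e6, 6)
                local = (length - off) if reverse else (off + 1)
                markers.append({"marker": mid, "chromosome": chrom, "cM": cm})
                placements.append(MarkerPlacement(
                    marker_id=mid, map_chrom=chrom, cm=cm, scaffold_id=sid,
                    scaffold_pos=local,
                    pident=round(99.2 + 0.8 * float(rng.random()), 2),
                    evalue=1e-50))
            parts.append(forward)
            pos += length
            prev_sid = sid
        pseudos[chrom] = "".join(parts)
    from .pseudomolecule import AGP_COLUMNS
    return ScaffoldSim(
        scaffolds=scaffolds,
        marker_map=pd.DataFrame(markers),
        placements=placements,
        truth_agp=pd.DataFrame(agp_rows, columns=AGP_COLUMNS),
        truth_pseudomolecules=pseudos,
        junction_gaps=gaps,
        planted_motifs=planted)


# ---------------------------------------------------------------------------
# recovery evaluation

def evaluate_recovery(truth: Truth,
                      diffs: Sequence[StructuralDifference],
                      min_size: int = 4) -> pd.DataFrame:
    """Match injected events of >= ``min_size`` collinear pairs to detected
    differences (majority member overlap) and score kind + verdict."""
    kind_map = {("real_inversion", ""): "orientation",
                ("error_inversion", ""): "orientation",
                ("real_translocation", "intra"): "intra_location",
                ("real_translocation", "inter"): "inter_location",
                ("error_relocation", "intra"): "intra_location",
                ("error_relocation", "inter"): "inter_location"}
    rows = []
    for ev in truth.events:
        if ev.size < min_size or not ev.expected_verdict:
            continue
        members = set(ev.member_query_ids)
        want_kind = kind_map[(ev.kind, ev.scope)]
        # member-wise vote: an event split over several detected blocks is
        # still recovered if most members land in differences of the right
        # kind and verdict
        covered = kind_hits = verdict_hits = correct_hits = 0
        kinds_seen: dict[tuple[str, str], int] = {}
        for d in diffs:
            ov = members & set(d.member_ids)
            if not ov:
                continue
            covered += len(ov)
            kinds_seen[(d.kind, d.verdict)] = (
                kinds_seen.get((d.kind, d.verdict), 0) + len(ov))
            if d.kind == want_kind:
                kind_hits += len(ov)
            if d.verdict == ev.expected_verdict:
                verdict_hits += len(ov)
            if d.kind == want_kind and d.verdict == ev.expected_verdict:
                correct_hits += len(ov)
        need = (len(members) + 1) // 2
        top = max(kinds_seen, key=kinds_seen.get) if kinds_seen else ("", "")
        rows.append({"event_id": ev.event_id, "kind": ev.kind,
                     "scope": ev.scope, "size": ev.size,
                     "detected": covered >= need,
                     "kind_ok": kind_hits >= need,
                     "verdict_ok": verdict_hits >= need,
                     "correct": correct_hits >= need,
                     "detected_kind": top[0], "detected_verdict": top[1]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth table I/O

def write_truth(truth: Truth, class_path: str | Path,
                event_path: str | Path) -> None:
    pd.DataFrame(sorted(truth.gene_class.items()),
                 columns=["gene_id", "klass"]).to_csv(
        class_path, sep="\t", index=False)
    pd.DataFrame([{
        "event_id": e.event_id, "kind": e.kind, "scope": e.scope,
        "query_chrom": e.query_chrom, "size": e.size,
        "expected_verdict": e.expected_verdict,
        "member_query_ids": ",".join(e.member_query_ids),
    } for e in truth.events]).to_csv(event_path, sep="\t", index=False)


def read_truth(class_path: str | Path, event_path: str | Path) -> Truth:
    classes = pd.read_csv(class_path, sep="\t")
    events_df = pd.read_csv(event_path, sep="\t", keep_default_na=False)
    events = [TruthEvent(
        event_id=r.event_id, kind=r.kind, scope=r.scope,
        query_chrom=r.query_chrom,
        member_query_ids=tuple(r.member_query_ids.split(","))
        if r.member_query_ids else (),
        size=int(r.size), expected_verdict=r.expected_verdict)
        for r in events_df.itertuples(index=False)]
    return Truth(gene_class=dict(zip(classes.gene_id, classes.klass)),
                 events=events)
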