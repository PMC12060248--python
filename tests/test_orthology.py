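"""Collinearity chaining, shared-target adjudication, classification."""
import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from cgnkit.io import Gene, HitRecord, ValidationError, assign_hit_ranks
from cgnkit.orthology import (ThresholdSpec, chain_collinear_blocks,
                              classify_genes, derive_identity_threshold,
                              flag_spurious_duplicates, refine_blocks,
                              resolve_shared_targets)
from conftest import make_pairs
from _oracles import chain_cover_oracle


class TestThreshold:
    def test_zero_variance_returns_mu(self):
        assert derive_identity_threshold(
            ThresholdSpec(mu=100, sigma=0, alpha=0.01)) == 100

    def test_default_orthologue_model_quantile(self):
        t = derive_identity_threshold(ThresholdSpec())
        assert t == pytest.approx(95.56, abs=0.01)

    def test_median_quantile(self):
        assert derive_identity_threshold(
            ThresholdSpec(mu=50, sigma=10, alpha=0.5)) == pytest.approx(50)

    def test_alpha_bounds_enforced(self):
        with pytest.raises(ValidationError):
            ThresholdSpec(alpha=0.0)


class TestSharedTargets:
    def _pairs(self, pidents):
        return make_pairs([5] * len(pidents), pidents=pidents)

    def test_one_above_threshold_decides(self):
        verdicts = resolve_shared_targets(self._pairs([99.5, 93.0]))
        assert verdicts == {"q1": "candidate", "q2": "paralogous"}

    def test_both_above_threshold_is_uncertain(self):
        verdicts = resolve_shared_targets(self._pairs([99.5, 98.2]))
        assert set(verdicts.values()) == {"uncertain"}

    def test_both_below_threshold_is_uncertain(self):
        verdicts = resolve_shared_targets(self._pairs([95.0, 93.0]))
        assert set(verdicts.values()) == {"uncertain"}

    def test_distant_queries_are_not_adjudicated(self):
        pairs = make_pairs([5, 9, 9], pidents=[99.0, 99.5, 93.0])
        # q2 and q3 juxtaposed on t9; q1 hits t5 alone
        verdicts = resolve_shared_targets(pairs)
        assert "q1" not in verdicts
        assert verdicts["q2"] == "candidate"


class TestChaining:
    def test_worked_example_backbone_and_paralogue(self, worked_example_pairs):
        blocks, singles = chain_collinear_blocks(worked_example_pairs)
        assert len(blocks) == 1
        assert [p.query.id for p in blocks[0].members] == list("ABDEFG")
        assert blocks[0].direction == "ascending"
        assert [p.query.id for p in singles] == ["C"]

    def test_identity_permutation_is_one_block(self):
        blocks, singles = chain_collinear_blocks(make_pairs([1, 2, 3, 4, 5]))
        assert len(blocks) == 1 and blocks[0].size == 5 and not singles

    def test_empty_input(self):
        assert chain_collinear_blocks([]) == ([], [])

    def test_fully_descending_chromosome_is_one_descending_block(self):
        blocks, singles = chain_collinear_blocks(make_pairs([5, 4, 3, 2, 1]))
        assert len(blocks) == 1
        assert blocks[0].direction == "descending" and not singles

    @pytest.mark.parametrize("n", range(1, 7))
    def test_small_permutations_match_brute_force(self, n):
        for perm in itertools.permutations(range(1, n + 1)):
            blocks, _ = chain_collinear_blocks(make_pairs(perm))
            covered = sum(b.size for b in blocks)
            assert covered == chain_cover_oracle(perm), perm

    def test_random_n12_permutations_match_brute_force(self):
        rng = random.Random(0)
        for _ in range(25):
            perm = list(range(1, 13))
            rng.shuffle(perm)
            blocks, _ = chain_collinear_blocks(make_pairs(perm))
            assert sum(b.size for b in blocks) == chain_cover_oracle(perm), perm

    def test_non_dominant_chromosome_block_is_flagged(self):
        pairs = make_pairs([1, 2, 3, 4, 5, 6],
                           target_chroms=["d1"] * 4 + ["d2"] * 2)
        # last two hit another chromosome at consecutive ranks
        pairs[4:] = make_pairs([1, 2], target_chroms=["d2", "d2"])
        for i, p in enumerate(pairs[4:]):
            object.__setattr__(p.query, "rank", 5 + i)
        blocks, _ = chain_collinear_blocks(pairs)
        off = [b for b in blocks if b.target_chrom == "d2"]
        assert len(off) == 1 and not off[0].on_homologue
        assert off[0].placement == "displaced"


class TestRefinement:
    def test_two_gene_flip_recovered_as_descending_pair(self):
        # ranks ...4,5 swapped to 5,4 inside an ascending run
        targets = [1, 2, 3, 5, 4, 6, 7, 8]
        blocks, singles = chain_collinear_blocks(make_pairs(targets))
        blocks, singles = refine_blocks(blocks, singles)
        desc = [b for b in blocks if b.direction == "descending"]
        assert len(desc) == 1 and desc[0].size == 2
        assert [p.target_rank for p in desc[0].members] == [5, 4]
        assert not singles

    def test_inverted_segment_edges_reclaimed(self):
        # 5-gene in-place inversion in a 15-gene chromosome
        targets = list(range(1, 16))
        targets[5:10] = targets[5:10][::-1]
        blocks, singles = chain_collinear_blocks(make_pairs(targets))
        blocks, singles = refine_blocks(blocks, singles)
        desc = [b for b in blocks if b.direction == "descending"]
        assert len(desc) == 1
        assert desc[0].size == 5 and desc[0].placement == "in_place"
        assert not singles

    def test_worked_example_paralogue_is_not_rescued(self, worked_example_pairs):
        blocks, singles = chain_collinear_blocks(worked_example_pairs)
        blocks, singles = refine_blocks(blocks, singles)
        assert [p.query.id for p in singles] == ["C"]
        assert sum(b.size for b in blocks) == 6


def _genes_and_hits(targets, qchrom="c1", tchrom="d1"):
    genes_a = [Gene(id=f"q{i + 1}", chromosome=qchrom, start=(i + 1) * 1000,
                    end=(i + 1) * 1000 + 500) for i in range(len(targets))]
    genes_b = [Gene(id=f"t{i + 1}", chromosome=tchrom, start=(i + 1) * 1000,
                    end=(i + 1) * 1000 + 500) for i in range(len(targets))]
    hits = [HitRecord(query_id=f"q{i + 1}", target_id=f"t{t}", pident=99.0,
                      align_len=500, mismatches=5, gapopens=0, qstart=1,
                      qend=500, tstart=1, tend=500, evalue=1e-80,
                      bitscore=900.0) for i, t in enumerate(targets)]
    return genes_a, genes_b, assign_hit_ranks(hits)


class TestClassification:
    def test_worked_example_classes(self):
        genes_a, genes_b, hits = _genes_and_hits([1, 2, 6, 3, 4, 5, 7])
        records, blocks = classify_genes(genes_a, genes_b, hits)
        classes = {r.query_id: r.klass for r in records}
        assert classes["q3"] == "paralogous"
        assert sum(1 for k in classes.values() if k == "orthologous") == 6
        assert sum(1 for k in classes.values() if k == "paralogous") == 1

    def test_gene_without_hits_is_undetected(self):
        genes_a, genes_b, hits = _genes_and_hits([1, 2, 3])
        genes_a.append(Gene(id="q9", chromosome="c1", start=9000, end=9500))
        records, _ = classify_genes(genes_a, genes_b, hits)
        assert {r.klass for r in records if r.query_id == "q9"} == {"undetected"}

    def test_hit_to_unknown_gene_rejected(self):
        genes_a, genes_b, hits = _genes_and_hits([1, 2, 3])
        orphan = HitRecord(query_id="ghost", target_id="t1", pident=99.0,
                           align_len=10, mismatches=0, gapopens=0, qstart=1,
                           qend=10, tstart=1, tend=10, evalue=0.0,
                           bitscore=20.0)
        with pytest.raises(ValidationError, match="ghost"):
            classify_genes(genes_a, genes_b, hits + [orphan])

    def test_classification_partitions_all_queries(self, default_genome_pair,
                                                   classified_default_pair):
        records, _ = classified_default_pair
        assert len(records) == len(default_genome_pair.genes_a)
        assert all(r.klass in ("orthologous", "paralogous", "uncertain",
                               "undetected") for r in records)

    def test_row_order_invariance(self):
        targets = [3, 1, 4, 2, 6, 5, 7, 9, 8, 10]
        genes_a, genes_b, hits = _genes_and_hits(targets)
        base, _ = classify_genes(genes_a, genes_b, hits)
        rng = random.Random(2)
        shuffled_hits = list(hits)
        rng.shuffle(shuffled_hits)
        shuffled_a = list(genes_a)
        rng.shuffle(shuffled_a)
        again, _ = classify_genes(shuffled_a, genes_b, shuffled_hits)
        assert ({r.query_id: r.klass for r in base}
                == {r.query_id: r.klass for r in again})

    def test_clean_simulation_is_fully_orthologous(self):
        from cgnkit.simulate import SimConfig, simulate_genome_pair
        cfg = SimConfig(seed=1, genes_per_chromosome=120, n_chromosomes=2,
                        undetected_hc=0.0, undetected_lc=0.0,
                        paralog_fraction_hc=0.0, paralog_fraction_lc=0.0,
                        n_transpositions=0, n_tandem_dup_loss=0,
                        n_shared_target_dups=0, segdup_intra_sizes=(),
                        segdup_inter_sizes=(), real_inversion_sizes=(),
                        error_inversion_sizes=(), error_reloc_intra_sizes=(),
                        error_reloc_inter_sizes=(), decoy_rate=0.0)
        pair = simulate_genome_pair(cfg)
        records, blocks = classify_genes(pair.genes_a, pair.genes_b, pair.hits)
        assert all(r.klass == "orthologous" for r in records)
        per_chrom = {}
        for b in blocks:
            per_chrom.setdefault(b.query_chrom, []).append(b)
        for chrom_blocks in per_chrom.values():
            assert len(chrom_blocks) == 1
            assert chrom_blocks[0].direction == "ascending"

    def test_spurious_duplicates_flagged(self):
        genes = [Gene(id="a", chromosome="c", start=100, end=500),
                 Gene(id="b", chromosome="c", start=100, end=450),
                 Gene(id="d", chromosome="c", start=900, end=999)]
        assert flag_spurious_duplicates(genes) == {"a", "b"}

    @given(st.lists(st.integers(1, 30), min_size=1, max_size=30, unique=True))
    @settings(max_examples=60, deadline=None)
    def test_partition_property_over_random_orders(self, targets):
        genes_a, genes_b, hits = _genes_and_hits(
            targets + list(set(range(1, max(targets) + 1)) - set(targets)))
        genes_a = genes_a[:len(targets)]
        hits = [h for h in hits if h.query_id in {g.id for g in genes_a}]
        records, _ = classify_genes(genes_a, genes_b, hits)
        assert len(records) == len(genes_a)
        counts = {}
        for r in records:
            counts[r.klass] = counts.get(r.klass, 0) + 1
        assert sum(counts.values()) == len(genes_a)
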