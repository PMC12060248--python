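"""Anchoring, AGP/FASTA construction, in-silico digestion, CMAP comparison."""
import random

import pytest
from hypothesis import given, settings, strategies as st

from cgnkit.io import ValidationError
from cgnkit.pseudomolecule import (CmapLabelSet, MarkerPlacement,
                                   ScaffoldAssignment, align_cmaps,
                                   anchor_scaffolds, build_pseudomolecules,
                                   insilico_digest, read_agp, read_cmap,
                                   reconstruct_from_agp, write_agp,
                                   write_cmap)

REVCOMP = str.maketrans("ACGT", "TGCA")


def _placements(sid, marker_data, chrom="P01"):
    return [MarkerPlacement(marker_id=f"m{i}", map_chrom=chrom, cm=cm,
                            scaffold_id=sid, scaffold_pos=bp, pident=99.5,
                            evalue=1e-50)
            for i, (cm, bp) in enumerate(marker_data)]


class TestAnchoring:
    def test_concordant_markers_give_plus(self):
        (asg,) = anchor_scaffolds(_placements("s1", [(1, 100), (2, 500),
                                                     (3, 900)]))
        assert asg.orientation == "+" and asg.oriented

    def test_anticoncordant_markers_give_minus(self):
        (asg,) = anchor_scaffolds(_placements("s1", [(1, 900), (2, 500),
                                                     (3, 100)]))
        assert asg.orientation == "-" and asg.oriented

    def test_single_marker_is_unoriented_plus(self):
        (asg,) = anchor_scaffolds(_placements("s1", [(1, 100)]))
        assert asg.orientation == "+" and not asg.oriented

    def test_weak_placements_filtered(self):
        weak = [MarkerPlacement(marker_id="m", map_chrom="P01", cm=1.0,
                                scaffold_id="s1", scaffold_pos=10,
                                pident=95.0, evalue=1e-50)]
        assert anchor_scaffolds(weak) == []

    def test_order_follows_mean_cm(self):
        ps = (_placements("late", [(30, 10), (31, 500)])
              + _placements("early", [(1, 10), (2, 500)]))
        assignments = anchor_scaffolds(ps)
        order = {a.scaffold_id: a.order_index for a in assignments}
        assert order == {"early": 1, "late": 2}

    def test_conflicts_flagged(self):
        ps = (_placements("s1", [(1, 10), (2, 500)], chrom="P01")
              + _placements("s1", [(9, 700)], chrom="P02"))
        (asg,) = anchor_scaffolds(ps)
        assert "multi_chromosome" in asg.conflict_flags

    def test_scaffold_recovery_on_seeded_fixture(self, scaffold_sim):
        assignments = anchor_scaffolds(scaffold_sim.placements)
        truth_w = scaffold_sim.truth_agp[
            scaffold_sim.truth_agp.component_type == "W"]
        by_chrom_truth = {
            chrom: list(rows.component_id)
            for chrom, rows in truth_w.groupby("object")}
        by_chrom_got = {}
        orient_got = {}
        for a in sorted(assignments, key=lambda a: (a.chromosome,
                                                    a.order_index)):
            by_chrom_got.setdefault(a.chromosome, []).append(a.scaffold_id)
            orient_got[a.scaffold_id] = a.orientation
        assert by_chrom_got == by_chrom_truth
        for row in truth_w.itertuples(index=False):
            assert orient_got[row.component_id] == row.orientation


class TestBuild:
    def _assign(self, sids, chrom="P01"):
        return [ScaffoldAssignment(scaffold_id=s, chromosome=chrom,
                                   order_index=i + 1, orientation="+",
                                   oriented=True, n_markers=2, mean_cm=i)
                for i, s in enumerate(sids)]

    def test_unknown_gap_inserts_exactly_100_ns(self):
        seqs = {"a": "A" * 10_000, "b": "C" * 20_000}
        pseudos, agp, stats = build_pseudomolecules(self._assign(["a", "b"]),
                                                    seqs)
        assert len(pseudos["P01"]) == 30_100
        assert pseudos["P01"][10_000:10_100] == "N" * 100
        assert list(agp.component_type) == ["W", "U", "W"]
        u = agp[agp.component_type == "U"].iloc[0]
        assert (u.component_id, u.component_beg, u.component_end,
                u.orientation) == ("100", "scaffold", "yes", "map")

    def test_known_gap_length_is_respected(self):
        seqs = {"a": "A" * 100, "b": "C" * 200}
        pseudos, agp, _ = build_pseudomolecules(
            self._assign(["a", "b"]), seqs, {("a", "b"): 23})
        assert pseudos["P01"] == "A" * 100 + "N" * 23 + "C" * 200
        assert agp[agp.component_type == "N"].iloc[0].component_id == "23"

    def test_minus_scaffold_is_reverse_complemented(self):
        asg = self._assign(["a"])
        asg[0].orientation = "-"
        pseudos, _, _ = build_pseudomolecules(asg, {"a": "AACG"})
        assert pseudos["P01"] == "CGTT"

    def test_length_conservation_on_random_chromosome(self):
        rng = random.Random(4)
        sids = [f"s{i}" for i in range(10)]
        seqs = {s: "".join(rng.choice("ACGT")
                           for _ in range(rng.randint(500, 3000)))
                for s in sids}
        gaps = {}
        for left, right in zip(sids, sids[1:]):
            gaps[(left, right)] = (None if rng.random() < 0.3
                                   else rng.randint(23, 800))
        pseudos, agp, stats = build_pseudomolecules(self._assign(sids),
                                                    seqs, gaps)
        expect_gap = sum(100 if g is None else g for g in gaps.values())
        total = stats[stats.chromosome == "Total"].iloc[0]
        assert total.total_length == sum(map(len, seqs.values())) + expect_gap
        assert total.n_count == expect_gap
        assert total.gap_count == 9
        assert (stats.effective_length
                == stats.total_length - stats.gap_length).all()

    def test_missing_sequence_rejected(self):
        with pytest.raises(ValidationError, match="no sequence"):
            build_pseudomolecules(self._assign(["ghost"]), {})

    def test_agp_fasta_round_trip(self, tmp_path, scaffold_sim):
        assignments = anchor_scaffolds(scaffold_sim.placements)
        pseudos, agp, _ = build_pseudomolecules(
            assignments, scaffold_sim.scaffolds, scaffold_sim.junction_gaps)
        path = tmp_path / "x.agp"
        write_agp(agp, path)
        again = read_agp(path)
        rebuilt = reconstruct_from_agp(again, scaffold_sim.scaffolds)
        assert rebuilt == pseudos

    def test_truth_agp_and_fasta_recovered_exactly(self, scaffold_sim):
        assignments = anchor_scaffolds(scaffold_sim.placements)
        pseudos, agp, _ = build_pseudomolecules(
            assignments, scaffold_sim.scaffolds, scaffold_sim.junction_gaps)
        assert agp.astype(str).equals(scaffold_sim.truth_agp.astype(str))
        assert pseudos == scaffold_sim.truth_pseudomolecules


class TestDigest:
    def test_single_site(self):
        assert insilico_digest("ACTTAAGT").positions == (2,)

    def test_no_site(self):
        assert insilico_digest("ACGTACGT").positions == ()

    def test_case_insensitive(self):
        assert insilico_digest("acttaagt").positions == (2,)

    def test_n_in_window_never_matches(self):
        assert insilico_digest("ACTTANGT").positions == ()

    def test_empty_motif_rejected(self):
        with pytest.raises(ValidationError):
            insilico_digest("ACGT", motif="")

    @given(st.text(alphabet="ACGTN", min_size=6, max_size=300))
    @settings(max_examples=150, deadline=None)
    def test_reverse_complement_symmetry(self, seq):
        # CTTAAG is its own reverse complement: site count is conserved and
        # positions mirror as L - p - m + 2
        fwd = insilico_digest(seq)
        rc = seq.translate(REVCOMP)[::-1] if set(seq) <= set("ACGTN") else seq
        rev = insilico_digest(rc)
        L, m = len(seq), 6
        assert len(fwd.positions) == len(rev.positions)
        assert sorted(L - p - m + 2 for p in fwd.positions) \
            == sorted(rev.positions)

    def test_overlapping_sites_all_reported(self):
        # CTTAAG CTTAAG back to back plus an embedded overlap region
        seq = "CTTAAGCTTAAG"
        assert insilico_digest(seq).positions == (1, 7)

    def test_planted_site_count_matches_digest(self, scaffold_sim):
        for sid, seq in scaffold_sim.scaffolds.items():
            got = len(insilico_digest(seq).positions)
            assert got == scaffold_sim.planted_motifs[sid]

    def test_digest_lifts_through_pseudomolecule(self, scaffold_sim):
        assignments = anchor_scaffolds(scaffold_sim.placements)
        pseudos, agp, _ = build_pseudomolecules(
            assignments, scaffold_sim.scaffolds, scaffold_sim.junction_gaps)
        lifted = {}
        for row in agp.itertuples(index=False):
            if row.component_type != "W":
                continue
            seq = scaffold_sim.scaffolds[row.component_id]
            if row.orientation == "-":
                seq = seq.translate(REVCOMP)[::-1]
            for p in insilico_digest(seq).positions:
                lifted.setdefault(row.object, []).append(
                    int(row.object_beg) + p - 1)
        for chrom, pseudo in pseudos.items():
            assert tuple(sorted(lifted.get(chrom, []))) \
                == insilico_digest(pseudo).positions


class TestCmap:
    def test_write_read_round_trip(self, tmp_path):
        ls = CmapLabelSet(map_id="7", length=5000,
                          positions=(10, 600, 3200, 4999))
        path = tmp_path / "x.cmap"
        write_cmap([ls], path)
        (again,) = read_cmap(path)
        assert again.positions == ls.positions
        assert again.length == ls.length

    def test_positions_must_increase(self):
        with pytest.raises(ValidationError):
            CmapLabelSet(map_id="1", length=100, positions=(5, 5))

    def test_identical_maps_fully_match(self):
        ls = CmapLabelSet(map_id="1", length=10_000,
                          positions=tuple(range(100, 9000, 700)))
        aln = align_cmaps(ls, ls)
        assert aln.orientation == "+"
        assert len(aln.matched_pairs) == len(ls.positions)
        assert aln.unmatched_qry_runs == []

    def test_translation_invariance(self):
        ref = CmapLabelSet(map_id="1", length=10_000,
                           positions=tuple(range(100, 9000, 700)))
        qry = CmapLabelSet(map_id="1", length=10_500,
                           positions=tuple(p + 500
                                           for p in ref.positions))
        aln = align_cmaps(ref, qry)
        assert len(aln.matched_pairs) == len(ref.positions)

    def test_reversed_query_is_detected(self):
        rng = random.Random(8)
        intervals = [int(300 * 1.25 ** i) for i in range(12)]
        pos = [100]
        for iv in intervals:
            pos.append(pos[-1] + iv)
        ref = CmapLabelSet(map_id="1", length=pos[-1] + 100,
                           positions=tuple(pos))
        L = ref.length
        qry = CmapLabelSet(map_id="1", length=L,
                           positions=tuple(sorted(L - p + 1
                                                  for p in pos)))
        aln = align_cmaps(ref, qry)
        assert aln.orientation == "-"
        assert len(aln.matched_pairs) == len(pos)

    def test_internal_reversed_segment_reported_discordant(self):
        # strictly growing intervals so a reversed run cannot re-match
        intervals = [int(200 * 1.3 ** i) for i in range(20)]
        pos = [50]
        for iv in intervals:
            pos.append(pos[-1] + iv)
        ref_pos = list(pos)
        seg = slice(6, 16)  # 10 labels
        block = ref_pos[seg]
        lo, hi = block[0], block[-1]
        qry_pos = (ref_pos[:seg.start]
                   + sorted(lo + hi - p for p in block)
                   + ref_pos[seg.stop:])
        ref = CmapLabelSet(map_id="1", length=pos[-1] + 50,
                           positions=tuple(ref_pos))
        qry = CmapLabelSet(map_id="1", length=pos[-1] + 50,
                           positions=tuple(qry_pos))
        aln = align_cmaps(ref, qry)
        discordant = {i for a, b in aln.unmatched_qry_runs
                      for i in range(a, b + 1)}
        inner = set(range(seg.start + 1, seg.stop - 1))
        # one interval of the reversed run can still match in isolation,
        # so allow up to two adjacent inner labels to pair off
        assert len(inner - discordant) <= 2
        outer = set(range(0, seg.start - 1)) | \
            set(range(seg.stop + 1, len(qry_pos)))
        assert not (outer & discordant)

    def test_tiny_maps_are_undetermined(self):
        a = CmapLabelSet(map_id="1", length=100, positions=(10, 20))
        b = CmapLabelSet(map_id="1", length=100, positions=(10, 20))
        assert align_cmaps(a, b).undetermined
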