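"""Marker discovery across strains and synthetic strain generation."""

import numpy as np
import pytest

import mappability as mp
from mappability.markers import group_separation_report, marker_report
from mappability.oracle import brute_force_presence
from mappability.synthetic import generate_strains, recover_markers


def build(seqs, **kw):
    col = mp.collection_from_strings(seqs, **kw)
    return col, mp.build_index(col)


class TestMarkerReport:
    def test_two_genome_example(self):
        col, idx = build(["ACGTACGT", "ACGTTTTT"])
        reps = marker_report(idx, col, 4, 0)
        # genome0: CGTA, GTAC, TACG unique; ACGT shared (positions 0 and 4)
        assert reps[0].n_unique == 3
        assert reps[0].n_pseudo == 0
        assert reps[0].n_shared == 2
        # genome1: CGTT, GTTT unique; TTTT occurs twice -> pseudo at both
        assert reps[1].n_unique == 2
        assert reps[1].n_pseudo == 2
        assert reps[1].n_shared == 1

    def test_duplicated_genome_has_no_unique_markers(self):
        col, idx = build(["ACGTACGTAC", "ACGTACGTAC"])
        reps = marker_report(idx, col, 4, 0)
        assert all(r.n_unique == 0 for r in reps)
        assert all(r.n_pseudo == 0 for r in reps)

    def test_private_insert_yields_markers_only_near_insert(self):
        backbone = "ACGTTGCAACGGATCGATTACCGGTAGGCATCGAAC"
        insert = "TTTTCCCCTTTTCCCC"
        at = 18
        strains = [backbone[:at] + insert + backbone[at:], backbone, backbone]
        col, idx = build(strains)
        k = 6
        reps = marker_report(idx, col, k, 0)
        assert reps[1].n_unique == 0 and reps[2].n_unique == 0
        assert reps[0].n_unique > 0
        lo, hi = at - (k - 1), at + len(insert) + (k - 1)
        for pos in reps[0].unique_positions:
            assert lo <= pos < hi  # only inside the insert +- k-1 flanks

    def test_nonadjacent_markers_collapse_runs(self):
        backbone = "ACGTTGCAACGGATCGATTACCGGTAGGCATCGAAC"
        insert = "TTTTCCCCTTTTCCCC"
        strains = [backbone[:18] + insert + backbone[18:], backbone, backbone]
        col, idx = build(strains)
        reps = marker_report(idx, col, 6, 0)
        # one contiguous run of unique markers -> at most one non-adjacent
        assert reps[0].n_unique_nonadjacent <= 1
        assert reps[0].n_unique_nonadjacent < reps[0].n_unique

    def test_fewer_than_two_genomes_rejected(self):
        col, idx = build(["ACGTACGT"])
        with pytest.raises(ValueError):
            marker_report(idx, col, 4, 0)

    def test_distance_statistics(self):
        col, idx = build(["ACGTTGCAGGATC", "TTTTTTTTTTTTT"])
        reps = marker_report(idx, col, 4, 0)
        rep = reps[0]
        pos = np.sort(rep.unique_positions)
        if len(pos) > 1:
            gaps = np.diff(pos)
            assert rep.dist_mean == pytest.approx(gaps.mean())
            assert rep.dist_sd == pytest.approx(gaps.std())


class TestGroupSeparation:
    def test_same_genome_in_both_groups_rejected(self):
        col, idx = build(["ACGTACGT", "ACGTACGT"])
        with pytest.raises(ValueError):
            group_separation_report(idx, col, [0], [0], 4, 0)

    def test_identical_content_groups_never_separate(self):
        col, idx = build(["ACGTACGTAC", "ACGTACGTAC"])
        reps = group_separation_report(idx, col, [0], [1], 4, 0)
        assert all(r.n_separating == 0 for r in reps)

    def test_disjoint_alphabet_groups_fully_separate(self):
        col, idx = build(["AAAAAAAA", "CCCCCCCC"])
        reps = group_separation_report(idx, col, [0], [1], 4, 0)
        assert [r.n_separating for r in reps] == [5, 5]

    def test_large_error_budget_matches_everything(self):
        col, idx = build(["AAAA", "CCCC"])
        reps = group_separation_report(idx, col, [0], [1], 2, 2)
        assert all(r.n_separating == 0 for r in reps)

    def test_group_shared_segment_separates(self):
        shared_a = "TTTTTCCCCCTTTTT"
        base = ["ACGTTGCAACGGATCGATTACC", "GGTAGGCATCGAACACGTTGCA"]
        strains = [base[0] + shared_a, base[1] + shared_a,
                   "CAGGATCCGTAACGTAGGCCAT"]
        col, idx = build(strains)
        reps = group_separation_report(idx, col, [0, 1], [2], 6, 0)
        by_genome = {r.genome: r for r in reps}
        assert by_genome[0].n_separating > 0
        assert by_genome[1].n_separating > 0

    def test_matches_presence_oracle(self, rng):
        for _ in range(5):
            strains = generate_strains(
                length=150, n_strains=4, sub_rate=0.05,
                seed=int(rng.integers(0, 2**31)),
            )
            col = strains.to_collection()
            idx = mp.build_index(col)
            k, e = 8, 1
            reps = group_separation_report(idx, col, [0, 1], [2, 3], k, e)
            presence = brute_force_presence(col, k, e)
            positions = mp.valid_kmer_positions(col, k)
            expected = {g: 0 for g in range(4)}
            for pres, p in zip(presence, positions.tolist()):
                g = col.genome_of_position(int(p))
                own = {0, 1} if g in (0, 1) else {2, 3}
                other = {2, 3} if g in (0, 1) else {0, 1}
                if own <= pres and not (pres & other):
                    expected[g] += 1
            for r in reps:
                assert r.n_separating == expected[r.genome]


class TestGenerateStrains:
    def test_reproducible(self):
        a = generate_strains(200, 3, 0.02, 1, 30, seed=5)
        b = generate_strains(200, 3, 0.02, 1, 30, seed=5)
        assert a.strains == b.strains
        assert a.truth == b.truth

    def test_no_mutation_no_insert_gives_identical_strains(self):
        ss = generate_strains(300, 4, 0.0, seed=1)
        assert len(set(ss.strains)) == 1
        col = ss.to_collection()
        idx = mp.build_index(col)
        assert all(r.n_unique == 0 for r in marker_report(idx, col, 12, 0))

    def test_truth_records_point_at_inserted_segments(self):
        ss = generate_strains(400, 3, 0.0, n_private_segments=2,
                              segment_length=40, seed=9)
        assert len(ss.truth) == 6
        for seg in ss.truth:
            assert len(ss.strains[seg.strain]) == 400 + 2 * 40
            assert 0 <= seg.position <= len(ss.strains[seg.strain]) - seg.length

    def test_segment_longer_than_genome_rejected(self):
        with pytest.raises(ValueError):
            generate_strains(50, 2, 0.0, n_private_segments=1,
                             segment_length=60, seed=0)

    def test_fasta_emission(self, tmp_path):
        ss = generate_strains(120, 2, 0.01, seed=3)
        paths = ss.write_fasta(tmp_path)
        col = mp.read_fasta(paths)
        assert col.n_genomes == 2
        assert col.genomes[0].decode() == ss.strains[0]


class TestRecoverMarkers:
    def test_perfect_recall_with_clean_inserts(self):
        ss = generate_strains(1500, 3, 0.0, n_private_segments=1,
                              segment_length=100, seed=17)
        score = recover_markers(ss, 20, 0)
        assert score.recall == 1.0
        assert score.n_relevant == 3 * (100 - 20 + 1)

    def test_divergent_backbone_not_reported_with_large_e(self):
        # strains differ only by scattered SNPs; allowing e >= divergence
        # per k-mer suppresses backbone "unique" calls away from inserts
        ss = generate_strains(600, 2, 0.0, n_private_segments=1,
                              segment_length=80, seed=23)
        score_e0 = recover_markers(ss, 15, 0)
        score_e1 = recover_markers(ss, 15, 1)
        assert score_e1.precision >= score_e0.precision - 1e-9
        assert score_e1.recall <= 1.0

    def test_shuffled_truth_degrades_precision(self, rng):
        ss = generate_strains(1000, 2, 0.0, n_private_segments=1,
                              segment_length=80, seed=31)
        score = recover_markers(ss, 20, 0)
        # move the truth segments elsewhere: claimed markers no longer hit
        shifted = generate_strains(1000, 2, 0.0, n_private_segments=1,
                                   segment_length=80, seed=31)
        for seg in shifted.truth:
            seg.position = (seg.position + 400) % (1000 - 80)
        from mappability.synthetic import recover_markers as rm
        degraded = rm(shifted, 20, 0)
        assert degraded.precision < score.precision
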