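"""(k,e)-frequency engine: examples, oracle equivalence, ablations."""

import math

import numpy as np
import pytest

import mappability as mp
from mappability.core import clamp, compute_s
from mappability.oracle import brute_force_frequency, hash_frequency


class TestHammingDistance:
    def test_examples(self):
        assert mp.hamming_distance("ACGT", "ACGT") == 0
        assert mp.hamming_distance("ACGT", "ACGA") == 1

    def test_symmetric(self, rng):
        for _ in range(20):
            a = rng.choice(list("ACGT"), size=9)
            b = rng.choice(list("ACGT"), size=9)
            assert mp.hamming_distance(a, b) == mp.hamming_distance(b, a)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mp.hamming_distance("ACG", "ACGT")


class TestComputeS:
    @pytest.mark.parametrize(
        "k,e,expected",
        [
            (36, 0, 25),   # floor(36 * 0.7)
            (30, 2, 4),    # floor(30 * 0.3 * 0.49)
            (101, 1, 70),  # floor(101 * 1.0 * 0.7)
            (24, 1, 5),    # floor(24 * 0.3 * 0.7)
            (50, 2, 12),   # floor(50 * 0.5 * 0.49)
        ],
    )
    def test_published_rule(self, k, e, expected):
        assert compute_s(k, e) == expected

    def test_always_within_group_bounds(self):
        for k in range(2, 120):
            for e in range(0, min(5, k)):
                s = compute_s(k, e)
                assert 1 <= s <= max(1, k - e + 1)

    def test_clamp(self):
        assert clamp(0.08, 0.3, 1.0) == 0.3
        assert clamp(1.2, 0.3, 1.0) == 1.0
        assert clamp(0.5, 0.3, 1.0) == 0.5


class TestFrequencyExamples:
    def test_exact_repeat(self, simple_collection):
        col, idx = simple_collection
        f = mp.frequency(idx, col, 4, 0)
        assert f.values.tolist() == [2, 1, 1, 1, 2]

    def test_all_identical_kmers_with_error(self):
        col = mp.collection_from_strings(["AAAA"])
        idx = mp.build_index(col)
        f = mp.frequency(idx, col, 2, 1)
        assert f.values.tolist() == [3, 3, 3]

    def test_multi_genome_presence(self):
        col = mp.collection_from_strings(["ACGTACGT", "ACGTTTTT"])
        idx = mp.build_index(col)
        f = mp.frequency(idx, col, 4, 0, mode="multi_genome")
        # ACGT occurs in both genomes (positions 0, 4 of g0 and 0 of g1)
        acgt_positions = [0, 4, 9]
        for p, v in zip(f.positions.tolist(), f.values.tolist()):
            assert v == (2 if p in acgt_positions else 1)

    def test_invalid_parameters(self, simple_collection):
        col, idx = simple_collection
        with pytest.raises(ValueError):
            mp.frequency(idx, col, 2, 4)  # k - e + 1 < 1
        with pytest.raises(ValueError):
            mp.frequency(idx, col, 4, 0, mode="both")
        with pytest.raises(ValueError):
            mp.frequency(idx, col, 8, 1, s=10)  # s > k - e + 1


class TestMappability:
    def test_reciprocal(self, simple_collection):
        col, idx = simple_collection
        m = mp.mappability(mp.frequency(idx, col, 4, 0))
        assert m.values.tolist() == [0.5, 1, 1, 1, 0.5]

    def test_all_unique(self):
        col = mp.collection_from_strings(["ACGTTGCA"])
        idx = mp.build_index(col)
        m = mp.mappability(mp.frequency(idx, col, 5, 0))
        assert (m.values == 1).all()

    def test_constant_repeat(self):
        col = mp.collection_from_strings(["AAAAA"])
        idx = mp.build_index(col)
        m = mp.mappability(mp.frequency(idx, col, 2, 0))
        assert m.values.tolist() == [0.25, 0.25, 0.25, 0.25]

    def test_zero_frequency_rejected(self, simple_collection):
        col, idx = simple_collection
        f = mp.frequency(idx, col, 4, 0)
        f.values[0] = 0
        with pytest.raises(ValueError):
            mp.mappability(f)


def _random_case(rng, multi=False):
    n = int(rng.integers(30, 300))
    skew = bool(rng.integers(0, 2))
    p = [0.4, 0.1, 0.1, 0.4] if skew else [0.25] * 4
    ngen = int(rng.integers(2, 4)) if multi else 1
    seqs = ["".join(rng.choice(list("ACGT"), size=n, p=p)) for _ in range(ngen)]
    col = mp.collection_from_strings(seqs)
    return col, mp.build_index(col)


class TestOracleEquivalence:
    @pytest.mark.parametrize("e", [0, 1, 2])
    def test_single_genome(self, rng, e):
        for _ in range(15):
            col, idx = _random_case(rng)
            k = int(rng.integers(max(4, 2 * e), 20))
            rc = bool(rng.integers(0, 2))
            got = mp.frequency(idx, col, k, e, reverse_complement=rc).values
            want = brute_force_frequency(col, k, e, reverse_complement=rc)
            assert np.array_equal(got, want)

    def test_multi_genome(self, rng):
        for _ in range(15):
            col, idx = _random_case(rng, multi=True)
            k = int(rng.integers(6, 16))
            e = int(rng.integers(0, 3))
            rc = bool(rng.integers(0, 2))
            got = mp.frequency(
                idx, col, k, e, mode="multi_genome", reverse_complement=rc
            ).values
            want = brute_force_frequency(
                col, k, e, reverse_complement=rc, mode="multi_genome"
            )
            assert np.array_equal(got, want)

    def test_exclude_policy_masks_windows(self):
        col = mp.collection_from_strings(["ACGTNACGTA"], n_policy="exclude")
        idx = mp.build_index(col)
        f = mp.frequency(idx, col, 4, 1)
        # valid windows avoid the masked base at offset 4
        assert f.positions.tolist() == [0, 5, 6]
        assert (f.values >= 1).all()

    def test_monotone_in_error_count(self, rng):
        for _ in range(8):
            col, idx = _random_case(rng)
            k = int(rng.integers(8, 16))
            prev = None
            for e in (0, 1, 2):
                cur = mp.frequency(idx, col, k, e).values
                if prev is not None:
                    assert (cur >= prev).all()
                prev = cur

    def test_exact_mode_agrees_with_hash_counter(self, rng):
        for _ in range(10):
            col, idx = _random_case(rng, multi=bool(rng.integers(0, 2)))
            k = int(rng.integers(4, 14))
            mode = "multi_genome" if col.n_genomes > 1 else "single"
            got = mp.frequency(idx, col, k, 0, mode=mode).values
            assert np.array_equal(got, hash_frequency(col, k, mode=mode))

    def test_identical_kmers_get_identical_values(self, rng):
        for _ in range(6):
            col, idx = _random_case(rng)
            k = 6
            f = mp.frequency(idx, col, k, 1)
            text = col.concatenated()
            seen = {}
            for p, v in zip(f.positions.tolist(), f.values.tolist()):
                key = text[p : p + k].tobytes()
                assert seen.setdefault(key, v) == v


class TestAblations:
    def test_skipping_and_grouping_do_not_change_results(self, rng):
        for _ in range(10):
            col, idx = _random_case(rng, multi=bool(rng.integers(0, 2)))
            mode = "multi_genome" if col.n_genomes > 1 else "single"
            k = int(rng.integers(6, 18))
            e = int(rng.integers(0, 3))
            base = mp.frequency(idx, col, k, e, mode=mode).values
            no_skip = mp.frequency(idx, col, k, e, mode=mode, use_skipping=False).values
            no_group = mp.frequency(idx, col, k, e, mode=mode, s=1).values
            neither = mp.frequency(
                idx, col, k, e, mode=mode, s=1, use_skipping=False
            ).values
            assert np.array_equal(base, no_skip)
            assert np.array_equal(base, no_group)
            assert np.array_equal(base, neither)


class TestHeuristicFrequency:
    def test_infinite_threshold_equals_exact(self, rng):
        for _ in range(10):
            col, idx = _random_case(rng)
            k = int(rng.integers(4, 14))
            e = int(rng.integers(0, 3))
            exact = mp.frequency(idx, col, k, e).values
            heur = mp.heuristic_frequency(idx, col, k, e, t=math.inf).values
            assert np.array_equal(exact, heur)

    def test_hand_simulated_forwarding(self):
        # all 2-mers of AAAAAA are identical: the first search finds 5
        # occurrences, exceeds t=1, and forwards 5 everywhere
        col = mp.collection_from_strings(["AAAAAA"])
        idx = mp.build_index(col)
        f = mp.heuristic_frequency(idx, col, 2, 0, t=1)
        assert f.values.tolist() == [5, 5, 5, 5, 5]

    def test_overestimation_of_rare_kmers_exists(self):
        """A repetitive k-mer within e of a rarer one inflates the rare
        k-mer's value when the threshold forwards aggressively."""
        col = mp.collection_from_strings(["AAAAAACGAAAAAA"])
        idx = mp.build_index(col)
        exact = mp.frequency(idx, col, 4, 1).values
        heur = mp.heuristic_frequency(idx, col, 4, 1, t=1).values
        assert (heur >= exact).all()
        assert (heur > exact).any()

    def test_multi_genome_rejected(self):
        col = mp.collection_from_strings(["ACGT", "ACGT"])
        idx = mp.build_index(col)
        with pytest.raises(ValueError):
            mp.heuristic_frequency(idx, col, 2, 0)


class TestLocations:
    def test_stored_locations_sum_to_frequency(self, rng):
        col, idx = _random_case(rng)
        k, e = 8, 1
        f = mp.frequency(idx, col, k, e, store_locations=True)
        for p, v in zip(f.positions.tolist(), f.values.tolist()):
            assert len(f.locations[p]) == v

    def test_unique_kmer_location_is_itself(self):
        col = mp.collection_from_strings(["ACGTTGCA"])
        idx = mp.build_index(col)
        f = mp.frequency(idx, col, 5, 0, store_locations=True)
        for p in f.positions.tolist():
            assert f.locations[p].tolist() == [p]
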