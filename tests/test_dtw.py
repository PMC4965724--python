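from functools import lru_cache

import numpy as np
import pytest

from semgrip import dtw as dtw_mod
from semgrip.labeling import ActivitySegment
from semgrip.sax import modified_lexical_distance, strings_to_words


def brute_force_dtw(a, b):
    """Independent oracle: unbanded recursive DP with the same local cost."""
    a = np.atleast_2d(np.asarray(a))
    b = np.atleast_2d(np.asarray(b))

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0 and j == 0:
            return 0.0
        if i == 0 or j == 0:
            return float("inf")
        c = modified_lexical_distance(a[i - 1], b[j - 1])
        return c + min(rec(i - 1, j), rec(i, j - 1), rec(i - 1, j - 1))

    return rec(a.shape[0], b.shape[0])


def random_pair(rng, max_len=12, n=5):
    la, lb = rng.integers(1, max_len + 1, size=2)
    return rng.integers(0, n, size=(la, 8)), rng.integers(0, n, size=(lb, 8))


class TestDtwDistance:
    def test_identical_sequences_are_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 5, size=(20, 8))
        assert dtw_mod.dtw_distance(a, a, r=5) == 0

    def test_length_one_equals_local_cost(self):
        a, b = strings_to_words(["AAAAAAAA"]), strings_to_words(["AACCBBEE"])
        assert dtw_mod.dtw_distance(a, b, r=5) == 8

    def test_matches_unbanded_oracle_with_wide_band(self):
        rng = np.random.default_rng(1)
        for _ in range(150):
            a, b = random_pair(rng)
            r = max(len(a), len(b))
            assert dtw_mod.dtw_distance(a, b, r) == brute_force_dtw(a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b = random_pair(rng)
            r = max(len(a), len(b))
            assert dtw_mod.dtw_distance(a, b, r) == dtw_mod.dtw_distance(b, a, r)

    def test_zero_band_equal_length_is_positionwise_sum(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 7, size=(15, 8))
        b = rng.integers(0, 7, size=(15, 8))
        expected = sum(modified_lexical_distance(x, y) for x, y in zip(a, b))
        assert dtw_mod.dtw_distance(a, b, r=0) == expected

    def test_band_too_narrow_for_unequal_lengths(self):
        a = np.zeros((10, 8), dtype=int)
        b = np.zeros((2, 8), dtype=int)
        with pytest.raises(ValueError, match="band"):
            dtw_mod.dtw_distance(a, b, r=3)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            dtw_mod.dtw_distance(np.empty((0, 8)), np.zeros((3, 8)), r=5)


class TestPrefixEngine:
    def test_diagonal_equals_scalar_prefix_distances(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            a, b = random_pair(rng, max_len=10)
            diag = dtw_mod.prefix_distance_matrix(a, [b], r=5)
            for p in range(1, len(a) + 1):
                L = min(p, len(b))
                assert diag[p - 1, 0] == dtw_mod.dtw_distance(a[:L], b[:L], r=5)


def seg(label, words, idx=0):
    words = np.atleast_2d(np.asarray(words, dtype=np.int16))
    return ActivitySegment(
        label=label,
        times=0.05 * np.arange(1, len(words) + 1),
        values=np.zeros((len(words), 8)),
        rep_index=1,
        run_id=f"run{idx}",
        words=words,
    )


class TestClassifySegment:
    def test_identical_training_segment_wins_at_every_prefix(self):
        rng = np.random.default_rng(5)
        words = rng.integers(0, 5, size=(20, 8))
        training = [seg("HG", rng.integers(0, 5, size=(20, 8))), seg("HR", words)]
        res = dtw_mod.classify_segment(seg("HR", words), training)
        assert res.predictions == ["HR"] * 20
        np.testing.assert_array_equal(res.distances, 0)

    def test_disjoint_alphabets_hand_case(self):
        a_words = strings_to_words(["AAAAAAAA"] * 10)
        e_words = strings_to_words(["EEEEEEEE"] * 10)
        training = [seg("X", a_words), seg("Y", e_words)]
        res = dtw_mod.classify_segment(seg("X", a_words), training)
        assert res.predictions == ["X"] * 10
        # the rival accumulates (|4|-1) * 8 = 24 per word
        assert dtw_mod.dtw_distance(a_words[:1], e_words[:1], 5) == 24

    def test_one_prediction_per_prefix(self):
        rng = np.random.default_rng(6)
        test = seg("HG", rng.integers(0, 5, size=(17, 8)))
        training = [seg("HG", rng.integers(0, 5, size=(20, 8)))]
        assert len(dtw_mod.classify_segment(test, training)) == 17

    def test_distance_tie_prefers_earliest_training_segment(self):
        words = strings_to_words(["CCCCCCCC"] * 5)
        training = [seg("X", words, 0), seg("Y", words, 1)]
        res = dtw_mod.classify_segment(seg("Y", words), training)
        assert res.predictions == ["X"] * 5
        assert np.all(res.nn_indices == 0)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            dtw_mod.classify_segment(seg("X", np.zeros((3, 8))), [])

    def test_full_train_flag_matches_scalar(self):
        rng = np.random.default_rng(7)
        test = seg("HG", rng.integers(0, 5, size=(8, 8)))
        train = [seg("HG", rng.integers(0, 5, size=(10, 8)))]
        cfg = dtw_mod.DtwConfig(full_train=True)
        res = dtw_mod.classify_segment(test, train, cfg)
        for p in range(1, 9):
            if abs(p - 10) <= cfg.band:
                assert res.distances[p - 1] == dtw_mod.dtw_distance(
                    test.words[:p], train[0].words, cfg.band
                )


class TestAccuracyCurve:
    def test_all_correct_gives_flat_100(self):
        res = dtw_mod.PrefixResult(
            predictions=["HG"] * 5, nn_indices=np.zeros(5, int), distances=np.zeros(5)
        )
        curve = dtw_mod.accuracy_by_wordcount([("HG", res), ("HG", res)])
        assert all(v == 100.0 for v in curve.values())

    def test_only_long_enough_segments_participate(self):
        short = dtw_mod.PrefixResult(["HG"] * 2, np.zeros(2, int), np.zeros(2))
        long = dtw_mod.PrefixResult(["HR"] * 4, np.zeros(4, int), np.zeros(4))
        curve = dtw_mod.accuracy_by_wordcount([("HG", short), ("HG", long)])
        assert curve[1] == 50.0  # both participate, one wrong
        assert curve[3] == 0.0  # only the long (wrong) one remains
        assert set(curve) == {1, 2, 3, 4}

    def test_values_bounded(self):
        rng = np.random.default_rng(8)
        results = []
        for _ in range(10):
            m = int(rng.integers(1, 6))
            preds = [str(c) for c in rng.choice(["HG", "HR"], size=m)]
            results.append(
                ("HG", dtw_mod.PrefixResult(preds, np.zeros(m, int), np.zeros(m)))
            )
        curve = dtw_mod.accuracy_by_wordcount(results)
        assert all(0.0 <= v <= 100.0 for v in curve.values())
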