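"""Normalization, relevance, mutual information, pruning and mRMR."""

import numpy as np
import pandas as pd
import pytest

from radiotexnet.features import FeatureTable
from radiotexnet.selection import (discretize_equal_frequency, mi_map,
                                   mrmr_rank, mutual_information,
                                   normalize_table, pearson_relevance,
                                   prune_correlated, relevance_series,
                                   select_features)


def table_from(columns: dict, labels) -> FeatureTable:
    return FeatureTable(pd.DataFrame(columns), np.asarray(labels, int))


class TestNormalize:
    def test_positive_column(self):
        t = table_from({"a": [2.0, 4.0]}, [0, 1])
        out = normalize_table(t)
        np.testing.assert_allclose(out.data["a"], [0.5, 1.0])

    def test_abs_max_convention(self):
        t = table_from({"a": [-3.0, 1.0]}, [0, 1])
        out = normalize_table(t)
        np.testing.assert_allclose(out.data["a"], [-1.0, 1.0 / 3.0])

    def test_idempotent_and_bounded(self):
        rng = np.random.default_rng(0)
        t = table_from({f"c{i}": rng.normal(size=8) * 10 ** i
                        for i in range(4)}, [0, 1] * 4)
        once = normalize_table(t)
        twice = normalize_table(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        np.testing.assert_allclose(once.data.abs().max().to_numpy(), 1.0)

    def test_zero_column_flagged(self):
        t = table_from({"z": [0.0, 0.0], "a": [1.0, 2.0]}, [0, 1])
        out = normalize_table(t)
        assert out.manifest["zero_columns"] == ["z"]
        np.testing.assert_allclose(out.data["z"], [0.0, 0.0])


class TestPearson:
    def test_column_equal_to_target(self):
        assert pearson_relevance([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1)

    def test_anti_target(self):
        assert pearson_relevance([1, 1, 0, 0], [0, 0, 1, 1]) == pytest.approx(-1)

    def test_hand_computed_value(self):
        x = np.array([0.1, 0.4, 0.35, 0.8])
        y = np.array([0, 0, 1, 1])
        # closed form
        expect = (np.mean((x - x.mean()) * (y - y.mean()))
                  / (x.std() * y.std()))
        assert pearson_relevance(x, y) == pytest.approx(expect)
        assert pearson_relevance(x, y) == pytest.approx(
            np.corrcoef(x, y)[0, 1])

    def test_constant_column_maps_to_zero(self):
        assert pearson_relevance([5, 5, 5, 5], [0, 0, 1, 1]) == 0.0


class TestDiscretize:
    def test_four_values_two_bins(self):
        np.testing.assert_array_equal(
            discretize_equal_frequency(np.array([1, 2, 3, 4]), 2),
            [1, 1, 2, 2])

    def test_constant_column_single_label(self):
        labels = discretize_equal_frequency(np.full(10, 3.3), 4)
        assert set(labels) == {1}

    def test_uniform_draws_balanced_bins(self):
        rng = np.random.default_rng(1)
        labels = discretize_equal_frequency(rng.random(1000), 4)
        counts = np.bincount(labels)[1:]
        assert counts.min() >= 249 and counts.max() <= 251

    def test_fewer_distinct_than_bins(self):
        labels = discretize_equal_frequency(np.array([7, 7, 9, 9, 9]), 4)
        np.testing.assert_array_equal(labels, [1, 1, 2, 2, 2])


class TestMutualInformation:
    def test_constant_gives_zero(self):
        assert mutual_information(np.ones(8), np.r_[np.zeros(4), np.ones(4)]
                                  ) == pytest.approx(0.0)

    def test_identical_balanced_binary_is_one_bit(self):
        x = np.array([0, 1] * 5)
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_hand_computed_2x2_joint(self):
        # joint counts {(0,0):4, (0,1):1, (1,0):1, (1,1):4}
        x = np.array([0] * 5 + [1] * 5)
        y = np.array([0, 0, 0, 0, 1, 0, 1, 1, 1, 1])
        expect = 0.8 * np.log2(1.6) + 0.2 * np.log2(0.4)
        assert mutual_information(x, y) == pytest.approx(expect)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.integers(0, 4, size=30)
            y = rng.integers(0, 3, size=30)
            mi = mutual_information(x, y)
            assert mi >= 0
            assert mi == pytest.approx(mutual_information(y, x))


class TestMIMap:
    def test_identical_columns_share_entropy(self):
        t = table_from({"a": [1.0, 2, 3, 4, 1, 2, 3, 4],
                        "b": [1.0, 2, 3, 4, 1, 2, 3, 4]}, [0, 1] * 4)
        m = mi_map(t, bins=4)
        assert m.loc["a", "b"] == pytest.approx(m.loc["a", "a"])

    def test_independent_columns_low_mi(self):
        rng = np.random.default_rng(3)
        t = table_from({"a": rng.normal(size=2000),
                        "b": rng.normal(size=2000)}, [0, 1] * 1000)
        assert mi_map(t, bins=4).loc["a", "b"] < 0.05

    def test_symmetric_shape(self):
        rng = np.random.default_rng(4)
        t = table_from({f"c{i}": rng.normal(size=10) for i in range(5)},
                       [0, 1] * 5)
        m = mi_map(t)
        assert m.shape == (5, 5)
        np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T)
        assert (m.to_numpy() >= -1e-12).all()


class TestPrune:
    def test_duplicated_column_one_survives(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        t = table_from({"a": x, "b": x.copy(), "c": rng.normal(size=10)},
                       [0, 1] * 5)
        out, log = prune_correlated(t, 0.85)
        assert set(out.data.columns) & {"a", "b"} == {"a"}
        assert len(log) == 1

    def test_below_threshold_both_survive(self):
        t = table_from({"a": [0, 1, 0, 1, 0, 1.0],
                        "b": [0, 1, 1, 0, 0, 1.0]}, [0, 0, 0, 1, 1, 1])
        corr = abs(np.corrcoef(t.data["a"], t.data["b"])[0, 1])
        assert corr < 0.85
        out, log = prune_correlated(t, 0.85)
        assert list(out.data.columns) == ["a", "b"] and not log

    def test_three_collinear_columns_leave_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=12)
        t = table_from({"a": x, "b": 2 * x, "c": -x}, [0, 1] * 6)
        out, _ = prune_correlated(t, 0.85)
        assert out.data.shape[1] == 1

    def test_no_surviving_pair_above_threshold(self):
        rng = np.random.default_rng(7)
        base = rng.normal(size=(30, 4))
        cols = {f"f{i}": base[:, i % 4] + rng.normal(scale=0.3, size=30)
                for i in range(12)}
        t = table_from(cols, [0, 1] * 15)
        out, _ = prune_correlated(t, 0.85)
        c = np.abs(np.corrcoef(out.data.to_numpy().T))
        np.fill_diagonal(c, 0)
        assert c.max() <= 0.85 + 1e-12


class TestMRMR:
    def test_k_equals_available_is_identity(self):
        rng = np.random.default_rng(8)
        t = table_from({f"c{i}": rng.normal(size=10) for i in range(5)},
                       [0, 1] * 5)
        res = mrmr_rank(t, k=5)
        assert set(res.selected) == set(t.data.columns)

    def test_redundant_copy_excluded(self):
        # f1 = target, f2 = copy of f1, f3 = independent noise; with k=2 the
        # redundancy term must exclude the copy
        rng = np.random.default_rng(9)
        target = np.array([0, 1] * 10)
        t = table_from({"f1": target.astype(float),
                        "f2": target.astype(float),
                        "f3": rng.normal(size=20)}, target)
        res = mrmr_rank(t, k=2)
        assert set(res.selected) == {"f1", "f3"}

    def test_matches_exhaustive_set_criterion(self):
        # greedy backward deselection should find the best-phi subset here
        rng = np.random.default_rng(10)
        target = np.array([0, 1] * 12)
        t = table_from({
            "sig": target + rng.normal(scale=0.1, size=24),
            "sig_copy": target + rng.normal(scale=0.1, size=24),
            "noise1": rng.normal(size=24),
            "noise2": rng.normal(size=24),
        }, target)
        res = mrmr_rank(t, k=2)
        from itertools import combinations

        from radiotexnet.selection import (_discretized_matrix, _pairwise_mi,
                                           mutual_information)

        disc = _discretized_matrix(t, 4)
        cols = list(t.data.columns)
        rel = {c: mutual_information(disc[:, i], target)
               for i, c in enumerate(cols)}
        mi = _pairwise_mi(disc)

        def phi(subset):
            idx = [cols.index(c) for c in subset]
            red = np.mean([mi[a, b] for a in idx for b in idx if a < b])
            return np.mean([rel[c] for c in subset]) - red

        best = max(combinations(cols, 2), key=phi)
        assert set(res.selected) == set(best)

    def test_default_k_twenty(self):
        rng = np.random.default_rng(11)
        t = table_from({f"c{i}": rng.normal(size=30) for i in range(40)},
                       [0, 1] * 15)
        res = mrmr_rank(t, k=20)
        assert len(res.selected) == 20

    def test_k_exceeding_available_warns(self):
        rng = np.random.default_rng(12)
        t = table_from({f"c{i}": rng.normal(size=10) for i in range(3)},
                       [0, 1] * 5)
        with pytest.warns(UserWarning, match="exceeds"):
            res = mrmr_rank(t, k=9)
        assert len(res.selected) == 3

    def test_zero_redundancy_weight_is_top_k_by_mi(self):
        rng = np.random.default_rng(13)
        target = np.array([0, 1] * 15)
        t = table_from({f"c{i}": target * (i + 1) / 8.0
                        + rng.normal(scale=0.3 + 0.2 * i, size=30)
                        for i in range(8)}, target)
        res = mrmr_rank(t, k=3, redundancy_weight=0.0)
        from radiotexnet.selection import _discretized_matrix

        disc = _discretized_matrix(t, 4)
        mi_rel = [mutual_information(disc[:, i], target) for i in range(8)]
        top = sorted(range(8), key=lambda i: (-mi_rel[i], i))[:3]
        assert set(res.selected) == {f"c{i}" for i in top}

    def test_selection_deterministic(self, small_table):
        a = select_features(small_table, k=10)[1]
        b = select_features(small_table, k=10)[1]
        assert a.selected == b.selected
        assert a.relevance.equals(b.relevance)

    def test_ordering_by_descending_abs_relevance(self, small_table):
        _, res = select_features(small_table, k=10)
        rel = res.relevance.abs().to_numpy()
        assert np.all(np.diff(rel) <= 1e-12)

    def test_strong_synthetic_signal_detected(self, small_table):
        _, res = select_features(small_table, k=20)
        assert res.relevance.abs().max() >= 0.5

    def test_forward_scheme_runs(self):
        rng = np.random.default_rng(14)
        t = table_from({f"c{i}": rng.normal(size=20) for i in range(10)},
                       [0, 1] * 10)
        res = mrmr_rank(t, k=4, scheme="forward")
        assert len(res.selected) == 4
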