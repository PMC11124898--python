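"""Mutual-information estimators vs brute force; filter and wrapper contracts."""

import numpy as np
import pandas as pd
import pytest

from enoserot.selection import (
    SelectionConfig,
    discretize_equal_frequency,
    estimate_mi,
    estimate_cmi,
    mime_scores,
    filter_stage,
    rfecv_wrapper,
)


def brute_force_mi(a, b):
    """Literal four-loop plug-in MI in bits over discrete symbol tables."""
    a, b = list(a), list(b)
    n = len(a)
    total = 0.0
    for x in set(a):
        for y in set(b):
            p_xy = sum(1 for i in range(n) if a[i] == x and b[i] == y) / n
            p_x = sum(1 for i in range(n) if a[i] == x) / n
            p_y = sum(1 for i in range(n) if b[i] == y) / n
            if p_xy > 0:
                total += p_xy * np.log2(p_xy / (p_x * p_y))
    return total


def brute_force_cmi(a, b, c):
    n = len(c)
    total = 0.0
    for y in set(c):
        idx = [i for i in range(n) if c[i] == y]
        if len(idx) < 2:
            continue
        total += (len(idx) / n) * brute_force_mi([a[i] for i in idx],
                                                 [b[i] for i in idx])
    return total


class TestMutualInformation:
    def test_self_information_of_uniform_four_symbols_is_two_bits(self):
        a = np.repeat(np.arange(4), 5)
        assert estimate_mi(a, a) == pytest.approx(2.0, abs=1e-12)

    def test_product_of_marginals_gives_zero(self):
        a = np.tile([0, 0, 1, 1], 3)
        b = np.tile([0, 1, 0, 1], 3)
        assert estimate_mi(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_hand_summed_two_by_two_table(self):
        # joint counts [[2,1],[1,2]] over n=6
        a = np.array([0, 0, 0, 1, 1, 1])
        b = np.array([0, 0, 1, 0, 1, 1])
        expected = brute_force_mi(a, b)
        assert estimate_mi(a, b) == pytest.approx(expected, abs=1e-12)
        # and the closed form of that table: two cells of 2/6, two of 1/6
        closed = 2 * (2 / 6) * np.log2((2 / 6) / 0.25) \
            + 2 * (1 / 6) * np.log2((1 / 6) / 0.25)
        assert expected == pytest.approx(closed, abs=1e-12)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_brute_force_on_random_small_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 40)
        a = rng.integers(0, rng.integers(2, 6), n)
        b = rng.integers(0, rng.integers(2, 6), n)
        assert estimate_mi(a, b) == pytest.approx(brute_force_mi(a, b), abs=1e-12)

    def test_continuous_inputs_are_binned_consistently(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        binned = discretize_equal_frequency(x, 8)
        assert estimate_mi(x, x, bins=8) == pytest.approx(
            brute_force_mi(binned, binned), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            estimate_mi(np.arange(3), np.arange(4))


class TestConditionalMutualInformation:
    def test_independent_within_every_class_gives_zero(self):
        a = np.tile([0, 0, 1, 1], 4)
        b = np.tile([0, 1, 0, 1], 4)
        c = np.repeat([0, 1], 8)
        assert estimate_cmi(a, b, c) == pytest.approx(0.0, abs=1e-12)

    def test_identical_uniform_binary_within_classes_gives_one_bit(self):
        a = np.tile([0, 1], 6)
        c = np.repeat([0, 1, 2], 4)
        assert estimate_cmi(a, a, c) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_per_class_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = rng.integers(9, 40)
        a = rng.integers(0, 4, n)
        b = rng.integers(0, 3, n)
        c = rng.integers(0, 3, n)
        assert estimate_cmi(a, b, c) == pytest.approx(
            brute_force_cmi(list(a), list(b), list(c)), abs=1e-12)

    def test_sparse_class_contributes_zero_with_warning(self):
        a = np.array([0, 1, 0, 1, 0])
        c = np.array([0, 0, 0, 0, 9])  # class 9 has a single sample
        with pytest.warns(UserWarning, match="< 2 samples"):
            v = estimate_cmi(a, a, c)
        assert v == pytest.approx(0.8 * brute_force_mi([0, 1, 0, 1], [0, 1, 0, 1]))


def _toy_table(rng, n=60):
    y = np.repeat([0, 1, 2], n // 3)
    informative = y + rng.normal(scale=0.2, size=n)
    noise = rng.normal(size=n)
    return pd.DataFrame({"A": informative, "B": noise,
                         "C": rng.normal(size=n)}), y


class TestMimeScores:
    def test_degenerate_weights_reduce_to_plain_relevance(self):
        rng = np.random.default_rng(2)
        table, y = _toy_table(rng)
        cfg = SelectionConfig(alpha=0.0, beta=0.0, mi_bins=4)
        scores = mime_scores(table, y, cfg)
        for c in table.columns:
            binned = discretize_equal_frequency(table[c].to_numpy(), 4)
            assert scores[c] == pytest.approx(brute_force_mi(binned, y), abs=1e-12)

    def test_label_copy_scores_near_label_entropy(self):
        rng = np.random.default_rng(3)
        n = 90
        y = np.repeat([0, 1, 2], n // 3)
        table = pd.DataFrame({"copy": y.astype(float),
                              "n1": rng.normal(size=n), "n2": rng.normal(size=n)})
        scores = mime_scores(table, y, SelectionConfig(mi_bins=3))
        assert scores["copy"] == pytest.approx(np.log2(3), abs=0.2)
        assert scores["copy"] > scores["n1"] and scores["copy"] > scores["n2"]

    def test_duplicated_feature_penalized_by_redundancy(self):
        rng = np.random.default_rng(4)
        n = 90
        y = np.repeat([0, 1, 2], n // 3)
        f = y + rng.normal(scale=0.1, size=n)
        noise = rng.normal(size=n)
        solo = pd.DataFrame({"f": f, "noise": noise})
        dup = pd.DataFrame({"f": f, "f2": f.copy(), "noise": noise})
        cfg = SelectionConfig(alpha=1.0, beta=0.0, mi_bins=4)
        s_solo = mime_scores(solo, y, cfg)["f"]
        s_dup = mime_scores(dup, y, cfg)["f"]
        # solo: score = I(f,y) - I(f,noise); duplicated (m=2):
        # score = I(f,y) - (H_bin(f) + I(f,noise)) / 2
        f_b = discretize_equal_frequency(f, 4)
        n_b = discretize_equal_frequency(dup["noise"].to_numpy(), 4)
        h_f = brute_force_mi(f_b, f_b)
        i_fn = brute_force_mi(f_b, n_b)
        assert s_dup < s_solo
        assert s_solo - s_dup == pytest.approx((h_f - i_fn) / 2, abs=1e-12)

    def test_permutation_equivariance_in_feature_order(self):
        rng = np.random.default_rng(5)
        table, y = _toy_table(rng)
        s1 = mime_scores(table, y)
        s2 = mime_scores(table[["C", "A", "B"]], y)
        for c in table.columns:
            assert s1[c] == pytest.approx(s2[c], abs=1e-12)

    def test_single_feature_table_rejected(self):
        with pytest.raises(ValueError):
            mime_scores(pd.DataFrame({"A": [1.0, 2.0]}), np.array([0, 1]))


class TestFilterStage:
    def test_threshold_at_minimum_keeps_all(self):
        scores = pd.Series({"a": 0.1, "b": 0.5, "c": 0.9})
        cfg = SelectionConfig(filter_threshold=0.1)
        assert set(filter_stage(scores, cfg)) == {"a", "b", "c"}

    def test_infinite_threshold_keeps_top_one(self):
        scores = pd.Series({"a": 0.1, "b": 0.5, "c": 0.9})
        cfg = SelectionConfig(filter_threshold=np.inf)
        assert filter_stage(scores, cfg) == ["c"]

    def test_lower_quartile_on_144_scores_keeps_108(self):
        rng = np.random.default_rng(6)
        scores = pd.Series(rng.normal(size=144),
                           index=[f"f{i}" for i in range(144)])
        kept = filter_stage(scores, SelectionConfig(filter_quantile=0.25))
        assert len(kept) == 108


class TestWrapper:
    @pytest.fixture()
    def separable_table(self):
        rng = np.random.default_rng(7)
        n = 60
        y = np.repeat([0, 1, 2], n // 3)
        cols = {f"inf{i}": y + rng.normal(scale=0.3, size=n) for i in range(3)}
        cols["noise"] = rng.normal(size=n)
        return pd.DataFrame(cols), y

    @pytest.mark.parametrize("seed", range(10))
    def test_pure_noise_feature_always_deleted(self, separable_table, seed):
        table, y = separable_table
        res = rfecv_wrapper(table, y, SelectionConfig(seed=seed, cv_folds=3))
        assert "noise" not in res.selected

    def test_identical_copies_collapse_to_single_feature(self):
        rng = np.random.default_rng(8)
        n = 30
        y = np.repeat([0, 1, 2], n // 3)
        f = y + rng.normal(scale=0.05, size=n)
        table = pd.DataFrame({f"c{i}": f for i in range(5)})
        res = rfecv_wrapper(table, y, SelectionConfig(seed=0, cv_folds=3))
        assert len(res.selected) == 1

    def test_same_seed_reproduces_wrapper_log(self, separable_table):
        table, y = separable_table
        cfg = SelectionConfig(seed=3, cv_folds=3)
        r1 = rfecv_wrapper(table, y, cfg)
        r2 = rfecv_wrapper(table, y, cfg)
        assert r1.wrapper_log == r2.wrapper_log
        assert r1.selected == r2.selected

    def test_log_replays_to_final_selection(self, separable_table):
        table, y = separable_table
        res = rfecv_wrapper(table, y, SelectionConfig(seed=1, cv_folds=3))
        current = set(table.columns)
        for entry in res.wrapper_log:
            if entry["deleted"]:
                current.discard(entry["feature"])
        assert current == set(res.selected)

    def test_min_features_floor_respected(self):
        rng = np.random.default_rng(9)
        n = 30
        y = np.repeat([0, 1, 2], n // 3)
        table = pd.DataFrame({f"c{i}": y + rng.normal(scale=0.05, size=n)
                              for i in range(6)})
        res = rfecv_wrapper(table, y, SelectionConfig(seed=0, cv_folds=3,
                                                      min_features=4))
        assert len(res.selected) >= 4

    def test_single_class_labels_rejected(self, separable_table):
        table, _ = separable_table
        with pytest.raises(ValueError):
            rfecv_wrapper(table, np.zeros(len(table), dtype=int),
                          SelectionConfig())
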