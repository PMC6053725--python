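from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from chipdeg.ml import (
    CLASSIFIER_NAMES,
    RankedFeatureList,
    cfs_select,
    compute_metrics,
    cross_validate,
    info_gain,
    relieff,
    roc_auc,
    select_top_fraction,
    stratified_folds,
    stratified_split,
    train_classifier,
)
from chipdeg.ml.discretize import equal_frequency_cuts, mdl_cut_points
from chipdeg.ml.evaluate import largest_remainder_allocation
from chipdeg.ml.selection import cfs_merit, rank_features_infogain, symmetrical_uncertainty
from chipdeg.simulate import simulate_feature_matrix


def brute_force_info_gain(x, y) -> float:
    """Independent oracle: plain entropy arithmetic on categorical data."""

    def entropy(seq):
        seq = list(seq)
        h = 0.0
        for v in set(seq):
            p = seq.count(v) / len(seq)
            h -= p * math.log2(p)
        return h

    h_y = entropy(y)
    h_cond = 0.0
    for v in set(x):
        subset = [yy for xx, yy in zip(x, y) if xx == v]
        h_cond += len(subset) / len(x) * entropy(subset)
    return h_y - h_cond


class TestInfoGain:
    def test_perfect_separation_balanced(self):
        x = [0.0] * 20 + [1.0] * 20
        y = ["up"] * 20 + ["down"] * 20
        assert info_gain(x, y) == pytest.approx(1.0)

    def test_constant_feature_zero(self):
        y = ["up", "down"] * 10
        assert info_gain([3.0] * 20, y) == 0.0

    def test_constant_labels_zero(self):
        assert info_gain([1.0, 2.0, 3.0], ["up"] * 3) == 0.0

    def test_worked_two_bin_table(self):
        # contingency [[30,10],[10,30]] -> 1 - H(0.75)
        x = [0] * 40 + [1] * 40
        y = [0] * 30 + [1] * 10 + [0] * 10 + [1] * 30
        expected = 1.0 - (-(0.75 * math.log2(0.75)) - 0.25 * math.log2(0.25))
        assert info_gain(x, y, discretize="none") == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_discrete_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 80))
        x = rng.integers(0, 4, n).tolist()
        y = rng.integers(0, 3, n).tolist()
        assert info_gain(x, y, discretize="none") == pytest.approx(
            brute_force_info_gain(x, y), abs=1e-12
        )

    def test_mdl_needs_evidence(self):
        # tiny noisy feature: MDL must not cut, IG 0
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = rng.permutation(["up"] * 15 + ["down"] * 15)
        assert info_gain(x, y) == 0.0


class TestMDLCuts:
    def test_clear_boundary_found(self):
        x = np.concatenate([np.random.default_rng(1).normal(0, 0.1, 50),
                            np.random.default_rng(2).normal(5, 0.1, 50)])
        y = ["a"] * 50 + ["b"] * 50
        cuts = mdl_cut_points(x, y)
        assert len(cuts) >= 1
        assert 1.0 < cuts[0] < 4.0

    def test_no_cut_for_constant(self):
        assert mdl_cut_points([1.0] * 10, ["a", "b"] * 5) == []

    def test_equal_frequency_fallback(self):
        cuts = equal_frequency_cuts(np.arange(100.0), bins=10)
        assert len(cuts) == 9


class TestReliefF:
    def test_informative_beats_noise(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.permutation(["up"] * 30 + ["down"] * 30)
            informative = (y == "up").astype(float)
            noise = rng.normal(size=60)
            X = pd.DataFrame({"inf": informative, "noise": noise})
            w = relieff(X, y, k_neighbors=5)
            wins += int(w[0] > w[1])
        assert wins == 10

    def test_duplicated_columns_equal_weights(self, rng):
        y = rng.permutation(["up"] * 20 + ["down"] * 20)
        col = rng.normal(size=40)
        X = pd.DataFrame({"a": col, "b": col.copy()})
        w = relieff(X, y)
        assert w[0] == pytest.approx(w[1])

    def test_constant_feature_weight_zero(self, rng):
        y = rng.permutation(["up"] * 20 + ["down"] * 20)
        X = pd.DataFrame({"const": np.ones(40), "x": rng.normal(size=40)})
        assert relieff(X, y)[0] == 0.0

    def test_single_class_all_zero(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        assert np.all(relieff(X, ["up"] * 10) == 0.0)


class TestCFS:
    def test_single_feature_merit_is_su(self):
        su_fc = np.array([0.8])
        assert cfs_merit([0], su_fc, {}) == pytest.approx(0.8)

    def test_merit_formula(self):
        su_fc = np.array([0.6, 0.4])
        su_ff = {(0, 1): 0.5}
        k, rcf, rff = 2, 0.5, 0.5
        expected = k * rcf / math.sqrt(k + k * (k - 1) * rff)
        assert cfs_merit([0, 1], su_fc, su_ff) == pytest.approx(expected)

    def test_redundant_pair_collapses_to_one(self):
        rng = np.random.default_rng(3)
        y = rng.permutation(["up"] * 40 + ["down"] * 40)
        informative = (y == "up").astype(float) + rng.normal(0, 0.05, 80)
        X = pd.DataFrame({"f1": informative, "f2": informative.copy()})
        chosen = cfs_select(X, y)
        assert len(chosen) == 1

    def test_all_noise_gives_empty_or_tiny_subset(self):
        rng = np.random.default_rng(4)
        y = rng.permutation(["up"] * 25 + ["down"] * 25)
        X = pd.DataFrame({f"n{i}": rng.normal(size=50) for i in range(5)})
        chosen = cfs_select(X, y)
        assert len(chosen) <= 1

    def test_finds_best_subset_vs_exhaustive(self):
        rng = np.random.default_rng(5)
        y = rng.permutation(["up"] * 50 + ["down"] * 50)
        X = pd.DataFrame(
            {
                "good": (y == "up").astype(float) + rng.normal(0, 0.3, 100),
                "weak": (y == "up").astype(float) + rng.normal(0, 2.0, 100),
                "noise1": rng.normal(size=100),
                "noise2": rng.normal(size=100),
            }
        )
        chosen = set(cfs_select(X, y))
        # exhaustive oracle over all non-empty subsets
        from chipdeg.ml.discretize import discretize_values
        from chipdeg.ml.selection import _codes

        disc = {c: discretize_values(X[c].to_numpy(), y) for c in X.columns}
        y_codes = _codes(y)
        su_fc = np.array([symmetrical_uncertainty(disc[c], y_codes) for c in X.columns])
        su_ff = {
            (i, j): symmetrical_uncertainty(disc[X.columns[i]], disc[X.columns[j]])
            for i, j in itertools.combinations(range(4), 2)
        }
        best, best_m = None, -1.0
        for r in range(1, 5):
            for subset in itertools.combinations(range(4), r):
                m = cfs_merit(list(subset), su_fc, su_ff)
                if m > best_m:
                    best, best_m = subset, m
        assert chosen == {X.columns[i] for i in best}


class TestSelectTopFraction:
    def ranked(self, n):
        return RankedFeatureList([f"f{i}" for i in range(n)], list(range(n, 0, -1)))

    def test_paper_triple(self):
        assert len(select_top_fraction(self.ranked(468), 468, 0.05)) == 23
        assert len(select_top_fraction(self.ranked(114), 114, 0.40)) == 46
        assert len(select_top_fraction(self.ranked(84), 84, 0.30)) == 25

    def test_returns_prefix(self):
        assert select_top_fraction(self.ranked(10), 10, 0.2) == ["f0", "f1"]

    def test_zero_selection_rejected(self):
        with pytest.raises(ValueError):
            select_top_fraction(self.ranked(4), 4, 0.01)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            select_top_fraction(self.ranked(4), 4, 1.5)


class TestRankedFeatureList:
    def test_rejects_increasing_scores(self):
        with pytest.raises(ValueError):
            RankedFeatureList(["a", "b"], [0.1, 0.2])

    def test_rejects_duplicate_names(self):
        with pytest.raises(ValueError):
            RankedFeatureList(["a", "a"], [0.2, 0.1])


class TestStratifiedSplit:
    def test_paper_sizes(self):
        ids = [f"g{i}" for i in range(2674)]
        labels = ["up"] * 1600 + ["down"] * 1074
        split = stratified_split(ids, labels, 0.8, seed=1)
        assert len(split.train_ids) == 2139
        assert len(split.test_ids) == 535

    def test_per_class_largest_remainder(self):
        alloc = largest_remainder_allocation({"up": 1600, "down": 1074}, 2139)
        assert alloc == {"up": 1280, "down": 859}

    def test_small_case(self):
        split = stratified_split(
            [f"g{i}" for i in range(10)], ["up"] * 5 + ["down"] * 5, 0.8, seed=0
        )
        assert len(split.train_ids) == 8 and len(split.test_ids) == 2

    def test_disjoint_union(self):
        ids = [f"g{i}" for i in range(101)]
        labels = (["up"] * 41 + ["down"] * 60)
        split = stratified_split(ids, labels, 0.8, seed=9)
        assert set(split.train_ids) & set(split.test_ids) == set()
        assert sorted(split.train_ids + split.test_ids) == sorted(ids)

    def test_deterministic_given_seed(self):
        ids = [f"g{i}" for i in range(50)]
        labels = ["up"] * 25 + ["down"] * 25
        a = stratified_split(ids, labels, 0.8, seed=4)
        b = stratified_split(ids, labels, 0.8, seed=4)
        assert a.train_ids == b.train_ids

    def test_tiny_class_forced_to_training(self):
        ids = [f"g{i}" for i in range(11)]
        labels = ["up"] * 10 + ["down"]
        split = stratified_split(ids, labels, 0.8, seed=0)
        assert "g10" in split.train_ids

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(["a", "b"], ["up", "up"], 0.8, seed=0)


class TestMetrics:
    def test_worked_confusion_table(self):
        m = compute_metrics(40, 10, 20, 30)
        assert m["precision"] == pytest.approx(0.8)
        assert m["recall"] == pytest.approx(2 / 3, abs=1e-4)
        assert m["f_measure"] == pytest.approx(0.7273, abs=1e-4)
        # closed form MCC = (40*30 - 10*20) / sqrt(50*60*40*50)
        assert m["mcc"] == pytest.approx(1000 / math.sqrt(6_000_000))
        assert m["accuracy"] == pytest.approx(0.7)

    def test_perfect_prediction(self):
        m = compute_metrics(10, 0, 0, 10)
        assert m["accuracy"] == 1.0
        assert m["mcc"] == 1.0
        assert m["f_measure"] == 1.0

    def test_zero_denominator_flagged(self):
        m = compute_metrics(0, 0, 5, 5)
        assert m["precision"] == 0.0
        assert "precision" in m["flags"]

    def test_ranges(self, rng):
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(0, 40, 4)
            if tp + fp + fn + tn == 0:
                continue
            m = compute_metrics(int(tp), int(fp), int(fn), int(tn))
            for key in ("accuracy", "precision", "recall", "f_measure", "f_weighted"):
                assert 0.0 <= m[key] <= 1.0
            assert -1.0 <= m["mcc"] <= 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(-1, 0, 0, 1)


def brute_force_auc(scores, positives) -> float:
    """Exhaustive Mann-Whitney pair count; ties count one half."""
    pos = [s for s, p in zip(scores, positives) if p]
    neg = [s for s, p in zip(scores, positives) if not p]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], np.array([True, True, False, False]))
        assert auc == 1.0

    def test_all_equal_scores(self):
        auc, _ = roc_auc([0.5] * 6, np.array([True, False] * 3))
        assert auc == 0.5

    def test_worked_example(self):
        auc, _ = roc_auc([0.9, 0.4, 0.6, 0.1], np.array([True, True, False, False]))
        assert auc == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], np.array([True, True]))

    def test_accepts_string_labels(self):
        auc, _ = roc_auc([0.9, 0.1], np.array(["up", "down"]))
        assert auc == 1.0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        scores = np.round(rng.uniform(0, 1, n), 2)  # rounding forces ties
        pos = rng.random(n) < 0.5
        if pos.all() or not pos.any():
            pos[0] = ~pos[0]
        auc, _ = roc_auc(scores, pos)
        assert auc == pytest.approx(brute_force_auc(scores, pos), abs=1e-12)

    def test_roc_points_monotone(self, rng):
        scores = rng.uniform(0, 1, 100)
        pos = rng.random(100) < 0.4
        pos[0], pos[1] = True, False
        _, points = roc_auc(scores, pos)
        fprs = [p[0] for p in points]
        tprs = [p[1] for p in points]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)


class TestClassifiers:
    def separable(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)], "z": np.zeros(40)})
        y = np.array(["down"] * 20 + ["up"] * 20)
        return X, y

    def test_logistic_fits_separable(self):
        X, y = self.separable()
        model = train_classifier("logistic", X, y)
        assert (model.predict(X) == y).mean() == 1.0

    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_all_emit_valid_probabilities(self, name):
        X, y = self.separable()
        model = train_classifier(name, X, y, seed=3)
        p = model.prob_up(X)
        assert p.shape == (40,)
        assert np.all((0.0 <= p) & (p <= 1.0))
        assert p[:20].mean() < p[20:].mean()

    def test_unknown_name_rejected(self):
        X, y = self.separable()
        with pytest.raises(ValueError):
            train_classifier("svm", X, y)

    def test_missing_values_rejected(self):
        X, y = self.separable()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_classifier("logistic", X, y)

    def test_deterministic_given_seed(self):
        X, y = simulate_feature_matrix(n_genes=80, n_features=5, n_informative=2, seed=2)
        p1 = train_classifier("random_forest", X, y, seed=5).prob_up(X)
        p2 = train_classifier("random_forest", X, y, seed=5).prob_up(X)
        assert np.array_equal(p1, p2)


class TestCrossValidate:
    def test_perfect_feature_perfect_metrics(self):
        rng = np.random.default_rng(0)
        y = rng.permutation(["up"] * 30 + ["down"] * 30)
        X = pd.DataFrame({"perfect": (y == "up").astype(float)})
        report = cross_validate("logistic", X, y, folds=5, seed=1)
        assert report.pooled["f_measure"] == 1.0
        assert report.pooled["mcc"] == 1.0
        assert report.auc == 1.0

    def test_same_seed_identical(self):
        X, y = simulate_feature_matrix(n_genes=100, n_features=8, n_informative=3, seed=3)
        r1 = cross_validate("logistic", X.reset_index(drop=True), y.to_numpy(), folds=5, seed=7)
        r2 = cross_validate("logistic", X.reset_index(drop=True), y.to_numpy(), folds=5, seed=7)
        assert r1.pooled == r2.pooled and r1.auc == r2.auc

    def test_pooled_confusion_is_sum_of_folds(self):
        X, y = simulate_feature_matrix(n_genes=120, n_features=6, n_informative=2, seed=4)
        report = cross_validate("logistic", X.reset_index(drop=True), y.to_numpy(), folds=6, seed=2)
        for key in ("tp", "fp", "fn", "tn"):
            assert report.pooled[key] == sum(m[key] for m in report.fold_metrics)

    def test_in_fold_selection_records_features(self):
        X, y = simulate_feature_matrix(n_genes=100, n_features=10, n_informative=2, seed=5)
        report = cross_validate(
            "logistic",
            X.reset_index(drop=True),
            y.to_numpy(),
            folds=4,
            seed=0,
            selector="infogain",
            top_fraction=0.2,
        )
        assert len(report.selected_features) == 4
        assert all(len(f) == 2 for f in report.selected_features)

    def test_too_few_folds_rejected(self):
        X, y = simulate_feature_matrix(n_genes=20, n_features=2, n_informative=1, seed=6)
        with pytest.raises(ValueError):
            cross_validate("logistic", X.reset_index(drop=True), y.to_numpy(), folds=1)

    def test_stratified_folds_balanced(self):
        y = ["up"] * 40 + ["down"] * 60
        folds = stratified_folds(y, 10, seed=0)
        sizes = np.bincount(folds)
        assert sizes.min() >= 9 and sizes.max() <= 11
        for k in range(10):
            mask = folds == k
            ups = sum(1 for i in np.where(mask)[0] if y[i] == "up")
            assert 3 <= ups <= 5


class TestInfoGainRanking:
    def test_informative_features_rank_first(self):
        X, y = simulate_feature_matrix(
            n_genes=300, n_features=20, n_informative=4, effect_size=2.5, seed=8
        )
        ranked = rank_features_infogain(X, y)
        assert set(ranked.names[:4]) == {f"inf{j:03d}" for j in range(4)}
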