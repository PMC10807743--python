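"""PU labeling, inverse normal features, balanced forest, CV, AUROC and
F-threshold calibration."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from lncpath.predict import (
    BalancedRandomForest,
    CoinClassifier,
    OracleClassifier,
    PULabels,
    average_over_trials,
    build_feature_table,
    call_predictions,
    compute_auroc,
    cross_validate,
    f_statistic_curve,
    inverse_normal_transform,
    predict_pathway,
    select_threshold,
    train_balanced_forest,
)
from lncpath.simulate import PathwaySpec, SimulationConfig, simulate_catalog, simulate_expression
from oracles import auroc_pairwise


class TestInverseNormal:
    def test_three_point_example(self):
        out = inverse_normal_transform([3, 1, 2])
        expected = scipy.stats.norm.ppf([2.5 / 3, 0.5 / 3, 1.5 / 3])
        np.testing.assert_allclose(out, expected)
        np.testing.assert_allclose(out, [0.9674, -0.9674, 0.0], atol=1e-4)

    def test_median_of_odd_tiefree_input_is_zero(self, rng):
        v = rng.permutation(9).astype(float)
        out = inverse_normal_transform(v)
        assert out[np.argsort(v)[4]] == pytest.approx(0.0)

    def test_all_equal_maps_to_zeros(self):
        np.testing.assert_allclose(inverse_normal_transform([7.0] * 5), 0.0)

    def test_strictly_monotone_without_ties(self, rng):
        v = rng.normal(size=50)
        out = inverse_normal_transform(v)
        assert (np.argsort(out) == np.argsort(v)).all()

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([1.0])


class TestFeatureTable:
    def test_columns_are_rank_normalized(self, small_matrix):
        ft = build_feature_table(small_matrix)
        n = ft.shape[0]
        for c in ft.columns[:3]:
            col = ft[c].to_numpy()
            assert abs(col.mean()) < 0.2
            # tie-free column is exactly the normal quantile grid
            expected = np.sort(scipy.stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n))
            if len(np.unique(small_matrix.counts[c])) == n:
                np.testing.assert_allclose(np.sort(col), expected)

    def test_three_by_two_toy(self):
        from lncpath.de import ExpressionMatrix
        counts = pd.DataFrame(
            [[10, 5], [20, 1], [30, 9]],
            index=["g1", "g2", "g3"], columns=["s1", "s2"],
        )
        meta = pd.DataFrame({"condition": ["a", "b"]}, index=["s1", "s2"])
        ft = build_feature_table(ExpressionMatrix(counts=counts, sample_metadata=meta))
        grid = scipy.stats.norm.ppf([0.5 / 3, 1.5 / 3, 2.5 / 3])
        for c in ft.columns:
            np.testing.assert_allclose(np.sort(ft[c]), grid, atol=1e-9)

    def test_gene_permutation_equivariance(self, small_matrix):
        ft = build_feature_table(small_matrix)
        perm = small_matrix.counts.index[::-1]
        from lncpath.de import ExpressionMatrix
        m2 = ExpressionMatrix(
            counts=small_matrix.counts.loc[perm],
            sample_metadata=small_matrix.sample_metadata,
        )
        ft2 = build_feature_table(m2)
        pd.testing.assert_frame_equal(ft.loc[perm], ft2)


def _toy_features(n_pos=20, n_neg=500, n_unl=50, n_feat=30, signal=1.5, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg + n_unl
    X = rng.normal(size=(n, n_feat))
    X[:n_pos] += signal
    X[n_pos + n_neg:] += signal  # unlabeled genes carry the positive pattern
    ids = (
        [f"POS{i}" for i in range(n_pos)]
        + [f"NEG{i}" for i in range(n_neg)]
        + [f"UNL{i}" for i in range(n_unl)]
    )
    features = pd.DataFrame(X, index=ids, columns=[f"s{j}" for j in range(n_feat)])
    labels = PULabels(
        positive={f"POS{i}" for i in range(n_pos)},
        negative={f"NEG{i}" for i in range(n_neg)},
        unlabeled={f"UNL{i}" for i in range(n_unl)},
        lncrna={f"UNL{i}" for i in range(n_unl)},
    )
    return features, labels


class TestBalancedForest:
    def test_every_tree_trains_on_equal_classes(self):
        features, labels = _toy_features()
        model = train_balanced_forest(features, labels, n_trees=25, seed=1)
        y = labels.label_vector(features.index)
        y_lab = y[y >= 0]
        for idx in model.tree_indices_:
            assert len(idx) == 40  # 20 positives + 20 sampled negatives
            assert y_lab[idx].sum() == 20
            neg = idx[y_lab[idx] == 0]
            assert len(set(neg)) == len(neg)  # without replacement

    def test_identical_feature_rows_get_identical_scores(self):
        features, labels = _toy_features()
        # duplicate a positive gene as an unlabeled instance
        features.loc["UNL0"] = features.loc["POS0"]
        model = train_balanced_forest(features, labels, n_trees=30, seed=3)
        s = model.predict_score(features.to_numpy())
        ids = list(features.index)
        assert s[ids.index("UNL0")] == s[ids.index("POS0")]

    def test_scores_bounded_and_deterministic(self):
        features, labels = _toy_features()
        s1 = train_balanced_forest(features, labels, n_trees=20, seed=5).predict_score(
            features.to_numpy()
        )
        s2 = train_balanced_forest(features, labels, n_trees=20, seed=5).predict_score(
            features.to_numpy()
        )
        np.testing.assert_array_equal(s1, s2)
        assert (s1 >= 0).all() and (s1 <= 1).all()

    def test_more_positives_than_negatives_rejected(self):
        features, labels = _toy_features(n_pos=30, n_neg=10)
        with pytest.raises(ValueError, match="positives"):
            train_balanced_forest(features, labels)

    def test_planted_unlabeled_outscore_null_unlabeled(self):
        features, labels = _toy_features(signal=1.0, seed=7)
        # half the unlabeled get the pattern, half are re-randomized to null
        rng = np.random.default_rng(8)
        null_ids = [f"UNL{i}" for i in range(25, 50)]
        features.loc[null_ids] = rng.normal(size=(25, features.shape[1]))
        model = train_balanced_forest(features, labels, n_trees=50, seed=9)
        s = pd.Series(model.predict_score(features.to_numpy()), index=features.index)
        assert s[[f"UNL{i}" for i in range(25)]].mean() > s[null_ids].mean()


class TestAuroc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([0.9, 0.8, 0.4, 0.2], [1, 1, 0, 0], 1.0),
            ([0.9, 0.8, 0.4, 0.2], [0, 0, 1, 1], 0.0),
            ([0.9, 0.7, 0.6, 0.3], [1, 0, 1, 0], 0.75),
        ],
    )
    def test_hand_examples(self, scores, labels, expected):
        assert compute_auroc(scores, labels) == pytest.approx(expected)

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 200))
            scores = rng.integers(0, 6, size=n) / 5.0  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert compute_auroc(scores, labels) == pytest.approx(
                auroc_pairwise(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auroc([0.1, 0.2], [1, 1])


class TestCrossValidate:
    def test_oracle_classifier_scores_one_everywhere(self):
        features, labels = _toy_features(n_pos=30, n_neg=300, signal=0.0)
        y = labels.label_vector(features.index)
        mask = y >= 0
        oracle = OracleClassifier.from_data(features.to_numpy()[mask], y[mask])
        cv = cross_validate(features, labels, classifier=oracle, k=10, seed=0)
        assert cv.pooled_auroc == 1.0
        assert all(a == 1.0 for a in cv.fold_aurocs)

    def test_coin_classifier_is_null(self):
        features, labels = _toy_features(n_pos=500, n_neg=500, n_unl=0, signal=2.0)
        cv = cross_validate(features, labels, classifier=CoinClassifier(seed=11), k=10, seed=0)
        assert 0.45 <= cv.pooled_auroc <= 0.55

    def test_fewer_positives_than_folds_rejected(self):
        features, labels = _toy_features(n_pos=5, n_neg=100)
        with pytest.raises(ValueError):
            cross_validate(features, labels, k=10, seed=0)


class TestTrialAveraging:
    def test_single_trial_mean_is_that_trial(self):
        features, labels = _toy_features(n_neg=100)
        pred = average_over_trials(features, labels, n_trials=1, n_trees=10, base_seed=2)
        np.testing.assert_array_equal(
            pred.mean_score.to_numpy(), pred.trial_scores.iloc[:, 0].to_numpy()
        )

    def test_same_base_seed_reproduces(self):
        features, labels = _toy_features(n_neg=100)
        p1 = average_over_trials(features, labels, n_trials=3, n_trees=10, base_seed=4)
        p2 = average_over_trials(features, labels, n_trials=3, n_trees=10, base_seed=4)
        pd.testing.assert_frame_equal(p1.trial_scores, p2.trial_scores)

    def test_trial_mean_variance_shrinks(self):
        features, labels = _toy_features(n_neg=100, signal=0.5)
        few = average_over_trials(features, labels, n_trials=2, n_trees=10, base_seed=0)
        many = average_over_trials(features, labels, n_trials=8, n_trees=10, base_seed=0)
        # SE of the unlabeled genes' trial mean shrinks roughly as 1/sqrt(n)
        se_few = (few.trial_scores.std(axis=1) / np.sqrt(2)).loc[sorted(labels.unlabeled)].mean()
        se_many = (many.trial_scores.std(axis=1) / np.sqrt(8)).loc[sorted(labels.unlabeled)].mean()
        assert se_many < se_few


class TestFThreshold:
    def test_four_instance_curve_and_selection(self):
        scores = [0.9, 0.8, 0.7, 0.1]
        labels = [1, 0, 1, 0]
        curve = f_statistic_curve(scores, labels)
        by_thr = {t: f for t, _, _, f in curve}
        assert by_thr[0.9] == pytest.approx(2 / 3)
        assert by_thr[0.7] == pytest.approx(0.8)
        assert by_thr[0.1] == pytest.approx(2 / 3)
        thr, max_f = select_threshold(curve)
        assert max_f == pytest.approx(0.8)
        assert thr == pytest.approx(0.69)

    def test_perfect_separation_reaches_f_one(self):
        curve = f_statistic_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        _, max_f = select_threshold(curve)
        assert max_f == 1.0

    def test_all_negative_labels_give_zero_f(self):
        curve = f_statistic_curve([0.5, 0.4], [0, 0])
        assert all(f == 0.0 for _, _, _, f in curve)

    def test_threshold_clipped_at_zero(self):
        curve = [(0.005, 1.0, 1.0, 1.0)]
        thr, _ = select_threshold(curve)
        assert thr == 0.0

    def test_tied_max_f_takes_lower_threshold(self):
        curve = [(0.9, 1.0, 0.5, 2 / 3), (0.6, 1.0, 0.5, 2 / 3), (0.2, 0.5, 1.0, 2 / 3)]
        thr, _ = select_threshold(curve)
        assert thr == pytest.approx(0.19)


class TestCallPredictions:
    def test_impossible_threshold_gives_empty_set(self):
        features, labels = _toy_features(n_neg=100)
        pred = average_over_trials(features, labels, n_trials=1, n_trees=10, base_seed=0)
        pred.threshold = 1.01
        called = call_predictions(pred, labels)
        assert called[pred.pathway] == set()

    def test_multi_pathway_membership_and_unique_total(self):
        from lncpath.predict import prediction_summary
        sets = {"A": {"L1", "L2"}, "B": {"L2", "L3"}}
        summary = prediction_summary(sets)
        assert summary["per_pathway"] == {"A": 2, "B": 2}
        assert summary["n_multi_pathway"] == 1
        assert summary["n_unique"] == 3

    def test_planted_signal_recovered_on_simulation(self):
        """With strong planted signal and ~200 samples the called lncRNA set
        is strongly enriched for the planted ones."""
        cfg = SimulationConfig(
            n_protein_coding=600, n_lncrna=150,
            pathways=[PathwaySpec("P", 60, 30)],
            n_samples_per_condition=34,  # ~200 samples over stim/unstim
            effect_size=2.0, seed=12,
        )
        catalog, truth = simulate_catalog(cfg)
        matrix = simulate_expression(catalog, truth, cfg)
        features = build_feature_table(matrix)
        labels = PULabels.from_catalog(catalog, truth.pathway_members["P"])
        pred = predict_pathway(features, labels, pathway="P",
                               n_trials=5, n_trees=100, base_seed=3)
        from lncpath.predict import planted_recall_enrichment
        recall, enr = planted_recall_enrichment(
            pred.predicted, truth.planted_lncrnas["P"], labels.lncrna
        )
        assert recall >= 0.6
        assert enr.p_value < 1e-6
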