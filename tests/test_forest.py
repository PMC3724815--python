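"""Forest training, OOB estimates, importance, tuning, selection, dependence."""

import numpy as np
import pandas as pd
import pytest

from mirforest import (
    FeatureTable,
    RFConfig,
    forward_feature_selection,
    partial_dependence,
    predict,
    rank_features_by_gini,
    train_forest,
    tune_mtry,
)
from mirforest.features import LABEL_NON_TARGET, LABEL_TARGET
from mirforest.forest import WEIGHTED_PRESET


@pytest.fixture(scope="module")
def separable_table(small_table):
    """Table where alignment_score alone separates the classes perfectly
    and every other feature is uninformative (constant)."""
    from mirforest.features import NUMERIC_FEATURES, POSITION_FEATURES

    frame = small_table.frame.copy()
    frame[NUMERIC_FEATURES] = 0.0
    frame[POSITION_FEATURES] = "ABSENT"
    is_pos = frame["label"] == LABEL_TARGET
    frame["alignment_score"] = np.where(is_pos, 100.0, 20.0)
    return FeatureTable(frame)


def test_validation_errors(small_table):
    one_class = FeatureTable(
        small_table.frame[small_table.frame["label"] == LABEL_TARGET].reset_index(
            drop=True
        )
    )
    with pytest.raises(ValueError, match="single class"):
        train_forest(one_class, RFConfig(n_trees=10))
    tiny = FeatureTable(small_table.frame.iloc[:5].reset_index(drop=True))
    with pytest.raises(ValueError, match="10"):
        train_forest(tiny, RFConfig(n_trees=10))
    with pytest.raises(ValueError, match="mtry"):
        train_forest(small_table, RFConfig(n_trees=10, mtry=10_000))
    with pytest.raises(ValueError):
        RFConfig(n_trees=0)
    with pytest.raises(ValueError):
        RFConfig(class_weights={"TARGET": -1.0, "NON_TARGET": 1.0})


def test_separable_data_low_oob_error(separable_table):
    forest = train_forest(separable_table, RFConfig(n_trees=200, rng_seed=0))
    assert forest.oob_error <= 0.05


def test_permuted_labels_near_majority_rate(small_table):
    rng = np.random.default_rng(0)
    frame = small_table.frame.copy()
    frame["label"] = rng.permutation(frame["label"].to_numpy())
    forest = train_forest(FeatureTable(frame), RFConfig(n_trees=300, rng_seed=0))
    majority = frame["label"].value_counts(normalize=True).max()
    oob_accuracy = 1.0 - forest.oob_error
    assert abs(oob_accuracy - majority) <= 0.10


class TestPredict:
    def test_duplicated_row_same_probability(self, small_forest, small_table):
        doubled = FeatureTable(
            pd.concat([small_table.frame, small_table.frame.iloc[[0]]])
            .reset_index(drop=True)
        )
        preds = predict(small_forest, doubled)
        assert preds["probability"].iloc[0] == preds["probability"].iloc[-1]

    def test_hard_class_is_strictly_greater_rule(self, small_table):
        # two trees force probabilities into {0, 0.5, 1}: a tied vote at the
        # 0.5 threshold must be classified NON_TARGET
        forest = train_forest(small_table, RFConfig(n_trees=2, rng_seed=3))
        preds = predict(forest, small_table)
        assert (preds["probability"] == 0.5).any()
        expected = np.where(preds["probability"] > 0.5, LABEL_TARGET, LABEL_NON_TARGET)
        assert (preds["predicted"] == expected).all()

    def test_class_separation_in_probabilities(self, small_forest, small_table):
        preds = predict(small_forest, small_table)
        labels = small_table.labels.to_numpy()
        mean_pos = preds["probability"][labels == LABEL_TARGET].mean()
        mean_neg = preds["probability"][labels == LABEL_NON_TARGET].mean()
        assert mean_pos > mean_neg

    def test_schema_mismatch_names_missing_features(self, small_forest, small_table):
        from mirforest.forest import _check_schema

        broken = type("Tbl", (), {"frame": small_table.frame.drop(columns=["mfe_seed"])})()
        with pytest.raises(ValueError, match="mfe_seed"):
            _check_schema(broken, small_forest.feature_names)

    def test_reproducible_given_seed(self, small_table):
        a = train_forest(small_table, RFConfig(n_trees=50, rng_seed=9))
        b = train_forest(small_table, RFConfig(n_trees=50, rng_seed=9))
        pa = predict(a, small_table)["probability"]
        pb = predict(b, small_table)["probability"]
        assert (pa == pb).all()


class TestGiniRanking:
    def test_covers_all_features_non_increasing(self, small_forest):
        ranking = rank_features_by_gini(small_forest)
        assert len(ranking) == 34
        values = [v for _, v in ranking]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(v >= 0 for v in values)

    def test_planted_signal_ranked_first(self, separable_table):
        forest = train_forest(separable_table, RFConfig(n_trees=200, rng_seed=0))
        assert rank_features_by_gini(forest)[0][0] == "alignment_score"

    def test_importances_sum_over_encoded_columns(self, small_forest):
        assert small_forest.gini_importance.sum() == pytest.approx(1.0, abs=1e-9)


class TestTuneMtry:
    def test_singleton_grid(self, small_table):
        chosen, profile = tune_mtry(
            small_table, RFConfig(n_trees=30, rng_seed=0), grid=[1], k=3, repeats=1
        )
        assert chosen == 1 and len(profile) == 1

    def test_one_se_rule_prefers_simpler_model(self, small_table):
        chosen, profile = tune_mtry(
            small_table,
            RFConfig(n_trees=60, rng_seed=0),
            grid=[2, 6, 12, 24],
            k=3,
            repeats=2,
        )
        argmax = int(profile.loc[profile["mean_auc"].idxmax(), "mtry"])
        assert chosen <= argmax

    def test_out_of_range_values_dropped(self, small_table):
        chosen, profile = tune_mtry(
            small_table, RFConfig(n_trees=30, rng_seed=0), grid=[4, 10_000],
            k=3, repeats=1,
        )
        assert list(profile["mtry"]) == [4]


class TestForwardSelection:
    def test_profile_and_identity_at_full_size(self, small_table):
        cfg = RFConfig(n_trees=80, rng_seed=4)
        ranking = [
            n for n, _ in rank_features_by_gini(train_forest(small_table, cfg))
        ]
        profile, k = forward_feature_selection(small_table, cfg, ranking)
        assert len(profile) == 34
        assert 1 <= k <= 34
        # metrics at k = p equal a direct all-feature forest's OOB metrics
        direct = train_forest(small_table, cfg, feature_names=ranking)
        full_row = profile.iloc[-1]
        y = small_table.labels.to_numpy()
        pred = np.where(direct.oob_proba > 0.5, LABEL_TARGET, LABEL_NON_TARGET)
        acc = 100.0 * np.mean(pred == y)
        assert full_row["acc"] == pytest.approx(acc)

    def test_planted_informative_features_found_early(self, separable_table):
        cfg = RFConfig(n_trees=80, rng_seed=4)
        ranking = [
            n for n, _ in rank_features_by_gini(train_forest(separable_table, cfg))
        ]
        profile, k = forward_feature_selection(separable_table, cfg, ranking)
        assert k <= 8


class TestPartialDependence:
    def test_matches_brute_force(self, small_forest, small_table):
        sub = FeatureTable(small_table.frame.iloc[:25].reset_index(drop=True))
        prof = partial_dependence(small_forest, "position_2", sub)
        for _, row in prof.iterrows():
            forced = FeatureTable(sub.frame.copy())
            forced.frame["position_2"] = row["value"]
            expected = predict(small_forest, forced)["probability"].mean()
            assert row["mean_probability"] == pytest.approx(expected)

    def test_ignored_feature_gives_flat_profile(self, separable_table):
        # count_gap_seed is constant here, so no tree can split on it
        forest = train_forest(separable_table, RFConfig(n_trees=100, rng_seed=0))
        if forest.gini_importance["count_gap_seed"] == 0.0:
            prof = partial_dependence(forest, "count_gap_seed", separable_table)
            assert prof["mean_probability"].max() - prof["mean_probability"].min() < 1e-6

    def test_monotone_planted_effect(self, separable_table):
        forest = train_forest(separable_table, RFConfig(n_trees=100, rng_seed=0))
        prof = partial_dependence(forest, "alignment_score", separable_table)
        vals = prof.sort_values("value")["mean_probability"].to_numpy()
        assert (np.diff(vals) >= -1e-9).all()

    def test_unknown_feature(self, small_forest, small_table):
        with pytest.raises(KeyError):
            partial_dependence(small_forest, "not_a_feature", small_table)


def test_class_weight_direction(small_table):
    """Raising the NON_TARGET penalty must not lower OOB specificity."""
    y = small_table.labels.to_numpy()
    for seed in (0, 1, 2):
        plain = train_forest(small_table, RFConfig(n_trees=200, rng_seed=seed))
        weighted = train_forest(
            small_table,
            RFConfig(n_trees=200, rng_seed=seed, class_weights=dict(WEIGHTED_PRESET)),
        )
        spe_plain = 1.0 - plain.oob_error_per_class[LABEL_NON_TARGET]
        spe_weighted = 1.0 - weighted.oob_error_per_class[LABEL_NON_TARGET]
        assert spe_weighted >= spe_plain - 1e-9


def test_oob_error_stabilizes_with_ensemble_size(small_table):
    """OOB error varies less across seeds at 500 trees than at 100 trees."""
    def spread(n_trees):
        errs = [
            train_forest(small_table, RFConfig(n_trees=n_trees, rng_seed=s)).oob_error
            for s in range(6)
        ]
        return np.var(errs)

    assert spread(500) <= spread(100)
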