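import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from ftirbone import metrics as mt
from ftirbone import model as md


def brute_force_auc(scores, labels):
    """Pairwise concordance oracle: ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation_gives_one(self):
        assert mt.auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert mt.auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_eight_point_fixture_matches_concordance_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.4, 0.2, 0.9]
        labels = [0, 0, 1, 1, 1, 0, 0, 1]
        assert mt.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            mt.auc([0.1, 0.9], [1, 1])

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_on_random_instances(self, data):
        n = data.draw(st.integers(4, 30))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        scores = data.draw(
            st.lists(
                st.floats(0, 1, allow_nan=False).map(lambda v: round(v, 2)),
                min_size=n,
                max_size=n,
            )
        )
        assert mt.auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )


class TestClassMetrics:
    @pytest.mark.parametrize(
        "precision,sensitivity,printed_f1",
        [(0.80, 0.96, 0.87), (0.88, 0.90, 0.89), (0.67, 0.56, 0.61)],
    )
    def test_harmonic_mean_reproduces_printed_cells(self, precision, sensitivity, printed_f1):
        cm = mt.ClassMetrics.from_precision_sensitivity(precision, sensitivity)
        assert round(cm.f1, 2) == printed_f1

    def test_equal_precision_sensitivity_gives_same_f1(self):
        assert mt.ClassMetrics.from_precision_sensitivity(0.9, 0.9).f1 == pytest.approx(0.9)

    def test_invariant_enforced_on_construction(self):
        with pytest.raises(ValueError):
            mt.ClassMetrics(0.8, 0.9, 0.5)

    def test_zero_denominators_warn_and_give_zero(self):
        with pytest.warns(UserWarning):
            cm = mt.class_metrics([0, 0, 0], [0, 0, 1], positive_class=1)
        assert cm.precision == 0.0 and cm.f1 == 0.0

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_f1_invariant_for_every_constructed_instance(self, p, s):
        cm = mt.ClassMetrics.from_precision_sensitivity(p, s)
        expected = 2 * p * s / (p + s) if p + s > 0 else 0.0
        assert cm.f1 == pytest.approx(expected, abs=1e-12)


class TestDownsampleBalance:
    @staticmethod
    def table(n0, n1):
        return pd.DataFrame(
            {"y": [0] * n0 + [1] * n1, "x": np.arange(n0 + n1, dtype=float)}
        )

    @pytest.mark.parametrize("seed", [0, 1, 2, 42])
    def test_45_22_always_balances_to_22_22(self, seed):
        out = md.downsample_balance(self.table(45, 22), "y", seed)
        assert out["y"].value_counts().to_dict() == {0: 22, 1: 22}

    def test_already_balanced_is_unchanged_in_counts(self):
        out = md.downsample_balance(self.table(10, 10), "y", 0)
        assert out["y"].value_counts().to_dict() == {0: 10, 1: 10}

    def test_same_seed_gives_identical_rows(self):
        a = md.downsample_balance(self.table(30, 12), "y", 7)
        b = md.downsample_balance(self.table(30, 12), "y", 7)
        pd.testing.assert_frame_equal(a, b)

    def test_sampling_without_replacement(self):
        out = md.downsample_balance(self.table(40, 15), "y", 3)
        assert not out.index.duplicated().any()

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            md.downsample_balance(self.table(10, 0), "y", 0)


class TestMrmrSelect:
    def test_label_copy_selected_first(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 80)
        X = pd.DataFrame(
            {
                "noise1": rng.standard_normal(80),
                "label_copy": y.astype(float),
                "noise2": rng.standard_normal(80),
            }
        )
        assert md.mrmr_select(X, y, k=1)[0] == "label_copy"

    def test_redundant_copy_is_skipped(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 120)
        a = y + 0.1 * rng.standard_normal(120)
        b = np.where(y == 1, rng.normal(1.0, 0.6, 120), rng.normal(-1.0, 0.6, 120))
        X = pd.DataFrame({"a": a, "a_copy": a.copy(), "b": b})
        assert set(md.mrmr_select(X, y, k=2)) == {"a", "b"}

    def test_k_at_least_n_features_returns_all(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        y = rng.integers(0, 2, 30)
        assert sorted(md.mrmr_select(X, y, k=10)) == list("abcd")

    def test_invalid_k_raises(self):
        with pytest.raises(ValueError):
            md.mrmr_select(pd.DataFrame({"a": [1.0, 2.0]}), [0, 1], k=0)


def separable_toy(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame(
        {
            "f0": y * 4.0 + 0.1 * rng.standard_normal(n),
            "f1": rng.standard_normal(n),
        }
    )
    return X, y


class TestFitClassifier:
    def test_separable_toy_reaches_training_auc(self):
        X, y = separable_toy()
        model = md.fit_classifier(X, y)
        assert mt.auc(model.predict_proba(X), y) >= 0.99

    def test_same_seed_identical_coefficients(self):
        X, y = separable_toy(seed=3)
        a = md.fit_classifier(X, y, md.BoosterParams(seed=5)).coefficients
        b = md.fit_classifier(X, y, md.BoosterParams(seed=5)).coefficients
        pd.testing.assert_series_equal(a, b)

    def test_nan_features_raise_naming_column(self):
        X, y = separable_toy()
        X.loc[3, "f1"] = np.nan
        with pytest.raises(ValueError, match="f1"):
            md.fit_classifier(X, y)

    def test_tree_booster_exposes_surrogate_coefficients(self):
        X, y = separable_toy(seed=9)
        model = md.fit_classifier(X, y, md.BoosterParams(booster_kind="tree", n_rounds=30))
        coef = model.coefficients
        assert set(coef.index) == {"f0", "f1"}
        assert abs(coef["f0"]) > abs(coef["f1"])

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            md.BoosterParams(learning_rate=0.0)
        with pytest.raises(ValueError):
            md.BoosterParams(l1_weight=-1.0)


class TestCrossValidatedEval:
    @staticmethod
    def signal_table(n=80, strength=3.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        y = rng.binomial(1, expit(strength * x))
        return pd.DataFrame(
            {"x": x, "noise": rng.standard_normal(n), "y": y}
        )

    def test_planted_signal_gives_high_auc(self):
        tbl = self.signal_table(strength=4.0, seed=1)
        ev = md.cross_validated_eval(tbl, ["x", "noise"], "y", n_repeats=5, cv_folds=4)
        assert ev.auc >= 0.85

    def test_metrics_in_unit_interval_and_reproducible(self):
        tbl = self.signal_table(seed=2)
        a = md.cross_validated_eval(tbl, ["x", "noise"], "y", n_repeats=3, cv_folds=3, seed=9)
        b = md.cross_validated_eval(tbl, ["x", "noise"], "y", n_repeats=3, cv_folds=3, seed=9)
        assert a == b
        for v in (a.auc, a.accuracy, *[m.f1 for m in a.per_class.values()]):
            assert 0.0 <= v <= 1.0

    def test_no_signal_auc_near_half(self):
        aucs = []
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            tbl = pd.DataFrame(
                {"x": rng.standard_normal(120), "noise": rng.standard_normal(120),
                 "y": rng.integers(0, 2, 120)}
            )
            aucs.append(
                md.cross_validated_eval(tbl, ["x", "noise"], "y",
                                        n_repeats=4, cv_folds=3, seed=s).auc
            )
        assert 0.4 <= np.mean(aucs) <= 0.6

    def test_class_smaller_than_folds_suggests_fewer_folds(self):
        tbl = self.signal_table(n=20)
        tbl["y"] = [1] * 3 + [0] * 17
        with pytest.raises(ValueError, match="cv_folds"):
            md.cross_validated_eval(tbl, ["x"], "y", cv_folds=5)


class TestExtractImportances:
    def test_retention_and_ordering(self):
        coef = pd.Series({"a": 0.3, "b": -0.25, "c": 0.1})
        out = md.extract_importances(coef)
        assert out["feature"].tolist() == ["a", "b", "c"]
        assert out["retained"].tolist() == [True, True, False]

    def test_all_below_threshold_warns(self):
        with pytest.warns(UserWarning, match="retention"):
            out = md.extract_importances(pd.Series({"a": 0.1, "b": -0.05}))
        assert not out["retained"].any()

    def test_non_model_input_raises(self):
        with pytest.raises(ValueError):
            md.extract_importances({"a": 0.3})

    def test_fitted_model_coefficients_flow_through(self):
        X, y = separable_toy(seed=4)
        model = md.fit_classifier(X, y)
        out = md.extract_importances(model)
        assert out.iloc[0]["feature"] == "f0"
        assert out.iloc[0]["retained"]
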