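import numpy as np
import pandas as pd
import pytest

from cogload import models as mdl


def class_shift_features(
    rng, n_per_class=60, classes=("baseline", "visual", "code"), shift=2.0, n_noise=5
):
    """Gaussian feature table with one informative column per contrast."""
    rows, labels = [], []
    for ci, cls in enumerate(classes):
        block = rng.normal(0, 1, (n_per_class, n_noise + 1))
        block[:, 0] += ci * shift
        rows.append(block)
        labels += [cls] * n_per_class
    x = pd.DataFrame(
        np.vstack(rows), columns=["signal"] + [f"noise{i}" for i in range(n_noise)]
    )
    return x, pd.Series(labels)


class TestLrDf:
    @pytest.mark.parametrize(
        "n_selected,n_classes,expected",
        [(12, 2, 12), (13, 2, 13), (14, 2, 14), (15, 3, 30), (1, 2, 1)],
    )
    def test_identity(self, n_selected, n_classes, expected):
        assert mdl.lr_df(n_selected, n_classes) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            mdl.lr_df(0, 2)
        with pytest.raises(ValueError):
            mdl.lr_df(3, 1)


class TestFitLogistic:
    def test_single_binary_predictor_matches_log_odds_ratio(self, rng):
        # 2x2 contingency: feature=1 raises the odds of class "b"
        counts = {(0, "a"): 40, (0, "b"): 10, (1, "a"): 15, (1, "b"): 35}
        feat, lab = [], []
        for (x, y), c in counts.items():
            feat += [x] * c
            lab += [y] * c
        x = pd.DataFrame({"f": feat})
        fit = mdl.fit_logistic(x, pd.Series(lab), "a", standardize=False)
        log_or = np.log((35 / 15) / (10 / 40))
        assert np.isclose(fit.params.loc["f", "b"], log_or, atol=1e-4)
        assert fit.df == 1

    def test_df_invariant_and_chi_square_positive(self, rng):
        x, y = class_shift_features(rng)
        fit = mdl.fit_logistic(x, y, "baseline")
        assert fit.kind == "multinomial"
        assert fit.df == mdl.lr_df(len(fit.selected_features), 3) == 12
        assert fit.chi_square > 0
        assert fit.model_p < 0.001

    def test_negative_coefficient_means_lower_odds_vs_reference(self, rng):
        n = 200
        f = rng.normal(0, 1, n)
        # high feature value -> reference class more likely
        p = 1 / (1 + np.exp(2.0 * f))
        y = np.where(rng.uniform(size=n) < p, "other", "ref")
        fit = mdl.fit_logistic(pd.DataFrame({"f": f}), pd.Series(y), "ref")
        assert fit.params.loc["f", "other"] < 0

    def test_no_predictors_is_null_model(self, rng):
        x, y = class_shift_features(rng, n_per_class=30)
        fit = mdl.fit_logistic(x, y, "baseline", feature_names=[])
        assert fit.chi_square == 0.0
        assert fit.df == 0

    def test_separation_triggers_flagged_fallback(self):
        x = pd.DataFrame({"f": np.r_[np.zeros(20), np.ones(20)]})
        y = pd.Series(["a"] * 20 + ["b"] * 20)
        fit = mdl.fit_logistic(x, y, "a")
        assert fit.regularized
        assert np.isfinite(fit.params.to_numpy()).all()


class TestBackwardElimination:
    def test_strong_predictor_retained_across_seeds(self):
        kept = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x, y = class_shift_features(
                rng, n_per_class=170, classes=("a", "b"), shift=1.5, n_noise=9
            )
            selected, _, _ = mdl.backward_eliminate(x, y, "a")
            kept += "signal" in selected
        assert kept >= 9  # 1 strong predictor among 9 noise columns, n = 340

    def test_all_noise_collapses_to_near_empty_model(self, rng):
        x = pd.DataFrame(rng.normal(0, 1, (200, 8)),
                         columns=[f"n{i}" for i in range(8)])
        y = pd.Series(rng.choice(["a", "b"], 200))
        selected, trace, fit = mdl.backward_eliminate(x, y, "a")
        assert len(selected) <= 3
        assert fit.chi_square < 15.0

    def test_trace_monotone_and_no_reentry(self, rng):
        x, y = class_shift_features(rng, n_per_class=50, n_noise=6)
        selected, trace, _ = mdl.backward_eliminate(x, y, "baseline")
        removed = [t["removed"] for t in trace]
        assert len(removed) == len(set(removed))
        assert set(removed).isdisjoint(selected)
        remaining = [t["remaining"] for t in trace]
        assert remaining == sorted(remaining, reverse=True)

    def test_chi_square_shrinks_as_features_leave(self, rng):
        x, y = class_shift_features(rng, n_per_class=60, n_noise=4)
        full = mdl.fit_logistic(x, y, "baseline")
        _, trace, final = mdl.backward_eliminate(x, y, "baseline")
        chis = [full.chi_square] + [t["chi_square"] for t in trace]
        assert all(b <= a + 1e-6 for a, b in zip(chis, chis[1:]))

    def test_aic_criterion_matches_exhaustive_search_on_separable_design(self, rng):
        from itertools import combinations

        x, y = class_shift_features(
            rng, n_per_class=120, classes=("a", "b"), shift=2.5, n_noise=3
        )
        selected, _, fit = mdl.backward_eliminate(x, y, "a", criterion="aic")

        def aic_of(cols):
            f = mdl.fit_logistic(x, y, "a", feature_names=list(cols))
            return -2 * f.llf + 2 * (f.df + 1)

        best = min(
            (aic_of(c) for r in range(1, 5) for c in combinations(x.columns, r))
        )
        assert np.isclose(aic_of(selected), best, atol=1e-6)

    def test_constant_feature_dropped_with_warning(self, rng):
        x, y = class_shift_features(rng, n_per_class=40)
        x["const_col"] = 1.0
        with pytest.warns(UserWarning, match="const_col"):
            selected, _, _ = mdl.backward_eliminate(x, y, "baseline")
        assert "const_col" not in selected


class TestEvaluate:
    def test_perfect_predictions_are_100(self):
        y = np.array(["a", "b", "a", "b"])
        m = mdl._metrics(y, y, ["a", "b"], "in-sample")
        assert m.accuracy == m.precision == m.recall == 100.0

    def test_confusion_matrix_arithmetic(self):
        # confusion [[8,2],[3,7]] by class order (a, b)
        y_true = np.array(["a"] * 10 + ["b"] * 10)
        y_pred = np.array(["a"] * 8 + ["b"] * 2 + ["a"] * 3 + ["b"] * 7)
        m = mdl._metrics(y_true, y_pred, ["a", "b"], "in-sample")
        assert np.isclose(m.accuracy, 75.0)
        assert np.isclose(m.precision, 100 * (8 / 11 + 7 / 9) / 2)
        assert np.isclose(m.recall, 75.0)

    def test_majority_predictor_is_chance_on_balanced_classes(self):
        y_true = np.array(["a", "b", "c"] * 30)
        y_pred = np.array(["a"] * 90)
        m = mdl._metrics(y_true, y_pred, ["a", "b", "c"], "in-sample")
        assert np.isclose(m.accuracy, 100 / 3, atol=0.1)

    def test_in_sample_beats_label_permutation_by_wide_margin(self, rng):
        x, y = class_shift_features(
            rng, n_per_class=75, classes=("baseline", "code"), shift=2.5
        )
        _, _, fit = mdl.backward_eliminate(x, y, "baseline")
        real = mdl.evaluate(fit, x, y).accuracy
        y_perm = pd.Series(rng.permutation(y.to_numpy()))
        _, _, fit_perm = mdl.backward_eliminate(x, y_perm, "baseline")
        permuted = mdl.evaluate(fit_perm, x, y_perm).accuracy
        assert real - permuted >= 20.0

    def test_row_shuffle_leaves_fit_unchanged(self, rng):
        x, y = class_shift_features(rng, n_per_class=40)
        fit = mdl.fit_logistic(x, y, "baseline")
        order = rng.permutation(len(y))
        fit2 = mdl.fit_logistic(
            x.iloc[order].reset_index(drop=True),
            y.iloc[order].reset_index(drop=True),
            "baseline",
        )
        assert np.allclose(fit.params, fit2.params, atol=1e-6)
        assert np.isclose(fit.chi_square, fit2.chi_square, atol=1e-6)

    def test_k_fold_runs_and_reports_sane_metrics(self, rng):
        x, y = class_shift_features(
            rng, n_per_class=40, classes=("a", "b"), shift=2.0, n_noise=2
        )
        _, _, fit = mdl.backward_eliminate(x, y, "a")
        m = mdl.evaluate(fit, x, y, scheme="k-fold", n_folds=3)
        assert 50.0 <= m.accuracy <= 100.0
        assert m.scheme == "k-fold"

    def test_nested_feature_set_does_not_hurt_in_sample_accuracy(self, rng):
        x, y = class_shift_features(rng, n_per_class=50, classes=("visual", "code"))
        fit_small = mdl.fit_logistic(x, y, "visual", feature_names=["signal"])
        acc_small = mdl.evaluate(fit_small, x, y).accuracy
        fit_full = mdl.fit_logistic(x, y, "visual")
        acc_full = mdl.evaluate(fit_full, x, y).accuracy
        assert acc_full >= acc_small - 1e-9

    def test_missing_class_rejected(self, rng):
        x, y = class_shift_features(rng, n_per_class=30, classes=("a", "b"))
        fit = mdl.fit_logistic(x, y, "a")
        with pytest.raises(ValueError, match="classes"):
            mdl.evaluate(fit, x, pd.Series(["a"] * len(y)))
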