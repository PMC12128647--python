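"""Discriminant tests: thresholding, t-tests, stepwise Wilks selection,
LDA (vs closed-form and sklearn oracles) and leave-one-out CV."""
import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis as SkLDA

from spermshape import discriminant as disc
from spermshape.synth import FertilityRecord


def _records(rates):
    return [FertilityRecord(ram_id=f"r{i}", conception_rate=v) for i, v in enumerate(rates)]


class TestThresholdGroups:
    def test_population_cutoff_arithmetic(self):
        # left-skewed conception rates standardized to mean 89.0 and
        # population SD 6.6 (bounded above so no rate exceeds 100)
        rng = np.random.default_rng(0)
        x = -rng.gamma(2.0, 1.0, size=68)
        rates = 89.0 + (x - x.mean()) / x.std(ddof=0) * 6.6
        assert rates.max() <= 100.0
        recs, cutoff = disc.threshold_groups(_records(rates))
        assert cutoff == pytest.approx(82.4, abs=1e-9)
        for r in recs:
            assert r.group == ("LF" if r.conception_rate < 82.4 else "AF")

    def test_ram_exactly_at_cutoff_is_af(self):
        # [0,0,2,2]: mean 1, population SD 1 -> cutoff exactly 0, so the
        # rams sitting right on the cutoff take the >= branch (AF)
        recs, cutoff = disc.threshold_groups(_records([0.0, 0.0, 2.0, 2.0]))
        assert cutoff == 0.0
        assert all(r.group == "AF" for r in recs)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            disc.threshold_groups(_records([90.0, 90.0, 90.0]))

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            disc.threshold_groups(_records([90.0, 80.0]))

    def test_dataframe_route(self):
        df = pd.DataFrame({"conception_rate": [95.0, 94.0, 60.0, 93.0]})
        out, cutoff = disc.threshold_groups(df)
        assert (out["group"] == ["AF", "AF", "LF", "AF"]).all()


class TestGroupTTest:
    def test_identical_groups(self):
        out = disc.group_ttest({"AF": [1.0, 2.0, 3.0], "LF": [1.0, 2.0, 3.0]})
        assert out["t"] == pytest.approx(0.0)
        assert out["p"] == pytest.approx(1.0)

    def test_clear_separation(self):
        out = disc.group_ttest({"AF": [11.0, 12.0, 13.0], "LF": [1.0, 2.0, 3.0]})
        assert out["p"] < 0.01

    def test_pooled_variance_closed_form(self):
        # {2,4,6} vs {1,3,5}: pooled s^2 = 4, t = 1 / (2*sqrt(2/3))
        out = disc.group_ttest({"a": [2.0, 4.0, 6.0], "b": [1.0, 3.0, 5.0]})
        assert out["t"] == pytest.approx(1.0 / (2.0 * np.sqrt(2.0 / 3.0)), rel=1e-12)
        assert out["df"] == 4
        assert out["mean_a"] == pytest.approx(4.0)
        assert out["sem_b"] == pytest.approx(2.0 / np.sqrt(3.0))

    def test_welch_variant_available(self):
        out = disc.group_ttest(
            {"a": [2.0, 4.0, 6.0, 8.0], "b": [1.0, 1.1, 0.9]}, equal_var=False
        )
        assert out["df"] < 4  # Welch df shrinks under unequal variances

    def test_tiny_group_errors(self):
        with pytest.raises(ValueError):
            disc.group_ttest({"a": [1.0], "b": [1.0, 2.0]})


def _noise_cohort(rng, n=56, p=38, signal_col=None, delta=3.0, n_lf=9):
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{j}" for j in range(p)]
    )
    y = pd.Series(["AF"] * (n - n_lf) + ["LF"] * n_lf)
    if signal_col is not None:
        X.loc[y == "LF", signal_col] += delta
    return X, y


class TestStepwiseSelect:
    def test_informative_feature_found_first(self):
        hits = 0
        n_seeds = 200
        for s in range(n_seeds):
            rng = np.random.default_rng(10_000 + s)
            X, y = _noise_cohort(rng, signal_col="f7")
            sel, trace = disc.stepwise_select(X, y)
            entered_first = next(t.feature for t in trace if t.action == "enter")
            hits += entered_first == "f7"
        assert hits >= 0.95 * n_seeds

    def test_pure_noise_false_selection_consistent_with_level(self):
        """First-round false entry on pure noise tracks 1-(1-entry_p)^k.

        Greedy best-of-k entry means a lenient 0.15 level almost always
        admits something from 38 noise candidates; at a strict 0.01 level
        the predicted no-entry rate (1-0.01)^38 ~= 0.68 must be visible.
        """
        empty_strict = 0
        counts_lenient = []
        n_seeds = 60
        for s in range(n_seeds):
            rng = np.random.default_rng(20_000 + s)
            X, y = _noise_cohort(rng)
            sel_strict, _ = disc.stepwise_select(X, y, entry_p=0.01, stay_p=0.01)
            empty_strict += len(sel_strict) == 0
            sel_len, _ = disc.stepwise_select(X, y)
            counts_lenient.append(len(sel_len))
        expected_empty = (1 - 0.01) ** 38
        assert abs(empty_strict / n_seeds - expected_empty) < 0.2
        # lenient level: selections happen but stay bounded well below the
        # candidate count (backward elimination keeps pruning)
        assert np.median(counts_lenient) <= 12
        assert max(counts_lenient) < 20

    def test_duplicate_feature_never_selected_twice(self):
        rng = np.random.default_rng(3)
        X, y = _noise_cohort(rng, p=10, signal_col="f2")
        X["f2_copy"] = X["f2"]
        sel, _ = disc.stepwise_select(X, y)
        assert not ({"f2", "f2_copy"} <= set(sel))

    def test_partial_f_matches_regression_oracle(self):
        """F-to-enter equals the partial F of an OLS on the group indicator."""
        rng = np.random.default_rng(4)
        X, y = _noise_cohort(rng, n=40, p=6, signal_col="f1", delta=1.0)
        y01 = (y == "LF").to_numpy(float)
        sel = ["f1", "f4"]
        cand = "f3"
        lam_s = disc._wilks_lambda(X[sel].to_numpy(), (y == "LF").to_numpy().astype(int))
        lam_b = disc._wilks_lambda(
            X[sel + [cand]].to_numpy(), (y == "LF").to_numpy().astype(int)
        )
        F_wilks, p_wilks = disc._partial_f(lam_s, lam_b, len(X), len(sel))
        # oracle: extra-sum-of-squares F test in the equivalent regression
        def rss(cols):
            A = np.column_stack([np.ones(len(X)), X[cols].to_numpy()])
            beta, *_ = np.linalg.lstsq(A, y01, rcond=None)
            r = y01 - A @ beta
            return float(r @ r)
        rss0, rss1 = rss(sel), rss(sel + [cand])
        df2 = len(X) - len(sel) - 2
        F_ols = (rss0 - rss1) / (rss1 / df2)
        assert F_wilks == pytest.approx(F_ols, rel=1e-9)

    def test_invalid_levels_rejected(self):
        rng = np.random.default_rng(0)
        X, y = _noise_cohort(rng, n=20, p=3)
        with pytest.raises(ValueError):
            disc.stepwise_select(X, y, entry_p=0.0)


class TestLinearDiscriminant:
    def _separable(self, rng, n=30, d=4.0):
        X = pd.DataFrame(rng.normal(size=(2 * n, 3)), columns=list("abc"))
        X.iloc[n:, 0] += d
        y = pd.Series(["AF"] * n + ["LF"] * n)
        return X, y

    def test_fisher_direction_oracle(self):
        rng = np.random.default_rng(7)
        X, y = self._separable(rng)
        m = disc.fit_lda(X, y)
        mu = m.means_
        w = np.linalg.solve(m.pooled_cov_, mu[1] - mu[0])
        direction = m.coef_[1] - m.coef_[0]
        # proportional up to scale
        scale = direction @ w / (w @ w)
        assert np.allclose(direction, scale * w, atol=1e-9 * np.abs(direction).max())

    def test_agreement_with_sklearn(self):
        rng = np.random.default_rng(11)
        X, y = self._separable(rng, d=2.0)
        ours = disc.fit_lda(X, y)
        sk = SkLDA(priors=[0.5, 0.5]).fit(X.to_numpy(), y.to_numpy())
        assert (ours.predict(X) == sk.predict(X.to_numpy())).all()

    def test_canonical_correlation_is_score_correlation(self):
        rng = np.random.default_rng(13)
        X, y = self._separable(rng, d=1.5)
        m = disc.fit_lda(X, y)
        score = m.decision_function(X)
        y01 = (y == "LF").to_numpy(float)
        r = abs(np.corrcoef(score, y01)[0, 1])
        assert m.canonical_correlation_ == pytest.approx(r, abs=1e-10)

    def test_identical_group_means_null(self):
        X = pd.DataFrame(np.tile(np.random.default_rng(5).normal(size=(12, 2)), (2, 1)),
                         columns=["a", "b"])
        y = pd.Series(["AF"] * 12 + ["LF"] * 12)
        m = disc.fit_lda(X, y)
        assert m.canonical_correlation_ == pytest.approx(0.0, abs=1e-10)
        assert m.p_value_ == pytest.approx(1.0, abs=1e-10)

    def test_separable_clouds_zero_training_error(self):
        rng = np.random.default_rng(17)
        X, y = self._separable(rng, d=8.0)
        m = disc.fit_lda(X, y)
        assert (m.predict(X) == y.to_numpy()).all()

    def test_singular_covariance_error(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        y = pd.Series(["AF", "AF", "LF", "LF"])
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            disc.fit_lda(X, y)

    def test_sklearn_estimator_api(self):
        est = disc.StepwiseLDA(entry_p=0.1)
        est2 = clone(est)
        assert est2.get_params()["entry_p"] == 0.1
        est2.set_params(entry_p=0.2)
        assert est2.get_params()["entry_p"] == 0.2
        rng = np.random.default_rng(19)
        X, y = self._separable(rng, d=5.0)
        est2.fit(X, y)
        assert est2.selected_features_
        assert (est2.predict(X) == y.to_numpy()).mean() > 0.95


class TestCrossValidation:
    def test_published_confusion_arithmetic(self):
        """39/47 and 6/9 correct give 83.0 / 66.7 / 19.6 (prints 20) percent."""
        cv = disc.CrossValidationReport(af_correct=39, af_total=47, lf_correct=6, lf_total=9)
        assert cv.sensitivity_pct == 83.0
        assert cv.specificity_pct == 66.7
        assert cv.overall_error_pct == 19.6
        assert cv.overall_error_pct_rounded == 20

    def test_perfectly_separable_zero_error(self):
        rng = np.random.default_rng(23)
        X = pd.DataFrame(rng.normal(size=(24, 2)), columns=["a", "b"])
        X.iloc[12:, 0] += 10.0
        y = pd.Series(["AF"] * 12 + ["LF"] * 12)
        cv = disc.loo_crossvalidate(X, y)
        assert cv.overall_error_pct == 0.0

    def test_row_order_irrelevant(self):
        rng = np.random.default_rng(29)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        X.iloc[10:, 0] += 1.0
        y = pd.Series(["AF"] * 10 + ["LF"] * 10)
        cv1 = disc.loo_crossvalidate(X, y)
        perm = rng.permutation(20)
        cv2 = disc.loo_crossvalidate(X.iloc[perm].reset_index(drop=True), y.iloc[perm])
        assert cv1.to_dict() == cv2.to_dict()

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(31)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        X.iloc[10:, 0] += 1.2
        y = pd.Series(["AF"] * 10 + ["LF"] * 10)
        cv = disc.loo_crossvalidate(X, y)
        swapped = y.map({"AF": "LF", "LF": "AF"})
        cv_swap = disc.loo_crossvalidate(X, swapped)
        assert cv.sensitivity_pct == cv_swap.specificity_pct
        assert cv.specificity_pct == cv_swap.sensitivity_pct

    def test_permuted_labels_near_majority_baseline_with_proportional_priors(self):
        """With proportional priors a signal-free model predicts mostly AF,
        so permuted-label LOO error sits near the 9/56 minority rate."""
        rng = np.random.default_rng(37)
        X = pd.DataFrame(rng.normal(size=(56, 3)), columns=["a", "b", "c"])
        errors = []
        for _ in range(40):
            y = pd.Series(rng.permutation(["AF"] * 47 + ["LF"] * 9))
            cv = disc.loo_crossvalidate(X, y, priors="proportional")
            errors.append(cv.overall_error)
        baseline = 9 / 56
        assert abs(np.mean(errors) - baseline) < 0.05


class TestReport:
    def test_error_rate_recomputed_from_counts(self):
        cv = disc.CrossValidationReport(39, 47, 6, 9)
        rep = disc.build_report(None, cv)
        assert rep["cross_validation"]["error_check"] == pytest.approx(11 / 56)
        assert rep["model"]["null_model"]

    def test_json_roundtrip(self, tmp_path):
        import json

        from spermshape import io

        cv = disc.CrossValidationReport(39, 47, 6, 9)
        rep = disc.build_report(None, cv, cutoff=82.4)
        io.write_json(rep, tmp_path / "r.json")
        back = json.loads((tmp_path / "r.json").read_text())
        assert back["cross_validation"] == json.loads(
            json.dumps(rep["cross_validation"])
        )
        assert back["fertility_cutoff"] == 82.4

    def test_markdown_contains_confusion_table(self):
        cv = disc.CrossValidationReport(39, 47, 6, 9)
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        X.iloc[10:, 0] += 3
        y = pd.Series(["AF"] * 10 + ["LF"] * 10)
        model = disc.StepwiseLDA().fit(X, y)
        md = disc.report_markdown(disc.build_report(model, cv))
        assert "83.0%" in md and "66.7%" in md and "20%" in md
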