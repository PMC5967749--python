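"""Logistic fitting (IRLS), AIC subset selection, explained deviance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from littoralhdm import (
    DegenerateSampleError,
    HabitatSpec,
    SyntheticCoastConfig,
    build_design,
    explained_deviance,
    fit_logistic,
    generate_environment,
    generate_habitat,
    predict_prob,
    select_model_aic,
)
from littoralhdm.hdm_fit import DesignMatrix, design_for, null_deviance


def _plain_design(X):
    """Intercept + raw columns as a DesignMatrix."""
    n = X.shape[0]
    M = np.column_stack([np.ones(n), X])
    names = ["intercept"] + [f"x{j}" for j in range(X.shape[1])]
    return DesignMatrix(M, tuple(names), tuple(names[1:]), {})


class TestFitLogistic:
    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        fit = fit_logistic(_plain_design(np.empty((100, 0))), y)
        assert fit.coef[0] == pytest.approx(logit(0.3), abs=1e-8)
        assert fit.d2 == pytest.approx(0.0, abs=1e-8)

    def test_two_by_two_log_odds_ratio(self):
        # binary predictor with cell counts a=20,b=30 (x=1), c=10,d=40 (x=0)
        x = np.r_[np.ones(50), np.zeros(50)]
        y = np.r_[np.ones(20), np.zeros(30), np.ones(10), np.zeros(40)]
        fit = fit_logistic(_plain_design(x[:, None]), y)
        expected = np.log((20 * 40) / (30 * 10))
        assert fit.coef[1] == pytest.approx(expected, abs=1e-6)

    def test_parameter_recovery_large_n(self):
        rng = np.random.default_rng(0)
        n = 16098
        X = rng.standard_normal((n, 2))
        beta = np.array([-0.5, 1.2, -0.8])
        y = (rng.random(n) < expit(beta[0] + X @ beta[1:])).astype(float)
        fit = fit_logistic(_plain_design(X), y)
        for j in range(3):
            assert abs(fit.coef[j] - beta[j]) < 3 * fit.se[j]

    def test_degenerate_response_raises(self):
        X = _plain_design(np.random.default_rng(1).standard_normal((20, 1)))
        with pytest.raises(DegenerateSampleError):
            fit_logistic(X, np.zeros(20))
        with pytest.raises(DegenerateSampleError):
            fit_logistic(X, np.ones(20))

    def test_deviance_ordering_and_aic(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 3))
        y = (rng.random(200) < expit(X[:, 0])).astype(float)
        fit = fit_logistic(_plain_design(X), y)
        assert fit.residual_deviance <= fit.null_deviance + 1e-8
        assert fit.aic == pytest.approx(fit.residual_deviance + 2 * 4)
        assert 0.0 <= fit.d2 <= 100.0

    def test_separation_flagged_not_fatal(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        fit = fit_logistic(_plain_design(x[:, None]), y)
        assert fit.separation_flag
        assert np.isfinite(fit.coef).all()

    def test_statsmodels_oracle_equivalence(self):
        """IRLS coefficients match an independent GLM fit to 1e-4."""
        import statsmodels.api as sm
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(60, 150))
            p = int(rng.integers(1, 4))
            X = rng.standard_normal((n, p))
            beta = rng.normal(0, 0.8, p + 1)
            y = (rng.random(n) < expit(beta[0] + X @ beta[1:])).astype(float)
            if y.min() == y.max():
                continue
            ours = fit_logistic(_plain_design(X), y)
            ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
            np.testing.assert_allclose(ours.coef, ref.params, atol=1e-4)
            assert ours.residual_deviance == pytest.approx(ref.deviance, abs=1e-6)


class TestDesign:
    def test_dummy_coding_reference_most_frequent(self, small_env):
        dm = build_design(small_env.df, ("geology",))
        ref = small_env.df["geology"].value_counts().index[0]
        assert dm.ref_levels["geology"] == ref
        assert f"geology[{ref}]" not in dm.columns

    def test_explicit_reference_levels(self, small_env):
        dm = build_design(small_env.df, ("substrate",), {"substrate": "natural"})
        assert dm.ref_levels["substrate"] == "natural"

    def test_aliased_columns_dropped(self):
        df = pd.DataFrame({
            "sst_avg": [17.0, 17.5, 18.0, 18.5] * 5,
            "wh_avg": [17.0, 17.5, 18.0, 18.5] * 5,  # duplicate of sst
            "wh_min": np.linspace(0.01, 0.05, 20),
        })
        with pytest.warns(UserWarning, match="aliased"):
            dm = build_design(df, ("sst_avg", "wh_avg", "wh_min"))
        assert len(dm.columns) == 3  # intercept + 2 independent columns

    def test_unseen_level_maps_to_reference(self, small_env):
        train = small_env.df[small_env.df["geology"].isin(["plutonic", "sedimentary"])]
        y = (np.arange(len(train)) % 2).astype(float)
        fit = fit_logistic(build_design(train, ("geology",)), y)
        with pytest.warns(UserWarning, match="unseen"):
            X = design_for(fit, small_env.df)
        assert X.shape == (small_env.n, len(fit.columns))


class TestSelection:
    def test_subset_count_two_candidates(self, widespread_dataset, monkeypatch):
        calls = []
        import littoralhdm.hdm_fit as hf
        orig = hf.fit_logistic
        monkeypatch.setattr(hf, "fit_logistic", lambda *a, **k: calls.append(1) or orig(*a, **k))
        y = widespread_dataset.habitat("wide")
        select_model_aic(("sst_avg", "wh_avg"), widespread_dataset.df, y)
        assert len(calls) == 4

    def test_selected_aic_not_worse_than_full_or_null(self, widespread_dataset):
        y = widespread_dataset.habitat("wide")
        df = widespread_dataset.df
        best = select_model_aic(("sst_avg", "wh_avg", "slope_class"), df, y)
        full = fit_logistic(build_design(df, ("sst_avg", "wh_avg", "slope_class")), y)
        null = fit_logistic(build_design(df, ()), y)
        assert best.aic <= full.aic + 1e-9
        assert best.aic <= null.aic + 1e-9

    def test_strong_single_signal_always_kept(self):
        """A habitat driven by SST alone always keeps sst_avg; spurious terms
        enter only at the usual AIC false-inclusion rate (~16 % per term)."""
        exact = 0
        for w in range(10):
            env = generate_environment(SyntheticCoastConfig(n=5000, seed=600 + w, ar_rho=0.9))
            spec = HabitatSpec("h", "widespread", 0.4, {"sst_avg": -4.0}, 0.0)
            ds = generate_habitat(env, spec, seed=700 + w)
            fit = select_model_aic(("sst_avg", "wh_avg", "substrate"), ds.df, ds.habitat("h"))
            assert "sst_avg" in fit.selected
            exact += fit.selected == ("sst_avg",)
        assert exact >= 5

    def test_pure_noise_prefers_intercept_only(self):
        """With no signal, the intercept-only model is selected most often."""
        rng = np.random.default_rng(8)
        wins = 0
        n_reps = 15
        for _ in range(n_reps):
            df = pd.DataFrame({
                "sst_avg": rng.standard_normal(400),
                "wh_avg": rng.standard_normal(400),
            })
            y = (rng.random(400) < 0.4).astype(float)
            fit = select_model_aic(("sst_avg", "wh_avg"), df, y)
            wins += fit.selected == ()
        assert wins > n_reps / 2

    def test_too_many_candidates_refused(self, widespread_dataset):
        y = widespread_dataset.habitat("wide")
        with pytest.raises(ValueError):
            select_model_aic(tuple(f"x{i}" for i in range(13)), widespread_dataset.df, y)


class TestExplainedDeviance:
    def test_direct_arithmetic(self):
        class F:
            null_deviance = 138.6
            residual_deviance = 103.95
        assert explained_deviance(F()) == pytest.approx(25.0)

    def test_intercept_only_zero(self):
        y = np.r_[np.ones(10), np.zeros(20)]
        fit = fit_logistic(_plain_design(np.empty((30, 0))), y)
        assert explained_deviance(fit) == pytest.approx(0.0, abs=1e-8)

    def test_perfect_separation_approaches_100(self):
        x = np.r_[np.zeros(40), np.ones(40)]
        fit = fit_logistic(_plain_design(x[:, None]), x.copy())
        assert explained_deviance(fit) > 99.0

    def test_zero_null_deviance_rejected(self):
        class F:
            null_deviance = 0.0
            residual_deviance = 0.0
        with pytest.raises(ValueError):
            explained_deviance(F())


class TestPredict:
    def test_zero_coefficients_give_half(self, widespread_dataset):
        y = widespread_dataset.habitat("wide")
        fit = fit_logistic(build_design(widespread_dataset.df, ("sst_avg",)), y)
        fit.coef = np.zeros_like(fit.coef)
        p = predict_prob(fit, widespread_dataset.df)
        np.testing.assert_allclose(p, 0.5)

    def test_mean_fitted_equals_training_prevalence(self, widespread_dataset):
        y = widespread_dataset.habitat("wide")
        fit = fit_logistic(build_design(widespread_dataset.df, ("sst_avg", "wh_avg")), y)
        p = predict_prob(fit, widespread_dataset.df)
        assert p.mean() == pytest.approx(y.mean(), abs=1e-6)

    def test_saturation_clipped_below_one(self, widespread_dataset):
        y = widespread_dataset.habitat("wide")
        fit = fit_logistic(build_design(widespread_dataset.df, ("sst_avg",)), y)
        fit.coef = np.array([500.0] + [0.0] * (len(fit.coef) - 1))
        p = predict_prob(fit, widespread_dataset.df)
        assert np.all(p >= 1 - 1e-6)
        assert np.all(p < 1.0)

    def test_missing_column_reported(self, widespread_dataset):
        y = widespread_dataset.habitat("wide")
        fit = fit_logistic(build_design(widespread_dataset.df, ("sst_avg",)), y)
        with pytest.raises(KeyError, match="sst_avg"):
            predict_prob(fit, widespread_dataset.df.drop(columns=["sst_avg"]))
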