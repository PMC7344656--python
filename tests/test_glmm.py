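"""Random-intercept logistic ML: design coding, likelihood oracles, fitting."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import carisk as ck
from carisk.glmm import (
    ModelSpec,
    build_design,
    fit_ml,
    lr_test,
    marginal_loglik,
    odds_ratios,
)

CONSTANTS = {"irsd": {"mean": 1000.0, "sd": 100.0},
             "access": {"mean": 0.002, "sd": 0.001}}


def _records(n_areas, n_per_area, seed, beta_access=0.0, tau2=0.3,
             intercept=-0.5, beta_male=0.4):
    rng = np.random.default_rng(seed)
    n = n_areas * n_per_area
    area = np.repeat(np.arange(n_areas), n_per_area)
    male = rng.integers(0, 2, n)
    irsd = rng.normal(1000, 100, n_areas)
    access = rng.normal(0.002, 0.001, n_areas)
    u = rng.normal(0, np.sqrt(tau2), n_areas)
    z_acc = (access - CONSTANTS["access"]["mean"]) / CONSTANTS["access"]["sd"]
    eta = intercept + beta_male * male + beta_access * z_acc[area] + u[area]
    y = (rng.random(n) < expit(eta)).astype(float)
    return pd.DataFrame({
        "area_id": [f"A{i:04d}" for i in area],
        "sex": np.where(male == 1, "male", "female"),
        "age_group": "18-29",
        "irsd": irsd[area],
        "access": access[area],
        "higher_risk": y,
    })


class TestBuildDesign:
    def test_reference_row_is_all_zero_but_intercept(self):
        df = pd.DataFrame({"area_id": ["A"], "sex": ["female"],
                           "age_group": ["18-29"], "irsd": [1000.0],
                           "access": [0.002], "higher_risk": [0.0]})
        spec = ModelSpec("higher_risk", ("intercept", "sex", "age_group",
                                        "irsd_z", "access_z"))
        d = build_design(df, spec, CONSTANTS)
        assert d.X.shape == (1, 10)
        assert list(d.X[0]) == [1.0] + [0.0] * 9

    def test_indicator_and_zscore_coding(self):
        df = pd.DataFrame({"area_id": ["A"], "sex": ["male"],
                           "age_group": ["80+"], "irsd": [900.0],
                           "access": [0.002], "higher_risk": [1.0]})
        spec = ModelSpec("higher_risk", ("intercept", "sex", "age_group",
                                        "irsd_z", "access_z"))
        d = build_design(df, spec, CONSTANTS)
        row = dict(zip(d.columns, d.X[0]))
        assert row["male"] == 1.0
        assert row["age_80+"] == 1.0
        assert sum(v for k, v in row.items() if k.startswith("age_")) == 1.0
        assert row["irsd_z"] == pytest.approx(-1.0)
        assert row["access_z"] == pytest.approx(0.0)

    def test_column_count_for_sex_age_model(self):
        df = _records(2, 5, 0)
        spec = ModelSpec("higher_risk", ("intercept", "sex", "age_group"))
        d = build_design(df, spec)
        assert d.X.shape[1] == 8  # 1 + 1 + 6

    def test_unseen_age_label_rejected(self):
        df = _records(2, 5, 0)
        df.loc[0, "age_group"] = "17-18"
        spec = ModelSpec("higher_risk", ("intercept", "age_group"))
        with pytest.raises(ValueError, match="age-band"):
            build_design(df, spec)

    def test_zero_sd_rejected(self):
        df = _records(2, 5, 0)
        spec = ModelSpec("higher_risk", ("intercept", "irsd_z"))
        bad = {"irsd": {"mean": 1000.0, "sd": 0.0}}
        with pytest.raises(ValueError, match="SD"):
            build_design(df, spec, bad)


class TestMarginalLoglik:
    def test_sigma_zero_equals_ordinary_logistic(self):
        df = _records(5, 8, 1)
        spec = ModelSpec("higher_risk", ("intercept", "sex"))
        d = build_design(df, spec)
        beta = np.array([-0.2, 0.7])
        ours = marginal_loglik(beta, -np.inf, d)
        ref = float(sm.Logit(d.y, d.X).loglike(beta))
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_dense_trapezoid_oracle(self):
        """AGQ agrees with brute-force integration on a tiny fixture."""
        df = _records(3, 4, 2)
        spec = ModelSpec("higher_risk", ("intercept", "sex"), quadrature_order=15)
        d = build_design(df, spec)
        rng = np.random.default_rng(7)
        for _ in range(5):
            beta = rng.normal(0, 1, 2)
            sigma = float(rng.uniform(0.2, 1.5))
            ours = marginal_loglik(beta, np.log(sigma), d, 15)
            z = np.linspace(-8, 8, 20001)
            phi = np.exp(-z ** 2 / 2) / np.sqrt(2 * np.pi)
            eta = d.X @ beta
            oracle = 0.0
            for g in range(d.n_groups):
                rows = d.group_idx == g
                e = eta[rows][:, None] + sigma * z[None, :]
                p = expit(e)
                lik = np.prod(np.where(d.y[rows][:, None] == 1, p, 1 - p), axis=0)
                oracle += np.log(np.trapezoid(lik * phi, z))
            assert ours == pytest.approx(oracle, abs=1e-6)

    def test_duplicating_areas_doubles_loglik(self):
        df = _records(4, 6, 3)
        dup = df.copy()
        dup["area_id"] = dup["area_id"] + "_copy"
        both = pd.concat([df, dup], ignore_index=True)
        spec = ModelSpec("higher_risk", ("intercept", "sex"))
        beta = np.array([0.1, -0.4])
        one = marginal_loglik(beta, np.log(0.6), build_design(df, spec))
        two = marginal_loglik(beta, np.log(0.6), build_design(both, spec))
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_invariant_to_row_permutation_and_relabelling(self):
        df = _records(6, 10, 4)
        spec = ModelSpec("higher_risk", ("intercept", "sex"))
        beta = np.array([0.3, 0.2])
        base = marginal_loglik(beta, np.log(0.5), build_design(df, spec))
        shuffled = df.sample(frac=1.0, random_state=0)
        relabel = {a: f"Z{i}" for i, a in enumerate(df["area_id"].unique())}
        shuffled["area_id"] = shuffled["area_id"].map(relabel)
        again = marginal_loglik(beta, np.log(0.5), build_design(shuffled, spec))
        assert again == pytest.approx(base, rel=1e-12)

    def test_nonfinite_parameters_rejected(self):
        d = build_design(_records(2, 4, 5), ModelSpec("higher_risk"))
        with pytest.raises(ValueError):
            marginal_loglik(np.array([np.nan]), 0.0, d)
        with pytest.raises(ValueError):
            marginal_loglik(np.array([0.0]), np.nan, d)


class TestFitMl:
    def test_null_variance_recovery(self):
        df = _records(60, 60, 6, tau2=0.0)
        spec = ModelSpec("higher_risk", ("intercept", "sex"))
        fit = fit_ml(spec, df)
        assert fit.tau2 < 0.01
        assert abs(fit.beta[1] - 0.4) < 3 * fit.se[1]

    def test_aic_identity(self, simulated_cohort):
        areas, records, _ = simulated_cohort
        const = ck.compute_standardization(areas)
        spec = ModelSpec("higher_risk", ("intercept", "access_z"), name="M2")
        fit = fit_ml(spec, records, const)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
        assert fit.n_params == len(fit.beta) + 1

    def test_quadrature_order_converged(self, simulated_cohort):
        areas, records, _ = simulated_cohort
        const = ck.compute_standardization(areas)
        f7 = fit_ml(ModelSpec("higher_risk", ("intercept",), quadrature_order=7),
                    records, const, compute_se=False)
        ll21 = marginal_loglik(
            f7.beta, np.log(np.sqrt(f7.tau2)),
            build_design(records, ModelSpec("higher_risk", ("intercept",))), 21)
        ll7 = marginal_loglik(
            f7.beta, np.log(np.sqrt(f7.tau2)),
            build_design(records, ModelSpec("higher_risk", ("intercept",))), 7)
        assert abs(ll21 - ll7) < 1e-4

    def test_single_class_outcome_rejected(self):
        df = _records(3, 5, 7)
        df["higher_risk"] = 1.0
        with pytest.raises(ValueError, match="single class"):
            fit_ml(ModelSpec("higher_risk"), df)

    def test_single_area_rejected(self):
        df = _records(1, 20, 8)
        with pytest.raises(ValueError, match="areas"):
            fit_ml(ModelSpec("higher_risk"), df)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available for the cross-check")
    def test_agrees_with_lme4_glmer(self, tmp_path):
        """Independent oracle: lme4's glmer at the same quadrature order."""
        df = _records(60, 30, 5, tau2=0.4, intercept=-0.8, beta_male=0.6)
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        fit = fit_ml(ModelSpec("higher_risk", ("intercept", "sex"),
                               quadrature_order=15), df)
        rcode = f"""
        suppressMessages(library(lme4))
        d <- read.csv('{csv}')
        d$male <- as.integer(d$sex == 'male')
        m <- glmer(higher_risk ~ male + (1 | area_id), data = d,
                   family = binomial, nAGQ = 15)
        cat(sprintf('%.8f %.8f %.8f %.8f %.8f %.8f\\n',
            logLik(m), as.numeric(VarCorr(m)$area_id),
            fixef(m)[1], fixef(m)[2],
            sqrt(diag(vcov(m)))[1], sqrt(diag(vcov(m)))[2]))
        """
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        ll, tau2, b0, b1, se0, se1 = map(float, out.stdout.split())
        assert fit.loglik == pytest.approx(ll, abs=1e-3)
        assert fit.tau2 == pytest.approx(tau2, abs=0.01)
        assert fit.beta[0] == pytest.approx(b0, abs=0.005)
        assert fit.beta[1] == pytest.approx(b1, abs=0.005)
        assert fit.se[0] == pytest.approx(se0, abs=0.005)
        assert fit.se[1] == pytest.approx(se1, abs=0.005)


class TestOddsRatios:
    def _fit_like(self, beta, se):
        spec = ModelSpec("higher_risk", ("intercept",), name="toy")
        from carisk.glmm import GlmmFit
        k = len(beta)
        return GlmmFit(spec=spec, columns=[f"b{i}" for i in range(k)],
                       beta=np.asarray(beta, float), se=np.asarray(se, float),
                       tau2=0.1, loglik=-10.0, aic=24.0, n_obs=100, n_groups=10,
                       n_params=k + 1, converged=True)

    def test_zero_coefficient(self):
        tab = odds_ratios(self._fit_like([0.0], [0.1]))
        assert tab["or"].iloc[0] == pytest.approx(1.0)
        assert tab["ci_low"].iloc[0] < 1.0 < tab["ci_high"].iloc[0]

    def test_published_scale_interval(self):
        # beta/se back-derived from a printed interval 0.94 (0.91-0.96)
        tab = odds_ratios(self._fit_like([-0.0635], [0.0138]))
        assert round(tab["or"].iloc[0], 2) == 0.94
        assert round(tab["ci_low"].iloc[0], 2) == 0.91
        assert round(tab["ci_high"].iloc[0], 2) == 0.96

    def test_exact_exponential(self):
        tab = odds_ratios(self._fit_like([np.log(2.0)], [0.05]))
        assert tab["or"].iloc[0] == pytest.approx(2.0, rel=1e-12)


class TestLrTest:
    def test_identical_fits_statistic_zero(self, simulated_cohort):
        areas, records, _ = simulated_cohort
        const = ck.compute_standardization(areas)
        fit = fit_ml(ModelSpec("higher_risk", ("intercept",), name="M1"),
                     records, const, compute_se=False)
        stat, df_, p = lr_test(fit, fit)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_critical_value(self):
        from scipy.stats import chi2
        assert chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_non_nested_rejected(self, simulated_cohort):
        areas, records, _ = simulated_cohort
        const = ck.compute_standardization(areas)
        m2 = fit_ml(ModelSpec("higher_risk", ("intercept", "access_z"), name="M2"),
                    records, const, compute_se=False)
        m3 = fit_ml(ModelSpec("higher_risk", ("intercept", "sex", "age_group"),
                              name="M3"), records, const, compute_se=False)
        with pytest.raises(ValueError, match="not nested"):
            lr_test(m2, m3)
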