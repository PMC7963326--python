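"""Tests of the random-intercept count GLMM: likelihood, fitting, inference."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cryptmosaic.glmm import (
    GLMMFit,
    GLMMSpec,
    fit_glmm,
    make_design,
    marginal_loglik,
    wald_summary,
)
from tests.conftest import toy_glmm_frame


def simulate_glmm_data(
    rng, n_groups=40, n_per=50, beta0=-3.0, beta1=np.log(1.2), sigma=0.2
):
    rows = []
    for i in range(n_groups):
        u = rng.normal(0.0, sigma) if sigma > 0 else 0.0
        x = 1.0 if i >= n_groups // 2 else 0.0
        expo = rng.poisson(14, n_per).clip(min=1)
        y = rng.poisson(np.exp(beta0 + beta1 * x + u) * expo)
        rows += [
            {"y": int(yy), "x": x, "expo": float(e), "mouse_id": f"m{i}"}
            for e, yy in zip(expo, y)
        ]
    return pd.DataFrame(rows)


SPEC = GLMMSpec(response="y", fixed_effects=["x"], exposure="expo", group="mouse_id")


class TestMarginalLoglik:
    def test_sigma_zero_equals_independent_poisson_logpmf(self, rng):
        df = toy_glmm_frame(rng)
        beta = np.array([-1.5, 0.4])
        ll = marginal_loglik(df, SPEC, beta, sigma_u=0.0)
        eta = beta[0] + beta[1] * df["x"] + np.log(df["expo"])
        expected = stats.poisson.logpmf(df["y"], np.exp(eta)).sum()
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_sigma_zero_equals_independent_negbin_logpmf(self, rng):
        df = toy_glmm_frame(rng)
        spec = GLMMSpec(
            family="negbin", response="y", fixed_effects=["x"], exposure="expo"
        )
        beta, alpha = np.array([-1.5, 0.4]), 0.4
        ll = marginal_loglik(df, spec, beta, sigma_u=0.0, alpha=alpha)
        mu = np.exp(beta[0] + beta[1] * df["x"] + np.log(df["expo"]))
        r = 1.0 / alpha
        expected = stats.nbinom.logpmf(df["y"], r, r / (r + mu)).sum()
        assert ll == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("family,alpha", [("poisson", None), ("negbin", 0.3)])
    def test_agq_matches_dense_grid_oracle(self, rng, family, alpha):
        spec = GLMMSpec(
            family=family, response="y", fixed_effects=["x"], exposure="expo"
        )
        for _ in range(5):
            df = toy_glmm_frame(rng)
            beta = rng.normal(0, 0.5, 2)
            sigma = float(rng.uniform(0.05, 1.5))
            agq = marginal_loglik(df, spec, beta, sigma, alpha=alpha, n_points=50)
            grid = marginal_loglik(
                df, spec, beta, sigma, alpha=alpha, method="grid_oracle"
            )
            assert agq == pytest.approx(grid, abs=1e-6)

    def test_invariant_to_row_permutation_and_group_relabelling(self, rng):
        df = toy_glmm_frame(rng)
        beta = np.array([-1.0, 0.2])
        base = marginal_loglik(df, SPEC, beta, 0.4)
        shuffled = df.sample(frac=1.0, random_state=1)
        assert marginal_loglik(shuffled, SPEC, beta, 0.4) == pytest.approx(base, abs=1e-10)
        relabelled = df.copy()
        relabelled["mouse_id"] = relabelled["mouse_id"].map({"g0": "z", "g1": "q", "g2": "a"})
        assert marginal_loglik(relabelled, SPEC, beta, 0.4) == pytest.approx(base, abs=1e-10)

    def test_negative_and_noninteger_response_rejected(self, rng):
        df = toy_glmm_frame(rng)
        bad = df.copy()
        bad.loc[bad.index[0], "y"] = -1
        with pytest.raises(ValueError, match="nonnegative integers"):
            marginal_loglik(bad, SPEC, [0.0, 0.0], 0.1)
        frac = df.copy()
        frac["y"] = frac["y"].astype(float)
        frac.loc[frac.index[0], "y"] = 1.5
        with pytest.raises(ValueError, match="nonnegative integers"):
            fit_glmm(frac, SPEC)


class TestFit:
    def test_sigma_zero_data_reduces_to_poisson_glm(self):
        """On data with no mouse effect the variance estimate collapses to the
        boundary for a fair share of realizations, and a boundary fit must
        reproduce the ordinary Poisson GLM; the sigma=0 likelihood matches the
        GLM likelihood exactly for every realization."""
        import statsmodels.api as sm

        saw_boundary = False
        for seed in (1, 2, 3, 4):
            df = simulate_glmm_data(np.random.default_rng(seed), sigma=0.0)
            fit = fit_glmm(df, SPEC)
            X = np.column_stack([np.ones(len(df)), df["x"]])
            glm = sm.GLM(
                df["y"], X, family=sm.families.Poisson(), offset=np.log(df["expo"])
            ).fit()
            assert marginal_loglik(df, SPEC, glm.params, 0.0) == pytest.approx(
                glm.llf, abs=1e-8
            )
            assert fit.loglik >= glm.llf - 1e-5
            assert fit.sigma_u < 0.15
            if fit.boundary_sigma:
                saw_boundary = True
                assert np.allclose(fit.beta, glm.params, atol=1e-3)
        assert saw_boundary

    def test_loglik_not_below_glm_start(self):
        df = simulate_glmm_data(np.random.default_rng(2), sigma=0.3)
        fit = fit_glmm(df, SPEC)
        import statsmodels.api as sm

        X = np.column_stack([np.ones(len(df)), df["x"]])
        glm = sm.GLM(
            df["y"], X, family=sm.families.Poisson(), offset=np.log(df["expo"])
        ).fit()
        start_ll = marginal_loglik(df, SPEC, glm.params, 0.0)
        assert fit.loglik >= start_ll - 1e-6

    def test_parameter_recovery_40_groups(self):
        """Mean bias of the group effect < 0.02 on the log scale and sigma_u
        recovered within 20%, averaged over replicate fits."""
        b1 = np.log(1.2)
        ests, sigmas = [], []
        for rep in range(25):
            df = simulate_glmm_data(np.random.default_rng(100 + rep), sigma=0.2)
            fit = fit_glmm(df, SPEC)
            ests.append(fit.beta[1])
            sigmas.append(fit.sigma_u)
        assert abs(np.mean(ests) - b1) < 0.02
        assert abs(np.mean(sigmas) - 0.2) < 0.04

    def test_offset_shift_moves_only_intercept(self):
        df = simulate_glmm_data(np.random.default_rng(3), n_groups=10, n_per=20)
        fit = fit_glmm(df, SPEC)
        shifted = df.copy()
        shifted["log_expo"] = np.log(shifted["expo"]) + 2.0
        spec2 = GLMMSpec(
            response="y", fixed_effects=["x"], offset="log_expo", group="mouse_id"
        )
        fit2 = fit_glmm(shifted, spec2)
        assert fit2.beta[0] == pytest.approx(fit.beta[0] - 2.0, abs=1e-4)
        assert fit2.beta[1] == pytest.approx(fit.beta[1], abs=1e-4)
        assert fit2.loglik == pytest.approx(fit.loglik, abs=1e-6)

    def test_negbin_fit_recovers_dispersion(self):
        rng = np.random.default_rng(4)
        rows = []
        alpha = 0.15
        for i in range(30):
            u = rng.normal(0, 0.15)
            mu = np.exp(4.0 + u)
            r = 1 / alpha
            y = rng.negative_binomial(r, r / (r + mu), 60)
            rows += [{"y": int(v), "mouse_id": f"m{i}"} for v in y]
        df = pd.DataFrame(rows)
        spec = GLMMSpec(family="negbin", response="y", group="mouse_id")
        fit = fit_glmm(df, spec)
        assert fit.converged
        assert fit.alpha == pytest.approx(alpha, rel=0.25)
        assert fit.beta[0] == pytest.approx(4.0, abs=0.15)

    def test_rank_deficient_design_warns_not_crashes(self, rng):
        df = toy_glmm_frame(rng)
        df["x2"] = df["x"]
        spec = GLMMSpec(response="y", fixed_effects=["x", "x2"], exposure="expo")
        with pytest.warns(UserWarning, match="rank deficient"):
            fit_glmm(df, spec)


class TestWald:
    def _fake_fit(self, beta, se):
        return GLMMFit(
            family="poisson",
            term_names=["Intercept", "x"],
            beta=np.asarray(beta, dtype=float),
            se_beta=np.asarray(se, dtype=float),
            sigma_u=0.1,
            alpha=None,
            loglik=-10.0,
            converged=True,
            boundary_sigma=False,
            n_obs=10,
            n_groups=2,
            spec=GLMMSpec(response="y"),
        )

    def test_null_effect_gives_rr1_p1(self):
        w = wald_summary(self._fake_fit([0.5, 0.0], [0.1, 0.2]), "x")
        assert w.rate_ratio == 1.0
        assert w.z == 0.0
        assert w.p == 1.0

    def test_log_rr_exponentiates_and_ci_is_exact(self):
        b, se = np.log(1.2), 0.07
        w = wald_summary(self._fake_fit([0.0, b], [0.1, se]), "x")
        assert w.rate_ratio == pytest.approx(1.2, rel=1e-12)
        assert w.ci_low == np.exp(b - 1.96 * se)
        assert w.ci_high == np.exp(b + 1.96 * se)

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown term"):
            wald_summary(self._fake_fit([0.0, 0.1], [0.1, 0.1]), "nope")


def test_fit_agrees_with_lme4_glmer(tmp_path):
    """Independent cross-check: R lme4's glmer with adaptive quadrature on the
    same data should give the same ML estimates."""
    df = simulate_glmm_data(np.random.default_rng(7), n_groups=12, n_per=25, sigma=0.25)
    fit = fit_glmm(df, SPEC)
    csv = tmp_path / "dat.csv"
    df.to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(
        """
        suppressMessages(library(lme4))
        d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
        m <- glmer(y ~ x + (1|mouse_id) + offset(log(expo)), data=d,
                   family=poisson, nAGQ=25)
        # logLik from the Laplace fit: with nAGQ>1 lme4 reports the AGQ
        # deviance on a scale that drops constant terms
        m1 <- glmer(y ~ x + (1|mouse_id) + offset(log(expo)), data=d,
                    family=poisson, nAGQ=1)
        cat(jsonlite::toJSON(list(beta=unname(fixef(m)),
                                  sigma=sqrt(unname(as.numeric(VarCorr(m)$mouse_id))),
                                  loglik=as.numeric(logLik(m1)))))
        """
    )
    out = subprocess.run(
        ["Rscript", str(rscript), str(csv)], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    ref = json.loads(out.stdout)
    assert np.allclose(fit.beta, ref["beta"], atol=2e-3)
    assert fit.sigma_u == pytest.approx(ref["sigma"][0], abs=5e-3)
    # Laplace and 25-node AGQ log-likelihoods differ by well under 0.01 here
    assert fit.loglik == pytest.approx(ref["loglik"][0], abs=0.01)
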