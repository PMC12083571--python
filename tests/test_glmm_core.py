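"""The PQL working model, the summary-based REML solver and BLUPs."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from d3mi import (
    Family,
    GLMMModel,
    blups_from_summaries,
    fit_lmm_from_summaries,
    fit_pql,
    make_summary,
    working_response,
)
from d3mi.lmm import reml_criterion_profile
from d3mi.model import CrossProductSummary

from conftest import GAUSS_MODEL


class TestWorkingResponse:
    def test_gaussian_identity_is_exact(self):
        z, w = working_response(np.array([2.0]), np.array([17.3]), "gaussian")
        assert z[0] == 2.0 and w[0] == 1.0

    def test_binomial_at_eta_zero(self):
        z, w = working_response(np.array([1.0]), np.array([0.0]), "binomial")
        assert z[0] == pytest.approx(2.0)
        assert w[0] == pytest.approx(0.25)

    def test_binomial_clipping_keeps_z_finite(self):
        z, w = working_response(np.array([1.0]), np.array([40.0]), "binomial")
        assert np.isfinite(z[0])
        assert w[0] == pytest.approx(1e-6, rel=1e-3)

    @pytest.mark.parametrize(
        "y, eta",
        [(np.array([np.nan]), np.array([0.0])), (np.array([1.0]), np.array([np.inf]))],
    )
    def test_nonfinite_inputs_rejected(self, y, eta):
        with pytest.raises(ValueError):
            working_response(y, eta, "gaussian" if np.isnan(y).any() else "binomial")

    def test_nonbinary_outcome_rejected_for_binomial(self):
        with pytest.raises(ValueError, match="0/1"):
            working_response(np.array([0.5]), np.array([0.0]), "binomial")


class TestSummary:
    def test_hand_computed_gram(self):
        # two rows, gaussian: X = [[1,0],[1,1]], y = (1,3), w = 1
        X = np.array([[1.0, 0.0], [1.0, 1.0]])
        z = np.array([1.0, 3.0])
        sm = make_summary(X, z, np.ones(2), "s")
        expected = np.array(
            [
                [2.0, 1.0, 4.0, 2.0],  # 1'1, 1'x, 1'y, 1'1
                [1.0, 1.0, 3.0, 1.0],  # x'1, x'x, x'y, x'1
                [4.0, 3.0, 10.0, 4.0],  # y'., y'y
                [2.0, 1.0, 4.0, 2.0],
            ]
        )
        np.testing.assert_allclose(sm.gram, expected)
        assert sm.total_weight == 2.0

    def test_gram_is_exactly_symmetric(self, rng):
        X = rng.normal(size=(30, 3))
        sm = make_summary(X, rng.normal(size=30), rng.random(30) + 0.1, "s")
        np.testing.assert_array_equal(sm.gram, sm.gram.T)

    def test_asymmetric_gram_rejected(self):
        g = np.eye(4)
        g[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            CrossProductSummary("s", 2, g)


def _sim_sites(rng, L, n, sigma_u, sigma_e=1.0, beta=(1.0, 2.0)):
    out = []
    for i in range(L):
        x = rng.normal(size=n)
        u = rng.normal(0, sigma_u)
        y = beta[0] + beta[1] * x + u + rng.normal(0, sigma_e, n)
        X = np.column_stack([np.ones(n), x])
        out.append((f"s{i}", X, y))
    return out


def _summaries(sites):
    return [make_summary(X, y, np.ones(len(y)), sid) for sid, X, y in sites]


class TestLMMFromSummaries:
    def test_zero_between_site_variance_reduces_to_gls(self, rng):
        """With no between-site signal, beta equals pooled weighted LS."""
        sites = _sim_sites(rng, L=6, n=80, sigma_u=0.0)
        fit = fit_lmm_from_summaries(_summaries(sites))
        Xp = np.vstack([X for _, X, _ in sites])
        yp = np.concatenate([y for _, _, y in sites])
        ols = np.linalg.lstsq(Xp, yp, rcond=None)[0]
        # sigma_u2 lands at/near zero so the GLS solution is (close to) OLS
        assert fit.sigma_u2 < 5e-3
        np.testing.assert_allclose(fit.beta, ols, atol=2e-3)

    def test_balanced_anova_closed_form(self, rng):
        """Intercept-only balanced layout: REML equals the ANOVA formulas."""
        L, n = 8, 25
        data = [rng.normal(2.0 + rng.normal(0, 1.0), 1.5, size=n) for _ in range(L)]
        sms = [
            make_summary(np.ones((n, 1)), y, np.ones(n), f"s{i}")
            for i, y in enumerate(data)
        ]
        fit = fit_lmm_from_summaries(sms)
        ybar_i = np.array([y.mean() for y in data])
        grand = np.concatenate(data).mean()
        mse = sum(((y - y.mean()) ** 2).sum() for y in data) / (L * (n - 1))
        msa = n * ((ybar_i - grand) ** 2).sum() / (L - 1)
        sigma_u2_expected = max(0.0, (msa - mse) / n)
        assert fit.phi == pytest.approx(mse, rel=1e-6)
        assert fit.sigma_u2 == pytest.approx(sigma_u2_expected, rel=1e-6)

    def test_duplicating_summaries_halves_covariance(self, rng):
        sites = _sim_sites(rng, L=5, n=50, sigma_u=0.5)
        sms = _summaries(sites)
        fit1 = fit_lmm_from_summaries(sms)
        doubled = sms + [
            CrossProductSummary(f"{s.site_id}_b", s.n, s.gram.copy()) for s in sms
        ]
        fit2 = fit_lmm_from_summaries(doubled)
        np.testing.assert_allclose(fit2.beta, fit1.beta, rtol=1e-2, atol=1e-3)
        # doubling the data halves the information; the variance-parameter
        # re-estimate under the doubled layout shifts the intercept entry a bit
        np.testing.assert_allclose(
            np.diag(fit2.cov_beta), 0.5 * np.diag(fit1.cov_beta), rtol=0.15
        )

    def test_matches_statsmodels_mixedlm(self, rng):
        """Independent oracle: statsmodels MixedLM REML on the pooled rows."""
        import statsmodels.formula.api as smf

        sites = _sim_sites(rng, L=6, n=40, sigma_u=0.8)
        fit = fit_lmm_from_summaries(_summaries(sites))
        df = pd.concat(
            [
                pd.DataFrame({"y": y, "x": X[:, 1], "site": sid})
                for sid, X, y in sites
            ]
        )
        sm_fit = smf.mixedlm("y ~ x", df, groups=df["site"]).fit(reml=True)
        np.testing.assert_allclose(fit.beta, sm_fit.fe_params.values, atol=1e-4)
        assert fit.phi == pytest.approx(sm_fit.scale, rel=1e-3)
        assert fit.sigma_u2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-2)

    def test_permutation_and_split_invariance(self, rng):
        sites = _sim_sites(rng, L=4, n=30, sigma_u=0.5)
        sms = _summaries(sites)
        fit = fit_lmm_from_summaries(sms)
        fit_perm = fit_lmm_from_summaries(sms[::-1])
        np.testing.assert_allclose(fit_perm.beta, fit.beta, atol=1e-9)
        assert fit_perm.sigma_u2 == pytest.approx(fit.sigma_u2, abs=1e-7)
        # splitting one site's rows into two summaries then summing them
        sid, X, y = sites[0]
        a = make_summary(X[:10], y[:10], np.ones(10), sid)
        b = make_summary(X[10:], y[10:], np.ones(20), sid)
        merged = CrossProductSummary(sid, a.n + b.n, a.gram + b.gram)
        np.testing.assert_allclose(merged.gram, sms[0].gram, rtol=1e-12, atol=1e-9)

    def test_criterion_is_profile_optimal(self, rng):
        sites = _sim_sites(rng, L=6, n=40, sigma_u=0.6)
        sms = _summaries(sites)
        fit = fit_lmm_from_summaries(sms)
        lam_hat = fit.sigma_u2 / fit.phi
        grid = np.concatenate([[1e-8], np.geomspace(1e-4, 10.0, 40), [lam_hat + 1e-3]])
        crits = reml_criterion_profile(sms, grid)
        assert fit.criterion >= crits.max() - 1e-6

    def test_rank_deficiency_names_columns(self, rng):
        n = 40
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2.0 * x])
        sm = make_summary(X, rng.normal(size=n), np.ones(n), "s")
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_lmm_from_summaries([sm], coef_names=("(Intercept)", "a", "b"))

    def test_tau_never_exceeds_sigma_u2(self, rng):
        sites = _sim_sites(rng, L=6, n=15, sigma_u=0.7)
        fit = fit_lmm_from_summaries(_summaries(sites))
        for _, (v, tau) in fit.blups.items():
            assert 0.0 <= tau <= fit.sigma_u2 + 1e-12


class TestBlups:
    def test_hand_case(self):
        # sigma_u2=1, phi=1, w=4, rbar=0.5 -> v=0.4, tau=0.2
        X = np.ones((4, 1))
        z = np.full(4, 0.5)
        sm = make_summary(X, z, np.ones(4), "s")
        blups = blups_from_summaries([sm], beta=np.zeros(1), sigma_u2=1.0, phi=1.0)
        v, tau = blups["s"]
        assert v == pytest.approx(0.4)
        assert tau == pytest.approx(0.2)

    def test_zero_variance_limit(self):
        sm = make_summary(np.ones((3, 1)), np.ones(3), np.ones(3), "s")
        v, tau = blups_from_summaries([sm], np.zeros(1), 0.0, 1.0)["s"]
        assert v == 0.0 and tau == 0.0

    def test_shrinkage_vanishes_with_weight(self):
        rbar = 0.5
        for w_tot, expect_close in [(4.0, False), (1e8, True)]:
            n = 4
            sm = make_summary(
                np.ones((n, 1)), np.full(n, rbar), np.full(n, w_tot / n), "s"
            )
            v, _ = blups_from_summaries([sm], np.zeros(1), 1.0, 1.0)["s"]
            if expect_close:
                assert v == pytest.approx(rbar, rel=1e-6)
            else:
                assert v < rbar


class TestFitPQL:
    def test_gaussian_one_iteration_is_converged(self, rng, gaussian_federation):
        df = gaussian_federation.to_frame()
        f1 = fit_pql(df, GAUSS_MODEL, max_outer_iter=1)
        f50 = fit_pql(df, GAUSS_MODEL, max_outer_iter=50)
        np.testing.assert_allclose(f1.beta, f50.beta, atol=1e-10)
        assert f1.sigma_u2 == pytest.approx(f50.sigma_u2, abs=1e-10)
        assert f1.converged and f50.converged

    def test_gaussian_zero_heterogeneity_matches_ols(self, rng):
        # pooled OLS oracle when the generator has no site effects
        n = 500
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 0.3 + 1.2 * x1 - 0.7 * x2 + rng.normal(0, 1, n)
        df = pd.DataFrame(
            {"y": y, "x1": x1, "x2": x2, "site": np.repeat(["a", "b", "c", "d"], n // 4)}
        )
        fit = fit_pql(df, GAUSS_MODEL)
        X = np.column_stack([np.ones(n), x1, x2])
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        if fit.sigma_u2 == 0.0:
            np.testing.assert_allclose(fit.beta, ols, atol=1e-8)
        else:  # tiny estimated heterogeneity still keeps beta near OLS
            np.testing.assert_allclose(fit.beta, ols, atol=1e-3)

    def test_binomial_recovery_large_n(self):
        """Parameter-recovery oracle at n=5000, L=10, fixed seed."""
        rng = np.random.default_rng(77)
        L, n = 10, 500
        beta_true = np.array([-0.4, 0.7, -0.5])
        sigma_u = 0.4
        frames = []
        for i in range(L):
            u = rng.normal(0, sigma_u)
            x1, x2 = rng.normal(size=n), rng.normal(size=n)
            p = expit(beta_true[0] + beta_true[1] * x1 + beta_true[2] * x2 + u)
            y = (rng.random(n) < p).astype(float)
            frames.append(pd.DataFrame({"y": y, "x1": x1, "x2": x2, "site": f"s{i}"}))
        df = pd.concat(frames, ignore_index=True)
        model = GLMMModel(outcome="y", covariates=("x1", "x2"), family=Family.binomial)
        fit = fit_pql(df, model, max_outer_iter=50)
        assert fit.converged
        assert fit.phi == 1.0
        se = np.sqrt(np.diag(fit.cov_beta))
        assert np.all(np.abs(fit.beta - beta_true) < 3 * se + 0.05)

    def test_identical_sites_have_small_blups(self):
        rng = np.random.default_rng(3)
        L, n = 8, 2000
        frames = []
        for i in range(L):  # no site effects at all, huge n
            x1, x2 = rng.normal(size=n), rng.normal(size=n)
            y = 0.5 + x1 - x2 + rng.normal(0, 1, n)
            frames.append(pd.DataFrame({"y": y, "x1": x1, "x2": x2, "site": f"s{i}"}))
        fit = fit_pql(pd.concat(frames, ignore_index=True), GAUSS_MODEL)
        for _, (v, tau) in fit.blups.items():
            assert abs(v) <= 3 * np.sqrt(tau) + 1e-8
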