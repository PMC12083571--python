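"""Monte-Carlo benchmark: D3MI against GLM-based distributed imputation.

Per replicate the harness generates a complete federation, imposes the MAR
mask, runs each requested method on the same data (a paired design), and
collects the full fixed-effect vector of the analysis GLMM.  Reported
metrics over R replicates, with ``beta_true = (-0.5, 0.5, 0.5, 0.1)``:

* relative ``Bias = ||mean(b) - beta_true||_2 / ||beta_true||_2``,
* ``SD = sqrt(mean ||b - mean(b)||_2^2)``,
* ``rMSE = sqrt(mean ||b - beta_true||_2^2)``,

which satisfy ``rMSE^2 = SD^2 + (Bias * ||beta_true||_2)^2`` exactly.

Methods:

* ``CD`` — complete-data analysis (the pre-mask data; a hypothetical
  benchmark);
* ``CC`` — complete-case analysis (rows without missing cells);
* ``D3MI`` — federated mixed-model multiple imputation, one dPQL round per
  imputation-model fit (the communication-efficient default);
* ``PQL`` — the same pipeline with every PQL fit iterated to convergence on
  the pooled data (the centralized reference);
* ``AVGM`` — distributed (G)LM-based imputation: per-site maximum-likelihood
  fits without a random intercept, averaged with observed-row-count weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .families import Family
from .federation import Federation, dpql_fit
from .mi import CompletedDataset, ImputationSpec, initial_fill, make_specs
from .model import GLMMModel
from .pooling import impute_analyze_pool
from .simulate import (
    BETA_TRUE,
    ScenarioConfig,
    calibrate_mar_intercept,
    generate_dataset,
    impose_mar,
)

logger = logging.getLogger("d3mi.benchmark")

METHODS = ("CD", "CC", "PQL", "D3MI", "AVGM")
_ALIASES = {"PQL_CENTRAL": "PQL", "PQL-CENTRAL": "PQL"}

ANALYSIS_MODEL = GLMMModel(
    outcome="y", covariates=("x1", "x2", "x3"), family=Family.gaussian
)


@dataclass
class MetricsRow:
    """(Bias, SD, rMSE) for one method in one simulation cell."""

    method: str
    bias: float
    sd: float
    rmse: float
    n_reps: int
    n_failed: int = 0


def compute_metrics(
    estimates: np.ndarray, beta_true: np.ndarray, method: str = "", n_failed: int = 0
) -> MetricsRow:
    """Bias/SD/rMSE over replicate fixed-effect vectors (rows)."""
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    beta_true = np.asarray(beta_true, dtype=float)
    if est.shape[1] != len(beta_true):
        raise ValueError(
            f"estimates have {est.shape[1]} coefficients, truth has {len(beta_true)}"
        )
    if est.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    mean = est.mean(axis=0)
    norm_true = float(np.linalg.norm(beta_true))
    bias = float(np.linalg.norm(mean - beta_true)) / norm_true
    sd = float(np.sqrt(np.mean(np.sum((est - mean) ** 2, axis=1))))
    rmse = float(np.sqrt(np.mean(np.sum((est - beta_true) ** 2, axis=1))))
    return MetricsRow(
        method=method, bias=bias, sd=sd, rmse=rmse, n_reps=est.shape[0], n_failed=n_failed
    )


def metrics_mc_se(
    estimates: np.ndarray,
    beta_true: np.ndarray,
    n_boot: int = 500,
    seed: int = 12345,
) -> dict[str, float]:
    """Bootstrap Monte-Carlo standard errors of the three metrics."""
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    rng = np.random.default_rng(seed)
    vals = np.empty((n_boot, 3))
    R = est.shape[0]
    for bi in range(n_boot):
        row = compute_metrics(est[rng.integers(0, R, size=R)], beta_true)
        vals[bi] = (row.bias, row.sd, row.rmse)
    se = vals.std(axis=0, ddof=1)
    return {"bias": float(se[0]), "sd": float(se[1]), "rmse": float(se[2])}


# ---------------------------------------------------------------------------
# AVGM: GLM-based distributed imputation (no random intercept)
# ---------------------------------------------------------------------------

def _avgm_pooled_fit(fed: Federation, spec: ImputationSpec):
    """Observed-count-weighted average of per-site ML (G)LM fits.

    Returns (gamma_bar, V_bar, phi_hat, d) where phi_hat/d describe the
    pooled residual variance for gaussian targets (None for binomial).
    Sites whose local model cannot be fitted are dropped with a warning;
    if every site fails the step errors out.
    """
    q = 1 + len(spec.predictors)
    fits = []  # (n_obs, gamma, cov, rss)
    for s in fed.sites:
        rows = ~s.mask[spec.target]
        n_obs = int(rows.sum())
        if n_obs <= q:
            logger.warning("AVGM: site %s has too few observed rows; dropped", s.site_id)
            continue
        X = s.design(spec.predictors, rows)
        t = s.values[spec.target][rows]
        try:
            if spec.family is Family.gaussian:
                gamma, res_ss, rank, _ = np.linalg.lstsq(X, t, rcond=None)
                if rank < q:
                    raise np.linalg.LinAlgError("rank-deficient local design")
                resid = t - X @ gamma
                rss = float(resid @ resid)
                sigma2 = rss / (n_obs - q)
                cov = sigma2 * np.linalg.inv(X.T @ X)
                fits.append((n_obs, gamma, cov, rss))
            else:
                res = sm.GLM(t, X, family=sm.families.Binomial()).fit(maxiter=50)
                if not res.converged or not np.all(np.isfinite(res.params)):
                    raise RuntimeError("local logistic fit did not converge")
                fits.append((n_obs, res.params, np.asarray(res.cov_params()), 0.0))
        except Exception as exc:
            logger.warning("AVGM: site %s dropped (%s)", s.site_id, exc)
    if not fits:
        raise RuntimeError(f"AVGM: no site could fit the model for {spec.target!r}")
    n_tot = sum(f[0] for f in fits)
    w = np.array([f[0] / n_tot for f in fits])
    gamma_bar = sum(wi * f[1] for wi, f in zip(w, fits))
    v_bar = sum(wi**2 * f[2] for wi, f in zip(w, fits))
    if spec.family is Family.gaussian:
        d = n_tot - q  # pooled residual df across the kept sites
        phi_hat = sum(f[3] for f in fits) / d
        return gamma_bar, v_bar, phi_hat, d
    return gamma_bar, v_bar, None, None


def _avgm_impute_column(
    fed: Federation, spec: ImputationSpec, rng: np.random.Generator
) -> None:
    from scipy.special import expit

    gamma_bar, v_bar, phi_hat, d = _avgm_pooled_fit(fed, spec)
    eigval, eigvec = np.linalg.eigh(0.5 * (v_bar + v_bar.T))
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    gamma_star = gamma_bar + root @ rng.standard_normal(len(gamma_bar))
    phi_star = None
    if spec.family is Family.gaussian:
        phi_star = float(phi_hat * d / rng.chisquare(d))
    for s in fed.sites:
        rows = s.mask[spec.target]
        if not rows.any():
            continue
        Z = s.design(spec.predictors, rows)
        eta = Z @ gamma_star
        if spec.family is Family.gaussian:
            s.values[spec.target][rows] = eta + rng.normal(
                0.0, np.sqrt(phi_star), size=len(eta)
            )
        else:
            s.values[spec.target][rows] = (rng.random(len(eta)) < expit(eta)).astype(
                float
            )


def avgm_impute(
    federation: Federation,
    specs: list[ImputationSpec],
    M: int = 5,
    n_between_iter: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> list[CompletedDataset]:
    """AVGM-based multiple imputation: chained equations with ``v* = 0``.

    The imputation model drops the random intercept; coefficients are
    observed-count-weighted averages of per-site ML fits with covariance
    ``sum_i w_i^2 V_i``.  Orchestration (initial fill, sweeps, seed
    discipline) mirrors :func:`d3mi.mi.mice_run`.
    """
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    specs = sorted(specs, key=lambda s: s.visit_rank)
    completed = []
    for m in range(1, M + 1):
        if not specs:
            completed.append(CompletedDataset(federation.copy(), m=m, iteration=0))
            continue
        fill_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=root.entropy, spawn_key=(m, 0, 0))
        )
        fed = initial_fill(federation, specs, fill_rng)
        for sweep in range(1, n_between_iter + 1):
            for ci, spec in enumerate(specs):
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=root.entropy, spawn_key=(m, sweep, ci + 1)
                    )
                )
                _avgm_impute_column(fed, spec, rng)
        completed.append(CompletedDataset(fed, m=m, iteration=n_between_iter))
    return completed


# ---------------------------------------------------------------------------
# The benchmark driver
# ---------------------------------------------------------------------------

CONVERGED_ROUNDS = 50


def _run_method(
    method: str,
    complete_fed: Federation,
    masked_fed: Federation,
    config: ScenarioConfig,
    mi_seed: np.random.SeedSequence,
) -> np.ndarray:
    if method == "CD":
        fit = dpql_fit(complete_fed, ANALYSIS_MODEL, n_outer_iter=1)
        return fit.beta
    if method == "CC":
        eligible = {
            s.site_id: ~np.logical_or.reduce([s.mask[c] for c in s.values])
            for s in masked_fed.sites
        }
        fit = dpql_fit(masked_fed, ANALYSIS_MODEL, n_outer_iter=1, eligible=eligible)
        return fit.beta
    specs = make_specs(masked_fed, outcome="y", targets=list(config.incomplete_columns))
    if method in ("D3MI", "PQL"):
        rounds = 1 if method == "D3MI" else CONVERGED_ROUNDS
        from .mi import mice_run

        completed = mice_run(
            masked_fed,
            specs,
            M=config.m_imputations,
            n_between_iter=config.between_iterations,
            fit_rounds=rounds,
            seed=mi_seed,
        )
        pooled = impute_analyze_pool(completed, ANALYSIS_MODEL, fit_rounds=rounds)
        return pooled.beta_pooled
    if method == "AVGM":
        completed = avgm_impute(
            masked_fed,
            specs,
            M=config.m_imputations,
            n_between_iter=config.between_iterations,
            seed=mi_seed,
        )
        pooled = impute_analyze_pool(completed, ANALYSIS_MODEL, fit_rounds=1)
        return pooled.beta_pooled
    raise ValueError(f"unknown method {method!r}")


@dataclass
class BenchmarkResult:
    """Per-method replicate estimates and derived metrics for one cell."""

    config: ScenarioConfig
    estimates: dict[str, np.ndarray]
    n_failed: dict[str, int]
    n_reps: int

    def metrics(self) -> list[MetricsRow]:
        return [
            compute_metrics(
                self.estimates[m], BETA_TRUE, method=m, n_failed=self.n_failed[m]
            )
            for m in self.estimates
        ]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.metrics():
            rows.append(
                {
                    "scenario": self.config.scenario,
                    "N": self.config.n_total,
                    "L": self.config.n_sites,
                    "heterogeneity": self.config.heterogeneity,
                    "method": r.method,
                    "bias": r.bias,
                    "sd": r.sd,
                    "rmse": r.rmse,
                    "n_reps": r.n_reps,
                    "n_failed": r.n_failed,
                }
            )
        return pd.DataFrame(rows)


def run_benchmark(
    config: ScenarioConfig,
    methods: tuple[str, ...] = METHODS,
    n_reps: int = 200,
    seed: int = 0,
    max_failure_rate: float = 0.05,
) -> BenchmarkResult:
    """Run one simulation cell: R paired replicates of every method.

    Fully determined by ``seed``: the MAR intercept calibration, each
    replicate's data and mask, and every method's imputation streams derive
    from it by fixed spawn keys.  A method failing on more than
    ``max_failure_rate`` of replicates aborts the run; isolated failures are
    recorded and excluded.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    methods = tuple(_ALIASES.get(m.upper(), m.upper()) for m in methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    cal_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    alphas = calibrate_mar_intercept(config, rng=cal_rng)
    collected: dict[str, list[np.ndarray]] = {m: [] for m in methods}
    n_failed = {m: 0 for m in methods}
    for r in range(n_reps):
        gen_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(1, r))
        )
        complete_fed, _ = generate_dataset(config, gen_rng)
        mask_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(2, r))
        )
        masked_fed = impose_mar(complete_fed, config, alphas, mask_rng)
        for mi, method in enumerate(methods):
            mi_seed = np.random.SeedSequence(entropy=seed, spawn_key=(3, r, mi))
            try:
                beta = _run_method(method, complete_fed, masked_fed, config, mi_seed)
                collected[method].append(beta)
            except Exception as exc:
                n_failed[method] += 1
                logger.warning("replicate %d, method %s failed: %s", r, method, exc)
    for m in methods:
        if n_failed[m] > max_failure_rate * n_reps:
            raise RuntimeError(
                f"method {m} failed on {n_failed[m]}/{n_reps} replicates"
            )
    return BenchmarkResult(
        config=config,
        estimates={m: np.stack(collected[m]) for m in methods},
        n_failed=n_failed,
        n_reps=n_reps,
    )
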