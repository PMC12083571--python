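"""Multilevel multiple imputation with chained equations.

Each incomplete covariate ``x_k`` gets its own random-intercept imputation
GLMM

.. math:: g(E[x_{ijk} \\mid v_i]) = v_i + \\gamma_0 + \\gamma_y y_{ij}
          + Z_{ijk}^\\top \\gamma,

fitted (federated, by dPQL) on the rows where the target is observed, with
the analysis outcome always among the predictors.  Parameter uncertainty is
propagated by approximate-Bayesian draws: fixed effects from their
estimated multivariate normal, the dispersion and random-intercept variance
from scaled inverse-chi-square distributions, and each site's intercept from
its conditional normal ``N(v_hat_i, tau_i)``.  Missing cells are then
imputed stochastically, site by site, and the univariate steps are cycled
in a chained-equations sweep when several covariates are incomplete.

Randomness is governed by one root seed; independent streams are derived
per (imputation m, sweep, column) with counter-based spawn keys, so results
do not depend on evaluation order and the first M datasets are unchanged
when M grows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .families import Family
from .federation import Federation, dpql_fit
from .model import GLMMFit, GLMMModel

logger = logging.getLogger("d3mi.mi")


@dataclass(frozen=True)
class ImputationSpec:
    """Imputation model for one incomplete covariate.

    ``predictors`` are the other covariates plus the analysis outcome (the
    outcome must be included so that imputation preserves its association
    with the target); ``visit_rank`` orders the chained-equations sweep.
    """

    target: str
    predictors: tuple[str, ...]
    family: Family
    visit_rank: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictors", tuple(self.predictors))
        object.__setattr__(self, "family", Family.coerce(self.family))
        if self.target in self.predictors:
            raise ValueError("target cannot be among its own predictors")

    def model(self, site_column: str = "site") -> GLMMModel:
        return GLMMModel(
            outcome=self.target,
            covariates=self.predictors,
            family=self.family,
            site_column=site_column,
        )


def make_specs(
    federation: Federation,
    outcome: str,
    targets: list[str] | None = None,
) -> list[ImputationSpec]:
    """Default imputation specs: one per incomplete covariate.

    Predictors are the analysis outcome followed by every other covariate;
    the family is binomial for declared binary columns, gaussian otherwise.
    Visit order is increasing observed missing fraction.
    """
    cols = [c for c in federation.columns if c != outcome]
    if targets is None:
        targets = [c for c in cols if federation.n_masked(c) > 0]
    n_total = federation.n_total
    ranked = sorted(targets, key=lambda c: (federation.n_masked(c) / n_total, c))
    specs = []
    for rank, t in enumerate(ranked):
        predictors = (outcome,) + tuple(c for c in cols if c != t)
        fam = Family.binomial if t in federation.binary_columns else Family.gaussian
        specs.append(
            ImputationSpec(target=t, predictors=predictors, family=fam, visit_rank=rank)
        )
    return specs


@dataclass
class ParameterDraw:
    """One approximate-Bayesian draw of an imputation model's parameters."""

    gamma_star: np.ndarray
    sigma_v2_star: float
    phi_star: float | None
    v_star: dict[str, float]


@dataclass
class CompletedDataset:
    """A federation snapshot with every masked cell filled."""

    federation: Federation
    m: int
    iteration: int


def draw_parameters(fit: GLMMFit, n_sites: int, rng: np.random.Generator) -> ParameterDraw:
    """Approximate-Bayesian draw from a fitted imputation GLMM.

    * ``gamma* ~ MVN(gamma_hat, Var(gamma_hat))``;
    * for gaussian targets ``phi* = phi_hat * d / chi2_d`` with
      ``d = n_obs - q`` (scaled inverse-chi-square);
    * ``sigma_v2* = sigma_v2_hat * (L-1) / chi2_{L-1}``;
    * ``v_i* ~ N(v_hat_i, tau_i)`` independently per site.

    A fit with ``sigma_v2_hat = 0`` yields degenerate draws
    ``sigma_v2* = 0`` and ``v* = 0``.
    """
    cov = 0.5 * (fit.cov_beta + fit.cov_beta.T)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[0] < -1e-8 * max(eigval[-1], 1.0):
        raise ValueError("cov_beta is not positive semi-definite")
    root = eigvec * np.sqrt(np.clip(eigval, 0.0, None))
    gamma_star = fit.beta + root @ rng.standard_normal(len(fit.beta))

    phi_star: float | None = None
    if fit.family is None or fit.family is Family.gaussian:
        d = fit.n_obs - len(fit.beta)
        if d < 1:
            raise ValueError("not enough residual degrees of freedom for a phi draw")
        phi_star = float(fit.phi * d / rng.chisquare(d))

    if fit.sigma_u2 <= 0.0:
        sigma_v2_star = 0.0
    elif n_sites < 2:
        logger.warning("single site: between-site variance draw forced to 0")
        sigma_v2_star = 0.0
    else:
        sigma_v2_star = float(fit.sigma_u2 * (n_sites - 1) / rng.chisquare(n_sites - 1))

    v_star: dict[str, float] = {}
    for site_id in fit.blups:
        v_hat, tau = fit.blups[site_id]
        if fit.sigma_u2 <= 0.0:
            v_star[site_id] = 0.0
        else:
            v_star[site_id] = float(rng.normal(v_hat, np.sqrt(max(tau, 0.0))))
    return ParameterDraw(
        gamma_star=gamma_star,
        sigma_v2_star=sigma_v2_star,
        phi_star=phi_star,
        v_star=v_star,
    )


def impute_cells(
    Z: np.ndarray,
    site_ids: np.ndarray,
    draw: ParameterDraw,
    family: Family,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stochastic imputations for rows with a missing target.

    ``Z`` is the design matrix (intercept first) of those rows and
    ``site_ids`` their site labels.  The linear predictor is
    ``eta = Z gamma* + v*_site``; gaussian targets add ``N(0, phi*)`` noise,
    binomial targets draw ``Bernoulli(expit(eta))``.
    """
    missing_sites = set(map(str, site_ids)) - set(draw.v_star)
    if missing_sites:
        raise KeyError(f"no random-intercept draw for sites: {sorted(missing_sites)}")
    v = np.array([draw.v_star[str(s)] for s in site_ids])
    eta = Z @ draw.gamma_star + v
    if family is Family.gaussian:
        if draw.phi_star is None:
            raise ValueError("gaussian imputation requires a phi draw")
        return eta + rng.normal(0.0, np.sqrt(draw.phi_star), size=len(eta))
    return (rng.random(len(eta)) < expit(eta)).astype(float)


def initial_fill(
    federation: Federation,
    specs: list[ImputationSpec],
    rng: np.random.Generator,
) -> Federation:
    """Starting state for chained equations: hot-deck fill of masked cells.

    Each masked cell is filled by sampling with replacement from the same
    site's observed values of that column; a site with none observed falls
    back to the global observed pool.  Observed cells are untouched.
    """
    fed = federation.copy()
    for spec in sorted(specs, key=lambda s: s.visit_rank):
        col = spec.target
        global_pool = np.concatenate(
            [s.values[col][~s.mask[col]] for s in fed.sites]
        )
        if len(global_pool) == 0:
            raise ValueError(f"column {col!r} has no observed values anywhere")
        for s in fed.sites:
            k = int(s.mask[col].sum())
            if k == 0:
                continue
            pool = s.values[col][~s.mask[col]]
            if len(pool) == 0:
                pool = global_pool
            s.values[col][s.mask[col]] = rng.choice(pool, size=k, replace=True)
    return fed


def _impute_one_column(
    fed: Federation,
    spec: ImputationSpec,
    fit_rounds: int,
    rng: np.random.Generator,
    context: str,
) -> None:
    """Fit the imputation GLMM on observed-target rows, draw, impute in place."""
    model = spec.model()
    eligible = {s.site_id: ~s.mask[spec.target] for s in fed.sites}
    try:
        fit = dpql_fit(fed, model, n_outer_iter=fit_rounds, eligible=eligible)
        draw = draw_parameters(fit, fed.n_sites, rng)
    except Exception as exc:  # annotate with position in the chain
        raise RuntimeError(f"imputation failed at {context}: {exc}") from exc
    for s in fed.sites:
        rows = s.mask[spec.target]
        if not rows.any():
            continue
        Z = s.design(spec.predictors, rows)
        site_ids = np.full(int(rows.sum()), s.site_id, dtype=object)
        s.values[spec.target][rows] = impute_cells(Z, site_ids, draw, spec.family, rng)


def mice_run(
    federation: Federation,
    specs: list[ImputationSpec],
    M: int = 5,
    n_between_iter: int = 10,
    fit_rounds: int = 1,
    seed: int | np.random.SeedSequence = 0,
) -> list[CompletedDataset]:
    """Chained-equations multiple imputation: M completed federations.

    For each imputation ``m``: hot-deck initial fill, then
    ``n_between_iter`` sweeps; each sweep visits the incomplete columns in
    ``visit_rank`` order, fits the imputation GLMM by dPQL on rows where the
    target is observed (``fit_rounds`` outer iterations, default 1 — the
    communication-efficient mode), draws parameters and imputes the masked
    cells.  ``(seed, m)`` fully determines dataset ``m``.
    """
    if M < 1 or n_between_iter < 1:
        raise ValueError("M and n_between_iter must be >= 1")
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    specs = sorted(specs, key=lambda s: s.visit_rank)
    completed: list[CompletedDataset] = []
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
                _impute_one_column(
                    fed,
                    spec,
                    fit_rounds,
                    rng,
                    context=f"(m={m}, sweep={sweep}, column={spec.target!r})",
                )
        completed.append(CompletedDataset(fed, m=m, iteration=n_between_iter))
    return completed
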