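"""Penalized quasi-likelihood (PQL) outer loop for random-intercept GLMMs.

PQL alternates (i) linearizing the GLMM at the current fixed effects and
predicted random intercepts into a weighted working LMM and (ii) solving
that LMM by REML.  For the gaussian identity link the linearization is
exact, so a single solve is the converged fit.  For the binomial logit
link a few iterations — often one — suffice in practice.

The loop consumes only per-site cross-product summaries, so the pooled fit
(:func:`fit_pql`) and the federated fit share the same code path.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .families import Family
from .lmm import blups_from_summaries, fit_lmm_from_summaries
from .model import CrossProductSummary, GLMMFit, GLMMModel, make_summary

# A summary provider maps the current state (beta or None for the eta=0
# initialization, blups per site) to one CrossProductSummary per site.
SummaryFn = Callable[
    [np.ndarray | None, dict[str, float]], list[CrossProductSummary]
]


def _solve_glm_init(summaries: list[CrossProductSummary]) -> np.ndarray:
    """One IRLS pass of the no-random-effect GLM from eta = 0 summaries."""
    A = sum(sm.xtwx for sm in summaries)
    b = sum(sm.xtwz for sm in summaries)
    return np.linalg.solve(A, b)


def run_pql(
    summary_fn: SummaryFn,
    model: GLMMModel,
    max_outer_iter: int = 25,
    tol: float = 1e-6,
) -> GLMMFit:
    """Drive the PQL outer loop against a summary provider.

    ``summary_fn(None, {})`` must return summaries at the ``eta = 0``
    initialization (only requested for the binomial family);
    ``summary_fn(beta, blups)`` returns summaries linearized at that state.
    """
    if max_outer_iter < 1:
        raise ValueError("max_outer_iter must be >= 1")
    family = model.family
    names = model.coef_names

    if family is Family.gaussian:
        # Working response z = y, w = 1 regardless of the state: one REML
        # solve is the converged fit.
        summaries = summary_fn(np.zeros(model.n_coef), {})
        fit = fit_lmm_from_summaries(summaries, estimate_phi=True, coef_names=names)
        fit.family = family
        fit.converged = True
        fit.n_iter_used = 1
        return fit

    # Binomial: initialize beta from the no-random-effect GLM (one IRLS
    # pass at eta = 0), blups at 0.
    init_summaries = summary_fn(None, {})
    _check_weights(init_summaries)
    beta = _solve_glm_init(init_summaries)
    blups: dict[str, float] = {sm.site_id: 0.0 for sm in init_summaries}
    sigma_u2, phi = 0.0, 1.0
    fit: GLMMFit | None = None
    converged = False
    n_iter = 0
    for _ in range(max_outer_iter):
        n_iter += 1
        summaries = summary_fn(beta, blups)
        _check_weights(summaries)
        new_fit = fit_lmm_from_summaries(summaries, estimate_phi=False, coef_names=names)
        delta = max(
            float(np.max(np.abs(new_fit.beta - beta))),
            abs(new_fit.sigma_u2 - sigma_u2),
            abs(new_fit.phi - phi),
        )
        beta = new_fit.beta
        sigma_u2, phi = new_fit.sigma_u2, new_fit.phi
        blups = {site: v for site, (v, _) in new_fit.blups.items()}
        fit = new_fit
        if delta < tol:
            converged = True
            break
    assert fit is not None
    fit.family = family
    fit.converged = converged
    fit.n_iter_used = n_iter
    return fit


def _check_weights(summaries: list[CrossProductSummary]) -> None:
    total_w = sum(sm.total_weight for sm in summaries)
    total_n = sum(sm.n for sm in summaries)
    if total_n > 0 and total_w < 1e-8 * total_n:
        raise ValueError(
            "degenerate binomial working weights (possible complete separation)"
        )


def _site_arrays(
    data, model: GLMMModel
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Split a pooled table into per-site (id, X, y) arrays, intercept first."""
    import pandas as pd

    if not isinstance(data, pd.DataFrame):
        raise TypeError("fit_pql expects a pandas DataFrame")
    missing = [
        c
        for c in (model.site_column, model.outcome, *model.covariates)
        if c not in data.columns
    ]
    if missing:
        raise KeyError(f"columns not in data: {missing}")
    out = []
    for site_id, grp in data.groupby(model.site_column, sort=False):
        X = np.column_stack(
            [np.ones(len(grp))] + [grp[c].to_numpy(dtype=float) for c in model.covariates]
        )
        y = grp[model.outcome].to_numpy(dtype=float)
        out.append((str(site_id), X, y))
    return out


def summaries_at_state(
    site_arrays: Sequence[tuple[str, np.ndarray, np.ndarray]],
    family: Family,
    beta: np.ndarray | None,
    blups: dict[str, float],
) -> list[CrossProductSummary]:
    """Working-response summaries for in-memory per-site arrays."""
    from .families import working_response

    out = []
    for site_id, X, y in site_arrays:
        if beta is None:
            eta = np.zeros(len(y))
        else:
            eta = X @ beta + blups.get(site_id, 0.0)
        z, w = working_response(y, eta, family)
        out.append(make_summary(X, z, w, site_id))
    return out


def fit_pql(
    data,
    model: GLMMModel,
    max_outer_iter: int = 25,
    tol: float = 1e-6,
) -> GLMMFit:
    """PQL fit of a random-intercept GLMM on a pooled table.

    Parameters
    ----------
    data : pandas.DataFrame
        Pooled rows including the site column.
    model : GLMMModel
        Outcome, covariates (intercept implicit) and family.
    max_outer_iter, tol
        Outer-loop budget and convergence tolerance on the maximum absolute
        change in the fixed effects and variance parameters.
    """
    arrays = _site_arrays(data, model)

    def summary_fn(beta, blups):
        return summaries_at_state(arrays, model.family, beta, blups)

    return run_pql(summary_fn, model, max_outer_iter=max_outer_iter, tol=tol)


def predict_blup(
    fit: GLMMFit, summaries: list[CrossProductSummary]
) -> dict[str, tuple[float, float]]:
    """Per-site (v_hat, tau) given a fit state and fresh summaries."""
    return blups_from_summaries(summaries, fit.beta, fit.sigma_u2, fit.phi)
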