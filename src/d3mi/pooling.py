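"""Analysis of completed datasets and Rubin's-rules pooling.

Each completed dataset is analyzed with the random-intercept GLMM of
interest (via the federated engine), and the M sets of estimates are
combined: the pooled point estimate is the mean, the total covariance is
``T = U_bar + (1 + 1/M) B`` with ``U_bar`` the mean within-imputation
covariance and ``B`` the between-imputation covariance, and confidence
intervals use the Barnard-Rubin small-sample degrees of freedom.  The
random-intercept variance is pooled by its mean (point estimate only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .federation import dpql_fit
from .mi import CompletedDataset
from .model import GLMMFit, GLMMModel

logger = logging.getLogger("d3mi.pooling")


@dataclass
class PooledResult:
    """Rubin's-rules pooled estimates across M imputations."""

    beta_pooled: np.ndarray
    within_cov: np.ndarray
    between_cov: np.ndarray
    total_cov: np.ndarray
    df: np.ndarray
    ci_level: float
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    sigma_u2_pooled: float
    M: int
    coef_names: tuple[str, ...]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.total_cov))

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-coefficient table."""
        return pd.DataFrame(
            {
                "coefficient": list(self.coef_names),
                "estimate": self.beta_pooled,
                "se": self.se,
                "df": self.df,
                "ci_lo": self.ci_lower,
                "ci_hi": self.ci_upper,
            }
        )


def analyze_completed(
    completed: CompletedDataset,
    analysis_model: GLMMModel,
    fit_rounds: int = 1,
) -> GLMMFit:
    """Fit the analysis GLMM to one completed dataset via dPQL."""
    for s in completed.federation.sites:
        for c, v in s.values.items():
            if np.isnan(v).any():
                raise ValueError(
                    f"completed dataset m={completed.m} still has missing cells "
                    f"in column {c!r} at site {s.site_id!r}"
                )
    return dpql_fit(completed.federation, analysis_model, n_outer_iter=fit_rounds)


def rubin_pool(
    fits: list[GLMMFit],
    ci_level: float = 0.95,
    n_total: int | None = None,
) -> PooledResult:
    """Pool M analysis fits by Rubin's rules.

    Parameters
    ----------
    fits
        The M per-imputation fits; coefficient schemas must agree.
    ci_level
        Two-sided confidence level for the per-coefficient intervals.
    n_total
        Complete-data sample size, used for the Barnard-Rubin
        complete-data degrees of freedom ``nu_com = n_total - p``; defaults
        to the fits' recorded row count.
    """
    M = len(fits)
    if M < 1:
        raise ValueError("need at least one fit to pool")
    names = fits[0].coef_names
    for f in fits[1:]:
        if f.coef_names != names:
            raise ValueError("heterogeneous coefficient schemas across fits")
    if M == 1:
        logger.warning("M = 1: between-imputation variance is 0 by construction")
    p = len(names)
    betas = np.stack([f.beta for f in fits])
    q_bar = betas.mean(axis=0)
    u_bar = np.mean([f.cov_beta for f in fits], axis=0)
    if M > 1:
        dev = betas - q_bar
        b = dev.T @ dev / (M - 1)
    else:
        b = np.zeros((p, p))
    t_cov = u_bar + (1.0 + 1.0 / M) * b

    if n_total is None:
        n_total = fits[0].n_obs
    nu_com = max(n_total - p, 1)
    lam = (1.0 + 1.0 / M) * np.diag(b) / np.diag(t_cov)
    lam = np.clip(lam, 0.0, 1.0)
    nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
    lam_safe = np.where(lam > 0, lam, 1.0)
    nu_old = (M - 1) / np.square(lam_safe)
    df = np.where(lam > 0, nu_old * nu_obs / (nu_old + nu_obs), nu_obs)

    alpha = 1.0 - ci_level
    tq = stats.t.ppf(1.0 - alpha / 2.0, df)
    se = np.sqrt(np.diag(t_cov))
    sigma_u2_pooled = float(np.mean([f.sigma_u2 for f in fits]))
    return PooledResult(
        beta_pooled=q_bar,
        within_cov=u_bar,
        between_cov=b,
        total_cov=t_cov,
        df=df,
        ci_level=ci_level,
        ci_lower=q_bar - tq * se,
        ci_upper=q_bar + tq * se,
        sigma_u2_pooled=sigma_u2_pooled,
        M=M,
        coef_names=names,
    )


def impute_analyze_pool(
    completed: list[CompletedDataset],
    analysis_model: GLMMModel,
    fit_rounds: int = 1,
    ci_level: float = 0.95,
) -> PooledResult:
    """Analyze each completed dataset and pool the results."""
    fits = [analyze_completed(c, analysis_model, fit_rounds) for c in completed]
    return rubin_pool(fits, ci_level=ci_level)
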