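"""Synthetic multi-site data with site random intercepts and MAR missingness.

The generator emulates a federation of ``L`` equal-sized sites with one
continuous outcome and three covariates, each carrying its own site-level
random intercept:

* ``x3 ~ N(0, 0.5^2)`` (always fully observed),
* ``x2 ~ N(u_i2 + 0.1 x3, 0.1^2)`` with ``u_i2 ~ N(0, 0.1^2)``,
* ``x1 ~ Bernoulli(expit(u_i1 + 0.1 x2 + 0.1 x3))`` with ``u_i1 ~ N(0, 0.1^2)``,
* ``y ~ N(-0.5 + 0.5 x1 + 0.5 x2 + 0.1 x3 + u_iy, 0.5^2)`` with
  ``u_iy ~ N(0, sigma_uy2)``.

Between-site heterogeneity in the outcome is "weak" (``sigma_uy = 0.1``)
or "strong" (``sigma_uy = 0.5``).  Three missingness scenarios are
studied: (a) ``x1`` incomplete, (b) ``x2`` incomplete, (c) both.  Cells are
masked missing-at-random via a logistic model on fully observed quantities;
the logit intercept is calibrated on a large pilot sample so the expected
missing proportion hits the target (default 17.5%, within the 15-20% band).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .federation import Federation, SiteData

BETA_TRUE = np.array([-0.5, 0.5, 0.5, 0.1])  # (intercept, x1, x2, x3)

# Outcome random-intercept scale: u_iy ~ N(0, sigma_uy^2) with sigma_uy =
# 0.1 (weak) or 0.5 (strong).  The variance reading (0.1/0.5 as sigma^2)
# is ruled out by the complete-data analysis: across sample sizes the gap
# SD^2(strong) - SD^2(weak) of the estimator equals (0.25 - 0.01)/L, the
# signature of standard deviations 0.1 and 0.5.
HETEROGENEITY = {"weak": 0.01, "strong": 0.25}

# MAR missingness-model predictors per scenario and target column.  Only
# fully observed quantities may drive the mask (the MAR contract): in
# scenario c, where both x1 and x2 are incomplete, each mask depends only
# on x3 and y.
MAR_PREDICTORS: dict[str, dict[str, tuple[str, ...]]] = {
    "a": {"x1": ("x2", "x3", "y")},
    "b": {"x2": ("x1", "x3", "y")},
    "c": {"x1": ("x3", "y"), "x2": ("x3", "y")},
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation cell.

    ``scenario`` selects which covariates are incomplete; ``n_total`` rows
    are evenly distributed over ``n_sites`` sites; ``heterogeneity`` sets
    the outcome random-intercept variance.  ``mar_slope`` is the common
    coefficient of every predictor in the missingness logit (the intercept
    is calibrated separately).
    """

    scenario: str = "a"
    n_total: int = 600
    n_sites: int = 5
    heterogeneity: str = "weak"
    target_missing_rate: float = 0.175
    mar_slope: float = 1.0
    m_imputations: int = 5
    between_iterations: int = 10

    def __post_init__(self) -> None:
        if self.scenario not in MAR_PREDICTORS:
            raise ValueError(f"scenario must be one of {sorted(MAR_PREDICTORS)}")
        if self.heterogeneity not in HETEROGENEITY:
            raise ValueError("heterogeneity must be 'weak' or 'strong'")
        if self.n_total % self.n_sites != 0:
            raise ValueError("n_total must be divisible by n_sites (equal-sized sites)")

    @property
    def sigma_uy2(self) -> float:
        return HETEROGENEITY[self.heterogeneity]

    @property
    def incomplete_columns(self) -> tuple[str, ...]:
        return tuple(sorted(MAR_PREDICTORS[self.scenario]))


def _simulate_arrays(
    n_sites: int, n_per_site: int, sigma_uy2: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Vectorized draw of the complete data for n_sites x n_per_site rows."""
    L, n = n_sites, n_per_site
    site_idx = np.repeat(np.arange(L), n)
    u2 = rng.normal(0.0, 0.1, size=L)
    u1 = rng.normal(0.0, 0.1, size=L)
    uy = rng.normal(0.0, np.sqrt(sigma_uy2), size=L)
    x3 = rng.normal(0.0, 0.5, size=L * n)
    x2 = rng.normal(u2[site_idx] + 0.1 * x3, 0.1)
    p1 = expit(u1[site_idx] + 0.1 * x2 + 0.1 * x3)
    x1 = (rng.random(L * n) < p1).astype(float)
    y = rng.normal(
        BETA_TRUE[0] + BETA_TRUE[1] * x1 + BETA_TRUE[2] * x2 + BETA_TRUE[3] * x3
        + uy[site_idx],
        0.5,
    )
    return {
        "site_idx": site_idx,
        "x1": x1,
        "x2": x2,
        "x3": x3,
        "y": y,
        "u1": u1,
        "u2": u2,
        "uy": uy,
    }


def generate_dataset(
    config: ScenarioConfig, rng: np.random.Generator
) -> tuple[Federation, dict]:
    """Complete (pre-mask) federation plus the ground-truth record.

    The truth record keeps the site random intercepts and the full pre-mask
    covariate values, so benchmarks can run the hypothetical complete-data
    analysis and score imputations against the masked-out truth.
    """
    n_per_site = config.n_total // config.n_sites
    arr = _simulate_arrays(config.n_sites, n_per_site, config.sigma_uy2, rng)
    sites = []
    for i in range(config.n_sites):
        sel = arr["site_idx"] == i
        sites.append(
            SiteData(
                site_id=f"site{i + 1:02d}",
                values={
                    "y": arr["y"][sel],
                    "x1": arr["x1"][sel],
                    "x2": arr["x2"][sel],
                    "x3": arr["x3"][sel],
                },
            )
        )
    fed = Federation(sites, binary_columns={"x1"})
    truth = {
        "beta_true": BETA_TRUE.copy(),
        "u1": arr["u1"],
        "u2": arr["u2"],
        "uy": arr["uy"],
        "complete": {k: arr[k].copy() for k in ("x1", "x2", "x3", "y")},
        "site_idx": arr["site_idx"],
    }
    return fed, truth


def _mask_eta(
    values: dict[str, np.ndarray], predictors: tuple[str, ...], slope: float
) -> np.ndarray:
    eta = np.zeros_like(values["y"])
    for pred in predictors:
        eta = eta + slope * values[pred]
    return eta


def calibrate_mar_intercept(
    config: ScenarioConfig,
    pilot_size: int = 100_000,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Missingness-logit intercept per incomplete column, by bisection.

    A pilot federation with the cell's per-site size (but enough sites to
    average over the random intercepts) supplies the predictor
    distribution; the intercept is bisected until the pilot mean of
    ``expit(alpha0 + slope * predictors)`` is within 1e-3 of the target
    rate.  With all slopes zero this reduces to ``logit(rate)``.
    """
    rate = config.target_missing_rate
    if not 0.0 < rate < 1.0:
        raise ValueError("target missing rate must be in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng(0)
    n_per_site = config.n_total // config.n_sites
    n_pilot_sites = max(int(np.ceil(pilot_size / n_per_site)), 50)
    arr = _simulate_arrays(n_pilot_sites, n_per_site, config.sigma_uy2, rng)
    alphas: dict[str, float] = {}
    for col, predictors in MAR_PREDICTORS[config.scenario].items():
        eta = _mask_eta(arr, predictors, config.mar_slope)
        if np.allclose(eta, 0.0):
            alphas[col] = float(logit(rate))
            continue
        lo, hi = -40.0, 40.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            achieved = float(np.mean(expit(mid + eta)))
            if abs(achieved - rate) <= 1e-3:
                break
            if achieved < rate:
                lo = mid
            else:
                hi = mid
        alphas[col] = mid
    return alphas


def impose_mar(
    federation: Federation,
    config: ScenarioConfig,
    alphas: dict[str, float],
    rng: np.random.Generator,
) -> Federation:
    """Mask the scenario's incomplete columns under the MAR logistic model.

    Each targeted cell is masked independently with probability
    ``expit(alpha0 + slope * predictors)``; masked values are set to NaN
    and recorded in the mask.  Only scenario-designated columns are touched.
    """
    fed = federation.copy()
    for col, predictors in MAR_PREDICTORS[config.scenario].items():
        for s in fed.sites:
            eta = _mask_eta(s.values, predictors, config.mar_slope)
            prob = expit(alphas[col] + eta)
            mask = rng.random(s.n) < prob
            s.mask[col] = mask
            s.values[col] = s.values[col].copy()
            s.values[col][mask] = np.nan
    return fed
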