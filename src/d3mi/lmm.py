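"""REML solver for the random-intercept working LMM, from summaries only.

The model is ``z_i = X_i beta + 1 v_i + e_i`` with ``v_i ~ N(0, sigma_u2)``
and ``e_i ~ N(0, phi W_i^{-1})``.  The per-site marginal covariance is

.. math:: \\Sigma_i = \\phi W_i^{-1} + \\sigma_u^2 \\mathbf{1}\\mathbf{1}^\\top,

whose inverse, via the Woodbury identity, needs only the site's total
weight.  Every quantity the REML criterion requires is therefore a function
of the sites' ``[X | z | 1]`` weighted Gram matrices — the federated and the
pooled fit share this solver bit for bit.

Writing ``lam = sigma_u2 / phi`` and ``k_i = lam / (1 + lam * w_{i+})``:

* ``X' Sigma^{-1} X = (A - sum_i k_i c_i c_i') / phi`` with ``A = sum XtWX``
  and ``c_i = X_i' W_i 1``;
* the GLS estimate is the solve of that system against the matching
  right-hand side, and the residual quadratic form reduces to a scalar.

``phi`` is profiled out for the gaussian family (REML: ``rss/(n - p)``) and
held at 1 for binomial (classical PQL).  The single remaining variance
parameter is optimized by bounded scalar search on ``log(lam)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize_scalar

from .model import CrossProductSummary, GLMMFit

# Search bounds for log(sigma_u2 / phi); the lower bound maps to sigma_u2=0.
_LOG_LAM_BOUNDS = (-18.0, 18.0)
_XATOL = 1e-9


@dataclass
class _Blocks:
    A: np.ndarray  # (p, p)  sum_i X'WX
    b: np.ndarray  # (p,)    sum_i X'Wz
    S: float  # sum_i z'Wz
    C: np.ndarray  # (L, p)  per-site X'W1
    s: np.ndarray  # (L,)    per-site z'W1
    w: np.ndarray  # (L,)    per-site total weight
    n: int
    site_ids: list[str]


def _collect(summaries: list[CrossProductSummary]) -> _Blocks:
    if not summaries:
        raise ValueError("no summaries supplied")
    p = summaries[0].p
    for sm in summaries:
        if sm.p != p:
            raise ValueError(
                f"site {sm.site_id!r}: summary has {sm.p} design columns, expected {p}"
            )
    A = np.zeros((p, p))
    b = np.zeros(p)
    S = 0.0
    C = np.empty((len(summaries), p))
    s = np.empty(len(summaries))
    w = np.empty(len(summaries))
    n = 0
    ids = []
    for i, sm in enumerate(summaries):
        A += sm.xtwx
        b += sm.xtwz
        S += sm.ztwz
        C[i] = sm.xtw1
        s[i] = sm.ztw1
        w[i] = sm.total_weight
        n += sm.n
        ids.append(sm.site_id)
    return _Blocks(A=A, b=b, S=S, C=C, s=s, w=w, n=n, site_ids=ids)


def _check_rank(A: np.ndarray, coef_names: tuple[str, ...] | None) -> None:
    p = A.shape[0]
    eig = np.linalg.eigvalsh(A)
    if eig[0] <= max(eig[-1], 1.0) * 1e-10:
        names = coef_names or tuple(f"col{i}" for i in range(p))
        # Name the columns involved in the near-null space.
        _, vecs = np.linalg.eigh(A)
        null = np.abs(vecs[:, 0])
        bad = [names[i] for i in np.nonzero(null > 0.1 * null.max())[0]]
        raise np.linalg.LinAlgError(
            "fixed-effect design is rank-deficient; collinear columns: "
            + ", ".join(bad)
        )


def _profile(lam: float, blk: _Blocks):
    """GLS pieces at lam = sigma_u2/phi.  Returns (beta, rss, logdetM, logdetV, cho)."""
    k = lam / (1.0 + lam * blk.w) if lam > 0 else np.zeros_like(blk.w)
    M = blk.A - (blk.C * k[:, None]).T @ blk.C
    m = blk.b - blk.C.T @ (k * blk.s)
    cho = cho_factor(0.5 * (M + M.T), lower=True)
    beta = cho_solve(cho, m)
    rss = blk.S - np.sum(k * blk.s * blk.s) - float(beta @ m)
    rss = max(rss, 1e-300)
    logdetM = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    logdetV = float(np.sum(np.log1p(lam * blk.w)))
    return beta, rss, logdetM, logdetV, cho


def blups_from_summaries(
    summaries: list[CrossProductSummary],
    beta: np.ndarray,
    sigma_u2: float,
    phi: float,
) -> dict[str, tuple[float, float]]:
    """Per-site BLUP ``v_hat_i`` and its conditional variance ``tau_i``.

    ``v_hat_i = sigma_u2 * w_i * rbar_i / (phi + sigma_u2 * w_i)`` with
    ``rbar_i`` the weighted mean working residual, and
    ``tau_i = (1/sigma_u2 + w_i/phi)^{-1}``; at ``sigma_u2 = 0`` both are 0
    (the defined no-heterogeneity limit).  A site with zero total weight
    gets the prior: ``v_hat = 0``, ``tau = sigma_u2``.
    """
    out: dict[str, tuple[float, float]] = {}
    for sm in summaries:
        w = sm.total_weight
        if sigma_u2 <= 0.0:
            out[sm.site_id] = (0.0, 0.0)
        elif w <= 0.0:
            out[sm.site_id] = (0.0, float(sigma_u2))
        else:
            rbar = (sm.ztw1 - float(sm.xtw1 @ beta)) / w
            denom = phi + sigma_u2 * w
            v = sigma_u2 * w * rbar / denom
            tau = sigma_u2 * phi / denom
            out[sm.site_id] = (float(v), float(tau))
    return out


def fit_lmm_from_summaries(
    summaries: list[CrossProductSummary],
    estimate_phi: bool = True,
    coef_names: tuple[str, ...] | None = None,
) -> GLMMFit:
    """REML fit of the random-intercept working LMM from site summaries.

    Parameters
    ----------
    summaries
        One :class:`CrossProductSummary` per site, sharing a column schema.
    estimate_phi
        If True (gaussian working model) the dispersion is profiled by REML;
        if False it is held at 1 (binomial PQL).
    coef_names
        Optional fixed-effect names used in error messages and the fit.

    Notes
    -----
    The profiled REML deviance (up to constants free of the variance
    parameters) is, with ``lam = sigma_u2/phi``:

    ``f(lam) = sum_i log(1 + lam w_i) + logdet(X'V^-1 X) + (n-p) log(rss)``

    when phi is profiled, and with ``(n-p) log(rss)`` replaced by ``rss``
    when ``phi = 1``.  A boundary optimum at ``sigma_u2 = 0`` is a valid
    estimate, not an error.
    """
    blk = _collect(summaries)
    p = blk.A.shape[0]
    if blk.n <= p:
        raise ValueError(f"need more than p={p} rows to fit; got n={blk.n}")
    _check_rank(blk.A, coef_names)
    ndf = blk.n - p

    def objective(log_lam: float) -> float:
        _, rss, logdetM, logdetV, _ = _profile(float(np.exp(log_lam)), blk)
        fit_term = ndf * np.log(rss) if estimate_phi else rss
        return logdetV + logdetM + fit_term

    res = minimize_scalar(
        objective,
        bounds=_LOG_LAM_BOUNDS,
        method="bounded",
        options={"xatol": _XATOL},
    )
    lam = float(np.exp(res.x))
    f_opt = float(res.fun)
    # The lower boundary means "no between-site variance"; compare against
    # the exact lam = 0 limit and snap when it is at least as good up to
    # numerical ties (a single site makes the profile flat in lam, in which
    # case the boundary is the defined estimate).
    f_zero = objective(-np.inf)
    tie_tol = 1e-6 * max(1.0, abs(f_opt))
    if f_zero <= f_opt + tie_tol or res.x <= _LOG_LAM_BOUNDS[0] + 0.1:
        lam, f_opt = 0.0, min(f_zero, f_opt)

    beta, rss, logdetM, logdetV, cho = _profile(lam, blk)
    if estimate_phi:
        phi = rss / ndf
        criterion = -0.5 * (logdetV + logdetM + ndf * (np.log(phi) + 1.0))
    else:
        phi = 1.0
        criterion = -0.5 * (logdetV + logdetM + rss)
    sigma_u2 = lam * phi
    cov_beta = phi * cho_solve(cho, np.eye(p))
    cov_beta = 0.5 * (cov_beta + cov_beta.T)
    blups = blups_from_summaries(summaries, beta, sigma_u2, phi)
    names = coef_names or tuple(f"col{i}" for i in range(p))
    return GLMMFit(
        beta=beta,
        cov_beta=cov_beta,
        sigma_u2=float(sigma_u2),
        phi=float(phi),
        blups=blups,
        n_iter_used=1,
        converged=True,
        criterion=float(criterion),
        coef_names=names,
        family=None,
        n_obs=blk.n,
    )


def reml_criterion_profile(
    summaries: list[CrossProductSummary], lam_grid: np.ndarray, estimate_phi: bool = True
) -> np.ndarray:
    """Restricted log-likelihood (up to a constant) along a grid of
    ``lam = sigma_u2/phi`` values; used to verify profile optimality."""
    blk = _collect(summaries)
    ndf = blk.n - blk.A.shape[0]
    out = np.empty(len(lam_grid))
    for i, lam in enumerate(lam_grid):
        _, rss, logdetM, logdetV, _ = _profile(float(lam), blk)
        if estimate_phi:
            phi = rss / ndf
            out[i] = -0.5 * (logdetV + logdetM + ndf * (np.log(phi) + 1.0))
        else:
            out[i] = -0.5 * (logdetV + logdetM + rss)
    return out
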