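"""Model descriptions and fit containers for random-intercept GLMMs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .families import Family

INTERCEPT = "(Intercept)"


@dataclass(frozen=True)
class GLMMModel:
    """A random-intercept GLMM: ``g(E[y_ij | u_i]) = u_i + b0 + X_ij' b``.

    The intercept is always implicit and occupies the first coefficient
    position; ``covariates`` lists the remaining fixed-effect columns in
    design order.
    """

    outcome: str
    covariates: tuple[str, ...]
    family: Family
    site_column: str = "site"

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "family", Family.coerce(self.family))
        cols = self.covariates
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate fixed-effect columns")
        if self.outcome in cols or self.site_column in cols:
            raise ValueError(
                "fixed-effect columns must not include the outcome or site column"
            )

    @property
    def coef_names(self) -> tuple[str, ...]:
        return (INTERCEPT,) + self.covariates

    @property
    def n_coef(self) -> int:
        return 1 + len(self.covariates)


@dataclass
class GLMMFit:
    """Result of a (federated or pooled) PQL fit.

    Attributes
    ----------
    beta : ndarray, shape (p,)
        Fixed effects, intercept first.
    cov_beta : ndarray, shape (p, p)
        GLS covariance of ``beta`` at the variance-parameter optimum.
    sigma_u2 : float
        Random-intercept variance (>= 0; 0 is a valid boundary estimate).
    phi : float
        Dispersion: residual variance for gaussian, fixed at 1 for binomial.
    blups : dict
        site_id -> (v_hat, tau): predicted random intercept and its
        conditional variance; ``tau <= sigma_u2`` always.
    criterion : float
        Restricted log-likelihood of the final working model, up to an
        additive constant not involving the variance parameters.
    n_obs : int
        Number of rows that entered the fit (across all sites).
    """

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma_u2: float
    phi: float
    blups: dict[str, tuple[float, float]]
    n_iter_used: int
    converged: bool
    criterion: float
    coef_names: tuple[str, ...]
    family: Family | None = None
    n_obs: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.cov_beta = np.asarray(self.cov_beta, dtype=float)
        if self.sigma_u2 < 0:
            raise ValueError("sigma_u2 must be non-negative")
        if self.phi <= 0:
            raise ValueError("phi must be positive")

    def to_record(self) -> dict[str, float]:
        """Flat key-value serialization for audit logs."""
        rec: dict[str, float] = {}
        for name, b in zip(self.coef_names, self.beta):
            rec[f"beta.{name}"] = float(b)
        p = len(self.beta)
        for i in range(p):
            for j in range(p):
                rec[f"cov.{self.coef_names[i]}.{self.coef_names[j]}"] = float(
                    self.cov_beta[i, j]
                )
        rec["sigma_u2"] = float(self.sigma_u2)
        rec["phi"] = float(self.phi)
        for site, (v, tau) in self.blups.items():
            rec[f"blup.{site}.v_hat"] = float(v)
            rec[f"blup.{site}.tau"] = float(tau)
        return rec


@dataclass
class CrossProductSummary:
    """The only payload a site ever shares.

    ``gram`` is the weighted cross-product of the horizontally concatenated
    blocks ``[X | z | 1]`` where ``X`` is the fixed-effect design (intercept
    first), ``z`` the working response and ``1`` a constant column, with the
    IRLS weights on the diagonal:

    .. math:: G = [X\\;z\\;1]^\\top W [X\\;z\\;1].

    Its size is ``(p + 2) x (p + 2)`` — independent of the site's row count,
    which is the privacy contract: no row-level data leave the site.
    """

    site_id: str
    n: int
    gram: np.ndarray

    def __post_init__(self) -> None:
        self.gram = np.asarray(self.gram, dtype=float)
        g = self.gram
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError("gram must be a square matrix")
        if not np.allclose(g, g.T, atol=1e-10, rtol=1e-8):
            raise ValueError(f"site {self.site_id!r}: gram is not symmetric")

    @property
    def p(self) -> int:
        return self.gram.shape[0] - 2

    # Block accessors: indices [0:p] = X, p = z, p+1 = constant.
    @property
    def xtwx(self) -> np.ndarray:
        return self.gram[: self.p, : self.p]

    @property
    def xtwz(self) -> np.ndarray:
        return self.gram[: self.p, self.p]

    @property
    def xtw1(self) -> np.ndarray:
        return self.gram[: self.p, self.p + 1]

    @property
    def ztwz(self) -> float:
        return float(self.gram[self.p, self.p])

    @property
    def ztw1(self) -> float:
        return float(self.gram[self.p, self.p + 1])

    @property
    def total_weight(self) -> float:
        return float(self.gram[self.p + 1, self.p + 1])

    def to_record(self) -> dict[str, object]:
        """Flat serialization (upper triangle, row-major) for audit logs."""
        k = self.gram.shape[0]
        tri = [self.gram[i, j] for i in range(k) for j in range(i, k)]
        return {"site_id": self.site_id, "n": self.n, "gram_upper": tri}


def make_summary(
    X: np.ndarray, z: np.ndarray, w: np.ndarray, site_id: str
) -> CrossProductSummary:
    """Assemble the ``[X | z | 1]`` weighted Gram matrix for one site."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    blocks = np.column_stack([X, np.asarray(z, float), np.ones(n)])
    gram = blocks.T @ (np.asarray(w, float)[:, None] * blocks)
    gram = 0.5 * (gram + gram.T)
    return CrossProductSummary(site_id=site_id, n=n, gram=gram)


def zero_summary(p: int, site_id: str) -> CrossProductSummary:
    """All-zero summary for a site with no eligible rows."""
    return CrossProductSummary(site_id=site_id, n=0, gram=np.zeros((p + 2, p + 2)))
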