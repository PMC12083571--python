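"""Scikit-learn-style estimators over the federated GLMM/MI core.

:class:`RandomInterceptGLMM` is a fit/predict estimator for the
random-intercept GLMM itself; :class:`DistributedMIAnalysis` runs the whole
impute-analyze-pool pipeline on a table with missing covariate cells.  Both
follow sklearn conventions (``get_params``/``set_params``, trailing-
underscore fitted attributes, input validation) and compose with sklearn
model-selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

from .families import Family
from .federation import federation_from_frame
from .mi import make_specs, mice_run
from .model import GLMMModel
from .pooling import impute_analyze_pool
from .pql import fit_pql


class RandomInterceptGLMM(BaseEstimator):
    """Random-intercept GLMM fitted by penalized quasi-likelihood.

    Parameters
    ----------
    family : {"gaussian", "binomial"}
        Response family (identity resp. logit link).
    max_iter : int
        Outer PQL iteration budget (gaussian converges in one).
    tol : float
        Convergence tolerance on the max absolute parameter change.

    Attributes
    ----------
    intercept_ : float
    coef_ : ndarray of shape (n_features,)
    cov_params_ : ndarray, (n_features + 1, n_features + 1)
        GLS covariance of (intercept, coef) at the variance optimum.
    sigma_u2_ : float
        Between-group (random-intercept) variance.
    phi_ : float
        Dispersion (residual variance for gaussian; 1 for binomial).
    random_effects_ : dict
        group label -> (BLUP, conditional variance).
    n_iter_ : int
    converged_ : bool

    Examples
    --------
    >>> est = RandomInterceptGLMM(family="gaussian")
    >>> est.fit(X, y, groups=site_labels)  # doctest: +SKIP
    """

    def __init__(self, family: str = "gaussian", max_iter: int = 25, tol: float = 1e-6):
        self.family = family
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y, groups):
        X = check_array(X, ensure_2d=True, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        groups = np.asarray(groups)
        if not (len(y) == len(X) == len(groups)):
            raise ValueError("X, y and groups must have equal length")
        names = tuple(f"x{i}" for i in range(X.shape[1]))
        df = pd.DataFrame(X, columns=list(names))
        df["__y__"] = y
        df["__site__"] = groups.astype(str)
        model = GLMMModel(
            outcome="__y__",
            covariates=names,
            family=Family.coerce(self.family),
            site_column="__site__",
        )
        fit = fit_pql(df, model, max_outer_iter=self.max_iter, tol=self.tol)
        self.intercept_ = float(fit.beta[0])
        self.coef_ = fit.beta[1:].copy()
        self.cov_params_ = fit.cov_beta
        self.sigma_u2_ = fit.sigma_u2
        self.phi_ = fit.phi
        self.random_effects_ = dict(fit.blups)
        self.n_iter_ = fit.n_iter_used
        self.converged_ = fit.converged
        self.criterion_ = fit.criterion
        self.n_features_in_ = X.shape[1]
        return self

    def _linear_predictor(self, X, groups=None) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, ensure_2d=True, dtype=float)
        eta = self.intercept_ + X @ self.coef_
        if groups is not None:
            v = np.array(
                [self.random_effects_.get(str(g), (0.0, 0.0))[0] for g in groups]
            )
            eta = eta + v
        return eta

    def predict(self, X, groups=None):
        """Predicted mean response, including the group BLUP when known."""
        eta = self._linear_predictor(X, groups)
        if Family.coerce(self.family) is Family.binomial:
            return expit(eta)
        return eta


class DistributedMIAnalysis(BaseEstimator):
    """Impute-analyze-pool pipeline for one incomplete multi-site table.

    Fits a random-intercept imputation GLMM per incomplete covariate
    (federated, one dPQL round by default), imputes ``m_imputations`` times
    via chained equations, analyzes each completed dataset with the
    random-intercept analysis GLMM and pools by Rubin's rules.

    Parameters
    ----------
    outcome, covariates, site_column
        Analysis-model columns; missing cells (NaN) in the covariates are
        imputed.  The outcome must be fully observed.
    binary_columns : tuple of str
        Covariates imputed with a binomial-logit model.
    m_imputations, between_iterations, fit_rounds
        Number of imputations, chained-equation sweeps, and dPQL rounds per
        imputation-model fit (1 = communication-efficient default).
    random_state : int
        Root seed for every stochastic step.

    Attributes
    ----------
    result_ : PooledResult
        Pooled estimates, covariances, Barnard-Rubin df and intervals.
    imputations_ : list of CompletedDataset
    """

    def __init__(
        self,
        outcome: str = "y",
        covariates: tuple[str, ...] = (),
        site_column: str = "site",
        binary_columns: tuple[str, ...] = (),
        m_imputations: int = 5,
        between_iterations: int = 10,
        fit_rounds: int = 1,
        ci_level: float = 0.95,
        random_state: int = 0,
    ):
        self.outcome = outcome
        self.covariates = covariates
        self.site_column = site_column
        self.binary_columns = binary_columns
        self.m_imputations = m_imputations
        self.between_iterations = between_iterations
        self.fit_rounds = fit_rounds
        self.ci_level = ci_level
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame with a site column")
        covs = tuple(self.covariates) or tuple(
            c for c in X.columns if c not in (self.outcome, self.site_column)
        )
        cols = [self.site_column, self.outcome, *covs]
        missing = [c for c in cols if c not in X.columns]
        if missing:
            raise KeyError(f"columns not in X: {missing}")
        if X[self.outcome].isna().any():
            raise ValueError("the analysis outcome must be fully observed")
        fed = federation_from_frame(
            X[cols], site_column=self.site_column,
            binary_columns=set(self.binary_columns),
        )
        specs = make_specs(fed, outcome=self.outcome)
        completed = mice_run(
            fed,
            specs,
            M=self.m_imputations,
            n_between_iter=self.between_iterations,
            fit_rounds=self.fit_rounds,
            seed=self.random_state,
        )
        model = GLMMModel(
            outcome=self.outcome,
            covariates=covs,
            family=Family.gaussian,
            site_column=self.site_column,
        )
        self.result_ = impute_analyze_pool(
            completed, model, fit_rounds=self.fit_rounds, ci_level=self.ci_level
        )
        self.imputations_ = completed
        self.coef_names_ = model.coef_names
        return self

    def summary(self) -> pd.DataFrame:
        check_is_fitted(self, "result_")
        return self.result_.to_frame()
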