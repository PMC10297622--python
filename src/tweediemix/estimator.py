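"""scikit-learn style front end for the three-level Tweedie mixed model."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import estimation
from .data import validate_and_index

__all__ = ["TweedieMixedRegressor"]


class TweedieMixedRegressor(RegressorMixin, BaseEstimator):
    """Three-level Tweedie compound Poisson regression with gamma random effects.

    The marginal mean is log-linear, E[Y] = exp(X'beta), while cluster- and
    sub-cluster-level covariates enter through the means of their gamma
    random effects, so group-level covariates act at their own level instead
    of being attached to individual observations.  Fitting alternates Newton
    scoring for the regression blocks, closed-form BLUP prediction of the
    random effects, and adjusted Pearson moment updates of the dispersions.

    Parameters
    ----------
    p : float, default=1.5
        Tweedie index in (1, 2); fixed during fitting (estimate it
        externally, e.g. by profile likelihood, if unknown).
    level_map : dict or None
        Covariate name -> "cluster" | "subcluster" | "observation".  If
        None, every covariate is treated as observation level (the
        covariate-independent special case).
    cluster_col, subcluster_col : str
        Names of the grouping columns in X.
    fit_intercept : bool, default=True
        Add a constant column to the observation-level block.
    fix_sigma2, fix_tau2, fix_rho2 : float or None
        Pin a dispersion instead of estimating it.
    max_iter, tol_params, tol_score :
        Outer-iteration controls; convergence requires both the maximum
        relative parameter change below ``tol_params`` and the sup norm of
        the estimating function below ``tol_score``.

    Attributes
    ----------
    params_ : ModelParams
        Fitted parameters (coefficient blocks, sigma2, tau2, rho2, p).
    coef_ : ndarray
        Stacked coefficients (cluster, sub-cluster, observation blocks).
    se_, p_values_ : ndarray
        Model-based standard errors (sqrt diag of -S^{-1}) and two-sided
        Wald p-values.
    sigma2_, tau2_, rho2_ : float
        Estimated dispersions.
    blup_ : DataFrame
        Predicted random effects U_hat, V_hat with prediction MSEs.
    result_ : FitResult
        Full fit record (information matrices, trace, convergence flag).

    Examples
    --------
    >>> from tweediemix import TweedieMixedRegressor
    >>> from tweediemix.simulator import tmcdre_reference_design, simulate_tmcdre
    >>> sim = simulate_tmcdre(tmcdre_reference_design(I=80), seed=7)
    >>> est = TweedieMixedRegressor(p=1.55, level_map=sim.level_map,
    ...                             fit_intercept=False)
    >>> est.fit(sim.frame.drop(columns="y"), sim.frame["y"])
    TweedieMixedRegressor(...)
    """

    def __init__(
        self,
        p: float = 1.5,
        level_map: dict[str, str] | None = None,
        cluster_col: str = "cluster",
        subcluster_col: str = "subcluster",
        fit_intercept: bool = True,
        fix_sigma2: float | None = None,
        fix_tau2: float | None = None,
        fix_rho2: float | None = None,
        max_iter: int = 200,
        tol_params: float = 1e-8,
        tol_score: float = 1e-6,
    ):
        self.p = p
        self.level_map = level_map
        self.cluster_col = cluster_col
        self.subcluster_col = subcluster_col
        self.fit_intercept = fit_intercept
        self.fix_sigma2 = fix_sigma2
        self.fix_tau2 = fix_tau2
        self.fix_rho2 = fix_rho2
        self.max_iter = max_iter
        self.tol_params = tol_params
        self.tol_score = tol_score

    def _assemble(self, X: pd.DataFrame, y) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError(
                "X must be a DataFrame with cluster/sub-cluster label columns "
                "and covariate columns"
            )
        table = X.copy()
        table["y"] = np.asarray(y, dtype=float)
        return table

    def _resolved_level_map(self, X: pd.DataFrame) -> dict[str, str]:
        if self.level_map is not None:
            return dict(self.level_map)
        skip = {self.cluster_col, self.subcluster_col}
        return {c: "observation" for c in X.columns if c not in skip}

    def fit(self, X: pd.DataFrame, y):
        """Fit the model to a long-format table.

        X holds the grouping labels and covariates (one row per
        observation); y is the nonnegative semicontinuous response.
        """
        table = self._assemble(X, y)
        level_map = self._resolved_level_map(X)
        data = validate_and_index(
            table,
            level_map,
            cluster_col=self.cluster_col,
            subcluster_col=self.subcluster_col,
            add_intercept=self.fit_intercept,
        )
        result = estimation.fit(
            data,
            self.p,
            fix_sigma2=self.fix_sigma2,
            fix_tau2=self.fix_tau2,
            fix_rho2=self.fix_rho2,
            max_iter=self.max_iter,
            tol_params=self.tol_params,
            tol_score=self.tol_score,
        )
        self.data_ = data
        self.result_ = result
        self.params_ = result.params
        self.coef_ = result.coef
        self.coef_names_ = result.coef_names
        self.se_ = result.se
        self.p_values_ = result.p_values
        self.sigma2_ = result.params.sigma2
        self.tau2_ = result.params.tau2
        self.rho2_ = result.params.rho2
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        self.blup_ = result.blup.to_frame(data)
        self.feature_names_in_ = np.asarray(list(X.columns), dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Marginal mean exp(X'beta) for new covariate rows.

        Grouping columns are ignored; every covariate named in the fitted
        level map must be present.
        """
        check_is_fitted(self, "params_")
        eta = np.zeros(len(X))
        data = self.data_
        blocks = (
            (data.names1, self.params_.beta1),
            (data.names2, self.params_.beta2),
            (data.names3, self.params_.beta3),
        )
        for names, beta in blocks:
            for name, b in zip(names, beta):
                if name == "intercept" and name not in X.columns:
                    eta += b
                    continue
                if name not in X.columns:
                    raise ValueError(f"missing covariate column '{name}'")
                eta += b * pd.to_numeric(X[name]).to_numpy(dtype=float)
        return np.exp(eta)

    def summary(self) -> pd.DataFrame:
        """Coefficient table: level, estimate, SE, two-sided Wald p-value."""
        check_is_fitted(self, "result_")
        return self.result_.summary_frame(self.data_)

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"X_types": ["dataframe"], "allow_nan": False}
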