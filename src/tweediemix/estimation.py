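"""Joint estimation of regression and dispersion parameters.

The regression blocks beta = (beta1, beta2, beta3) solve the optimal
estimating equation psi(beta) = 0, where the level-wise components are

    psi1 = sum_i   Z_i   mu_i^{-1}      sigma2^{-1} (Uhat_i - mu_i)
    psi2 = sum_ij  Z_ij  mu_ij^{-1}     tau2^{-1}   (Vhat_ij - Uhat_i mu_ij)
    psi3 = sum_ijk Z_ijk mu_ijk^{1-p}   rho2^{-1}   (Y_ijk - Vhat_ij mu_ijk)

and, because the BLUPs are linear projections onto Y, the stacked score has
the equivalent global matrix form

    psi(beta) = X' diag(E Y) Var(Y)^{-1} (Y - E Y),

with sensitivity S = -V, variability V = X' D Var(Y)^{-1} D X and Godambe
information J = V (so the model-based asymptotic variance is -S^{-1} = V^{-1}).
Newton scoring updates beta* = beta - S^{-1} psi.  Dispersions are updated by
adjusted Pearson moment estimators whose bias corrections use the closed-form
prediction MSEs d(i), d(ij).  The outer loop iterates scoring -> BLUP ->
dispersion update to joint convergence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .blup import BlupResult, predict_random_effects
from .data import MeanComponents, ModelParams, MultilevelData
from .moments import marginal_covariance, mean_components

__all__ = [
    "FitResult",
    "score_components",
    "global_matrices",
    "scoring_step",
    "update_dispersions",
    "standard_errors",
    "fit",
    "initial_params",
    "profile_index_parameter",
]

logger = logging.getLogger(__name__)

DISPERSION_FLOOR = 1e-10
BOUNDARY_TOL = 1e-3
BOUNDARY_WINDOW = 10
BOUNDARY_DECAY = 0.75


@dataclass
class FitResult:
    """Converged (or diagnosed) fit of the three-level model."""

    params: ModelParams
    se: np.ndarray
    sensitivity: np.ndarray
    variability: np.ndarray
    godambe: np.ndarray
    blup: BlupResult
    coef_names: list[str]
    converged: bool
    n_iter: int
    score_inf_norm: float
    trace: list[dict] = field(default_factory=list)

    @property
    def coef(self) -> np.ndarray:
        return self.params.beta

    @property
    def p_values(self) -> np.ndarray:
        """Two-sided Wald p-values against a standard normal reference."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef / self.se
        return 2.0 * stats.norm.sf(np.abs(z))

    def summary_frame(self, data: MultilevelData | None = None):
        import pandas as pd

        levels = None
        if data is not None:
            levels = (
                ["cluster"] * len(data.names1)
                + ["subcluster"] * len(data.names2)
                + ["observation"] * len(data.names3)
            )
        df = pd.DataFrame(
            {
                "coef": self.coef_names,
                "estimate": self.coef,
                "se": self.se,
                "p_value": self.p_values,
            }
        )
        if levels is not None:
            df.insert(0, "level", levels)
        return df


def score_components(
    data: MultilevelData,
    params: ModelParams,
    blup: BlupResult,
    means: MeanComponents | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Level-wise estimating-function components (psi1, psi2, psi3).

    Requires sigma2 > 0 (if cluster covariates are present) and tau2 > 0
    (if sub-cluster covariates are present); the global matrix route in
    :func:`global_matrices` handles the degenerate limits.
    """
    if means is None:
        means = mean_components(data, params)
    q1, q2, q3 = data.Z1.shape[1], data.Z2.shape[1], data.Z3.shape[1]

    if q1:
        if params.sigma2 <= 0:
            raise ValueError("component-route psi1 requires sigma2 > 0")
        r1 = (blup.U_hat - means.mu_i) / (means.mu_i * params.sigma2)
        psi1 = data.Z1.T @ r1
    else:
        psi1 = np.zeros(0)
    if q2:
        if params.tau2 <= 0:
            raise ValueError("component-route psi2 requires tau2 > 0")
        r2 = (blup.V_hat - blup.U_hat[data.sub_cluster] * means.mu_ij) / (
            means.mu_ij * params.tau2
        )
        psi2 = data.Z2.T @ r2
    else:
        psi2 = np.zeros(0)
    if q3:
        r3 = (
            means.mu_ijk ** (1.0 - params.p)
            * (data.y - blup.V_hat[data.obs_subcluster] * means.mu_ijk)
            / params.rho2
        )
        psi3 = data.Z3.T @ r3
    else:
        psi3 = np.zeros(0)
    return psi1, psi2, psi3


def global_matrices(
    data: MultilevelData,
    params: ModelParams,
    means: MeanComponents | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Global score and information matrices, assembled cluster by cluster.

    Returns ``(psi, S, V, J)`` with psi = X' D Var(Y)^{-1} (Y - E Y),
    V = X' D Var(Y)^{-1} D X, S = -V and J = V, where D = diag(E Y).
    Clusters are independent, so Var(Y) is block diagonal and only
    per-cluster dense solves are needed.
    """
    if means is None:
        means = mean_components(data, params)
    X = data.stacked_design()
    q = X.shape[1]
    psi = np.zeros(q)
    V = np.zeros((q, q))
    mu = means.mu_i[data.obs_cluster] * means.mu_ij[data.obs_subcluster] * means.mu_ijk
    for i, sl in enumerate(data.cluster_slices()):
        cov = marginal_covariance(data, params, i, means)
        DX = X[sl] * mu[sl, None]
        resid = data.y[sl] - mu[sl]
        try:
            factor = cho_factor(cov)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular marginal covariance in cluster {data.cluster_labels[i]}"
            ) from exc
        sol = cho_solve(factor, np.column_stack([resid, DX]))
        psi += DX.T @ sol[:, 0]
        V += DX.T @ sol[:, 1:]
    V = 0.5 * (V + V.T)
    return psi, -V, V, V


def scoring_step(
    data: MultilevelData, params: ModelParams, means: MeanComponents | None = None
) -> np.ndarray:
    """One Newton-scoring update beta* = beta - S^{-1} psi of all blocks."""
    psi, S, _, _ = global_matrices(data, params, means)
    try:
        step = np.linalg.solve(S, psi)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "sensitivity matrix is singular; check the design for collinearity"
        ) from exc
    return params.beta - step


def update_dispersions(
    data: MultilevelData,
    params: ModelParams,
    blup: BlupResult,
    means: MeanComponents | None = None,
    floor: float = DISPERSION_FLOOR,
) -> tuple[float, float, float]:
    """Adjusted Pearson moment estimates of (sigma2, tau2, rho2).

    Each estimator is a Pearson-type average of squared BLUP residuals plus
    an additive bias correction built from the prediction MSEs:

        sigma2_hat = I^{-1} sum_i [(Uhat_i - mu_i)^2 + d(i)] / mu_i^2
        tau2_hat   = I^{-1} sum_i J_i^{-1} sum_j [(Vhat_ij - mu_ij Uhat_i)^2
                     + d(i) mu_ij^2 + d(ij) - 2 rho2 d(i) w_ij mu_ij^2]
                     / (mu_i mu_ij^2)
        rho2_hat   = I^{-1} sum_i J_i^{-1} sum_j n_ij^{-1} sum_k
                     [(Y_ijk - Vhat_ij mu_ijk)^2 / (mu_i mu_ij mu_ijk^p)
                     + d(ij) mu_ijk^(2-p) / (mu_i mu_ij)]

    Nonpositive updates are floored at ``floor`` with a warning.
    """
    if means is None:
        means = mean_components(data, params)
    I = data.n_clusters
    sub = data.sub_cluster
    osub = data.obs_subcluster

    d_i, d_ij = blup.d_i, blup.d_ij
    sigma2 = float(np.mean(((blup.U_hat - means.mu_i) ** 2 + d_i) / means.mu_i**2))

    J_i = data.J_i
    resV = blup.V_hat - means.mu_ij * blup.U_hat[sub]
    corr = (
        d_i[sub] * means.mu_ij**2
        + d_ij
        - 2.0 * params.rho2 * d_i[sub] * means.w_ij * means.mu_ij**2
    )
    per_sub = (resV**2 + corr) / (means.mu_i[sub] * means.mu_ij**2)
    tau2 = float(np.mean(np.bincount(sub, weights=per_sub, minlength=I) / J_i))

    n_ij = data.n_ij
    mu_prod = means.mu_i[sub] * means.mu_ij  # per sub-cluster mu_i * mu_ij
    resY = data.y - blup.V_hat[osub] * means.mu_ijk
    term1 = resY**2 / (mu_prod[osub] * means.mu_ijk**params.p)
    term2 = d_ij[osub] * means.mu_ijk ** (2.0 - params.p) / mu_prod[osub]
    per_sub_r = np.bincount(osub, weights=term1 + term2, minlength=data.n_subclusters) / n_ij
    rho2 = float(np.mean(np.bincount(sub, weights=per_sub_r, minlength=I) / J_i))

    out = []
    for name, val in (("sigma2", sigma2), ("tau2", tau2), ("rho2", rho2)):
        if val <= floor:
            warnings.warn(
                f"dispersion update for {name} was nonpositive ({val:.3e}); "
                f"floored at {floor:g} — possible model misspecification",
                RuntimeWarning,
                stacklevel=2,
            )
            val = floor
        out.append(val)
    return tuple(out)  # type: ignore[return-value]


def _solve_dispersions(
    data: MultilevelData,
    params: ModelParams,
    fix_sigma2: float | None,
    fix_tau2: float | None,
    fix_rho2: float | None,
    tol: float = 1e-12,
    max_inner: int = 500,
) -> tuple[float, float, float]:
    """Fixed point of the adjusted-Pearson map at the current beta.

    The plain one-sweep map is a slow contraction (rates near 1 are common
    at the reference design sizes), so after a short warm-up of plain
    sweeps — which settles the strongly nonlinear transient into the right
    basin — the stationarity condition log F(exp x) - x = 0 is solved over
    the free dispersions with a quasi-Newton root finder in log space
    (positivity is automatic).  The root is verified against the plain map;
    if the root finder fails or leaves the warm-up basin, the solver falls
    back to plain sweeps.  The solution is exactly the stationary point of
    the one-sweep adjusted-Pearson map; pinned dispersions are never moved.
    """
    from scipy import optimize

    free = np.array([fix_sigma2 is None, fix_tau2 is None, fix_rho2 is None])

    def F(theta: np.ndarray) -> np.ndarray:
        pars = params.replace(sigma2=theta[0], tau2=theta[1], rho2=theta[2])
        means = mean_components(data, pars)
        blup = predict_random_effects(data, pars, means)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            upd = np.asarray(update_dispersions(data, pars, blup, means))
        return np.where(free, upd, theta)

    def relnorm(delta: np.ndarray, ref: np.ndarray) -> float:
        return float(np.max(np.abs(delta) / (np.abs(ref) + 1e-12)))

    theta = np.array([params.sigma2, params.tau2, params.rho2], dtype=float)
    if not free.any():
        return tuple(theta)  # type: ignore[return-value]

    # warm-up: plain sweeps through the nonlinear transient
    for _ in range(25):
        t1 = F(theta)
        if relnorm(t1 - theta, theta) < tol:
            return float(t1[0]), float(t1[1]), float(t1[2])
        theta = t1

    def residual(x: np.ndarray) -> np.ndarray:
        full = theta.copy()
        full[free] = np.exp(x)
        out = F(full)
        return np.log(out[free]) - x

    anchor = theta.copy()
    sol = optimize.root(residual, np.log(theta[free]), method="hybr", tol=1e-12)
    cand = theta.copy()
    cand[free] = np.exp(sol.x)
    # accept the root only if it is a genuine fixed point near the warm-up basin
    if (
        sol.success
        and np.all(np.isfinite(cand))
        and relnorm(F(cand) - cand, cand) < 1e-9
        and np.all((cand[free] > anchor[free] / 50.0) & (cand[free] < anchor[free] * 50.0))
    ):
        return float(cand[0]), float(cand[1]), float(cand[2])

    for _ in range(max_inner):  # fallback: plain contraction
        t1 = F(theta)
        if relnorm(t1 - theta, theta) < tol:
            theta = t1
            break
        theta = t1
    return float(theta[0]), float(theta[1]), float(theta[2])


def standard_errors(S: np.ndarray) -> np.ndarray:
    """Model-based standard errors: sqrt of the diagonal of -S^{-1}."""
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        return np.zeros(0)
    try:
        factor = cho_factor(-S)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "sensitivity matrix is not negative definite; standard errors undefined"
        ) from exc
    inv = cho_solve(factor, np.eye(S.shape[0]))
    return np.sqrt(np.diag(inv))


def initial_params(
    data: MultilevelData,
    p: float,
    sigma2: float = 0.1,
    tau2: float = 0.1,
) -> ModelParams:
    """Starting values: a log-link GLM on the observation-level block.

    beta3 comes from a Tweedie quasi-likelihood GLM fit on Z3 ignoring the
    clustering; beta1 and beta2 start at zero; rho2 starts at the Pearson
    dispersion statistic of that GLM.  Cheap and scale-aware.
    """
    q1, q2, q3 = data.Z1.shape[1], data.Z2.shape[1], data.Z3.shape[1]
    beta3 = np.zeros(q3)
    rho2 = 1.0
    if q3:
        try:
            import statsmodels.api as sm

            fam = sm.families.Tweedie(var_power=p, link=sm.families.links.Log())
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(data.y, data.Z3, family=fam).fit()
            beta3 = np.asarray(res.params, dtype=float)
            mu = np.asarray(res.fittedvalues, dtype=float)
        except Exception:  # fall back to intercept-only start
            logger.debug("GLM initialization failed; falling back to flat start")
            const_cols = [
                k for k in range(q3) if np.all(data.Z3[:, k] == data.Z3[0, k]) and data.Z3[0, k] != 0
            ]
            if const_cols:
                beta3[const_cols[0]] = np.log(max(np.mean(data.y), 1e-8)) / data.Z3[0, const_cols[0]]
            mu = np.exp(data.Z3 @ beta3)
        dof = max(data.n_obs - q3, 1)
        rho2 = float(np.sum((data.y - mu) ** 2 / mu**p) / dof)
        rho2 = max(rho2, 1e-6)
    return ModelParams(
        beta1=np.zeros(q1), beta2=np.zeros(q2), beta3=beta3,
        sigma2=sigma2, tau2=tau2, rho2=rho2, p=p,
    )


def profile_index_parameter(
    data: MultilevelData,
    grid: tuple[float, ...] = (1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9),
    **fit_kwargs,
) -> tuple[float, dict[float, float]]:
    """Coarse grid search for the Tweedie index p.

    Fits the model at each grid value and scores it by the mean squared
    marginal Pearson residual, mean[(Y - EY)^2 / Var(Y)], with Var(Y) the
    fitted marginal variance; the grid value whose score is closest to 1 is
    returned together with the full score map.

    This is a heuristic convenience, NOT a maximum-likelihood estimate of p,
    and its discrimination is weak because the dispersion estimates re-adjust
    at every grid value; for serious use estimate p externally by Tweedie
    profile likelihood and pass it to :func:`fit`.
    """
    scores: dict[float, float] = {}
    for p in grid:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = fit(data, p, **fit_kwargs)
        means = mean_components(data, res.params)
        mu = (
            means.mu_i[data.obs_cluster]
            * means.mu_ij[data.obs_subcluster]
            * means.mu_ijk
        )
        var = (
            res.params.sigma2 * mu**2
            + res.params.tau2 * means.mu_i[data.obs_cluster] * (means.mu_ij[data.obs_subcluster] * means.mu_ijk) ** 2
            + res.params.rho2
            * means.mu_i[data.obs_cluster]
            * means.mu_ij[data.obs_subcluster]
            * means.mu_ijk**p
        )
        scores[p] = float(np.mean((data.y - mu) ** 2 / var))
    best = min(scores, key=lambda p: abs(scores[p] - 1.0))
    return best, scores


def _param_vector(params: ModelParams) -> np.ndarray:
    return np.r_[params.beta, params.sigma2, params.tau2, params.rho2]


def fit(
    data: MultilevelData,
    p: float,
    *,
    start: ModelParams | None = None,
    fix_sigma2: float | None = None,
    fix_tau2: float | None = None,
    fix_rho2: float | None = None,
    max_iter: int = 200,
    tol_params: float = 1e-8,
    tol_score: float = 1e-6,
    max_halvings: int = 10,
) -> FitResult:
    """Fit the model by iterating scoring -> BLUP -> dispersion updates.

    Convergence requires both the maximum relative parameter change below
    ``tol_params`` and the sup norm of the estimating function below
    ``tol_score``.  ``fix_*`` pins a dispersion at a given value (useful for
    degenerate special cases such as a pure Tweedie GLM with
    ``fix_sigma2=0, fix_tau2=0``).
    """
    if start is None:
        params = initial_params(data, p)
    else:
        params = start.replace(p=p)
    if fix_sigma2 is not None:
        params = params.replace(sigma2=float(fix_sigma2))
    if fix_tau2 is not None:
        params = params.replace(tau2=float(fix_tau2))
    if fix_rho2 is not None:
        params = params.replace(rho2=float(fix_rho2))

    trace: list[dict] = []
    prev_vec = _param_vector(params)
    rel_change = np.inf
    converged = False
    n_iter = 0
    psi = S = V = None
    update_disp = not (fix_sigma2 is not None and fix_tau2 is not None and fix_rho2 is not None)
    # boundary watch: a free dispersion decaying geometrically toward zero
    # has no interior fixed point; once it is monotone decreasing below
    # BOUNDARY_TOL for BOUNDARY_WINDOW iterations it is pinned at the floor.
    disp_history: list[tuple[float, float, float]] = []

    for it in range(1, max_iter + 1):
        means = mean_components(data, params)
        psi, S, V, _ = global_matrices(data, params, means)
        psi_inf = float(np.max(np.abs(psi))) if psi.size else 0.0
        trace.append(
            {
                "iter": it - 1,
                "beta": params.beta.copy(),
                "sigma2": params.sigma2,
                "tau2": params.tau2,
                "rho2": params.rho2,
                "score_inf_norm": psi_inf,
                "max_rel_change": rel_change if np.isfinite(rel_change) else None,
            }
        )
        if rel_change < tol_params and psi_inf < tol_score:
            converged = True
            n_iter = it - 1
            break
        n_iter = it

        # Newton scoring for beta, with step halving on overflow
        if psi.size:
            step = np.linalg.solve(S, psi)
            scale = 1.0
            for _ in range(max_halvings + 1):
                cand = params.with_beta(params.beta - scale * step)
                try:
                    cand_means = mean_components(data, cand)
                except ValueError:
                    scale *= 0.5
                    continue
                if np.all(np.isfinite(cand_means.mu_ijk)):
                    params, means = cand, cand_means
                    break
                scale *= 0.5
            else:
                raise RuntimeError(
                    "scoring step diverged (non-finite linear predictor); "
                    f"last good estimates: {prev_vec}"
                )

        # BLUP at the updated beta, then dispersion update (solved to its
        # fixed point at the current beta via Steffensen acceleration)
        if update_disp:
            s2, t2, r2 = _solve_dispersions(data, params, fix_sigma2, fix_tau2, fix_rho2)
            params = params.replace(sigma2=s2, tau2=t2, rho2=r2)
            disp_history.append((s2, t2, r2))
            if len(disp_history) > BOUNDARY_WINDOW:
                window = disp_history[-(BOUNDARY_WINDOW + 1):]
                for k, name in enumerate(("sigma2", "tau2", "rho2")):
                    if (fix_sigma2, fix_tau2, fix_rho2)[k] is not None or name == "rho2":
                        continue
                    vals = [w[k] for w in window]
                    if (
                        vals[-1] < BOUNDARY_TOL
                        and vals[-1] < BOUNDARY_DECAY * vals[0]
                        and all(b < a for a, b in zip(vals, vals[1:]))
                    ):
                        warnings.warn(
                            f"{name} is decaying toward the zero boundary "
                            f"({vals[-1]:.3e}); pinning it at {DISPERSION_FLOOR:g}",
                            RuntimeWarning,
                            stacklevel=2,
                        )
                        if name == "sigma2":
                            fix_sigma2 = DISPERSION_FLOOR
                            params = params.replace(sigma2=DISPERSION_FLOOR)
                        else:
                            fix_tau2 = DISPERSION_FLOOR
                            params = params.replace(tau2=DISPERSION_FLOOR)
        new_vec = _param_vector(params)
        if not np.all(np.isfinite(new_vec)):
            raise RuntimeError(
                f"parameters diverged to non-finite values; last good: {prev_vec}"
            )
        denom = np.abs(prev_vec) + 1e-10
        rel_change = float(np.max(np.abs(new_vec - prev_vec) / denom)) if new_vec.size else 0.0
        prev_vec = new_vec

    means = mean_components(data, params)
    if not converged:
        psi, S, V, _ = global_matrices(data, params, means)
        logger.warning("fit did not converge in %d iterations", max_iter)
    blup = predict_random_effects(data, params, means)
    se = standard_errors(S) if S.size else np.zeros(0)
    return FitResult(
        params=params,
        se=se,
        sensitivity=S,
        variability=V,
        godambe=V,
        blup=blup,
        coef_names=data.coef_names,
        converged=converged,
        n_iter=n_iter,
        score_inf_norm=float(np.max(np.abs(psi))) if psi is not None and psi.size else 0.0,
        trace=trace,
    )
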