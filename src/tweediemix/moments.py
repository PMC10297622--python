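"""Exact marginal moment structure of the three-level model.

All formulas follow from conditioning on the gamma random-effect layers:
U_i ~ Gamma(mean mu_i, dispersion sigma2), V_ij | U ~ Gamma(mean mu_ij U_i,
dispersion tau2 / U_i) and Y_ijk | V ~ Tweedie_p(mean mu_ijk V_ij,
dispersion rho2 V_ij**(1-p)).  In particular

    E[Y_ijk]            = mu_i mu_ij mu_ijk = exp(X_ijk' beta)
    Cov[Y_stl, Y_ijk]   = d(s,i) sigma2 mu_i^2 mu_ij mu_it mu_ijk mu_itl
                          + d(s,i) d(t,j) [tau2 mu_i mu_ij^2 mu_ijk mu_ijl
                          + d(l,k) rho2 mu_i mu_ij mu_ijk^p]

with d(.,.) the Kronecker delta.  The dense per-cluster covariance built
here is the oracle against which every closed-form predictor is checked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ETA_MAX, MeanComponents, ModelParams, MultilevelData

__all__ = [
    "mean_components",
    "marginal_mean",
    "marginal_covariance",
    "random_effect_moments",
    "RandomEffectMoments",
]


def _safe_exp(eta: np.ndarray, what: str) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if eta.size and np.max(np.abs(eta)) > ETA_MAX:
        raise ValueError(
            f"{what} linear predictor exceeds |eta| = {ETA_MAX:g}; "
            "rescale or center the covariates"
        )
    return np.exp(eta)


def mean_components(data: MultilevelData, params: ModelParams) -> MeanComponents:
    """Evaluate mu_i, mu_ij, mu_ijk under the log link, plus the weights w_ij."""
    mu_i = _safe_exp(data.Z1 @ params.beta1 if data.Z1.shape[1] else np.zeros(data.n_clusters), "cluster-level")
    mu_ij = _safe_exp(data.Z2 @ params.beta2 if data.Z2.shape[1] else np.zeros(data.n_subclusters), "sub-cluster-level")
    mu_ijk = _safe_exp(data.Z3 @ params.beta3 if data.Z3.shape[1] else np.zeros(data.n_obs), "observation-level")

    s2mp = np.bincount(
        data.obs_subcluster, weights=mu_ijk ** (2.0 - params.p), minlength=data.n_subclusters
    )
    w_ij = 1.0 / (params.rho2 + params.tau2 * mu_ij * s2mp)
    return MeanComponents(mu_i=mu_i, mu_ij=mu_ij, mu_ijk=mu_ijk, w_ij=w_ij)


def marginal_mean(
    data: MultilevelData, params: ModelParams, means: MeanComponents | None = None
) -> np.ndarray:
    """Per-observation marginal mean mu_i * mu_ij * mu_ijk (= exp(X'beta))."""
    if means is None:
        means = mean_components(data, params)
    return (
        means.mu_i[data.obs_cluster]
        * means.mu_ij[data.obs_subcluster]
        * means.mu_ijk
    )


def marginal_covariance(
    data: MultilevelData,
    params: ModelParams,
    cluster: int,
    means: MeanComponents | None = None,
) -> np.ndarray:
    """Dense covariance matrix of the observations of one cluster.

    Rows/columns follow the dataset's fixed (sub-cluster, observation)
    ordering.  The matrix is symmetric and positive definite whenever
    rho2 > 0 and the dispersions are nonnegative.
    """
    if means is None:
        means = mean_components(data, params)
    if not (0 <= cluster < data.n_clusters):
        raise ValueError(f"cluster index {cluster} out of range")
    sl = data.cluster_slices()[cluster]
    sub = data.obs_subcluster[sl]
    mu_ijk = means.mu_ijk[sl]
    mu_ij = means.mu_ij[sub]
    mu_i = means.mu_i[cluster]

    a = mu_ij * mu_ijk  # per observation: mu_ij * mu_ijk
    cov = params.sigma2 * mu_i**2 * np.outer(a, a)
    # tau2 term: tau2 * mu_i * mu_ij^2 * mu_ijk * mu_ijl on the same sub-cluster
    same_sub = sub[:, None] == sub[None, :]
    cov += np.where(same_sub, params.tau2 * mu_i * np.outer(a, a), 0.0)
    cov[np.diag_indices_from(cov)] += params.rho2 * mu_i * mu_ij * mu_ijk**params.p
    if not np.all(np.isfinite(cov)):
        raise ValueError(f"non-finite covariance entries in cluster {cluster}")
    return cov


@dataclass
class RandomEffectMoments:
    """First two moments of (U, V) and their covariances with Y, per cluster.

    For cluster i (observations ordered as in the dataset):

    - ``EU`` = mu_i, ``varU`` = sigma2 * mu_i**2
    - ``EV_j`` = mu_i * mu_ij,
      ``covV[j, t]`` = sigma2 mu_i^2 mu_ij mu_it + d(t,j) tau2 mu_i mu_ij^2
    - ``covUY[jk]`` = sigma2 mu_i^2 mu_ij mu_ijk
    - ``covVY[j, tl]`` = mu_itl * (sigma2 mu_i^2 mu_ij mu_it
      + d(t,j) tau2 mu_i mu_ij^2)

    These are exactly the ingredients of the matrix-form BLUPs.
    """

    EU: float
    varU: float
    EV: np.ndarray  # (J_i,)
    covV: np.ndarray  # (J_i, J_i)
    covUY: np.ndarray  # (n_i,)
    covVY: np.ndarray  # (J_i, n_i)
    sub_local: np.ndarray  # (n_i,) local sub-cluster index of each observation


def random_effect_moments(
    data: MultilevelData,
    params: ModelParams,
    cluster: int,
    means: MeanComponents | None = None,
) -> RandomEffectMoments:
    """Moments of the random effects of one cluster and their covariances with Y."""
    if means is None:
        means = mean_components(data, params)
    sl = data.cluster_slices()[cluster]
    sub_global = data.obs_subcluster[sl]
    subs = np.unique(sub_global)  # sorted == dataset order
    sub_local = np.searchsorted(subs, sub_global)

    mu_i = means.mu_i[cluster]
    mu_ij = means.mu_ij[subs]
    mu_ijk = means.mu_ijk[sl]

    EU = float(mu_i)
    varU = params.sigma2 * mu_i**2
    EV = mu_i * mu_ij
    covV = params.sigma2 * mu_i**2 * np.outer(mu_ij, mu_ij)
    covV[np.diag_indices_from(covV)] += params.tau2 * mu_i * mu_ij**2

    covUY = params.sigma2 * mu_i**2 * mu_ij[sub_local] * mu_ijk
    base = params.sigma2 * mu_i**2 * np.outer(mu_ij, mu_ij[sub_local])
    same = np.arange(len(subs))[:, None] == sub_local[None, :]
    base += np.where(same, params.tau2 * mu_i * (mu_ij**2)[:, None], 0.0)
    covVY = base * mu_ijk[None, :]
    return RandomEffectMoments(
        EU=EU, varU=varU, EV=EV, covV=covV, covUY=covUY, covVY=covVY, sub_local=sub_local
    )
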