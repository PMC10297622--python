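"""Orthodox best linear unbiased prediction of the random effects.

The orthodox BLUP of a random effect W given the responses Y of its cluster
is E(W) + Cov(W, Y) Var(Y)^{-1} (Y - E(Y)): the best predictor among all
linear-in-Y unbiased predictors, requiring only the first two joint moments.
For this model the predictors collapse to explicit positive combinations of
the responses,

    Uhat_i = [mu_i + sigma2 mu_i sum_jk w_ij mu_ijk^(1-p) Y_ijk]
             / [1 + sigma2 mu_i sum_jk w_ij mu_ij mu_ijk^(2-p)]
    Vhat_ij = rho2 w_ij mu_ij Uhat_i
              + tau2 mu_ij w_ij sum_k mu_ijk^(1-p) Y_ijk

with w_ij = 1 / (rho2 + tau2 mu_ij sum_k mu_ijk^(2-p)), together with the
closed-form prediction mean squared errors

    d(i)  = sigma2 mu_i^2 / [1 + sigma2 mu_i sum_jk w_ij mu_ij mu_ijk^(2-p)]
    d(ij) = rho2 w_ij tau2 mu_i mu_ij^2 + (rho2 w_ij)^2 mu_ij^2 d(i).

The grouping of the d(ij) expression (the exponent on the rho2 w_ij factor
multiplying d(i)) is fixed by requiring exact agreement with the dense
matrix form Var(W) - Cov(W, Y) Var(Y)^{-1} Cov(Y, W); the squared factor is
the coefficient of Uhat_i in Vhat_ij, so the cluster-level prediction error
propagates quadratically.

``predict_U_matrix`` / ``predict_V_matrix`` / ``prediction_mse_matrix``
evaluate the same quantities by dense per-cluster linear algebra and serve
as the oracle for the explicit forms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .data import MeanComponents, ModelParams, MultilevelData
from .moments import marginal_covariance, mean_components, random_effect_moments

__all__ = [
    "BlupResult",
    "predict_U_explicit",
    "predict_U_matrix",
    "predict_V",
    "predict_V_matrix",
    "prediction_mse",
    "prediction_mse_matrix",
    "predict_random_effects",
]


@dataclass
class BlupResult:
    """Predicted random effects with their prediction MSEs.

    ``U_hat[i]`` predicts the cluster effect U_i, ``V_hat[ij]`` the
    sub-cluster effect V_ij; ``d_i`` and ``d_ij`` are E(Uhat - U)^2 and
    E(Vhat - V)^2.  d(i) never exceeds the prior variance sigma2 * mu_i^2.
    """

    U_hat: np.ndarray  # (I,)
    V_hat: np.ndarray  # (M,)
    d_i: np.ndarray  # (I,)
    d_ij: np.ndarray  # (M,)

    def to_frame(self, data: MultilevelData) -> pd.DataFrame:
        sub_labels = data.subcluster_labels
        df = pd.DataFrame(
            {
                "cluster": [cl for cl, _ in sub_labels],
                "subcluster": [sc for _, sc in sub_labels],
                "U_hat": self.U_hat[data.sub_cluster],
                "V_hat": self.V_hat,
                "d_i": self.d_i[data.sub_cluster],
                "d_ij": self.d_ij,
            }
        )
        return df


def _sums(data: MultilevelData, params: ModelParams, means: MeanComponents):
    """Per-cluster building blocks A_i, B_i and per-sub-cluster C_ij.

    A_i = sum_j w_ij sum_k mu_ijk^(1-p) Y_ijk
    B_i = sum_j w_ij mu_ij sum_k mu_ijk^(2-p)
    C_ij = sum_k mu_ijk^(1-p) Y_ijk
    """
    m1p = means.mu_ijk ** (1.0 - params.p)
    C_ij = np.bincount(data.obs_subcluster, weights=m1p * data.y, minlength=data.n_subclusters)
    s2mp = np.bincount(
        data.obs_subcluster, weights=means.mu_ijk ** (2.0 - params.p), minlength=data.n_subclusters
    )
    A_i = np.bincount(data.sub_cluster, weights=means.w_ij * C_ij, minlength=data.n_clusters)
    B_i = np.bincount(
        data.sub_cluster, weights=means.w_ij * means.mu_ij * s2mp, minlength=data.n_clusters
    )
    return A_i, B_i, C_ij


def predict_U_explicit(
    data: MultilevelData, params: ModelParams, means: MeanComponents | None = None
) -> np.ndarray:
    """Closed-form BLUP of the cluster-level random effects."""
    if means is None:
        means = mean_components(data, params)
    A_i, B_i, _ = _sums(data, params, means)
    return means.mu_i * (1.0 + params.sigma2 * A_i) / (1.0 + params.sigma2 * means.mu_i * B_i)


def predict_V(
    data: MultilevelData,
    params: ModelParams,
    means: MeanComponents | None = None,
    U_hat: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form BLUP of the sub-cluster-level random effects."""
    if means is None:
        means = mean_components(data, params)
    if U_hat is None:
        U_hat = predict_U_explicit(data, params, means)
    _, _, C_ij = _sums(data, params, means)
    U_per_sub = U_hat[data.sub_cluster]
    return (
        params.rho2 * means.w_ij * means.mu_ij * U_per_sub
        + params.tau2 * means.mu_ij * means.w_ij * C_ij
    )


def prediction_mse(
    data: MultilevelData,
    params: ModelParams,
    means: MeanComponents | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form prediction MSEs (d_i per cluster, d_ij per sub-cluster)."""
    if means is None:
        means = mean_components(data, params)
    _, B_i, _ = _sums(data, params, means)
    d_i = params.sigma2 * means.mu_i**2 / (1.0 + params.sigma2 * means.mu_i * B_i)
    rw = params.rho2 * means.w_ij
    d_ij = means.mu_ij**2 * (
        rw * params.tau2 * means.mu_i[data.sub_cluster] + rw**2 * d_i[data.sub_cluster]
    )
    return d_i, d_ij


def predict_random_effects(
    data: MultilevelData, params: ModelParams, means: MeanComponents | None = None
) -> BlupResult:
    """All closed-form BLUPs and MSEs in one pass."""
    if means is None:
        means = mean_components(data, params)
    U_hat = predict_U_explicit(data, params, means)
    V_hat = predict_V(data, params, means, U_hat)
    d_i, d_ij = prediction_mse(data, params, means)
    return BlupResult(U_hat=U_hat, V_hat=V_hat, d_i=d_i, d_ij=d_ij)


# ---------------------------------------------------------------------------
# dense-matrix oracle forms
# ---------------------------------------------------------------------------


def _cluster_solve(data, params, means, cluster):
    """Cholesky factor of the cluster covariance and the centred responses."""
    sl = data.cluster_slices()[cluster]
    cov = marginal_covariance(data, params, cluster, means)
    try:
        factor = cho_factor(cov)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate input
        raise np.linalg.LinAlgError(
            f"singular marginal covariance in cluster {data.cluster_labels[cluster]}"
        ) from exc
    mu = (
        means.mu_i[data.obs_cluster[sl]]
        * means.mu_ij[data.obs_subcluster[sl]]
        * means.mu_ijk[sl]
    )
    resid = data.y[sl] - mu
    return factor, resid, sl


def predict_U_matrix(
    data: MultilevelData, params: ModelParams, means: MeanComponents | None = None
) -> np.ndarray:
    """Matrix-form BLUP E(U_i) + Cov(U_i, Y_i) Var(Y_i)^{-1} (Y_i - E(Y_i))."""
    if means is None:
        means = mean_components(data, params)
    out = np.empty(data.n_clusters)
    for i in range(data.n_clusters):
        rem = random_effect_moments(data, params, i, means)
        factor, resid, _ = _cluster_solve(data, params, means, i)
        out[i] = rem.EU + rem.covUY @ cho_solve(factor, resid)
    return out


def predict_V_matrix(
    data: MultilevelData, params: ModelParams, means: MeanComponents | None = None
) -> np.ndarray:
    """Matrix-form BLUP of every sub-cluster effect."""
    if means is None:
        means = mean_components(data, params)
    out = np.empty(data.n_subclusters)
    pos = 0
    for i in range(data.n_clusters):
        rem = random_effect_moments(data, params, i, means)
        factor, resid, _ = _cluster_solve(data, params, means, i)
        sol = cho_solve(factor, resid)
        J = rem.EV.size
        out[pos : pos + J] = rem.EV + rem.covVY @ sol
        pos += J
    return out


def prediction_mse_matrix(
    data: MultilevelData, params: ModelParams, means: MeanComponents | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Dense-matrix MSEs Var(W) - Cov(W, Y) Var(Y)^{-1} Cov(Y, W)."""
    if means is None:
        means = mean_components(data, params)
    d_i = np.empty(data.n_clusters)
    d_ij = np.empty(data.n_subclusters)
    pos = 0
    for i in range(data.n_clusters):
        rem = random_effect_moments(data, params, i, means)
        factor, _, _ = _cluster_solve(data, params, means, i)
        d_i[i] = rem.varU - rem.covUY @ cho_solve(factor, rem.covUY)
        J = rem.EV.size
        sol = cho_solve(factor, rem.covVY.T)  # (n_i, J)
        d_ij[pos : pos + J] = np.diag(rem.covV) - np.einsum("jn,nj->j", rem.covVY, sol)
        pos += J
    return d_i, d_ij
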