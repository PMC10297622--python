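"""Validated three-level data container and model parameters.

The data layout is long format: one row per observation, with a cluster
label, a sub-cluster label (unique within its cluster) and a nonnegative
response.  Covariates act at exactly one of the three levels: cluster-level
covariates are constant within a cluster, sub-cluster-level covariates are
constant within a sub-cluster, and observation-level covariates may vary
freely.  Rows are re-ordered deterministically (clusters, then sub-clusters,
then observations, by sorted label) so every downstream matrix has a fixed,
documented row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "ModelParams",
    "MultilevelData",
    "MeanComponents",
    "validate_and_index",
]

LEVELS = ("cluster", "subcluster", "observation")

#: linear predictors beyond this magnitude would overflow / underflow exp()
ETA_MAX = 700.0


@dataclass
class ModelParams:
    """Parameters of the three-level Tweedie compound Poisson mixed model.

    ``beta1``/``beta2``/``beta3`` are the regression blocks acting on the
    cluster-, sub-cluster- and observation-level means through a log link
    (the intercept, if any, lives in ``beta3``).  ``sigma2`` and ``tau2``
    are the dispersions of the gamma random-effect layers (a gamma with
    mean m and dispersion phi has variance phi * m**2), ``rho2`` is the
    Tweedie dispersion of the response layer and ``p`` the Tweedie index,
    restricted to (1, 2) so the response has positive mass at exactly zero.
    """

    beta1: np.ndarray
    beta2: np.ndarray
    beta3: np.ndarray
    sigma2: float
    tau2: float
    rho2: float
    p: float

    def __post_init__(self) -> None:
        self.beta1 = np.atleast_1d(np.asarray(self.beta1, dtype=float))
        self.beta2 = np.atleast_1d(np.asarray(self.beta2, dtype=float))
        self.beta3 = np.atleast_1d(np.asarray(self.beta3, dtype=float))
        if not (1.0 < self.p < 2.0):
            raise ValueError(f"Tweedie index p must lie in (1, 2); got {self.p}")
        for name in ("sigma2", "tau2", "rho2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative; got {getattr(self, name)}")
        if self.rho2 <= 0:
            raise ValueError(f"rho2 must be strictly positive; got {self.rho2}")

    @property
    def beta(self) -> np.ndarray:
        """Stacked coefficient vector (beta1, beta2, beta3)."""
        return np.concatenate([self.beta1, self.beta2, self.beta3])

    def with_beta(self, beta: np.ndarray) -> "ModelParams":
        """Return a copy with the stacked coefficient vector replaced."""
        q1, q2 = self.beta1.size, self.beta2.size
        beta = np.asarray(beta, dtype=float)
        return ModelParams(
            beta1=beta[:q1],
            beta2=beta[q1 : q1 + q2],
            beta3=beta[q1 + q2 :],
            sigma2=self.sigma2,
            tau2=self.tau2,
            rho2=self.rho2,
            p=self.p,
        )

    def replace(self, **kwargs) -> "ModelParams":
        d = dict(
            beta1=self.beta1,
            beta2=self.beta2,
            beta3=self.beta3,
            sigma2=self.sigma2,
            tau2=self.tau2,
            rho2=self.rho2,
            p=self.p,
        )
        d.update(kwargs)
        return ModelParams(**d)


@dataclass
class MultilevelData:
    """Validated, deterministically ordered three-level dataset.

    Observations are sorted by (cluster label, sub-cluster label, original
    order).  Sub-clusters are indexed globally (0..M-1); ``sub_cluster``
    maps each of the M sub-clusters to its cluster.
    """

    y: np.ndarray  # (N,) nonnegative responses
    Z1: np.ndarray  # (I, q1) cluster-level design
    Z2: np.ndarray  # (M, q2) sub-cluster-level design
    Z3: np.ndarray  # (N, q3) observation-level design
    obs_cluster: np.ndarray  # (N,) cluster index of each observation
    obs_subcluster: np.ndarray  # (N,) global sub-cluster index of each observation
    sub_cluster: np.ndarray  # (M,) cluster index of each sub-cluster
    cluster_labels: list
    subcluster_labels: list  # list of (cluster label, subcluster label)
    names1: list[str] = field(default_factory=list)
    names2: list[str] = field(default_factory=list)
    names3: list[str] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return self.y.size

    @property
    def n_clusters(self) -> int:
        return self.Z1.shape[0]

    @property
    def n_subclusters(self) -> int:
        return self.Z2.shape[0]

    @property
    def J_i(self) -> np.ndarray:
        """Number of sub-clusters per cluster."""
        return np.bincount(self.sub_cluster, minlength=self.n_clusters)

    @property
    def n_ij(self) -> np.ndarray:
        """Number of observations per sub-cluster."""
        return np.bincount(self.obs_subcluster, minlength=self.n_subclusters)

    @property
    def coef_names(self) -> list[str]:
        return list(self.names1) + list(self.names2) + list(self.names3)

    def stacked_design(self) -> np.ndarray:
        """Per-observation design X with rows (Z_i', Z_ij', Z_ijk')."""
        return np.hstack(
            [
                self.Z1[self.obs_cluster],
                self.Z2[self.obs_subcluster],
                self.Z3,
            ]
        )

    def cluster_slices(self) -> list[slice]:
        """Contiguous observation slice of each cluster (rows are sorted)."""
        counts = np.bincount(self.obs_cluster, minlength=self.n_clusters)
        ends = np.cumsum(counts)
        starts = ends - counts
        return [slice(int(s), int(e)) for s, e in zip(starts, ends)]

    def subcluster_slices(self) -> list[slice]:
        counts = self.n_ij
        ends = np.cumsum(counts)
        starts = ends - counts
        return [slice(int(s), int(e)) for s, e in zip(starts, ends)]


@dataclass
class MeanComponents:
    """Log-link mean structure and the per-sub-cluster BLUP weights.

    ``w_ij = 1 / (rho2 + tau2 * mu_ij * sum_k mu_ijk**(2-p))`` appears in
    every closed-form predictor; it is bounded above by 1/rho2.
    """

    mu_i: np.ndarray  # (I,)
    mu_ij: np.ndarray  # (M,)
    mu_ijk: np.ndarray  # (N,)
    w_ij: np.ndarray  # (M,)


def _require_columns(table: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")


def validate_and_index(
    table: pd.DataFrame,
    level_map: dict[str, str],
    *,
    cluster_col: str = "cluster",
    subcluster_col: str = "subcluster",
    response_col: str = "y",
    add_intercept: bool = False,
    check_rank: bool = True,
) -> MultilevelData:
    """Validate a long-format table and build the indexed dataset.

    Parameters
    ----------
    table:
        One row per observation with cluster/sub-cluster labels, the
        nonnegative response and covariate columns.
    level_map:
        Mapping covariate name -> "cluster" | "subcluster" | "observation".
        Every covariate used must appear here.
    add_intercept:
        If True, append a constant column named "intercept" to the
        observation-level block.

    Raises
    ------
    ValueError
        On negative or missing responses (naming the row), covariates
        varying within their declared level (naming cluster and covariate),
        misplaced intercepts, or a rank-deficient stacked design.
    """
    _require_columns(table, [cluster_col, subcluster_col, response_col])
    bad_level = {c: lv for c, lv in level_map.items() if lv not in LEVELS}
    if bad_level:
        raise ValueError(f"unknown level assignment(s): {bad_level}; levels are {LEVELS}")
    missing_cov = [c for c in level_map if c not in table.columns]
    if missing_cov:
        raise ValueError(f"covariate(s) in level map not found in data: {missing_cov}")

    y_raw = pd.to_numeric(table[response_col], errors="coerce")
    if y_raw.isna().any():
        row = int(np.flatnonzero(y_raw.isna().to_numpy())[0])
        raise ValueError(f"response '{response_col}' is missing or non-numeric at row {row}")
    if (y_raw < 0).any():
        row = int(np.flatnonzero((y_raw < 0).to_numpy())[0])
        raise ValueError(f"negative response at row {row}: y={y_raw.iloc[row]}")

    covs = list(level_map)
    for c in covs:
        vals = pd.to_numeric(table[c], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ValueError(f"covariate '{c}' is missing or non-numeric at row {row}")

    df = table[[cluster_col, subcluster_col, response_col] + covs].copy()
    df[response_col] = y_raw.to_numpy(dtype=float)
    for c in covs:
        df[c] = pd.to_numeric(df[c]).astype(float)
    # deterministic ordering: sorted cluster label, sub-cluster label, input order
    df["_ord"] = np.arange(len(df))
    df[cluster_col] = df[cluster_col].astype(str)
    df[subcluster_col] = df[subcluster_col].astype(str)
    df = df.sort_values([cluster_col, subcluster_col, "_ord"], kind="stable")
    df = df.reset_index(drop=True)

    # constancy of covariates within their declared level
    for c, lv in level_map.items():
        if lv == "cluster":
            n_unique = df.groupby(cluster_col, sort=False)[c].nunique()
            bad = n_unique[n_unique > 1]
            if len(bad):
                raise ValueError(
                    f"cluster-level covariate '{c}' varies within cluster "
                    f"'{bad.index[0]}'"
                )
        elif lv == "subcluster":
            n_unique = df.groupby([cluster_col, subcluster_col], sort=False)[c].nunique()
            bad = n_unique[n_unique > 1]
            if len(bad):
                raise ValueError(
                    f"sub-cluster-level covariate '{c}' varies within sub-cluster "
                    f"{bad.index[0]}"
                )

    cluster_codes, cluster_labels = pd.factorize(df[cluster_col], sort=True)
    sub_key = pd.MultiIndex.from_arrays([df[cluster_col], df[subcluster_col]])
    sub_codes, sub_labels = pd.factorize(sub_key, sort=True)

    names1 = [c for c in covs if level_map[c] == "cluster"]
    names2 = [c for c in covs if level_map[c] == "subcluster"]
    names3 = [c for c in covs if level_map[c] == "observation"]

    # constant (intercept-like) columns must live in the observation block;
    # only meaningful once there is more than one group to distinguish
    for c in covs:
        vals = df[c].to_numpy()
        if (
            vals.size > 1
            and df[cluster_col].nunique() > 1
            and np.all(vals == vals[0])
            and vals[0] != 0.0
        ):
            if level_map[c] != "observation":
                raise ValueError(
                    f"constant column '{c}' must be assigned to the observation "
                    "level (the single intercept lives in the observation block)"
                )
    if add_intercept:
        if any(np.all(df[c].to_numpy() == 1.0) for c in names3):
            raise ValueError("add_intercept=True but a constant 1 column already exists")
        df["intercept"] = 1.0
        names3 = ["intercept"] + names3

    first_of_cluster = np.flatnonzero(np.r_[True, cluster_codes[1:] != cluster_codes[:-1]])
    first_of_sub = np.flatnonzero(np.r_[True, sub_codes[1:] != sub_codes[:-1]])

    Z1 = df.iloc[first_of_cluster][names1].to_numpy(dtype=float).reshape(len(cluster_labels), len(names1))
    Z2 = df.iloc[first_of_sub][names2].to_numpy(dtype=float).reshape(len(sub_labels), len(names2))
    Z3 = df[names3].to_numpy(dtype=float).reshape(len(df), len(names3))

    sub_cluster = cluster_codes[first_of_sub]

    data = MultilevelData(
        y=df[response_col].to_numpy(dtype=float),
        Z1=Z1,
        Z2=Z2,
        Z3=Z3,
        obs_cluster=np.asarray(cluster_codes, dtype=np.intp),
        obs_subcluster=np.asarray(sub_codes, dtype=np.intp),
        sub_cluster=np.asarray(sub_cluster, dtype=np.intp),
        cluster_labels=list(cluster_labels),
        subcluster_labels=list(sub_labels),
        names1=names1,
        names2=names2,
        names3=names3,
    )

    n_coef = len(names1) + len(names2) + len(names3)
    if check_rank and n_coef:
        X = data.stacked_design()
        if np.linalg.matrix_rank(X) < n_coef:
            raise ValueError(
                "stacked design matrix (Z_i, Z_ij, Z_ijk) is rank deficient; "
                "remove collinear covariates (note: only one constant column, "
                "at the observation level, is identifiable)"
            )
    return data
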