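"""Hierarchical simulation of three-level semicontinuous data.

The generative hierarchy is

    U_i              ~ Gamma(mean mu_i, dispersion sigma2)
    V_ij | U_i = u   ~ Gamma(mean mu_ij u, dispersion tau2 / u)
    Y_ijk | V_ij = v ~ Tweedie_p(mean mu_ijk v, dispersion rho2 v**(1-p))

where a Gamma(mean m, dispersion phi) has shape 1/phi and scale phi*m
(variance phi*m**2) and the Tweedie layer is drawn exactly through its
compound Poisson representation: a Poisson number of iid gamma summands,
which places positive probability mass at exactly zero for 1 < p < 2.

The default designs mirror a family study of adolescent mental-health
scores: 269 clusters (parents), 1-5 sub-clusters (adolescents) each, 1-17
repeated observations each, with binary and age-like covariates at their
natural levels.  The covariate generators are a plausible reconstruction
(Bernoulli(0.5) binaries, uniform ages, uniform-integer months in study);
see the methods note for what they do and do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ModelParams, MultilevelData, validate_and_index

__all__ = [
    "CovariateSpec",
    "SimDesign",
    "SimulationResult",
    "sample_gamma_mean_disp",
    "sample_tweedie_cp",
    "simulate_tmcdre",
    "simulate_ctmm",
    "resimulate",
    "random_design",
    "tmcdre_reference_params",
    "ctmm_reference_params",
    "tmcdre_reference_design",
    "ctmm_reference_design",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One simulated covariate: its level and marginal generator."""

    name: str
    level: str  # cluster | subcluster | observation
    kind: str  # constant | binary | uniform | uniform_int
    value: float = 1.0  # for constant
    prob: float = 0.5  # for binary
    low: float = 0.0  # for uniform / uniform_int
    high: float = 1.0

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, self.value, dtype=float)
        if self.kind == "binary":
            if not 0.0 <= self.prob <= 1.0:
                raise ValueError(f"probability for '{self.name}' outside [0, 1]")
            return rng.binomial(1, self.prob, size=n).astype(float)
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, size=n)
        if self.kind == "uniform_int":
            return rng.integers(int(self.low), int(self.high) + 1, size=n).astype(float)
        raise ValueError(f"unknown covariate kind '{self.kind}' for '{self.name}'")


@dataclass
class SimDesign:
    """Simulation design: cluster structure, parameters and covariates.

    ``J_range`` and ``n_range`` are inclusive; sub-cluster counts and
    per-sub-cluster observation counts are drawn uniformly over them.
    ``coef`` maps covariate name -> true coefficient; the coefficient order
    within each level follows the order of ``covariates``.
    """

    I: int
    J_range: tuple[int, int]
    n_range: tuple[int, int]
    params: ModelParams
    covariates: list[CovariateSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.I < 1:
            raise ValueError("need at least one cluster")
        for name, (lo, hi) in (("J_range", self.J_range), ("n_range", self.n_range)):
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} must be a nonempty range of positive sizes")
        for lv, block in (("cluster", self.params.beta1), ("subcluster", self.params.beta2), ("observation", self.params.beta3)):
            n_cov = sum(1 for c in self.covariates if c.level == lv)
            if n_cov != block.size:
                raise ValueError(
                    f"{lv}-level coefficient block has {block.size} entries but "
                    f"{n_cov} covariates are declared at that level"
                )

    @property
    def level_map(self) -> dict[str, str]:
        return {c.name: c.level for c in self.covariates}


@dataclass
class SimulationResult:
    """Simulated dataset with the generating truth attached."""

    frame: pd.DataFrame  # long format: cluster, subcluster, y, covariates
    data: MultilevelData
    U: np.ndarray  # (I,) true cluster effects
    V: np.ndarray  # (M,) true sub-cluster effects, dataset order
    params: ModelParams
    level_map: dict[str, str]


def sample_gamma_mean_disp(
    mean, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma draws in the (mean, dispersion) parameterization.

    Shape 1/dispersion, scale dispersion*mean, so E = mean and
    Var = dispersion * mean**2.  dispersion = 0 returns the mean exactly.
    ``dispersion`` may be a scalar or an array broadcastable to ``mean``.
    """
    mean = np.asarray(mean, dtype=float)
    dispersion = np.asarray(dispersion, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("gamma mean must be strictly positive")
    if np.any(dispersion < 0):
        raise ValueError("gamma dispersion must be nonnegative")
    out = np.where(dispersion > 0,
                   rng.gamma(np.where(dispersion > 0, 1.0 / np.maximum(dispersion, 1e-300), 1.0),
                             dispersion * mean),
                   mean)
    return out


def sample_tweedie_cp(mu, rho2, p: float, rng: np.random.Generator) -> np.ndarray:
    """Exact Tweedie compound Poisson draws for 1 < p < 2.

    Draws N ~ Poisson(lambda) with lambda = mu**(2-p) / (rho2 * (2-p)),
    then the sum of N iid Gamma(shape (2-p)/(p-1), scale rho2*(p-1)*mu**(p-1))
    variables (a single gamma with shape N*alpha).  The result has mean mu,
    variance rho2 * mu**p and P(Y = 0) = exp(-lambda).
    """
    if not (1.0 < p < 2.0):
        raise ValueError(f"Tweedie index p must lie in (1, 2); got {p}")
    mu = np.asarray(mu, dtype=float)
    rho2 = np.asarray(rho2, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("Tweedie mean must be strictly positive")
    if np.any(rho2 <= 0):
        raise ValueError("Tweedie dispersion must be strictly positive")
    lam = mu ** (2.0 - p) / (rho2 * (2.0 - p))
    alpha = (2.0 - p) / (p - 1.0)
    scale = rho2 * (p - 1.0) * mu ** (p - 1.0)
    n = rng.poisson(lam)
    total_shape = n * alpha
    out = np.zeros(np.broadcast(mu, rho2).shape if np.ndim(mu) or np.ndim(rho2) else ())
    positive = n > 0
    if np.ndim(out) == 0:
        return float(rng.gamma(total_shape, scale)) if positive else 0.0
    scale_b = np.broadcast_to(scale, out.shape)
    out[positive] = rng.gamma(total_shape[positive], scale_b[positive])
    return out


def resimulate(
    data: MultilevelData, params: ModelParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Redraw (U, V, Y) on a fixed design (for Monte Carlo moment studies).

    Uses the dataset's covariates and index structure as-is; only the random
    layers are redrawn.  Returns (U, V, y) in dataset order.
    """
    from .moments import mean_components

    means = mean_components(data, params)
    U = np.maximum(sample_gamma_mean_disp(means.mu_i, params.sigma2, rng), 1e-300)
    Usub = U[data.sub_cluster]
    V = np.maximum(sample_gamma_mean_disp(means.mu_ij * Usub, params.tau2 / Usub, rng), 1e-300)
    Vobs = V[data.obs_subcluster]
    y = sample_tweedie_cp(
        means.mu_ijk * Vobs, params.rho2 * Vobs ** (1.0 - params.p), params.p, rng
    )
    return U, V, y


def _draw_structure(design: SimDesign, rng: np.random.Generator):
    J_i = rng.integers(design.J_range[0], design.J_range[1] + 1, size=design.I)
    n_ij = rng.integers(design.n_range[0], design.n_range[1] + 1, size=int(J_i.sum()))
    return J_i, n_ij


def _simulate(design: SimDesign, rng: np.random.Generator, mu_i, mu_ij, mu_ijk,
              frame: pd.DataFrame) -> SimulationResult:
    params = design.params
    J_i, n_ij = frame.attrs["J_i"], frame.attrs["n_ij"]
    sub_cluster = np.repeat(np.arange(design.I), J_i)
    obs_sub = np.repeat(np.arange(len(n_ij)), n_ij)

    U = np.maximum(sample_gamma_mean_disp(mu_i, params.sigma2, rng), 1e-300)
    V = np.maximum(
        sample_gamma_mean_disp(mu_ij * U[sub_cluster], params.tau2 / U[sub_cluster], rng),
        1e-300,  # gamma draws can underflow to exact 0 at large dispersion
    )
    y = sample_tweedie_cp(mu_ijk * V[obs_sub],
                          params.rho2 * V[obs_sub] ** (1.0 - params.p),
                          params.p, rng)
    frame = frame.copy()
    frame.insert(2, "y", y)
    del frame.attrs["J_i"], frame.attrs["n_ij"]
    data = validate_and_index(frame, design.level_map)
    return SimulationResult(frame=frame, data=data, U=U, V=V,
                            params=params, level_map=design.level_map)


def simulate_tmcdre(design: SimDesign, seed=None) -> SimulationResult:
    """Simulate from the covariate-dependent model.

    Covariates are drawn at their declared level (cluster covariates once
    per cluster, and so on); the draw order (structure, covariates by level,
    then the three random layers) is fixed, so results are reproducible
    given the seed.  The true (U, V) are returned for recovery studies.
    """
    rng = np.random.default_rng(seed)
    J_i, n_ij = _draw_structure(design, rng)
    M, N = int(J_i.sum()), int(n_ij.sum())
    sub_cluster = np.repeat(np.arange(design.I), J_i)
    obs_sub = np.repeat(np.arange(M), n_ij)
    obs_cluster = sub_cluster[obs_sub]

    cols: dict[str, np.ndarray] = {}
    eta1 = np.zeros(design.I)
    eta2 = np.zeros(M)
    eta3 = np.zeros(N)
    k1 = k2 = k3 = 0
    for spec in design.covariates:
        if spec.level == "cluster":
            v = spec.draw(design.I, rng)
            eta1 += design.params.beta1[k1] * v
            k1 += 1
            cols[spec.name] = v[obs_cluster]
        elif spec.level == "subcluster":
            v = spec.draw(M, rng)
            eta2 += design.params.beta2[k2] * v
            k2 += 1
            cols[spec.name] = v[obs_sub]
        else:
            v = spec.draw(N, rng)
            eta3 += design.params.beta3[k3] * v
            k3 += 1
            cols[spec.name] = v

    frame = pd.DataFrame({
        "cluster": [f"c{i:04d}" for i in obs_cluster],
        "subcluster": [f"s{j:05d}" for j in obs_sub],
        **cols,
    })
    frame.attrs["J_i"], frame.attrs["n_ij"] = J_i, n_ij
    return _simulate(design, rng, np.exp(eta1), np.exp(eta2), np.exp(eta3), frame)


def simulate_ctmm(design: SimDesign, seed=None) -> SimulationResult:
    """Simulate from the covariate-independent special case (mu_i = mu_ij = 1).

    All covariates must be declared at the observation level.
    """
    bad = [c.name for c in design.covariates if c.level != "observation"]
    if bad:
        raise ValueError(
            f"covariate-independent simulation requires observation-level "
            f"covariates only; misplaced: {bad}"
        )
    return simulate_tmcdre(design, seed=seed)


def random_design(
    rng: np.random.Generator,
    I_range: tuple[int, int] = (2, 5),
    J_range: tuple[int, int] = (1, 4),
    n_range: tuple[int, int] = (1, 5),
    p_choices: tuple[float, ...] = (1.1, 1.5, 1.9),
    disp_range: tuple[float, float] = (0.01, 5.0),
) -> SimDesign:
    """A small randomized design for property sweeps and cross-checks.

    Draws dimensions, one covariate per level plus an intercept, moderate
    coefficients, log-uniform dispersions and a Tweedie index from
    ``p_choices``.
    """
    lo, hi = np.log(disp_range[0]), np.log(disp_range[1])
    params = ModelParams(
        beta1=rng.uniform(-0.5, 0.5, size=1),
        beta2=rng.uniform(-0.5, 0.5, size=1),
        beta3=np.r_[rng.uniform(-1.0, 0.5), rng.uniform(-0.5, 0.5)],
        sigma2=float(np.exp(rng.uniform(lo, hi))),
        tau2=float(np.exp(rng.uniform(lo, hi))),
        rho2=float(np.exp(rng.uniform(lo, hi))),
        p=float(rng.choice(p_choices)),
    )
    return SimDesign(
        I=int(rng.integers(I_range[0], I_range[1] + 1)),
        J_range=(J_range[0], int(rng.integers(max(J_range[0], 1), J_range[1] + 1))),
        n_range=(n_range[0], int(rng.integers(max(n_range[0], 1), n_range[1] + 1))),
        params=params,
        covariates=[
            CovariateSpec("zc", "cluster", "binary", prob=0.5),
            CovariateSpec("zs", "subcluster", "uniform", low=-1, high=1),
            CovariateSpec("intercept", "observation", "constant", value=1.0),
            CovariateSpec("zo", "observation", "uniform", low=-1, high=1),
        ],
    )


# ---------------------------------------------------------------------------
# reference designs: the family-study conditions used throughout the tests
# ---------------------------------------------------------------------------


def tmcdre_reference_params() -> ModelParams:
    """Fitted covariate-dependent parameters of the family study (p = 1.55)."""
    return ModelParams(
        beta1=np.array([0.0110, 0.2310, -0.0165]),  # treatment, gender_pr, age_pr
        beta2=np.array([0.0403, 0.1148, 0.4058]),  # age_ad, race_ad, gender_ad
        beta3=np.array([-1.2114, -0.0503, 0.0880, -0.0173]),  # intercept, months, spring, summer
        sigma2=0.1050,
        tau2=0.3844,
        rho2=0.6794,
        p=1.55,
    )


def ctmm_reference_params() -> ModelParams:
    """Fitted covariate-independent parameters of the family study (p = 1.55)."""
    return ModelParams(
        beta1=np.zeros(0),
        beta2=np.zeros(0),
        beta3=np.array(
            [-1.1574, -0.0473, 0.0866, -0.0204, 0.0444, 0.1226, 0.4017, 0.0149, 0.2305, -0.0199]
        ),
        sigma2=0.1007,
        tau2=0.5921,
        rho2=0.5316,
        p=1.55,
    )


def _observation_covariates() -> list[CovariateSpec]:
    return [
        CovariateSpec("intercept", "observation", "constant", value=1.0),
        CovariateSpec("months", "observation", "uniform_int", low=0, high=60),
        CovariateSpec("spring", "observation", "binary", prob=0.5),
        CovariateSpec("summer", "observation", "binary", prob=0.5),
    ]


def tmcdre_reference_design(I: int = 269, params: ModelParams | None = None) -> SimDesign:
    """Covariate-dependent reference design: I parents, 1-5 adolescents, 1-17 visits."""
    return SimDesign(
        I=I,
        J_range=(1, 5),
        n_range=(1, 17),
        params=params or tmcdre_reference_params(),
        covariates=[
            CovariateSpec("treatment", "cluster", "binary", prob=0.5),
            CovariateSpec("gender_pr", "cluster", "binary", prob=0.5),
            CovariateSpec("age_pr", "cluster", "uniform", low=30, high=55),
            CovariateSpec("age_ad", "subcluster", "uniform", low=12, high=18),
            CovariateSpec("race_ad", "subcluster", "binary", prob=0.5),
            CovariateSpec("gender_ad", "subcluster", "binary", prob=0.5),
            *_observation_covariates(),
        ],
    )


def ctmm_reference_design(I: int = 269, params: ModelParams | None = None) -> SimDesign:
    """Covariate-independent reference design: same structure, all covariates per observation."""
    return SimDesign(
        I=I,
        J_range=(1, 5),
        n_range=(1, 17),
        params=params or ctmm_reference_params(),
        covariates=[
            *_observation_covariates(),
            CovariateSpec("age_ad", "observation", "uniform", low=12, high=18),
            CovariateSpec("race_ad", "observation", "binary", prob=0.5),
            CovariateSpec("gender_ad", "observation", "binary", prob=0.5),
            CovariateSpec("treatment", "observation", "binary", prob=0.5),
            CovariateSpec("gender_pr", "observation", "binary", prob=0.5),
            CovariateSpec("age_pr", "observation", "uniform", low=30, high=55),
        ],
    )
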