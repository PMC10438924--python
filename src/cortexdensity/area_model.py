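"""Across-area layer of the neurogenesis model.

Areas differ in their proliferation time t. The model places a Gaussian
with mean mu_y and variance sigma_y^2 on the auxiliary variable
y = y(t) (the log mean neuron density up to the additive ln rho_0), which
induces, through the monotone map y(t) and its inverses, the distribution
of proliferation times, of the within-area log-density variance
sigma_N^2, and of the across-area log mean density:

    ln <rho_N>  ~  Normal(ln rho_0 + mu_y, sigma_y^2).

The full cortex simulation draws one proliferation time per area, a
Poisson number of counting frames, and independent neuron densities per
frame from the within-area SDE, producing a table that feeds the same
analysis pipeline as experimental data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .density_tables import DensityTable
from .neurogenesis import (
    NeurogenesisParams,
    dy_dt,
    f_inverse,
    simulate_neuron_density,
    t_of_y,
    y_of_t,
)

__all__ = [
    "AreaTimeDistribution",
    "SimulatedCortex",
    "proliferation_time_pdf",
    "proliferation_time_cdf",
    "sample_proliferation_times",
    "sigma_N2_distribution_pdf",
    "log_mean_density_distribution",
    "simulate_cortex",
    "correlate_mean_variance",
    "T_MAX_DAYS",
]

# Support cap for normalization integrals; at the inferred parameters the
# mass beyond 300 days is < 1e-12.
T_MAX_DAYS = 300.0


@dataclass(frozen=True)
class AreaTimeDistribution:
    """Gaussian law over the auxiliary variable y, indexed by its median
    proliferation time t_half (mu_y = y(t_half) when consistent)."""

    mu_y: float
    sigma_y2: float
    t_half: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sigma_y2 < 0:
            raise ValueError("sigma_y2 must be nonnegative")
        if self.t_half is not None and self.t_half <= 0:
            raise ValueError("t_half must be positive")

    @property
    def sigma_y(self) -> float:
        return float(np.sqrt(self.sigma_y2))

    def is_consistent(self, params: NeurogenesisParams, tol: float = 1e-6) -> Optional[bool]:
        """Whether mu_y matches y(t_half) to tolerance (None if no t_half)."""
        if self.t_half is None:
            return None
        return bool(abs(self.mu_y - y_of_t(params, self.t_half)) <= tol)

    @classmethod
    def from_t_half(cls, params: NeurogenesisParams, t_half: float,
                    sigma_y2: float) -> "AreaTimeDistribution":
        return cls(mu_y=y_of_t(params, t_half), sigma_y2=sigma_y2, t_half=t_half)

    @classmethod
    def defaults(cls) -> "AreaTimeDistribution":
        """Marmoset-calibrated distribution: mu_y = 3.07, sigma_y^2 = 0.02,
        median proliferation time 45 days."""
        return cls(mu_y=3.07, sigma_y2=0.02, t_half=45.0)


@dataclass
class SimulatedCortex:
    """Per-area proliferation times and frame-level neuron densities."""

    area_ids: list[str]
    times: np.ndarray = field(repr=False)
    frame_densities: list[np.ndarray] = field(repr=False)
    seed: Optional[int]
    params: NeurogenesisParams
    dist: AreaTimeDistribution

    @property
    def n_areas(self) -> int:
        return len(self.area_ids)

    def area_means(self) -> np.ndarray:
        return np.array([np.mean(d) for d in self.frame_densities])

    def log_means(self) -> np.ndarray:
        return np.log(self.area_means())

    def log_variances(self, ddof: int = 1) -> np.ndarray:
        return np.array([np.var(np.log(d), ddof=ddof) for d in self.frame_densities])

    def to_table(self, species: str = "model") -> DensityTable:
        """Serialize to the standard density-table schema so that the whole
        testing/comparison pipeline runs unchanged on model output."""
        rows = []
        for aid, dens in zip(self.area_ids, self.frame_densities):
            for j, d in enumerate(dens):
                rows.append({"species": species, "area_id": aid,
                             "sample_id": f"frame{j:03d}", "density": float(d)})
        return DensityTable(pd.DataFrame(rows))


# ----------------------------------------------------------- distributions

def proliferation_time_pdf(dist: AreaTimeDistribution, params: NeurogenesisParams, t):
    """Density of proliferation times, p(t) = |dy/dt| N(y(t) | mu_y, sigma_y^2)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    y = np.array([y_of_t(params, ti) for ti in np.atleast_1d(t)]).reshape(t.shape)
    out = dy_dt(params, t) * stats.norm.pdf(y, loc=dist.mu_y, scale=dist.sigma_y)
    return out if out.ndim else float(out)


def proliferation_time_cdf(dist: AreaTimeDistribution, params: NeurogenesisParams, t):
    """CDF of proliferation times via the monotone map: Phi((y(t)-mu_y)/sigma_y)."""
    t = np.asarray(t, dtype=float)
    y = np.array([y_of_t(params, ti) for ti in np.atleast_1d(t)]).reshape(t.shape)
    out = stats.norm.cdf(y, loc=dist.mu_y, scale=dist.sigma_y)
    return out if out.ndim else float(out)


def sample_proliferation_times(
    dist: AreaTimeDistribution,
    params: NeurogenesisParams,
    n: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Inverse-transform sampling: draw y ~ N(mu_y, sigma_y^2), return t(y)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    y = rng.normal(dist.mu_y, dist.sigma_y, size=n)
    return np.atleast_1d(t_of_y(params, y))


def _df_inv_dv(params: NeurogenesisParams, v):
    """Derivative of f^-1 with respect to sigma_N^2.

    With g = sqrt(8(3 e^v - 1)): d f^-1/dv = 12 e^v / (g (g - 4)), where
    g - 4 is evaluated as 24(e^v - 1)/(g + 4) for small-v accuracy.
    """
    v = np.asarray(v, dtype=float)
    w = np.expm1(v)
    g = np.sqrt(16.0 + 24.0 * w)
    g_minus_4 = 24.0 * w / (g + 4.0)
    return 12.0 * (w + 1.0) / (g * g_minus_4)


def sigma_N2_distribution_pdf(dist: AreaTimeDistribution, params: NeurogenesisParams, sigma_N2):
    """Across-area density of the within-area log-density variance.

    p(v) = N(f^-1(v) | mu_y, sigma_y^2) * |d f^-1/dv| — the change of
    variables through the strictly increasing map f.
    """
    v = np.asarray(sigma_N2, dtype=float)
    if np.any(v <= 0):
        raise ValueError("sigma_N2 must be positive")
    y = f_inverse(params, v)
    out = stats.norm.pdf(y, loc=dist.mu_y, scale=dist.sigma_y) * _df_inv_dv(params, v)
    return out if out.ndim else float(out)


def log_mean_density_distribution(
    dist: AreaTimeDistribution, params: NeurogenesisParams
) -> tuple[float, float]:
    """(mean, variance) of ln<rho_N> across areas:
    Normal(ln rho_0 + mu_y, sigma_y^2)."""
    return float(np.log(params.rho0) + dist.mu_y), float(dist.sigma_y2)


# ------------------------------------------------------------- simulation

def simulate_cortex(
    dist: AreaTimeDistribution,
    params: NeurogenesisParams,
    n_areas: int = 114,
    mean_frames: float = 36.6,
    seed: Optional[int] = None,
    min_frames: int = 3,
    mode: str = "stratonovich",
) -> SimulatedCortex:
    """Simulate a full cortex: one proliferation time per area, a Poisson
    number of counting frames (redrawn until >= min_frames), and one
    independent within-area SDE realization per frame.

    All paths step jointly over a shared time grid (step dt, with each
    path's final step shortened to land exactly on its own proliferation
    time), so the cost is one vectorized sweep regardless of n_areas.
    """
    if n_areas < 1:
        raise ValueError("n_areas must be >= 1")
    if mean_frames <= 0:
        raise ValueError("mean_frames must be positive")
    rng = np.random.default_rng(seed)

    if dist.sigma_y2 > 0:
        times = sample_proliferation_times(dist, params, n_areas, rng=rng)
    else:
        times = np.full(n_areas, float(t_of_y(params, dist.mu_y)))
    n_frames = np.empty(n_areas, dtype=int)
    for i in range(n_areas):
        k = rng.poisson(mean_frames)
        while k < min_frames:
            k = rng.poisson(mean_frames)
        n_frames[i] = k

    # flatten all frames into one path ensemble with per-path end times
    t_end = np.repeat(times, n_frames)
    n_paths = int(t_end.size)
    dt = params.dt
    drift = params.rate_diff
    n_steps = int(np.ceil(t_end.max() / dt - 1e-9))
    rho_N = np.zeros(n_paths)
    if mode == "stratonovich":
        log_rho = np.full(n_paths, np.log(params.rho0))
        for k in range(n_steps):
            h = np.clip(t_end - k * dt, 0.0, dt)
            rho_N += params.lambda_N * np.exp(log_rho) * h
            g = rng.standard_normal(n_paths)
            log_rho += drift * h + params.sigma * np.sqrt(h) * g
    elif mode == "ito":
        rho = np.full(n_paths, params.rho0)
        for k in range(n_steps):
            h = np.clip(t_end - k * dt, 0.0, dt)
            rho_N += params.lambda_N * rho * h
            g = rng.standard_normal(n_paths)
            rho = rho * (1.0 + drift * h + params.sigma * np.sqrt(h) * g)
    else:
        raise ValueError("mode must be 'stratonovich' or 'ito'")

    offsets = np.concatenate([[0], np.cumsum(n_frames)])
    frames = [rho_N[offsets[i]:offsets[i + 1]].copy() for i in range(n_areas)]
    area_ids = [f"A{i + 1:03d}" for i in range(n_areas)]
    return SimulatedCortex(area_ids=area_ids, times=times, frame_densities=frames,
                           seed=seed, params=params, dist=dist)


def correlate_mean_variance(
    cortex_or_table: Union[SimulatedCortex, DensityTable],
    min_samples: int = 2,
) -> tuple[float, float]:
    """Pearson correlation between per-area ln(mean density) and
    var(ln density), with a one-sided (positive-association) p-value from
    the t-distributed Wald statistic r sqrt((n-2)/(1-r^2)).

    Returns (nan, nan) when either coordinate is degenerate.
    """
    if isinstance(cortex_or_table, SimulatedCortex):
        groups = list(zip(cortex_or_table.area_ids, cortex_or_table.frame_densities))
    else:
        groups = [(f"{sp}/{a}", d) for (sp, a), d in cortex_or_table.by_area().items()]
    log_means, log_vars = [], []
    for _, dens in groups:
        if dens.size >= min_samples:
            log_means.append(np.log(np.mean(dens)))
            log_vars.append(np.var(np.log(dens), ddof=1))
    if len(log_means) < 4:
        raise ValueError("need at least 4 areas with enough samples")
    x, y = np.asarray(log_means), np.asarray(log_vars)
    if (np.ptp(x) <= 1e-12 * max(1.0, float(np.max(np.abs(x))))
            or np.ptp(y) <= 1e-12 * max(1.0, float(np.max(np.abs(y))))):
        return float("nan"), float("nan")
    res = stats.pearsonr(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)
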