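"""Stochastic model of neurogenesis with a noisy proliferation rate.

Within a radial unit, progenitor density rho_P follows a multiplicative
SDE, d/dt rho_P = (lambda_P - lambda_N + sigma*xi) rho_P, with xi a
zero-mean unit-strength Gaussian white noise. Under the Stratonovich
interpretation the log density obeys an ordinary chain rule, so
ln rho_P(t) is Gaussian: rho_P is lognormal at all times with

    mu_P(t)      = ln rho_0 + (lambda_P - lambda_N) t,
    sigma_P(t)^2 = sigma^2 t            (constant rates and noise).

Neurons are terminally differentiated; their density is the path integral
rho_N(t) = int_0^t lambda_N rho_P(s) ds, which is well approximated by a
lognormal with matched first and second moments. The auxiliary quantity
y(t) = ln(<rho_N(t)>/rho_0) maps proliferation time monotonically to log
mean density; with lambda_P = lambda_N = lambda and constant sigma,

    y(t) = ln(2 lambda / sigma^2) + ln(exp(sigma^2 t / 2) - 1),

and f^-1, the inverse of the map y -> sigma_N^2, has the closed form
implemented in :func:`f_inverse`. All rates are per day, sigma is per
sqrt(day), densities are cells/mm^3.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "NeurogenesisParams",
    "LognormalMoments",
    "progenitor_moments",
    "neuron_moments",
    "sigma_N2_of_t",
    "simulate_progenitors",
    "simulate_neuron_density",
    "y_of_t",
    "t_of_y",
    "f_inverse",
]


@dataclass(frozen=True)
class NeurogenesisParams:
    """Constant-rate model parameters.

    lambda_P, lambda_N : proliferation / neurogenesis rates (1/day)
    sigma              : noise intensity (1/sqrt(day))
    rho0               : initial progenitor density (cells/mm^3)
    dt                 : integration time step (day)
    """

    lambda_P: float
    lambda_N: float
    sigma: float
    rho0: float
    dt: float = 0.05

    def __post_init__(self) -> None:
        if self.lambda_P < 0 or self.lambda_N < 0:
            raise ValueError("rates must be nonnegative")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.rho0 <= 0:
            raise ValueError("rho0 must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def rate_diff(self) -> float:
        return self.lambda_P - self.lambda_N

    @classmethod
    def defaults(cls) -> "NeurogenesisParams":
        """Parameters inferred for marmoset neurogenesis.

        lambda = ln(2)/1.5 per day (1.5-day progenitor cell cycle),
        sigma = 0.061 per sqrt(day), rho0 = 3.8e3 cells/mm^3, dt = 0.05 day.
        """
        lam = np.log(2.0) / 1.5
        return cls(lambda_P=lam, lambda_N=lam, sigma=0.061, rho0=3.8e3, dt=0.05)

    def with_(self, **kwargs) -> "NeurogenesisParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LognormalMoments:
    """Log-space parameters and linear-space moments of a (near-)lognormal."""

    mu: float
    sigma2: float
    mean: float
    second_moment: float

    @property
    def variance(self) -> float:
        return self.second_moment - self.mean**2


def _eint(r: float, t: float) -> float:
    """int_0^t exp(r s) ds = (exp(r t) - 1)/r, with the r -> 0 limit t."""
    rt = r * t
    if abs(rt) < 1e-12:
        return t * (1.0 + 0.5 * rt)
    return float(np.expm1(rt) / r)


def progenitor_moments(params: NeurogenesisParams, t: float) -> LognormalMoments:
    """Exact lognormal law of the progenitor density at time t.

    mu_P = ln rho0 + (lambda_P - lambda_N) t and sigma_P^2 = sigma^2 t;
    the linear-space moments follow from the lognormal moment formulas.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    mu = float(np.log(params.rho0) + params.rate_diff * t)
    s2 = float(params.sigma**2 * t)
    mean = float(np.exp(mu + 0.5 * s2))
    second = float(np.exp(2 * mu + 2 * s2))
    return LognormalMoments(mu=mu, sigma2=s2, mean=mean, second_moment=second)


def _neuron_raw_moments(params: NeurogenesisParams, t: float) -> tuple[float, float]:
    """First two linear-space moments of rho_N(t), constant-rate closed form.

    <rho_N>   = lambda_N rho0 int_0^t e^{b s} ds,            b = dlam + a,
    <rho_N^2> = 2 lambda_N^2 rho0^2 / c [E(b+c,t) - E(b,t)], c = dlam + 3a,
    with a = sigma^2/2 and E(r,t) = (e^{rt}-1)/r; verified against direct
    2-D quadrature of the covariance integral.
    """
    a = 0.5 * params.sigma**2
    dlam = params.rate_diff
    b = dlam + a
    c = dlam + 3 * a
    lamN, rho0 = params.lambda_N, params.rho0
    m1 = lamN * rho0 * _eint(b, t)
    if abs(c) * t > 1e-10:
        inner = (_eint(b + c, t) - _eint(b, t)) / c
    else:  # c -> 0: int_0^t s' e^{b s'} ds'
        if abs(b) * t > 1e-10:
            inner = (t * np.exp(b * t) - _eint(b, t)) / b
        else:
            inner = 0.5 * t**2
    m2 = 2.0 * lamN**2 * rho0**2 * inner
    return float(m1), float(m2)


def neuron_moments(params: NeurogenesisParams, t: float) -> LognormalMoments:
    """Moment-matched lognormal approximation of the neuron density at t.

    The matched log-space parameters are mu_N = ln<rho_N> - sigma_N^2/2 and
    sigma_N^2 = ln(1 + Var(rho_N)/<rho_N>^2). When lambda_P = lambda_N the
    moment ratio has the exact form 1 + 2u/3 + u^2/6 with
    u = exp(sigma^2 t/2) - 1, which is used for numerical stability.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t == 0:
        raise ValueError("rho_N(0) = 0 has no lognormal parameters")
    m1, m2 = _neuron_raw_moments(params, t)
    if params.rate_diff == 0.0:
        u = np.expm1(0.5 * params.sigma**2 * t)
        s2 = float(np.log1p(u * (2.0 / 3.0 + u / 6.0)))
    else:
        s2 = float(np.log(m2 / m1**2))
    mu = float(np.log(m1) - 0.5 * s2)
    return LognormalMoments(mu=mu, sigma2=s2, mean=m1, second_moment=m2)


def sigma_N2_of_t(params: NeurogenesisParams, t: float) -> float:
    """Variance of the logarithmic neuron density after proliferation time t."""
    return neuron_moments(params, t).sigma2


# ------------------------------------------------------------- simulation

def _step_arrays(t_end: float, dt: float) -> np.ndarray:
    """Step durations covering [0, t_end]; a short final step absorbs the
    remainder when t_end is not a multiple of dt."""
    if t_end < 0:
        raise ValueError("t_end must be nonnegative")
    n_full = int(np.floor(t_end / dt + 1e-9))
    rem = t_end - n_full * dt
    steps = np.full(n_full, dt)
    if rem > 1e-9 * max(dt, 1.0):
        steps = np.append(steps, rem)
    return steps


def simulate_progenitors(
    params: NeurogenesisParams,
    t_end: float,
    n_paths: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    mode: str = "stratonovich",
    full: bool = True,
):
    """Simulate progenitor-density paths of the multiplicative-noise SDE.

    In the canonical ``"stratonovich"`` mode the log density is stepped
    with exact Gaussian increments,
    d ln rho_P = (lambda_P - lambda_N) dt + sigma sqrt(dt) G, which solves
    the Stratonovich SDE exactly for constant coefficients; paths are
    strictly positive. ``"ito"`` applies Euler-Maruyama directly to the
    density (kept for comparison; its stationary statistics differ by a
    factor exp(sigma^2 t/2) in the mean).

    Returns ``(times, paths)`` with ``paths`` of shape
    (n_paths, len(times)) when ``full``; otherwise the final densities only.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if mode not in ("stratonovich", "ito"):
        raise ValueError("mode must be 'stratonovich' or 'ito'")
    if rng is None:
        rng = np.random.default_rng(seed)
    steps = _step_arrays(t_end, params.dt)
    drift = params.rate_diff
    if mode == "stratonovich":
        incr = drift * steps + params.sigma * np.sqrt(steps) * rng.standard_normal(
            (n_paths, steps.size)
        )
        log_paths = np.log(params.rho0) + np.concatenate(
            [np.zeros((n_paths, 1)), np.cumsum(incr, axis=1)], axis=1
        )
        paths = np.exp(log_paths)
    else:
        paths = np.empty((n_paths, steps.size + 1))
        paths[:, 0] = params.rho0
        cur = np.full(n_paths, params.rho0)
        for k, h in enumerate(steps):
            g = rng.standard_normal(n_paths)
            cur = cur * (1.0 + drift * h + params.sigma * np.sqrt(h) * g)
            paths[:, k + 1] = cur
    times = np.concatenate([[0.0], np.cumsum(steps)])
    if full:
        return times, paths
    return paths[:, -1]


def simulate_neuron_density(
    params: NeurogenesisParams,
    t_end: float,
    n_paths: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    mode: str = "stratonovich",
) -> np.ndarray:
    """Final neuron densities rho_N(t_end) for n_paths independent units.

    rho_N accumulates lambda_N * rho_P as a left-endpoint Riemann sum along
    each simulated progenitor path (mirroring the Euler-style stepping), so
    it is nonnegative and nondecreasing. Memory is O(n_paths): only the
    running state is kept.
    """
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    if mode not in ("stratonovich", "ito"):
        raise ValueError("mode must be 'stratonovich' or 'ito'")
    if rng is None:
        rng = np.random.default_rng(seed)
    steps = _step_arrays(t_end, params.dt)
    drift = params.rate_diff
    rho_N = np.zeros(n_paths)
    if mode == "stratonovich":
        log_rho = np.full(n_paths, np.log(params.rho0))
        for h in steps:
            rho_N += params.lambda_N * np.exp(log_rho) * h
            log_rho += drift * h + params.sigma * np.sqrt(h) * rng.standard_normal(n_paths)
    else:
        rho = np.full(n_paths, params.rho0)
        for h in steps:
            rho_N += params.lambda_N * rho * h
            rho = rho * (1.0 + drift * h + params.sigma * np.sqrt(h) * rng.standard_normal(n_paths))
    return rho_N


# --------------------------------------------------- auxiliary map y(t)

def y_of_t(params: NeurogenesisParams, t: float) -> float:
    """y(t) = ln(<rho_N(t)>/rho0), the monotone map from proliferation
    time to log mean neuron density.

    With lambda_P = lambda_N = lambda and sigma > 0 this is
    ln(2 lambda/sigma^2) + ln(exp(sigma^2 t/2) - 1); the general
    constant-rate form ln(lambda_N * E(b, t)) is used otherwise.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if params.sigma > 0 and params.rate_diff == 0.0:
        s2 = params.sigma**2
        return float(np.log(2.0 * params.lambda_N / s2) + np.log(np.expm1(0.5 * s2 * t)))
    b = params.rate_diff + 0.5 * params.sigma**2
    return float(np.log(params.lambda_N * _eint(b, t)))


def dy_dt(params: NeurogenesisParams, t) -> np.ndarray:
    """Derivative of y(t); needed for the proliferation-time density."""
    t = np.asarray(t, dtype=float)
    a = 0.5 * params.sigma**2
    if params.sigma > 0 and params.rate_diff == 0.0:
        return a * np.exp(a * t) / np.expm1(a * t)
    b = params.rate_diff + a
    if b == 0:
        return 1.0 / t
    return b * np.exp(b * t) / np.expm1(b * t)


def t_of_y(params: NeurogenesisParams, y) -> np.ndarray:
    """Inverse of :func:`y_of_t`: t = (2/sigma^2) ln(1 + sigma^2/(2 lambda) e^y).

    Requires lambda_P = lambda_N; the noiseless sigma -> 0 limit
    t = e^y / lambda is used when sigma = 0.
    """
    if params.rate_diff != 0.0:
        raise ValueError("t_of_y requires lambda_P == lambda_N")
    y = np.asarray(y, dtype=float)
    if params.sigma == 0:
        out = np.exp(y) / params.lambda_N
        return out if out.ndim else float(out)
    s2 = params.sigma**2
    out = (2.0 / s2) * np.log1p(s2 / (2.0 * params.lambda_N) * np.exp(y))
    return out if out.ndim else float(out)


def f_inverse(params: NeurogenesisParams, sigma_N2) -> np.ndarray:
    """Inverse of the map y -> sigma_N^2 (log-density variance of neurons).

    f^-1(v) = ln(lambda/sigma^2) + ln(sqrt(8(3 e^v - 1)) - 4) for v > 0.
    The second logarithm's argument is evaluated as 24 w/(sqrt(16+24w)+4)
    with w = e^v - 1 to stay accurate for small v. Strictly increasing;
    diverges to -inf as v -> 0+.
    """
    if params.sigma <= 0:
        raise ValueError("f_inverse requires sigma > 0")
    if params.rate_diff != 0.0:
        raise ValueError("f_inverse requires lambda_P == lambda_N")
    v = np.asarray(sigma_N2, dtype=float)
    if np.any(v <= 0):
        raise ValueError("sigma_N2 must be positive")
    w = np.expm1(v)
    arg = 24.0 * w / (np.sqrt(16.0 + 24.0 * w) + 4.0)
    out = np.log(params.lambda_N / params.sigma**2) + np.log(arg)
    return out if out.ndim else float(out)
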