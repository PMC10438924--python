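"""Parameter estimation for the neurogenesis model from density tables.

Recipe (constant rates, lambda_P = lambda_N = lambda):

1. lambda = ln(2)/ell from the progenitor cell-cycle length ell.
2. mu_y-hat = empirical mean of f^-1(sigma_N^2) over areas, where
   sigma_N^2 is the per-area variance of the log frame densities. This is
   the exact MLE under the across-area law of sigma_N^2 because the
   Jacobian of the change of variables does not depend on mu_y.
3. sigma from the median constraint y(t_half) = mu_y-hat.
4. sigma_y^2 such that a fixed fraction (default 2%) of proliferation
   times falls outside a window (default [30, 60] days).
5. rho_0 = exp(mean(ln area-mean density) - mu_y-hat), the MLE under
   ln<rho_N> ~ Normal(ln rho_0 + mu_y, sigma_y^2).

Steps 2 and 3 are mutually dependent (f^-1 contains sigma), but the
dependence cancels exactly: both f^-1 and y(t_half) carry the same
additive -2 ln(sigma), so the median constraint determines sigma in
closed form,

    sigma^2 = (2/t_half) ln(1 + exp(mean_i ln g(v_i) - ln 2)),
    g(v)    = sqrt(8 (3 e^v - 1)) - 4,

with v_i the per-area log-density variances; mu_y-hat then follows by
substitution. ``estimate_all`` uses this joint solution and reports the
residuals of both constraints as diagnostics.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .density_tables import DensityTable
from .neurogenesis import NeurogenesisParams, f_inverse, y_of_t

__all__ = [
    "EstimationResult",
    "rate_from_cell_cycle",
    "estimate_mu_y",
    "solve_sigma",
    "solve_sigma_y",
    "solve_mu_y_sigma_joint",
    "estimate_rho0",
    "estimate_all",
]


@dataclass
class EstimationResult:
    """Point estimates of the neurogenesis-model parameters."""

    lam: float
    sigma: float
    mu_y: float
    sigma_y2: float
    rho0: float
    t_half: float
    diagnostics: dict = field(default_factory=dict)

    def to_params(self, dt: float = 0.05) -> NeurogenesisParams:
        return NeurogenesisParams(lambda_P=self.lam, lambda_N=self.lam,
                                  sigma=self.sigma, rho0=self.rho0, dt=dt)

    def to_dict(self) -> dict:
        return {
            "lambda_per_day": self.lam,
            "sigma_per_sqrt_day": self.sigma,
            "mu_y": self.mu_y,
            "sigma_y2": self.sigma_y2,
            "rho0_cells_per_mm3": self.rho0,
            "t_half_days": self.t_half,
            "diagnostics": dict(self.diagnostics),
        }


def rate_from_cell_cycle(cell_cycle_length: float) -> float:
    """Proliferation rate lambda = ln(2)/ell for cell-cycle length ell (days)."""
    if cell_cycle_length <= 0:
        raise ValueError("cell cycle length must be positive")
    return float(np.log(2.0) / cell_cycle_length)


def estimate_mu_y(
    area_sigma_N2: Sequence[float], params: NeurogenesisParams
) -> float:
    """MLE of mu_y: the mean of f^-1 over the per-area log-density variances.

    Non-positive variance entries are skipped with a warning (f^-1 is
    undefined there).
    """
    v = np.asarray(area_sigma_N2, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one area variance")
    good = v > 0
    if not np.all(good):
        warnings.warn(f"skipping {int((~good).sum())} non-positive variance entries")
        v = v[good]
    if v.size == 0:
        raise ValueError("no positive variance entries")
    return float(np.mean(f_inverse(params, v)))


def solve_sigma(mu_y: float, t_half: float, lam: float, *,
                tol: float = 1e-12) -> float:
    """Noise intensity sigma solving the median constraint y(t_half) = mu_y.

    y(t_half) is strictly increasing in sigma with limit ln(lambda*t_half)
    as sigma -> 0, so a unique positive root exists iff
    mu_y > ln(lambda*t_half). Solved by bracketed Brent iteration on
    s = sigma^2.
    """
    if t_half <= 0 or lam <= 0:
        raise ValueError("t_half and lambda must be positive")
    floor = np.log(lam * t_half)
    if mu_y <= floor:
        raise ValueError(
            f"mu_y={mu_y:.6g} is not above the sigma->0 limit ln(lambda*t_half)={floor:.6g}"
        )

    def g(s: float) -> float:
        # y(t_half) - mu_y at sigma^2 = s
        return float(np.log(2.0 * lam / s) + np.log(np.expm1(0.5 * s * t_half)) - mu_y)

    lo = 1e-14
    hi = 1.0
    while g(hi) < 0:
        hi *= 4.0
        if hi > 1e8:
            raise RuntimeError("failed to bracket sigma")
    s = optimize.brentq(g, lo, hi, xtol=tol, rtol=8.9e-16)
    return float(np.sqrt(s))


def _tail_mass(mu_y: float, sigma_y: float, y_lo: float, y_hi: float) -> float:
    return float(stats.norm.cdf((y_lo - mu_y) / sigma_y)
                 + stats.norm.sf((y_hi - mu_y) / sigma_y))


def solve_sigma_y(
    mu_y: float,
    params: NeurogenesisParams,
    lower: float = 30.0,
    upper: float = 60.0,
    tail_mass: float = 0.02,
    *,
    tol: float = 1e-12,
) -> float:
    """Variance sigma_y^2 putting ``tail_mass`` of proliferation times
    outside [lower, upper] days (solved as an equality).

    Requires y(lower) < mu_y < y(upper); the tail mass is strictly
    increasing in sigma_y, so the root is unique.
    """
    if not (0 < tail_mass < 1):
        raise ValueError("tail_mass must be in (0, 1)")
    y_lo, y_hi = y_of_t(params, lower), y_of_t(params, upper)
    if not (y_lo < mu_y < y_hi):
        raise ValueError(
            f"mu_y={mu_y:.6g} must lie strictly between y(lower)={y_lo:.6g} "
            f"and y(upper)={y_hi:.6g}"
        )

    def g(sy: float) -> float:
        return _tail_mass(mu_y, sy, y_lo, y_hi) - tail_mass

    lo, hi = 1e-10, 10.0
    while g(hi) < 0:
        hi *= 4.0
    sy = optimize.brentq(g, lo, hi, xtol=tol, rtol=8.9e-16)
    return float(sy**2)


def solve_mu_y_sigma_joint(
    area_sigma_N2: Sequence[float], lam: float, t_half: float
) -> tuple[float, float]:
    """Solve the coupled (mu_y-hat, sigma) system in closed form.

    mu_y-hat = mean_i f^-1(v_i) depends on sigma only through an additive
    -2 ln(sigma), and so does y(t_half); equating the two eliminates
    sigma from the constraint and yields
    sigma^2 = (2/t_half) ln(1 + e^T) with T = mean_i ln g(v_i) - ln 2.
    """
    v = np.asarray(area_sigma_N2, dtype=float)
    v = v[v > 0]
    if v.size == 0:
        raise ValueError("need at least one positive area variance")
    w = np.expm1(v)
    log_g = np.log(24.0 * w / (np.sqrt(16.0 + 24.0 * w) + 4.0))
    T = float(np.mean(log_g)) - np.log(2.0)
    sigma2 = (2.0 / t_half) * np.log1p(np.exp(T))
    sigma = float(np.sqrt(sigma2))
    params = NeurogenesisParams(lambda_P=lam, lambda_N=lam, sigma=sigma,
                                rho0=1.0, dt=0.05)
    mu_y = estimate_mu_y(v, params)
    return mu_y, sigma


def estimate_rho0(area_log_mean_densities: Sequence[float], mu_y: float) -> float:
    """rho_0 = exp(mean(ln<rho_N>) - mu_y) over areas."""
    x = np.asarray(area_log_mean_densities, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one area")
    return float(np.exp(np.mean(x) - mu_y))


def estimate_all(
    table: DensityTable,
    cell_cycle_length: float = 1.5,
    t_half: float = 45.0,
    lower: float = 30.0,
    upper: float = 60.0,
    tail_mass: float = 0.02,
    dt: float = 0.05,
) -> EstimationResult:
    """Full estimation recipe on a within-area density table.

    The table must contain areas with at least 2 samples each (counting
    frames); the per-area variance of ln(density) and ln(mean density)
    are the sufficient statistics. The mu_y <-> sigma circularity is
    resolved exactly by :func:`solve_mu_y_sigma_joint`.
    """
    lam = rate_from_cell_cycle(cell_cycle_length)

    by_area = table.by_area()
    sigmas_N2, log_means = [], []
    for _, dens in sorted(by_area.items()):
        if dens.size >= 2:
            sigmas_N2.append(np.var(np.log(dens), ddof=1))
            log_means.append(np.log(np.mean(dens)))
    if not sigmas_N2:
        raise ValueError(
            "estimate_mu_y: no areas with >= 2 samples; within-area "
            "variances are required"
        )
    sigmas_N2 = np.asarray(sigmas_N2)
    log_means = np.asarray(log_means)

    mu_y, sigma = solve_mu_y_sigma_joint(sigmas_N2, lam, t_half)
    params = NeurogenesisParams(lambda_P=lam, lambda_N=lam, sigma=sigma,
                                rho0=1.0, dt=dt)

    sigma_y2 = solve_sigma_y(mu_y, params, lower=lower, upper=upper,
                             tail_mass=tail_mass)
    rho0 = estimate_rho0(log_means, mu_y)

    y_residual = abs(y_of_t(params, t_half) - mu_y)
    tail_residual = abs(
        _tail_mass(mu_y, np.sqrt(sigma_y2), y_of_t(params, lower), y_of_t(params, upper))
        - tail_mass
    )
    return EstimationResult(
        lam=lam, sigma=sigma, mu_y=mu_y, sigma_y2=sigma_y2, rho0=rho0,
        t_half=t_half,
        diagnostics={
            "n_areas": int(sigmas_N2.size),
            "median_constraint_residual": float(y_residual),
            "tail_mass_residual": float(tail_residual),
        },
    )
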