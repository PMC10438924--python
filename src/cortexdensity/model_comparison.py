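"""Maximum-likelihood fitting of positive-support distributions and
AIC-based model comparison.

Seven candidate families are fitted to a sample of positive densities:
lognormal, truncated normal (truncated at 0), inverse normal (inverse
Gaussian), gamma, inverse gamma, Levy, and Weibull. Models are ranked by
the Akaike Information Criterion, AIC = 2k - 2 ln L, and compared through
the relative likelihood L_r = exp((AIC_min - AIC_i)/2); families with
L_r below a significance threshold (default 0.05) are flagged as
significantly worse than the best model.

Parameter counts: every family estimates two parameters (the truncated
normal's truncation point is fixed at 0 and not counted).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "DistributionFit",
    "ModelComparison",
    "fit_mle",
    "aic",
    "relative_likelihoods",
    "compare_models",
    "log_likelihood",
    "family_distribution",
]

FAMILIES = (
    "lognormal",
    "truncated_normal",
    "inverse_normal",
    "gamma",
    "inverse_gamma",
    "levy",
    "weibull",
)

_N_RESTARTS = 5
_XTOL = 1e-10


@dataclass(frozen=True)
class DistributionFit:
    family: str
    params: dict
    k: int
    log_likelihood: float
    converged: bool = True


@dataclass
class ModelComparison:
    fits: dict[str, DistributionFit]
    aic: dict[str, float]
    rel_likelihood: dict[str, float]
    best_family: str
    alpha: float = 0.05
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def significantly_worse(self) -> list[str]:
        return sorted(f for f, lr in self.rel_likelihood.items() if lr < self.alpha)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "best_family": self.best_family,
            "aic": dict(self.aic),
            "rel_likelihood": dict(self.rel_likelihood),
            "significantly_worse": self.significantly_worse,
            "params": {f: fit.params for f, fit in self.fits.items()},
            "errors": dict(self.errors),
        }


def family_distribution(family: str, params: Mapping[str, float]):
    """Frozen scipy distribution for a fitted family (for pdf/cdf/sampling)."""
    if family == "lognormal":
        return stats.lognorm(s=params["sigma"], scale=np.exp(params["mu"]))
    if family == "truncated_normal":
        m, s = params["loc"], params["scale"]
        return stats.truncnorm(a=(0.0 - m) / s, b=np.inf, loc=m, scale=s)
    if family == "inverse_normal":
        m, lam = params["mean"], params["shape"]
        return stats.invgauss(mu=m / lam, scale=lam)
    if family == "gamma":
        return stats.gamma(a=params["shape"], scale=params["scale"])
    if family == "inverse_gamma":
        return stats.invgamma(a=params["shape"], scale=params["scale"])
    if family == "levy":
        return stats.levy(loc=params["loc"], scale=params["scale"])
    if family == "weibull":
        return stats.weibull_min(c=params["shape"], scale=params["scale"])
    raise ValueError(f"unknown family {family!r}")


def log_likelihood(family: str, params: Mapping[str, float], x: Sequence[float]) -> float:
    """Total log-likelihood of ``x`` under a family with given parameters."""
    x = np.asarray(x, dtype=float)
    return float(np.sum(family_distribution(family, params).logpdf(x)))


def _check_data(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 samples for a meaningful MLE fit")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("data must be positive and finite")
    return x


# ----------------------------------------------------------- per-family MLEs

def _fit_lognormal(x: np.ndarray) -> tuple[dict, bool]:
    logs = np.log(x)
    mu = float(np.mean(logs))
    sigma = float(np.sqrt(np.mean((logs - mu) ** 2)))  # MLE uses 1/n variance
    return {"mu": mu, "sigma": sigma}, True


def _fit_inverse_normal(x: np.ndarray) -> tuple[dict, bool]:
    # closed-form MLE of the inverse Gaussian IG(mean m, shape lambda)
    m = float(np.mean(x))
    lam = float(1.0 / np.mean(1.0 / x - 1.0 / m))
    return {"mean": m, "shape": lam}, True


def _fit_gamma(x: np.ndarray) -> tuple[dict, bool]:
    shape, _, scale = stats.gamma.fit(x, floc=0)
    return {"shape": float(shape), "scale": float(scale)}, True


def _fit_inverse_gamma(x: np.ndarray) -> tuple[dict, bool]:
    shape, _, scale = stats.invgamma.fit(x, floc=0)
    return {"shape": float(shape), "scale": float(scale)}, True


def _fit_weibull(x: np.ndarray) -> tuple[dict, bool]:
    shape, _, scale = stats.weibull_min.fit(x, floc=0)
    return {"shape": float(shape), "scale": float(scale)}, True


def _fit_levy(x: np.ndarray) -> tuple[dict, bool]:
    # Profile likelihood over the location; the scale MLE is closed-form
    # given the location: c = n / sum(1/(x - loc)).
    n = x.size
    xmin = float(np.min(x))
    span = max(float(np.ptp(x)), xmin, 1e-12)

    def neg_profile(theta: float) -> float:
        loc = xmin - np.exp(theta)
        d = x - loc
        s = np.sum(1.0 / d)
        c = n / s
        ll = 0.5 * n * np.log(c) - 0.5 * n * np.log(2 * np.pi) - 0.5 * n \
            - 1.5 * np.sum(np.log(d))
        return -ll

    res = optimize.minimize_scalar(
        neg_profile,
        bounds=(np.log(span) - 40.0, np.log(span) + 10.0),
        method="bounded",
        options={"xatol": _XTOL},
    )
    loc = xmin - float(np.exp(res.x))
    scale = float(n / np.sum(1.0 / (x - loc)))
    return {"loc": loc, "scale": scale}, bool(res.success)


def _fit_truncated_normal(x: np.ndarray, seed: int = 0) -> tuple[dict, bool]:
    # Normal truncated to (0, inf); location and scale estimated, the
    # truncation point is fixed. Unconstrained optimization in (loc, ln scale)
    # with random restarts.
    m0, s0 = float(np.mean(x)), float(np.std(x))
    s0 = max(s0, 1e-8 * max(m0, 1.0))

    def nll(theta) -> float:
        m, log_s = theta
        s = np.exp(log_s)
        z = (x - m) / s
        # log of the normalizing constant P(X > 0) = 1 - Phi(-m/s)
        log_norm = stats.norm.logsf(-m / s)
        val = np.sum(stats.norm.logpdf(z)) - x.size * np.log(s) - x.size * log_norm
        return -val if np.isfinite(val) else 1e300

    rng = np.random.default_rng(seed)
    best = None
    starts = [(m0, np.log(s0))]
    starts += [
        (m0 * (1 + 0.5 * rng.standard_normal()), np.log(s0) + 0.5 * rng.standard_normal())
        for _ in range(_N_RESTARTS - 1)
    ]
    for start in starts:
        res = optimize.minimize(nll, start, method="Nelder-Mead",
                                options={"xatol": _XTOL, "fatol": _XTOL, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    m, log_s = best.x
    return {"loc": float(m), "scale": float(np.exp(log_s))}, bool(best.fun < 1e299)


_FITTERS = {
    "lognormal": _fit_lognormal,
    "truncated_normal": _fit_truncated_normal,
    "inverse_normal": _fit_inverse_normal,
    "gamma": _fit_gamma,
    "inverse_gamma": _fit_inverse_gamma,
    "levy": _fit_levy,
    "weibull": _fit_weibull,
}


def fit_mle(family: str, x: Sequence[float]) -> DistributionFit:
    """Maximum-likelihood fit of one family to positive data.

    Closed forms are used where they exist (lognormal, inverse normal);
    the remaining families are fitted numerically. Every family estimates
    k = 2 parameters.
    """
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    x = _check_data(x)
    params, converged = _FITTERS[family](x)
    ll = log_likelihood(family, params, x)
    if not np.isfinite(ll):
        converged = False
    return DistributionFit(family=family, params=params, k=2,
                           log_likelihood=ll, converged=converged)


def aic(fit: DistributionFit) -> float:
    """Akaike Information Criterion, 2k - 2 ln L."""
    return 2 * fit.k - 2.0 * fit.log_likelihood


def relative_likelihoods(aics: Mapping[str, float]) -> dict[str, float]:
    """exp((AIC_min - AIC_i)/2) per family; the minimum-AIC family gets 1."""
    if not aics:
        raise ValueError("need at least one family")
    amin = min(aics.values())
    return {f: float(np.exp((amin - a) / 2.0)) for f, a in aics.items()}


def compare_models(x: Sequence[float], alpha: float = 0.05) -> ModelComparison:
    """Fit all seven families and rank them by relative likelihood.

    Per-family fit failures are recorded and do not abort the comparison.
    Ties for the minimum AIC are broken lexicographically by family name.
    """
    x = _check_data(x)
    fits: dict[str, DistributionFit] = {}
    errors: dict[str, str] = {}
    for family in FAMILIES:
        try:
            fit = fit_mle(family, x)
            if not fit.converged:
                errors[family] = "optimizer did not converge"
            fits[family] = fit
        except (ValueError, FloatingPointError, RuntimeError) as exc:
            errors[family] = str(exc)
    if not fits:
        raise ValueError("all family fits failed")
    aics = {f: aic(fit) for f, fit in fits.items()}
    rel = relative_likelihoods(aics)
    amin = min(aics.values())
    best = min(f for f, a in aics.items() if a == amin)
    return ModelComparison(fits=fits, aic=aics, rel_likelihood=rel,
                           best_family=best, alpha=alpha, errors=errors)
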