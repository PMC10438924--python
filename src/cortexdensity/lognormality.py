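"""Lognormality testing of density samples.

Protocol: take the natural logarithm of the densities, z-score, exclude
extreme outliers (|z| >= 3, computed once on the full sample), then apply
the Shapiro-Wilk normality test to the retained values. Two-sample
Kolmogorov-Smirnov tests compare the z-scored log densities across groups,
and normal probability plots provide a visual linearity check.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .density_tables import DensityTable

__all__ = [
    "LognormalityResult",
    "PairwiseKSResult",
    "zscore_log",
    "exclude_outliers",
    "shapiro_wilk",
    "test_group_lognormality",
    "pairwise_ks",
    "probability_plot_points",
]

OUTLIER_Z_THRESHOLD = 3.0
SW_MAX_N = 5000


@dataclass
class LognormalityResult:
    """Outcome of the lognormality test for one group of densities."""

    group_id: str
    n_total: int
    n_outliers_removed: int
    outlier_ids: list[str]
    W: Optional[float]
    p_value: Optional[float]
    z_scores: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    error: Optional[str] = None

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_outliers_removed

    def not_rejected(self, alpha: float = 0.05) -> Optional[bool]:
        """True when lognormality is compatible with the data at ``alpha``."""
        if self.p_value is None:
            return None
        return bool(self.p_value > alpha)

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "n_total": self.n_total,
            "n_outliers_removed": self.n_outliers_removed,
            "outlier_ids": list(self.outlier_ids),
            "W": self.W,
            "p_value": self.p_value,
            "not_rejected_0.05": self.not_rejected(0.05),
            "not_rejected_0.001": self.not_rejected(0.001),
            "error": self.error,
        }


@dataclass(frozen=True)
class PairwiseKSResult:
    """Two-sample two-sided Kolmogorov-Smirnov outcome for one group pair."""

    group_a: str
    group_b: str
    D: float
    p_value: float


def zscore_log(densities: Sequence[float]) -> np.ndarray:
    """Z-score the natural logarithms of positive densities.

    Uses the sample standard deviation (denominator n-1); the output has
    exact mean 0 and sample sd 1.
    """
    x = np.asarray(densities, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need at least 2 values")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("densities must be positive and finite")
    logs = np.log(x)
    sd = np.std(logs, ddof=1)
    if sd == 0 or np.unique(logs).size < 2:
        raise ValueError("zero variance: all log-densities identical")
    return (logs - np.mean(logs)) / sd


def exclude_outliers(
    z: Sequence[float],
    ids: Optional[Sequence[str]] = None,
    threshold: float = OUTLIER_Z_THRESHOLD,
) -> tuple[np.ndarray, list[str]]:
    """Single-pass removal of samples with |z| >= threshold.

    The z-scores are taken as given (computed once from the full sample)
    and are NOT recomputed after removal; the rule is inclusive at the
    threshold. Returns (retained z-scores, ids of removed samples).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    z = np.asarray(z, dtype=float)
    if ids is None:
        ids = [str(i) for i in range(z.size)]
    ids = list(map(str, ids))
    if len(ids) != z.size:
        raise ValueError("z and ids must have the same length")
    keep = np.abs(z) < threshold
    removed = [i for i, k in zip(ids, keep) if not k]
    return z[keep], removed


def shapiro_wilk(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W statistic, p-value).

    Delegates to scipy's implementation of the Royston AS R94 algorithm.
    Valid for 3 <= n <= 5000.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError(f"Shapiro-Wilk requires n >= 3, got n={x.size}")
    if x.size > SW_MAX_N:
        raise ValueError(f"Shapiro-Wilk p-values unreliable beyond n={SW_MAX_N}")
    if np.ptp(x) == 0:
        raise ValueError("constant input")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def test_group_lognormality(
    table: DensityTable,
    grouping: str = "by_species",
    alpha: float = 0.05,
    threshold: float = OUTLIER_Z_THRESHOLD,
) -> dict[str, LognormalityResult]:
    """Run the full lognormality pipeline per group.

    ``grouping`` is ``"by_species"`` (across-area tables; outliers are
    reported by area id) or ``"by_area"`` (within-area counting-frame
    tables; outliers reported by sample id). Groups that are too small
    yield a per-group error record instead of aborting the run.
    """
    if grouping == "by_species":
        groups = table.by_species()
        frame = table.frame
        labels = {k: frame.loc[frame["species"] == k, "area_id"].to_numpy() for k in groups}
        keys = {k: k for k in groups}
    elif grouping == "by_area":
        groups_raw = table.by_area()
        frame = table.frame
        groups, labels, keys = {}, {}, {}
        for (sp, area), dens in groups_raw.items():
            gid = f"{sp}/{area}"
            groups[gid] = dens
            sel = (frame["species"] == sp) & (frame["area_id"] == area)
            labels[gid] = frame.loc[sel, "sample_id"].to_numpy()
            keys[gid] = gid
    else:
        raise ValueError("grouping must be 'by_species' or 'by_area'")

    results: dict[str, LognormalityResult] = {}
    for gid, dens in groups.items():
        n_total = int(dens.size)
        try:
            z = zscore_log(dens)
            z_kept, removed = exclude_outliers(z, labels[gid], threshold=threshold)
            if z_kept.size < 3:
                raise ValueError(
                    f"insufficient data: {z_kept.size} samples after outlier removal"
                )
            W, p = shapiro_wilk(z_kept)
            results[gid] = LognormalityResult(
                group_id=gid, n_total=n_total, n_outliers_removed=len(removed),
                outlier_ids=removed, W=W, p_value=p, z_scores=z_kept,
            )
        except ValueError as exc:
            results[gid] = LognormalityResult(
                group_id=gid, n_total=n_total, n_outliers_removed=0,
                outlier_ids=[], W=None, p_value=None, error=str(exc),
            )
    return results


def pairwise_ks(groups: Mapping[str, Sequence[float]]) -> list[PairwiseKSResult]:
    """Two-sample two-sided KS test for every unordered pair of groups.

    Input values are expected to be z-scored log densities; the test is
    the plain two-sample test, applied as-is.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 samples")
    out = []
    for a, b in combinations(sorted(arrays), 2):
        res = stats.ks_2samp(arrays[a], arrays[b], alternative="two-sided")
        out.append(PairwiseKSResult(a, b, float(res.statistic), float(res.pvalue)))
    return out


def probability_plot_points(x: Sequence[float]) -> tuple[np.ndarray, np.ndarray, float]:
    """Normal probability-plot coordinates and their linearity correlation.

    Theoretical quantiles use Filliben's order-statistic medians,
    (i - 0.3175)/(n + 0.365) with adjusted endpoints, as in scipy's
    ``probplot``. Returns (theoretical quantiles, ordered sample, r).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    (osm, osr), (_, _, r) = stats.probplot(x, dist="norm", fit=True)
    return osm, osr, float(r)
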