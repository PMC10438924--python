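"""Synthetic density-table generators.

Three kinds of fixtures with the statistical structure the analysis
assumes: across-area species tables (lognormal area densities with
optional injected extreme outliers, emulating e.g. V1), cortex tables
produced by the full neurogenesis model (114 areas, Poisson(36.6)
counting frames per area), and i.i.d. control tables from any of the
comparison families. Fixed seeds give byte-identical tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .area_model import AreaTimeDistribution, simulate_cortex
from .density_tables import DensityTable
from .model_comparison import FAMILIES, family_distribution
from .neurogenesis import NeurogenesisParams

__all__ = [
    "SpeciesSpec",
    "CortexSpec",
    "generate_species_table",
    "generate_cortex_table",
    "generate_control_table",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """Across-area table spec: ln(density) ~ Normal(log_mean, log_sd^2).

    ``outliers`` lists (area label, z offset) pairs: each named area gets
    density exp(log_mean + offset * log_sd), so the |z| >= 3 exclusion
    rule's behavior is exactly controllable. Defaults place geometric-mean
    densities at plausible cortical magnitudes (~8e4 cells/mm^3).
    """

    species: str = "synthetic"
    n_areas: int = 100
    log_mean: float = 11.3
    log_sd: float = 0.3
    outliers: tuple = ()
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_areas < 3:
            raise ValueError("n_areas must be >= 3")
        if self.log_sd <= 0:
            raise ValueError("log_sd must be positive")


@dataclass(frozen=True)
class CortexSpec:
    """Full-model cortex spec (within-area SDE + across-area time law)."""

    params: NeurogenesisParams = field(default_factory=NeurogenesisParams.defaults)
    dist: AreaTimeDistribution = field(default_factory=AreaTimeDistribution.defaults)
    n_areas: int = 114
    mean_frames: float = 36.6
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_areas < 1:
            raise ValueError("n_areas must be >= 1")
        if self.mean_frames <= 0:
            raise ValueError("mean_frames must be positive")


def generate_species_table(spec: SpeciesSpec) -> DensityTable:
    """One density per area, lognormal with optional injected outliers."""
    rng = np.random.default_rng(spec.seed)
    logs = rng.normal(spec.log_mean, spec.log_sd, size=spec.n_areas)
    area_ids = [f"area{i + 1:03d}" for i in range(spec.n_areas)]
    for label, offset in spec.outliers:
        label = str(label)
        if label in area_ids:
            idx = area_ids.index(label)
        else:
            area_ids.append(label)
            logs = np.append(logs, 0.0)
            idx = len(area_ids) - 1
        logs[idx] = spec.log_mean + offset * spec.log_sd
    rows = [
        {"species": spec.species, "area_id": aid, "sample_id": aid,
         "density": float(np.exp(lv))}
        for aid, lv in zip(area_ids, logs)
    ]
    return DensityTable(pd.DataFrame(rows))


def generate_cortex_table(spec: CortexSpec, species: str = "model") -> DensityTable:
    """Run the full cortex simulation and serialize it to the table schema."""
    cortex = simulate_cortex(spec.dist, spec.params, n_areas=spec.n_areas,
                             mean_frames=spec.mean_frames, seed=spec.seed)
    return cortex.to_table(species=species)


def generate_control_table(
    family: str,
    params: dict,
    n: int,
    seed: Optional[int] = None,
    species: Optional[str] = None,
) -> DensityTable:
    """i.i.d. draws from a named comparison family, one area per draw."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = family_distribution(family, params).rvs(size=n, random_state=rng)
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("control draws must be positive; check parameters")
    species = species or f"control_{family}"
    rows = [
        {"species": species, "area_id": f"area{i + 1:03d}",
         "sample_id": f"area{i + 1:03d}", "density": float(v)}
        for i, v in enumerate(x)
    ]
    return DensityTable(pd.DataFrame(rows))
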