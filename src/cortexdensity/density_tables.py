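"""Data model and file I/O for neuron/cell density tables.

A density table is a long-format collection of volumetric density samples
(cells/mm^3), each identified by species, cortical area, and sample id.
One schema serves both across-area data sets (one sample per area) and
within-area data sets (many counting-frame samples per area).
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "DensitySample",
    "DensityTable",
    "AnalysisReport",
    "DensityTableError",
    "read_density_table",
    "write_density_table",
    "COLUMNS",
]

COLUMNS = ["species", "area_id", "sample_id", "density", "depth_fraction"]
REQUIRED_COLUMNS = ["species", "area_id", "sample_id", "density"]
UNITS = "cells/mm3"


class DensityTableError(ValueError):
    """Raised on malformed density tables or files."""


@dataclass(frozen=True)
class DensitySample:
    """A single volumetric density measurement.

    ``depth_fraction``, when present, is the normalized cortical depth of
    the sample: 0 at the L1/L2 boundary, 1 at the white-matter boundary.
    """

    species: str
    area_id: str
    sample_id: str
    density: float
    depth_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.density) or self.density <= 0:
            raise DensityTableError(
                f"density must be a positive finite number, got {self.density!r} "
                f"({self.species}/{self.area_id}/{self.sample_id})"
            )
        if self.depth_fraction is not None and not (0.0 <= self.depth_fraction <= 1.0):
            raise DensityTableError(
                f"depth_fraction must lie in [0, 1], got {self.depth_fraction!r}"
            )


class DensityTable:
    """Non-empty collection of :class:`DensitySample` with unique keys.

    Internally backed by a pandas DataFrame with the canonical column order
    ``species, area_id, sample_id, density, depth_fraction``. Groupings by
    species and by (species, area) are recoverable via :meth:`by_species`
    and :meth:`by_area`.
    """

    units = UNITS

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise DensityTableError(f"missing required column(s): {missing}")
        if "depth_fraction" not in frame.columns:
            frame["depth_fraction"] = np.nan
        frame = frame[COLUMNS]
        if len(frame) == 0:
            raise DensityTableError("density table must contain at least one sample")

        dens = pd.to_numeric(frame["density"], errors="coerce")
        bad = frame.index[~np.isfinite(dens) | (dens <= 0)]
        if len(bad) > 0:
            raise DensityTableError(
                f"non-positive or non-numeric density at row(s) {list(bad[:10])}"
            )
        frame["density"] = dens.astype(float)

        depth = pd.to_numeric(frame["depth_fraction"], errors="coerce")
        has_depth = depth.notna()
        if ((depth[has_depth] < 0) | (depth[has_depth] > 1)).any():
            bad = frame.index[has_depth & ((depth < 0) | (depth > 1))]
            raise DensityTableError(f"depth_fraction outside [0, 1] at row(s) {list(bad[:10])}")
        frame["depth_fraction"] = depth.astype(float)

        for col in ("species", "area_id", "sample_id"):
            frame[col] = frame[col].astype(str)

        dup = frame.duplicated(subset=["species", "area_id", "sample_id"])
        if dup.any():
            keys = frame.loc[dup, ["species", "area_id", "sample_id"]].iloc[0].tolist()
            raise DensityTableError(f"duplicate (species, area, sample) key: {keys}")

        self._frame = frame.reset_index(drop=True)

    # ------------------------------------------------------------------ views
    @property
    def frame(self) -> pd.DataFrame:
        """The underlying long-format DataFrame (copy-safe view)."""
        return self._frame

    @property
    def samples(self) -> Iterator[DensitySample]:
        for row in self._frame.itertuples(index=False):
            depth = None if pd.isna(row.depth_fraction) else float(row.depth_fraction)
            yield DensitySample(row.species, row.area_id, row.sample_id, float(row.density), depth)

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def species(self) -> list[str]:
        return sorted(self._frame["species"].unique())

    def by_species(self) -> dict[str, np.ndarray]:
        """Map species -> densities (one entry per sample)."""
        return {
            str(k): g["density"].to_numpy()
            for k, g in self._frame.groupby("species", sort=True)
        }

    def by_area(self) -> dict[tuple[str, str], np.ndarray]:
        """Map (species, area_id) -> densities of that area's samples."""
        return {
            (str(k[0]), str(k[1])): g["density"].to_numpy()
            for k, g in self._frame.groupby(["species", "area_id"], sort=True)
        }

    def area_labels(self, species: Optional[str] = None) -> dict[str, np.ndarray]:
        """Map area-level group label -> per-sample labels used in outlier reports.

        For across-area tables (one sample per area) the natural sample label
        is the area id; we report ``area_id`` so flagged outliers name areas.
        """
        frame = self._frame
        if species is not None:
            frame = frame[frame["species"] == species]
        return {
            str(k): g["area_id"].to_numpy()
            for k, g in frame.groupby("species", sort=True)
        }

    @classmethod
    def from_samples(cls, samples) -> "DensityTable":
        rows = [
            {
                "species": s.species,
                "area_id": s.area_id,
                "sample_id": s.sample_id,
                "density": s.density,
                "depth_fraction": np.nan if s.depth_fraction is None else s.depth_fraction,
            }
            for s in samples
        ]
        if not rows:
            raise DensityTableError("density table must contain at least one sample")
        return cls(pd.DataFrame(rows))

    def __eq__(self, other) -> bool:
        if not isinstance(other, DensityTable):
            return NotImplemented
        return self._frame.equals(other._frame)


# ---------------------------------------------------------------------- I/O

def _sep(dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    raise DensityTableError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")


def read_density_table(path, dialect: str = "csv") -> DensityTable:
    """Read a density table from a delimited text file.

    The header must name at least ``species, area_id, sample_id, density``;
    ``depth_fraction`` is optional and may be empty. Rows with missing or
    non-positive densities are rejected with row-indexed diagnostics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep=_sep(dialect), float_precision="round_trip",
                        dtype={"species": str, "area_id": str, "sample_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise DensityTableError(f"{path}: missing required column(s): {missing}")
    null_dens = frame.index[frame["density"].isna()]
    if len(null_dens) > 0:
        raise DensityTableError(f"{path}: missing density at data row(s) {list(null_dens[:10])}")
    try:
        return DensityTable(frame)
    except DensityTableError as exc:
        raise DensityTableError(f"{path}: {exc}") from exc


def write_density_table(table: DensityTable, path, dialect: str = "csv") -> None:
    """Write ``table`` to ``path``; output is re-readable and byte-stable.

    Densities are serialized with ``repr`` precision (17 significant digits),
    so a read/write round trip preserves values exactly.
    """
    sep = _sep(dialect)
    path = Path(path)
    frame = table.frame.copy()
    frame["depth_fraction"] = frame["depth_fraction"].map(
        lambda v: "" if pd.isna(v) else np.format_float_positional(v, trim="0")
    )
    frame["density"] = frame["density"].map(lambda v: repr(float(v)))
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep=sep, index=False, lineterminator="\n")


# ------------------------------------------------------------------ reports

@dataclass
class AnalysisReport:
    """Serializable container for per-group analysis results with provenance.

    Numeric values survive a JSON round trip without loss (floats are
    serialized at full precision by the json module).
    """

    results: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def with_provenance(self, *, seed=None, config: Optional[Mapping] = None,
                        timestamp: Optional[str] = None) -> "AnalysisReport":
        prov = dict(self.provenance)
        if seed is not None:
            prov["seed"] = int(seed)
        if config is not None:
            blob = json.dumps(config, sort_keys=True, default=str)
            prov["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
            prov["config"] = dict(config)
        if timestamp is not None:
            prov["timestamp"] = timestamp
        return AnalysisReport(results=self.results, provenance=prov)

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = {"results": self.results, "provenance": self.provenance}
        text = json.dumps(payload, indent=indent, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "AnalysisReport":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        return cls(results=payload.get("results", {}), provenance=payload.get("provenance", {}))
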