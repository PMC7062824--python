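"""Accuracy metrics for population projections and grids.

Percentage errors follow the demographic-forecasting convention: the
algebraic percentage error PE = (P − A)/A × 100 is positive when the
projection overestimates, and APE = |PE|.  Grid comparisons report RMSE,
%RMSE (RMSE as a percent of the mean reference value), MAE and MAD, where
MAD is the median absolute deviation of the errors from their median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .state import DimensionError

logger = logging.getLogger(__name__)


class UndefinedMetricError(ZeroDivisionError):
    pass


def pe(projected, actual):
    """Algebraic percentage error; positive means overestimation."""
    p = np.asarray(projected, dtype=float)
    a = np.asarray(actual, dtype=float)
    if np.any(a == 0):
        raise UndefinedMetricError("percentage error undefined for actual == 0")
    return (p - a) / a * 100.0


def ape(projected, actual):
    """Absolute percentage error, |PE|."""
    return np.abs(pe(projected, actual))


def _mad(errors: np.ndarray) -> float:
    med = np.median(errors)
    return float(np.median(np.abs(errors - med)))


def _summary(projected: np.ndarray, actual: np.ndarray) -> dict[str, float]:
    err = projected - actual
    rmse = float(np.sqrt(np.mean(err ** 2)))
    mean_actual = float(np.mean(actual))
    nz = actual != 0
    pes = (projected[nz] - actual[nz]) / actual[nz] * 100.0
    return {
        "rmse": rmse,
        "pct_rmse": rmse / mean_actual * 100.0 if mean_actual else float("nan"),
        "mae": float(np.mean(np.abs(err))),
        "mad": _mad(err),
        "mean_ape": float(np.mean(np.abs(pes))) if pes.size else float("nan"),
        "median_ape": float(np.median(np.abs(pes))) if pes.size else float("nan"),
        "mean_pe": float(np.mean(pes)) if pes.size else float("nan"),
    }


@dataclass
class ComparisonReport:
    """Per-unit errors plus summary statistics for one comparison."""

    level: str                       # national / provincial / zonal / cell
    units: np.ndarray                # unit identifiers
    projected: np.ndarray
    actual: np.ndarray
    summary: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = _summary(
                np.asarray(self.projected, dtype=float),
                np.asarray(self.actual, dtype=float),
            )

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "units": np.asarray(self.units).tolist(),
            "projected": np.asarray(self.projected, dtype=float).tolist(),
            "actual": np.asarray(self.actual, dtype=float).tolist(),
            "summary": self.summary,
        }


def zonal_metrics(
    grid: np.ndarray,
    zones: np.ndarray,
    actual_by_zone: dict[int, float],
    mode: str = "counts",
) -> ComparisonReport:
    """Aggregate a grid into zones and compare with actual zone values.

    ``mode='counts'`` compares person counts per zone; ``mode='densities'``
    divides both sides by the zone's pixel count.  Zones with zero pixels
    are excluded with a warning.
    """
    if grid.shape != zones.shape:
        raise DimensionError("zones raster not aligned with grid")
    if mode not in ("counts", "densities"):
        raise ValueError(f"unknown mode {mode!r}")
    ids, proj, act = [], [], []
    for z, a in sorted(actual_by_zone.items()):
        inside = zones == z
        n_pix = int(inside.sum())
        if n_pix == 0:
            logger.warning("zone %s has zero pixels; excluded", z)
            continue
        p = float(grid[inside].sum())
        if mode == "densities":
            p /= n_pix
            a = a / n_pix
        ids.append(z)
        proj.append(p)
        act.append(a)
    return ComparisonReport(
        level="zonal",
        units=np.array(ids),
        projected=np.array(proj),
        actual=np.array(act),
    )


def cell_compare(grid_a: np.ndarray, grid_b: np.ndarray) -> ComparisonReport:
    """Cell-by-cell comparison of two grids, with ``grid_a`` as reference.

    RMSE/MAE/MAD are computed over all cells; APE statistics only over
    cells where the reference is positive.
    """
    if grid_a.shape != grid_b.shape:
        raise DimensionError(
            f"grids have different shapes {grid_a.shape} vs {grid_b.shape}"
        )
    a = np.asarray(grid_a, dtype=float).ravel()
    b = np.asarray(grid_b, dtype=float).ravel()
    keep = a > 0
    report = ComparisonReport(
        level="cell",
        units=np.flatnonzero(keep),
        projected=b[keep],
        actual=a[keep],
    )
    return report
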