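"""Recursive dasymetric downscaling of provincial populations to a grid.

The base-year weight grid is a gridded-population layer with waterbodies
removed and two tiny ancillary terms added (inverse distance to roads and
to the provincial population centre of gravity, each rescaled into
[1.0e-5, 1.1e-5]) so that pixel values are pairwise distinct and sorting
is unambiguous.  Each year, coarse urban-land fractions decide how many
fine pixels per coarse cell are urban — the highest-valued pixels of the
previous year's grid are selected — and the provincial urban and rural
populations are spread proportionally over urban and non-urban pixels
respectively.  The previous year's result seeds the next year's mask, so
the urban footprint evolves with the projected population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .state import DimensionError


@dataclass
class PopulationGrid:
    """A fine-resolution population raster for one year and scenario,
    with its companion layers."""

    values: np.ndarray
    year: int
    scenario: str                      # e.g. "SSP2_RCP6"
    province_id: np.ndarray | None = None
    water: np.ndarray | None = None
    urban_mask: np.ndarray | None = None

    def province_sums(self) -> np.ndarray:
        if self.province_id is None:
            raise ValueError("no province raster attached")
        n = int(self.province_id.max()) + 1
        return np.bincount(
            self.province_id.ravel(), weights=self.values.ravel(), minlength=n
        )

EPS_LO, EPS_HI = 1.0e-5, 1.1e-5

#: joint (SSP, RCP) plausibility weights; pairs with zero weight are not
#: admissible scenario combinations.
SCENARIO_MATRIX: dict[tuple[str, str], float] = {
    ("SSP1", "RCP2.6"): 0.0909, ("SSP1", "RCP4.5"): 0.4545,
    ("SSP1", "RCP6"): 0.4545, ("SSP1", "RCP8.5"): 0.0000,
    ("SSP2", "RCP2.6"): 0.0000, ("SSP2", "RCP4.5"): 0.0909,
    ("SSP2", "RCP6"): 0.6818, ("SSP2", "RCP8.5"): 0.2273,
    ("SSP3", "RCP2.6"): 0.0000, ("SSP3", "RCP4.5"): 0.1667,
    ("SSP3", "RCP6"): 0.5000, ("SSP3", "RCP8.5"): 0.3333,
    ("SSP4", "RCP2.6"): 0.0000, ("SSP4", "RCP4.5"): 0.3704,
    ("SSP4", "RCP6"): 0.5556, ("SSP4", "RCP8.5"): 0.0741,
    ("SSP5", "RCP2.6"): 0.0000, ("SSP5", "RCP4.5"): 0.0741,
    ("SSP5", "RCP6"): 0.3704, ("SSP5", "RCP8.5"): 0.5556,
}


def admissible_pairs() -> list[tuple[str, str]]:
    """The (SSP, RCP) combinations with nonzero plausibility weight."""
    return [k for k, v in SCENARIO_MATRIX.items() if v > 0]


def check_scenario_pair(ssp: str, rcp: str) -> None:
    if SCENARIO_MATRIX.get((ssp, rcp), 0.0) <= 0.0:
        valid = ", ".join(f"{s}-{r}" for s, r in admissible_pairs())
        raise ValueError(
            f"scenario pair {ssp}-{rcp} has zero plausibility; valid pairs: {valid}"
        )


def round_half_up(x: np.ndarray | float) -> np.ndarray:
    """Nearest integer with .5 rounding up — the single place this is decided."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def _rescale(layer: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Min-max rescale ``layer`` over ``mask`` into [EPS_LO, EPS_HI]."""
    out = np.zeros_like(layer, dtype=float)
    vals = layer[mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        out[mask] = 0.5 * (EPS_LO + EPS_HI)
    else:
        out[mask] = EPS_LO + (vals - lo) / (hi - lo) * (EPS_HI - EPS_LO)
    return out


def build_base_grid(
    pop_grid_raw: np.ndarray,
    water_mask: np.ndarray,
    road_distance: np.ndarray,
    gravity_field: np.ndarray,
) -> np.ndarray:
    """Base weight grid: population with water removed plus epsilon terms.

    The inverse road distance and the gravity field are each min-max
    rescaled into [1.0e-5, 1.1e-5] and added; the additions are orders of
    magnitude below any population signal but make non-water pixel values
    pairwise distinct, which the urban-mask sort relies on.
    """
    shapes = {pop_grid_raw.shape, water_mask.shape, road_distance.shape,
              gravity_field.shape}
    if len(shapes) != 1:
        raise DimensionError(f"layers not co-registered: shapes {shapes}")
    land = ~water_mask.astype(bool)
    inv_road = 1.0 / (1.0 + np.asarray(road_distance, dtype=float))
    base = np.where(land, np.asarray(pop_grid_raw, dtype=float), 0.0)
    base = base + _rescale(inv_road, land) + _rescale(gravity_field, land)
    base[~land] = 0.0
    return base


def _coarse_blocks(shape: tuple[int, int], factor: int):
    rows, cols = shape
    if rows % factor or cols % factor:
        raise DimensionError("fine raster not divisible by coarse factor")
    for i in range(rows // factor):
        for j in range(cols // factor):
            yield (slice(i * factor, (i + 1) * factor),
                   slice(j * factor, (j + 1) * factor)), (i, j)


def compute_urban_mask(
    prev_grid: np.ndarray,
    urban_fraction: np.ndarray,
    coarse_factor: int,
    water_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Urban/rural classification of fine pixels from coarse urban fractions.

    Within each coarse cell, round-half-up(fraction × pixels in cell)
    pixels are marked urban, choosing the highest previous-year values
    first; ties (impossible on the unique-valued base grid, possible after
    years of equal allocation) break on flat pixel order.  Water pixels are
    never selected; the count is capped at the cell's non-water pixels.
    """
    prev = np.asarray(prev_grid, dtype=float)
    mask = np.zeros(prev.shape, dtype=bool)
    water = (np.zeros(prev.shape, dtype=bool) if water_mask is None
             else water_mask.astype(bool))
    frac = np.asarray(urban_fraction, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("urban fractions must lie in [0, 1]")
    for block, (i, j) in _coarse_blocks(prev.shape, coarse_factor):
        cell = prev[block].ravel()
        cell_water = water[block].ravel()
        n_pix = cell.size
        n_urban = int(round_half_up(frac[i, j] * n_pix))
        n_urban = min(n_urban, int((~cell_water).sum()))
        if n_urban == 0:
            continue
        # primary: land before water; then value descending; then pixel order
        order = np.lexsort((np.arange(n_pix), -cell, cell_water))
        sel = np.zeros(n_pix, dtype=bool)
        sel[order[:n_urban]] = True
        mask[block] = sel.reshape(coarse_factor, coarse_factor)
    return mask


def _distribute(total: float, weights: np.ndarray) -> np.ndarray:
    s = weights.sum()
    if s > 0:
        return total * (weights / s)
    return np.full(weights.shape, total / weights.size)


def allocate_year(
    prev_grid: np.ndarray,
    mask: np.ndarray,
    province_raster: np.ndarray,
    urban_pop: np.ndarray,
    rural_pop: np.ndarray,
    water_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Distribute provincial urban/rural totals over the fine grid.

    Within each province the urban total is spread over urban pixels
    proportionally to the previous year's values, and the rural total over
    non-urban land pixels likewise.  A province with urban population but
    no urban pixels spreads it uniformly over its highest-valued 1% of
    land pixels (at least one).
    """
    prev = np.asarray(prev_grid, dtype=float)
    water = (np.zeros(prev.shape, dtype=bool) if water_mask is None
             else water_mask.astype(bool))
    out = np.zeros_like(prev)
    provinces = np.unique(province_raster)
    if urban_pop.shape != rural_pop.shape or len(urban_pop) < len(provinces):
        raise DimensionError("one urban/rural total per province required")
    for i in provinces:
        inside = (province_raster == i) & ~water
        if not inside.any():
            raise ValueError(f"province {i} has no land pixels")
        urb = inside & mask
        rur = inside & ~mask
        if urban_pop[i] > 0 and not urb.any():
            n = max(1, int(round_half_up(0.01 * inside.sum())))
            vals = np.where(inside, prev, -np.inf).ravel()
            top = np.argpartition(-vals, n - 1)[:n]
            flat = out.ravel()
            flat[top] += urban_pop[i] / n
            logging.getLogger(__name__).warning(
                "province %s has urban population but no urban pixels; "
                "spread over top %d pixels", i, n,
            )
        elif urb.any():
            out[urb] += _distribute(float(urban_pop[i]), prev[urb])
        if rur.any():
            out[rur] += _distribute(float(rural_pop[i]), prev[rur])
        elif rural_pop[i] > 0:
            out[inside] += _distribute(float(rural_pop[i]), prev[inside])
    return out


def interpolate_fractions(
    urban_fraction_epochs: dict[int, np.ndarray], year: int
) -> np.ndarray:
    """Coarse urban fractions for an arbitrary year, linear between epochs
    and clamped at the ends."""
    years = sorted(urban_fraction_epochs)
    if year <= years[0]:
        return urban_fraction_epochs[years[0]]
    if year >= years[-1]:
        return urban_fraction_epochs[years[-1]]
    for y0, y1 in zip(years, years[1:]):
        if y0 <= year <= y1:
            w = (year - y0) / (y1 - y0)
            return ((1 - w) * urban_fraction_epochs[y0]
                    + w * urban_fraction_epochs[y1])
    raise AssertionError("unreachable")


def downscale_series(
    base_grid: np.ndarray,
    province_raster: np.ndarray,
    urban_by_year: dict[int, np.ndarray],
    rural_by_year: dict[int, np.ndarray],
    urban_fraction_epochs: dict[int, np.ndarray],
    coarse_factor: int,
    ssp: str,
    rcp: str,
    water_mask: np.ndarray | None = None,
) -> dict[int, np.ndarray]:
    """Yearly population grids for one admissible (SSP, RCP) pair.

    The first year's grid is the base weight grid rescaled to that year's
    provincial totals; every later year derives its urban mask from the
    previous year's grid and the (interpolated) urban fractions, then
    allocates that year's urban/rural totals.
    """
    check_scenario_pair(ssp, rcp)
    years = sorted(urban_by_year)
    water = (np.zeros(base_grid.shape, dtype=bool) if water_mask is None
             else water_mask.astype(bool))

    first = years[0]
    totals0 = urban_by_year[first] + rural_by_year[first]
    grid = np.zeros_like(base_grid, dtype=float)
    for i in np.unique(province_raster):
        inside = (province_raster == i) & ~water
        grid[inside] = _distribute(float(totals0[i]), base_grid[inside])
    out = {first: grid}

    for year in years[1:]:
        frac = interpolate_fractions(urban_fraction_epochs, year)
        mask = compute_urban_mask(out[year - 1], frac, coarse_factor, water)
        out[year] = allocate_year(
            out[year - 1], mask, province_raster,
            urban_by_year[year], rural_by_year[year], water,
        )
    return out
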