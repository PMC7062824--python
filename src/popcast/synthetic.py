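"""Synthetic census-like world generator.

Produces every input the projection pipeline would otherwise read from a
national census, statistical yearbooks, a gridded-population product, road
data and coarse urban-land fractions: a base-year multidimensional
population, fertility/mortality/progression/migration rate matrices with
known ground-truth TFR and life expectancy, provincial urbanization
histories lying on a known logistic curve, and a small multi-province
raster world.  Because the generating parameters are known, calibration
and parameter-recovery are directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .engine import calibrate_mortality, life_expectancy
from .state import (
    AGE_EDU_FEASIBLE,
    FERTILE_AGES,
    N_AGE,
    N_EDU,
    N_SEX,
    N_TRANSITIONS,
    ConfigurationError,
    PopulationState,
    RateSet,
    implied_tfr_by_province,
)

INCOME_CATEGORIES = ("high", "medium", "low")


@dataclass
class SyntheticWorldConfig:
    """Parameters of the synthetic world.

    ``raster_shape`` must be divisible by ``coarse_factor`` in both
    dimensions; every province is guaranteed at least one pixel.
    """

    n_provinces: int = 5
    income_category: tuple[str, ...] | None = None
    base_year: int = 2010
    raster_shape: tuple[int, int] = (120, 120)
    coarse_factor: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_provinces < 2:
            raise ConfigurationError("need at least 2 provinces")
        r, c = self.raster_shape
        if r % self.coarse_factor or c % self.coarse_factor:
            raise ConfigurationError(
                "raster_shape must be divisible by coarse_factor"
            )
        if self.raster_shape[0] * self.raster_shape[1] < self.n_provinces:
            raise ConfigurationError("fewer pixels than provinces")
        if self.income_category is None:
            self.income_category = tuple(
                INCOME_CATEGORIES[i % 3] for i in range(self.n_provinces)
            )
        if len(self.income_category) != self.n_provinces:
            raise ConfigurationError("one income category per province required")
        for cat in self.income_category:
            if cat not in INCOME_CATEGORIES:
                raise ConfigurationError(f"unknown income category {cat!r}")

    @property
    def provinces(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1:02d}" for i in range(self.n_provinces))


@dataclass
class GroundTruth:
    """Known generating parameters, for recovery tests."""

    tfr: np.ndarray                      # (P,) births/woman
    le: np.ndarray                       # (P, 2) years, male/female
    sigmoid: np.ndarray                  # (P, 3) columns b, c, d
    urban_fractions: dict[int, np.ndarray]  # epoch year -> coarse grid


def _rng(config: SyntheticWorldConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def generate_ground_truth(config: SyntheticWorldConfig) -> GroundTruth:
    rng = _rng(config, 0)
    p = config.n_provinces
    tfr = rng.uniform(1.3, 1.9, size=p)
    le = np.empty((p, 2))
    le[:, 0] = rng.uniform(70.0, 77.0, size=p)   # male
    le[:, 1] = le[:, 0] + rng.uniform(3.0, 6.0, size=p)  # female advantage
    sigmoid = np.column_stack([
        rng.uniform(0.70, 0.95, size=p),   # b: upper limit
        rng.uniform(0.04, 0.09, size=p),   # c: pace, 1/year
        rng.uniform(8.0, 30.0, size=p),    # d: inflection, years since 1995
    ])
    return GroundTruth(tfr=tfr, le=le, sigmoid=sigmoid, urban_fractions={})


def generate_base_population(config: SyntheticWorldConfig) -> PopulationState:
    """Base-year population counts by province × sex × age × education.

    Age pyramids follow a stationary-population shape from a Gompertz-type
    survival curve with mild cohort growth; education shares respect the
    stage entry ages (nobody holds a stage younger than its entry age).
    """
    rng = _rng(config, 1)
    p = config.n_provinces
    ages = np.arange(N_AGE, dtype=float)

    # survival-shaped pyramid with modest historical growth
    hazard = 5e-4 + 1e-2 * np.exp(-ages) + 5e-5 * np.exp(0.092 * ages)
    surv = np.exp(-np.cumsum(hazard))
    pyramid = surv * np.exp(-0.004 * ages)
    pyramid /= pyramid.sum()

    # adult education shares, stage order: illiterate .. master+
    adult_shares = np.array([0.05, 0.25, 0.38, 0.18, 0.05, 0.07, 0.02])

    counts = np.zeros((p, N_SEX, N_AGE, N_EDU))
    male_frac = np.clip(0.512 - 0.0008 * ages, 0.40, 0.60)
    for i in range(p):
        total = rng.uniform(2e6, 2e7)
        jitter = rng.normal(1.0, 0.05, size=N_AGE).clip(0.5)
        age_dist = pyramid * jitter
        age_dist /= age_dist.sum()
        shares = adult_shares * rng.normal(1.0, 0.1, size=N_EDU).clip(0.3)
        for a in range(N_AGE):
            w = shares * AGE_EDU_FEASIBLE[a]
            w /= w.sum()
            n_age = total * age_dist[a]
            counts[i, 0, a] = n_age * male_frac[a] * w
            counts[i, 1, a] = n_age * (1.0 - male_frac[a]) * w
    return PopulationState(counts, config.base_year, config.provinces)


def _gompertz_makeham_hazard(sex: int) -> np.ndarray:
    """Baseline hazard over ages 0..100; females carry a lower senescent term."""
    ages = np.arange(N_AGE, dtype=float)
    b = 6.0e-5 if sex == 0 else 3.5e-5
    return 4e-4 + 8e-3 * np.exp(-ages) + b * np.exp(0.095 * ages)


def generate_rates(
    config: SyntheticWorldConfig,
    ground_truth: GroundTruth,
    base_state: PopulationState | None = None,
) -> RateSet:
    """Base-year rate matrices calibrated to the ground-truth TFR and LE.

    Fertility is a fixed unimodal schedule over ages 15-49 with
    education-stage multipliers, scaled per province so the implied
    provincial TFR matches the ground truth exactly; mortality is a
    Gompertz–Makeham hazard scaled by root-finding so each province × sex
    life table reproduces the ground-truth life expectancy to 1e-6 years.
    """
    rng = _rng(config, 2)
    p = config.n_provinces
    if base_state is None:
        base_state = generate_base_population(config)

    # --- fertility ---------------------------------------------------------
    lo, hi = FERTILE_AGES
    ages = np.arange(N_AGE, dtype=float)
    shape = np.zeros(N_AGE)
    x = ages[lo:hi + 1] - (lo - 1)
    shape[lo:hi + 1] = x ** 2.2 * np.exp(-x / 4.5)
    edu_mult = np.array([1.3, 1.2, 1.1, 1.0, 0.9, 0.8, 0.7])
    fer = (
        shape[None, :, None]
        * edu_mult[None, None, :]
        * rng.normal(1.0, 0.05, size=(p, 1, 1)).clip(0.5)
    )
    fer[:, :lo, :] = 0.0
    fer[:, hi + 1:, :] = 0.0
    implied = implied_tfr_by_province(fer, base_state.females())
    fer *= (ground_truth.tfr / implied)[:, None, None]

    # --- mortality ---------------------------------------------------------
    mor = np.empty((p, N_SEX, N_AGE))
    for s in range(N_SEX):
        m = _gompertz_makeham_hazard(s)
        base_sched = np.empty(N_AGE)
        base_sched[:100] = 1.0 - np.exp(-m[:100])
        base_sched[100] = m[100]
        for i in range(p):
            mor[i, s], _ = calibrate_mortality(
                base_sched, ground_truth.le[i, s], bracket=(0.0, 50.0)
            )

    # --- progression -------------------------------------------------------
    g_base = np.array([0.97, 0.95, 0.88, 0.18, 0.34, 0.10])
    g = g_base[None, None, :] * rng.normal(1.0, 0.05, size=(p, N_SEX, 1)).clip(0.5)
    g = np.clip(g, 0.0, np.array([0.999, 0.999, 0.999, 0.30, 0.60, 0.30]))

    # --- migration ---------------------------------------------------------
    base_rate = {"high": 0.006, "medium": -0.002, "low": -0.005}
    age_profile = np.exp(-0.5 * ((ages - 25.0) / 9.0) ** 2)  # young adults move
    netpim = np.zeros((p, 1, N_AGE, 1))
    for i, cat in enumerate(config.income_category):
        level = base_rate[cat] * rng.uniform(0.7, 1.3)
        netpim[i, 0, :, 0] = level * age_profile

    srb = rng.uniform(1.12, 1.20, size=p)
    return RateSet(
        fer=fer,
        mor=mor,
        g=g,
        netpim=netpim,
        netgim=-0.3015e-3,
        bm=srb / (1.0 + srb),
        bf=1.0 / (1.0 + srb),
    )


def generate_urbanization_history(
    config: SyntheticWorldConfig,
    ground_truth: GroundTruth,
    noise_sd: float = 0.0,
    start: int = 1995,
    end: int = 2015,
) -> dict[str, np.ndarray]:
    """Per-province urbanization-rate series on the known logistic curve.

    PU(t) = b / (1 + exp(−c (t − start − d))), optionally with bounded
    Gaussian noise; values are clipped to stay strictly inside (0, b).
    Returns a mapping province -> array over years ``start..end``.
    """
    rng = _rng(config, 3)
    years = np.arange(start, end + 1, dtype=float)
    out: dict[str, np.ndarray] = {}
    for i, name in enumerate(config.provinces):
        b, c, d = ground_truth.sigmoid[i]
        pu = b / (1.0 + np.exp(-c * (years - start - d)))
        if noise_sd > 0:
            pu = pu + np.clip(
                rng.normal(0.0, noise_sd, size=years.size), -3 * noise_sd, 3 * noise_sd
            )
        eps = 1e-4 * b
        out[name] = np.clip(pu, eps, b - eps)
    return out


@dataclass
class RasterWorld:
    """Toy raster layers mirroring the downscaling inputs.

    All fine layers share ``config.raster_shape``; coarse layers have shape
    (rows // coarse_factor, cols // coarse_factor).
    """

    pop_raw: np.ndarray            # gridded-population style weights
    province_id: np.ndarray        # int raster; partitions every pixel (water carries zero weight)
    water: np.ndarray              # bool mask
    road_distance: np.ndarray      # euclidean pixel distance to synthetic roads
    gravity: np.ndarray            # inverse distance to provincial pop centroid
    urban_fraction: dict[int, np.ndarray]  # epoch year -> coarse fraction grid


def generate_raster_world(
    config: SyntheticWorldConfig,
    epochs: tuple[int, ...] = (2010, 2050, 2100),
) -> RasterWorld:
    """Generate the small multi-province raster world.

    Provinces are Voronoi cells of random seed pixels; water is a smoothed
    noise blob (cleared where it would drown a whole province); population
    weight is a continuous log-normal field so values are almost surely
    pairwise distinct; urban-land fractions per coarse cell increase across
    epochs.
    """
    rng = _rng(config, 4)
    rows, cols = config.raster_shape
    p = config.n_provinces
    yy, xx = np.mgrid[0:rows, 0:cols]

    idx = rng.choice(rows * cols, size=p, replace=False)
    seeds = np.column_stack(np.unravel_index(idx, (rows, cols)))
    d2 = (yy[..., None] - seeds[:, 0]) ** 2 + (xx[..., None] - seeds[:, 1]) ** 2
    province_id = np.argmin(d2, axis=-1).astype(np.int32)

    water = ndimage.gaussian_filter(rng.normal(size=(rows, cols)), 6) > 1.1
    for i in range(p):
        inside = province_id == i
        if np.all(water[inside]):
            water[inside] = False  # keep every province habitable

    smooth = ndimage.gaussian_filter(rng.normal(size=(rows, cols)), 3)
    peaks = np.zeros((rows, cols))
    for i in range(p):
        dist = np.sqrt((yy - seeds[i, 0]) ** 2 + (xx - seeds[i, 1]) ** 2)
        peaks += 3.0 * np.exp(-dist / 12.0)
    pop_raw = np.exp(smooth + peaks + rng.normal(0, 0.01, size=(rows, cols)))
    pop_raw[water] = 0.0

    road = np.zeros((rows, cols), dtype=bool)
    for _ in range(max(2, p // 2)):
        r0 = rng.integers(0, rows)
        road[r0, :] = True
        c0 = rng.integers(0, cols)
        road[:, c0] = True
    road_distance = ndimage.distance_transform_edt(~road).astype(float)

    gravity = np.zeros((rows, cols))
    for i in range(p):
        inside = province_id == i
        w = pop_raw * inside
        tot = w.sum()
        if tot == 0:
            cy, cx = seeds[i]
        else:
            cy = (yy * w).sum() / tot
            cx = (xx * w).sum() / tot
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        gravity[inside] = 1.0 / (1.0 + dist[inside])

    f = config.coarse_factor
    cr, cc = rows // f, cols // f
    density = pop_raw.reshape(cr, f, cc, f).mean(axis=(1, 3))
    rank = density.argsort(axis=None).argsort(axis=None).reshape(cr, cc)
    base_frac = 0.5 * rank / max(rank.max(), 1)
    urban_fraction = {}
    for k, year in enumerate(sorted(epochs)):
        growth = 1.0 + 0.6 * k / max(len(epochs) - 1, 1)
        urban_fraction[year] = np.clip(base_frac * growth, 0.0, 1.0)

    return RasterWorld(
        pop_raw=pop_raw,
        province_id=province_id,
        water=water,
        road_distance=road_distance,
        gravity=gravity,
        urban_fraction=urban_fraction,
    )


@dataclass
class SyntheticWorld:
    """Everything the pipeline needs, bundled: base state, base rates,
    per-province scalars for scenario assembly, urbanization history and
    the raster world."""

    config: SyntheticWorldConfig
    ground_truth: GroundTruth
    base_state: PopulationState
    base_rates: RateSet
    base_le: np.ndarray            # (P, 2)
    base_national_le: np.ndarray   # (2,) population-weighted
    base_srb: np.ndarray           # (P,)
    base_pr: np.ndarray            # (P, 2, n_transitions)
    pr_growth: np.ndarray          # (P, 2, n_transitions) annual rates
    urbanization_history: dict[str, np.ndarray]
    raster: RasterWorld

    @property
    def provinces(self) -> tuple[str, ...]:
        return self.config.provinces

    @property
    def income_categories(self) -> tuple[str, ...]:
        return self.config.income_category


def make_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate the full synthetic world deterministically from the config."""
    gt = generate_ground_truth(config)
    state = generate_base_population(config)
    rates = generate_rates(config, gt, base_state=state)
    raster = generate_raster_world(config)
    gt.urban_fractions = raster.urban_fraction

    weights = state.totals_by_province()
    national_le = (gt.le * weights[:, None]).sum(axis=0) / weights.sum()
    srb = rates.bm / rates.bf

    rng = _rng(config, 5)
    growth = rng.uniform(0.001, 0.010, size=(config.n_provinces, N_SEX, N_TRANSITIONS))

    return SyntheticWorld(
        config=config,
        ground_truth=gt,
        base_state=state,
        base_rates=rates,
        base_le=gt.le.copy(),
        base_national_le=national_le,
        base_srb=srb,
        base_pr=rates.g.copy(),
        pr_growth=growth,
        urbanization_history=generate_urbanization_history(config, gt),
        raster=raster,
    )
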