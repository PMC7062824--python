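"""SSP scenario assumption trajectories, 2010-2100.

Each SSP assigns a level (low / medium / high) to fertility, mortality,
migration and education; the level assignments follow the standard SSP
narratives (SSP1 sustainability, SSP2 middle-of-the-road, SSP3 regional
rivalry, SSP4 inequality, SSP5 fossil-fueled development).  The builders
below turn level names into complete year-by-year paths through the stated
anchor points, with linear interpolation between anchors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BASE_YEAR = 2010
END_YEAR = 2100
YEARS = tuple(range(BASE_YEAR, END_YEAR + 1))

# --- TFR anchors ------------------------------------------------------------
TFR_BASE_2010 = 1.6          # census TFR adjusted upward for undercount
TFR_MEDIUM_2020 = 1.8        # peak of the two-child-policy release
TFR_MEDIUM_2030 = 1.65       # post-release policy-incentive level
TFR_HIGH_2020 = 2.0          # fully-open-policy peak
#: UN medium-variant TFR anchors used for the post-2030 growth rate
UN_TFR_2030, UN_TFR_2100 = 1.706, 1.802
UN_GROWTH = (UN_TFR_2100 / UN_TFR_2030) ** (1.0 / 70.0)

# --- mortality: LE growth per decade by level -------------------------------
LE_DECADAL_RATE = {"medium": 1.0, "high": 0.5, "low": 1.5}

# --- international migration ------------------------------------------------
NETGIM_2010_PERMILLE = -0.3015   # mean of -0.3570 (2005-10) and -0.2460 (2010-15)

# --- sex ratio at birth -----------------------------------------------------
SRB_TARGET = 1.07
SRB_TARGET_YEAR = 2050

# --- education progression caps, in transition order ------------------------
#: enrolment, primary->junior, junior->senior capped by compulsory-education
#: saturation; the tertiary caps follow observed ceilings in high-attainment
#: systems (30% senior->college, 60% senior->bachelor, 30% bachelor->master).
PR_CAPS = np.array([0.999, 0.999, 0.999, 0.30, 0.60, 0.30])

#: SSP level grid: (fertility, mortality, migration, education)
SSP_TABLE = {
    "SSP1": ("low", "low", "medium", "high"),
    "SSP2": ("medium", "medium", "medium", "medium"),
    "SSP3": ("high", "high", "low", "low"),
    "SSP4": ("low", "medium", "medium", "income_dependent"),
    "SSP5": ("low", "low", "high", "high"),
}

#: SSP4 education: income category -> education level
SSP4_EDUCATION_BY_INCOME = {"high": "high", "medium": "medium", "low": "low"}


def _interp(anchors: dict[int, float]) -> dict[int, float]:
    """Piecewise-linear path through anchors, constant after the last one."""
    ys = sorted(anchors)
    years = np.arange(BASE_YEAR, END_YEAR + 1)
    vals = np.interp(years, ys, [anchors[y] for y in ys])
    return dict(zip(years.tolist(), vals.tolist()))


def build_tfr_path(level: str) -> dict[int, float]:
    """National TFR trajectory for a fertility level.

    medium: 1.6 (2010) -> 1.8 (2020) -> 1.65 (2030), then growing at the
    constant annual factor implied by the UN medium variant between 2030 and
    2100.  high: rises to 2.0 by 2020, reaches 1.25 × medium in 2050, then
    constant.  low: follows medium through 2020, falls to 0.75 × medium in
    2050, then constant.
    """
    medium_2050 = TFR_MEDIUM_2030 * UN_GROWTH ** (2050 - 2030)
    if level == "medium":
        path = _interp({BASE_YEAR: TFR_BASE_2010, 2020: TFR_MEDIUM_2020,
                        2030: TFR_MEDIUM_2030})
        for y in range(2031, END_YEAR + 1):
            path[y] = path[y - 1] * UN_GROWTH
        return path
    if level == "high":
        return _interp({BASE_YEAR: TFR_BASE_2010, 2020: TFR_HIGH_2020,
                        2050: 1.25 * medium_2050})
    if level == "low":
        return _interp({BASE_YEAR: TFR_BASE_2010, 2020: TFR_MEDIUM_2020,
                        2050: 0.75 * medium_2050})
    raise ValueError(f"unknown fertility level {level!r}")


def build_le_path(
    level: str,
    base_le_by_province: np.ndarray,
    base_national_le: np.ndarray | float,
) -> dict[int, np.ndarray]:
    """Life-expectancy trajectories per province × sex.

    Each province's LE grows linearly at (decadal base rate / 10) ×
    (provincial base LE / national base LE) years per year — the initial
    provincial-to-national ratio.  When the national value is a
    population-weighted mean dominated by high-LE provinces, the unweighted
    provincial mean gain falls slightly below the nominal base rate (the
    inverse-ratio convention cannot produce that: by Jensen's inequality its
    mean gain always meets or exceeds the base rate).
    ``base_le_by_province`` has shape (P, 2) (male, female);
    ``base_national_le`` is scalar or per-sex.
    """
    base = np.asarray(base_le_by_province, dtype=float)
    if np.any(base <= 0):
        raise ValueError("base life expectancies must be positive")
    try:
        rate = LE_DECADAL_RATE[level]
    except KeyError:
        raise ValueError(f"unknown mortality level {level!r}") from None
    national = np.asarray(base_national_le, dtype=float)
    increment = (rate / 10.0) * (base / national)  # (P, 2) years/year
    return {y: base + increment * (y - BASE_YEAR) for y in YEARS}


#: Table of provincial migration anchors: (income category, level) ->
#: anchor dict year -> scaling of the base-year NetPIM.  Paths are linear
#: between anchors and constant after the last.
_MIGRATION_ANCHORS: dict[tuple[str, str], dict[int, float]] = {
    # high-income provinces phase migration out (population ceilings)
    ("high", "high"): {BASE_YEAR: 0.0},
    ("high", "medium"): {BASE_YEAR: 1.0, 2020: 0.0},
    ("high", "low"): {BASE_YEAR: 1.0, 2030: 0.0},
    # medium-income provinces decline gradually
    ("medium", "high"): {BASE_YEAR: 1.0, 2100: 0.5},
    ("medium", "medium"): {BASE_YEAR: 1.0, 2050: 0.5, 2100: 0.0},
    ("medium", "low"): {BASE_YEAR: 1.0, 2030: 0.5, 2100: 0.0},
    # low-income provinces: attraction policies under high migration
    ("low", "high"): {BASE_YEAR: 1.0, 2050: 1.5},
    ("low", "medium"): {BASE_YEAR: 1.0},
    ("low", "low"): {BASE_YEAR: 1.0, 2050: 0.5},
}


def build_provincial_migration_path(
    income_category: str, level: str
) -> dict[int, float]:
    """Year -> scaling applied to the base-year NetPIM for one province."""
    try:
        anchors = _MIGRATION_ANCHORS[(income_category, level)]
    except KeyError:
        raise ValueError(
            f"unknown income category/level ({income_category!r}, {level!r})"
        ) from None
    return _interp(anchors)


def build_international_migration_path(level: str) -> dict[int, float]:
    """Year -> national net international migration rate in per-mille.

    Medium: constant at the 2010 value through 2050, then linear to 0 in
    2100.  High/low: 50% larger/smaller in magnitude throughout.
    """
    factor = {"medium": 1.0, "high": 1.5, "low": 0.5}.get(level)
    if factor is None:
        raise ValueError(f"unknown migration level {level!r}")
    base = _interp({BASE_YEAR: NETGIM_2010_PERMILLE, 2050: NETGIM_2010_PERMILLE,
                    2100: 0.0})
    return {y: v * factor for y, v in base.items()}


def build_srb_path(base_srb_by_province: np.ndarray) -> dict[int, np.ndarray]:
    """Sex ratio at birth per province: linear from the base value to the
    national-plan target of 1.07 in 2050, constant after."""
    base = np.asarray(base_srb_by_province, dtype=float)
    if np.any(base <= 0):
        raise ValueError("base sex ratios must be positive")
    out: dict[int, np.ndarray] = {}
    for y in YEARS:
        if y >= SRB_TARGET_YEAR:
            out[y] = np.full_like(base, SRB_TARGET)
        else:
            frac = (y - BASE_YEAR) / (SRB_TARGET_YEAR - BASE_YEAR)
            out[y] = base + (SRB_TARGET - base) * frac
    return out


def build_education_path(
    level: str,
    base_pr: np.ndarray,
    historical_growth: np.ndarray,
    income_category: list[str] | None = None,
) -> dict[int, np.ndarray]:
    """Progression-rate trajectories per province × sex × transition.

    medium: each rate compounds at its province-specific historical annual
    growth rate; low: frozen at the base-year value; high: every province
    compounds at the largest cross-province growth rate (per sex ×
    transition); income_dependent: provinces get the high/medium/low path
    according to their income category.  All paths are clipped below at 0
    and capped at the per-transition maxima, where they remain.

    ``base_pr`` and ``historical_growth`` have shape (P, 2, n_transitions);
    growth is an annual proportional rate (0.01 = +1%/yr).
    """
    base = np.asarray(base_pr, dtype=float)
    growth = np.asarray(historical_growth, dtype=float)
    if np.any((base < 0) | (base > 1)):
        raise ValueError("base progression rates must lie in [0, 1]")

    if level == "income_dependent":
        if income_category is None:
            raise ValueError("income_dependent education needs income categories")
        paths = {
            lvl: build_education_path(lvl, base, growth)
            for lvl in ("low", "medium", "high")
        }
        out = {}
        for y in YEARS:
            arr = np.empty_like(base)
            for i, cat in enumerate(income_category):
                arr[i] = paths[SSP4_EDUCATION_BY_INCOME[cat]][y][i]
            out[y] = arr
        return out

    if level == "low":
        g = np.zeros_like(growth)
    elif level == "medium":
        g = growth
    elif level == "high":
        g = np.broadcast_to(growth.max(axis=0), growth.shape)
    else:
        raise ValueError(f"unknown education level {level!r}")

    caps = np.minimum(PR_CAPS[None, None, :], 1.0)
    out = {}
    for y in YEARS:
        pr = base * (1.0 + g) ** (y - BASE_YEAR)
        out[y] = np.clip(pr, 0.0, caps)
    return out


@dataclass
class ScenarioSpec:
    """Assembled assumption trajectories for one SSP.

    All paths are total on 2010-2100.  ``netpim_path`` maps year to a (P,)
    scaling of the base-year provincial migration rates; ``netgim_path`` is
    in per-mille; ``le_path`` and ``pr_path`` map year to (P, 2[, T]) arrays.
    """

    ssp_id: str
    fertility_level: str
    mortality_level: str
    migration_level: str
    education_level: str
    tfr_path: dict[int, float]
    le_path: dict[int, np.ndarray]
    netpim_path: dict[int, np.ndarray]
    netgim_path: dict[int, float]
    srb_path: dict[int, np.ndarray]
    pr_path: dict[int, np.ndarray]

    def validate(self) -> None:
        for name in ("tfr_path", "le_path", "netpim_path", "netgim_path",
                     "srb_path", "pr_path"):
            path = getattr(self, name)
            missing = [y for y in YEARS if y not in path]
            if missing:
                raise ValueError(f"{name} missing years {missing[:3]}...")
            for y in YEARS:
                if np.any(~np.isfinite(np.asarray(path[y], dtype=float))):
                    raise ValueError(f"{name}[{y}] contains non-finite values")


def assemble_ssp(ssp_id: str, world) -> ScenarioSpec:
    """Build the full assumption set for one SSP against a synthetic world.

    ``world`` provides base demographic quantities: ``income_categories``
    (list of str per province), ``base_le`` (P, 2), ``base_national_le``
    (scalar or per-sex), ``base_srb`` (P,), ``base_pr`` and ``pr_growth``
    (P, 2, n_transitions).
    """
    if ssp_id not in SSP_TABLE:
        raise ValueError(f"unknown SSP id {ssp_id!r}; expected SSP1..SSP5")
    fert, mort, mig, edu = SSP_TABLE[ssp_id]
    cats = list(world.income_categories)
    mig_paths = [build_provincial_migration_path(c, mig) for c in cats]
    return ScenarioSpec(
        ssp_id=ssp_id,
        fertility_level=fert,
        mortality_level=mort,
        migration_level=mig,
        education_level=edu,
        tfr_path=build_tfr_path(fert),
        le_path=build_le_path(mort, world.base_le, world.base_national_le),
        netpim_path={
            y: np.array([p[y] for p in mig_paths]) for y in YEARS
        },
        netgim_path=build_international_migration_path(mig),
        srb_path=build_srb_path(world.base_srb),
        pr_path=build_education_path(
            edu, world.base_pr, world.pr_growth, income_category=cats
        ),
    )
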