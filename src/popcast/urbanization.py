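"""Logistic urbanization-rate projection and urban/rural split.

The urbanization rate of a province is modelled as a logistic (S-shaped)
function of time,

    PU(T) = b / (1 + exp(-c (T - d))),

where b is the saturation level, c the pace and d the inflection time.
The curve is linearized as ln(PU / (b - PU)) = c (T - d) and c, d are
estimated by ordinary least squares.  Under the fast and slow development
assumptions the pace is borrowed from a pool of reference provinces a few
points ahead of (behind) the target on the urbanization transition, with
the curve re-anchored through the target's latest observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

HISTORY_START = 1995
HISTORY_END = 2015
ASSUMPTIONS = ("fast", "medium", "slow")

#: saturation level b by (2015 urbanization band, assumption).  Bands are
#: half-open below 70%: lower bound inclusive, upper exclusive.
_B_TABLE = {
    "high": {"fast": 1.00, "medium": 1.00, "slow": 1.00},   # PU2015 >= 70%
    "mid": {"fast": 0.90, "medium": 0.80, "slow": 0.75},    # 60% <= PU2015 < 70%
    "low": {"fast": 0.85, "medium": 0.80, "slow": 0.70},    # PU2015 < 60%
}

#: default SSP -> urbanization assumption mapping (config-overridable);
#: "mixed" resolves per province by income category.
SSP_URBANIZATION = {
    "SSP1": "fast",
    "SSP2": "medium",
    "SSP3": "slow",
    "SSP4": "mixed",
    "SSP5": "fast",
}


class FitError(ValueError):
    pass


def assign_upper_limit(pu_2015: float, assumption: str) -> float:
    """Saturation level b from the province's 2015 urbanization rate."""
    if not 0.0 < pu_2015 < 1.0:
        raise ValueError(f"PU2015 must lie in (0, 1), got {pu_2015}")
    if assumption not in ASSUMPTIONS:
        raise ValueError(f"unknown assumption {assumption!r}")
    if pu_2015 >= 0.70:
        band = "high"
    elif pu_2015 >= 0.60:
        band = "mid"
    else:
        band = "low"
    return _B_TABLE[band][assumption]


def select_reference_provinces(
    target: str,
    all_series: dict[str, np.ndarray],
    assumption: str,
) -> list[str]:
    """Reference pool for the fast/slow fit of one target province.

    fast: provinces whose 2015 level lies in (PU2015, PU2015 + 5pp),
    excluding those whose 1995-2015 increase is smaller than the target's.
    slow: the mirror band (PU2015 − 5pp, PU2015), excluding larger increases.
    """
    if assumption == "medium":
        return []
    pu = all_series[target]
    pu_2015, delta = pu[-1], pu[-1] - pu[0]
    out = []
    for name, series in all_series.items():
        if name == target:
            continue
        r_2015 = series[-1]
        dr = series[-1] - series[0]
        if assumption == "fast":
            if pu_2015 < r_2015 < pu_2015 + 0.05 and not dr < delta:
                out.append(name)
        elif assumption == "slow":
            if pu_2015 - 0.05 < r_2015 < pu_2015 and not dr > delta:
                out.append(name)
        else:
            raise ValueError(f"unknown assumption {assumption!r}")
    return out


@dataclass
class SigmoidFit:
    """Fitted logistic urbanization curve.

    Time is measured in years since ``base_year``.  ``source`` records
    whether c came from the province's own history or a reference pool.
    """

    b: float
    c: float
    d: float
    base_year: int = HISTORY_START
    source: str = "own-history"
    r_squared: float = float("nan")
    stderr_c: float = float("nan")
    n_obs: int = 0
    reference_provinces: tuple[str, ...] = ()

    def predict(self, years: np.ndarray | int) -> np.ndarray:
        t = np.asarray(years, dtype=float) - self.base_year
        return self.b / (1.0 + np.exp(-self.c * (t - self.d)))

    # sklearn-style accessors so the fitter composes with generic tooling
    def get_params(self) -> dict:
        return {"b": self.b, "c": self.c, "d": self.d, "base_year": self.base_year}


def fit_sigmoid(
    series: np.ndarray,
    b: float,
    years: np.ndarray | None = None,
    base_year: int = HISTORY_START,
) -> SigmoidFit:
    """Estimate (c, d) of the logistic curve by OLS on the logit transform.

    ``series`` are observed urbanization rates, strictly inside (0, b);
    ``years`` defaults to consecutive calendar years starting at
    ``base_year``.  Raises :class:`FitError` when an observation reaches b
    (a larger b is needed); warns via the returned fit when the estimated
    pace is non-positive.
    """
    pu = np.asarray(series, dtype=float)
    if years is None:
        years = np.arange(base_year, base_year + pu.size)
    t = np.asarray(years, dtype=float) - base_year
    if np.any(pu <= 0) or np.any(pu >= b):
        raise FitError(
            f"series must lie strictly in (0, b={b}); "
            "choose a larger upper limit b"
        )
    y = np.log(pu / (b - pu))
    if pu.size == 2:
        c = (y[1] - y[0]) / (t[1] - t[0])
        intercept = y[0] - c * t[0]
        r2, se = 1.0, 0.0
    else:
        res = stats.linregress(t, y)
        c, intercept = res.slope, res.intercept
        r2, se = res.rvalue ** 2, res.stderr
    if c <= 0:
        raise FitError("estimated pace c <= 0: declining urbanization is "
                       "outside the logistic model")
    return SigmoidFit(
        b=b, c=float(c), d=float(-intercept / c), base_year=base_year,
        r_squared=float(r2), stderr_c=float(se), n_obs=int(pu.size),
    )


def _anchored_fit(
    b: float, c: float, anchor_year: int, anchor_pu: float,
    base_year: int = HISTORY_START,
) -> float:
    """Inflection d such that the curve passes through (anchor_year, anchor_pu)."""
    y = np.log(anchor_pu / (b - anchor_pu))
    return (anchor_year - base_year) - y / c


def project_urbanization(
    province: str,
    assumption: str,
    histories: dict[str, np.ndarray],
    start: int = 2010,
    end: int = 2100,
) -> tuple[dict[int, float], SigmoidFit]:
    """Urbanization-rate path 2010-2100 for one province.

    medium: fit c and d on the province's own 1995-2015 history with its
    banded saturation level.  fast/slow: pool the logit-transformed series
    of the reference provinces (using the TARGET's b) into one OLS for c,
    then re-anchor d so the curve passes through the target's 2015
    observation.  An empty reference pool falls back to the own-history fit.
    """
    pu = np.asarray(histories[province], dtype=float)
    pu_2015 = float(pu[-1])
    b = assign_upper_limit(pu_2015, assumption)
    b_eff = max(b, pu_2015 + 1e-6)  # history may already sit above the band cap

    if assumption == "medium":
        fit = fit_sigmoid(pu, b_eff)
    else:
        refs = select_reference_provinces(province, histories, assumption)
        if not refs:
            fit = fit_sigmoid(pu, b_eff)
            fit.source = "own-history-fallback"
        else:
            ts, ys = [], []
            for name in refs:
                series = np.asarray(histories[name], dtype=float)
                t = np.arange(series.size, dtype=float)
                ok = (series > 0) & (series < b_eff)
                ts.append(t[ok])
                ys.append(np.log(series[ok] / (b_eff - series[ok])))
            t_all = np.concatenate(ts)
            y_all = np.concatenate(ys)
            res = stats.linregress(t_all, y_all)
            if res.slope <= 0:
                raise FitError("pooled pace c <= 0")
            d = _anchored_fit(b_eff, res.slope, HISTORY_END, pu_2015)
            fit = SigmoidFit(
                b=b_eff, c=float(res.slope), d=float(d),
                source="reference-pool", r_squared=float(res.rvalue ** 2),
                stderr_c=float(res.stderr), n_obs=int(t_all.size),
                reference_provinces=tuple(refs),
            )
    years = np.arange(start, end + 1)
    path = dict(zip(years.tolist(), fit.predict(years).tolist()))
    return path, fit


def resolve_assumption(ssp_id: str, income_category: str) -> str:
    """Urbanization assumption for one province under one SSP."""
    a = SSP_URBANIZATION[ssp_id]
    if a != "mixed":
        return a
    return "fast" if income_category == "high" else "slow"


def split_urban_rural(
    totals: dict[int, np.ndarray],
    pu_paths: list[dict[int, float]],
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Split provincial totals into urban and rural populations.

    urban = total × PU; rural = total − urban, so urban + rural reproduces
    the total exactly.  ``totals`` maps year -> (P,) totals; ``pu_paths``
    is one PU path per province.
    """
    urban, rural = {}, {}
    for year, tot in totals.items():
        pu = np.array([pu_paths[i][year] for i in range(len(pu_paths))])
        if np.any((pu < 0) | (pu > 1)):
            raise ValueError("urbanization rates must lie in [0, 1]")
        u = tot * pu
        urban[year] = u
        rural[year] = tot - u
    return urban, rural
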