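"""Recursive multi-state cohort-component projection engine.

Each projected year applies, in order: fertility (births from the previous
year's female population at current-year rates), then for every surviving
cohort survival, provincial migration, education progression, and national
(international) migration.  Newborns enter at age 0 in the illiterate stage
and are not exposed to migration in their birth year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
from scipy.optimize import brentq

from .state import (
    N_AGE,
    N_EDU,
    N_SEX,
    TRANSITIONS,
    CalibrationError,
    PopulationState,
    RateSet,
    implied_tfr,
)

logger = logging.getLogger(__name__)

#: remaining life expectancy assigned to the open age interval when the
#: terminal mortality rate is zero
OPEN_INTERVAL_CAP = 10.0


def life_expectancy(mortality_schedule: np.ndarray) -> float:
    """Period life expectancy at birth for one mortality schedule.

    Parameters
    ----------
    mortality_schedule
        Length-101 array; entries 0..99 are annual death probabilities q_x,
        entry 100 is the central death rate m of the open "100+" interval.

    Notes
    -----
    Standard period life table with a_x = 0.5 for ages 0-99.  The open
    interval contributes l_100 / m_100 person-years; when m_100 = 0 each
    survivor is credited ``OPEN_INTERVAL_CAP`` remaining years instead.
    """
    q = np.asarray(mortality_schedule, dtype=float)
    if q.shape != (N_AGE,):
        raise ValueError(f"schedule must have length {N_AGE}")
    if np.any((q < 0) | (q > 1)):
        raise ValueError("mortality values must lie in [0, 1]")
    surv = np.concatenate(([1.0], np.cumprod(1.0 - q[:100])))  # l_0..l_100
    lx = surv[:100]
    lx1 = surv[1:101]
    person_years = 0.5 * (lx + lx1)  # L_x with a_x = 0.5
    m_open = q[100]
    e_open = (1.0 / m_open) if m_open > 0 else OPEN_INTERVAL_CAP
    return float(person_years.sum() + surv[100] * e_open)


def calibrate_fertility(
    fer_base: np.ndarray,
    tfr_target: float,
    female_state: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Scale a base fertility matrix so its implied national TFR hits a target.

    Returns the scaled matrix and the scalar applied.  Scaling is a single
    multiplier so the age/education/province profile of the base matrix is
    preserved exactly.
    """
    if tfr_target <= 0:
        raise ValueError("TFR target must be positive")
    base = implied_tfr(fer_base, female_state)
    if base <= 0:
        raise CalibrationError("base fertility matrix has zero implied TFR")
    s = tfr_target / base
    return fer_base * s, s


def calibrate_mortality(
    mor_base: np.ndarray,
    le_target: float,
    bracket: tuple[float, float] = (0.0, 10.0),
    tol: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Find k so that ``life_expectancy(clip(k * mor_base, 0, 1))`` = target.

    Life expectancy is strictly decreasing in k wherever any rate is
    unclipped, so bisection on the bracket is safe.  Raises
    :class:`CalibrationError` naming the achievable range when the target
    lies outside it.
    """
    mor_base = np.asarray(mor_base, dtype=float)

    def le_at(k: float) -> float:
        return life_expectancy(np.clip(k * mor_base, 0.0, 1.0))

    lo_k, hi_k = bracket
    le_hi = le_at(lo_k)   # lighter mortality -> higher LE
    le_lo = le_at(hi_k)
    if not (le_lo - tol <= le_target <= le_hi + tol):
        raise CalibrationError(
            f"LE target {le_target:.4f} outside achievable range "
            f"[{le_lo:.4f}, {le_hi:.4f}] for scales in {bracket}"
        )
    if abs(le_at(1.0) - le_target) <= tol:
        return np.clip(mor_base, 0.0, 1.0), 1.0
    k = brentq(lambda k: le_at(k) - le_target, lo_k, hi_k, xtol=1e-12)
    return np.clip(k * mor_base, 0.0, 1.0), float(k)


def compute_births(
    female_state_prev: np.ndarray,
    fer: np.ndarray,
    bm: np.ndarray,
    bf: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Newborn males and females per province.

    ``female_state_prev`` is the previous year's female counts (P, 101, 7);
    ``fer`` the current-year fertility (P, 101, 7).  Newborns are assigned
    age 0, illiterate stage, by the caller.
    """
    births = (female_state_prev * fer).sum(axis=(1, 2))
    return births * bm, births * bf


def age_and_educate(state_prev: PopulationState, rates: RateSet) -> PopulationState:
    """Advance every cohort one year of age with survival, migration and
    education progression.

    Per cell the surviving stream is scaled by (1 − MOR)(1 + NetPIM), split
    between staying in stage (1 − ΣG_out) and advancing along each outgoing
    transition (G each), and finally scaled by (1 + NetGIM).  The "100+"
    group receives survivors of both age 99 and of "100+" itself.  Age 0 is
    left empty (births are added separately).
    """
    p = state_prev.n_provinces
    counts = state_prev.counts
    mor = rates.mor[:, :, :, None]               # (P,2,101,1)
    netpim = rates.netpim_full()
    survived = counts * (1.0 - mor) * (1.0 + netpim)  # (P,2,101,7)

    # outgoing-transition probability per (sex, age, edu) cell: each
    # transition fires only for the cohort arriving at its entry age, i.e.
    # for source age entry_age - 1.
    g_out = np.zeros((p, N_SEX, N_AGE, N_EDU))
    moved = np.zeros((p, N_SEX, N_AGE, N_EDU))  # inflow at source-age index
    for t, (src, dst, entry) in enumerate(TRANSITIONS):
        g_t = rates.g[:, :, t]                  # (P,2)
        g_out[:, :, entry - 1, src] += g_t
        moved[:, :, entry - 1, dst] += survived[:, :, entry - 1, src] * g_t

    after_edu = survived * (1.0 - g_out) + moved
    after_edu *= 1.0 + rates.netgim

    new_counts = np.zeros_like(counts)
    new_counts[:, :, 1:100, :] = after_edu[:, :, 0:99, :]
    new_counts[:, :, 100, :] = after_edu[:, :, 99, :] + after_edu[:, :, 100, :]

    neg = new_counts < 0
    if np.any(neg):
        logger.warning("clamping %d negative cells to zero", int(neg.sum()))
        new_counts[neg] = 0.0
    return PopulationState(new_counts, state_prev.year + 1, state_prev.provinces)


def rebalance_migration(
    netpim: np.ndarray,
    state: PopulationState,
) -> tuple[np.ndarray, float]:
    """Scale down the heavier side of provincial migration so implied
    person-flows sum to zero across provinces.

    Flows are rate × at-risk population per province.  Whichever side
    (total inflow or total outflow) is larger is multiplied by the ratio
    smaller/larger; relative proportions within that side are preserved.
    Returns the adjusted rates and the factor applied (1.0 if balanced).
    """
    p = state.n_provinces
    full = np.broadcast_to(netpim, (p, N_SEX, N_AGE, N_EDU))
    flows = (full * state.counts).sum(axis=(1, 2, 3))
    inflow = flows[flows > 0].sum()
    outflow = -flows[flows < 0].sum()
    if (inflow == 0 and outflow == 0) or inflow == outflow:
        return np.asarray(netpim, dtype=float).copy(), 1.0
    adjusted = np.array(netpim, dtype=float, copy=True)
    prov_axis_rates = np.broadcast_to(adjusted, (p, N_SEX, N_AGE, N_EDU)).copy()
    if inflow > outflow:
        factor = outflow / inflow
        scale_mask = flows > 0
    else:
        factor = inflow / outflow
        scale_mask = flows < 0
    prov_axis_rates[scale_mask] *= factor
    return prov_axis_rates, float(factor)


@dataclass
class YearLog:
    """Calibration audit record for one projected year."""

    year: int
    fertility_scale: float
    mortality_scales: np.ndarray  # (P, 2)
    migration_factor: float


def project(
    state_2010: PopulationState,
    scenario,
    rates_base: RateSet,
    end_year: int = 2100,
) -> tuple[list[PopulationState], list[YearLog]]:
    """Run the recursive projection from the base year to ``end_year``.

    ``scenario`` is a :class:`~popcast.scenarios.ScenarioSpec`; for each year
    the base rate matrices are re-calibrated to the scenario's TFR and LE
    targets, provincial migration is scaled along the scenario path and
    rebalanced to zero net internal flow, progression rates and the sex
    ratio at birth follow their paths, and the state is advanced via the
    birth and cohort-iteration rules.
    """
    states = [state_2010.copy()]
    logs: list[YearLog] = []
    p = state_2010.n_provinces

    for year in range(state_2010.year + 1, end_year + 1):
        prev = states[-1]
        try:
            fer, f_scale = calibrate_fertility(
                rates_base.fer, scenario.tfr_path[year], prev.females()
            )
            mor = np.empty_like(rates_base.mor)
            m_scales = np.empty((p, N_SEX))
            for i in range(p):
                for s in range(N_SEX):
                    target = scenario.le_path[year][i, s]
                    mor[i, s], m_scales[i, s] = calibrate_mortality(
                        rates_base.mor[i, s], target
                    )
        except CalibrationError as err:
            raise CalibrationError(f"year {year}: {err}") from err

        mig_scale = scenario.netpim_path[year]          # (P,)
        netpim = rates_base.netpim * mig_scale[:, None, None, None]
        netpim, mig_factor = rebalance_migration(netpim, prev)

        g = np.clip(scenario.pr_path[year], 0.0, 1.0)   # (P, 2, n_transitions)
        r = scenario.srb_path[year]                     # (P,)
        rates = RateSet(
            fer=fer,
            mor=mor,
            g=g,
            netpim=netpim,
            netgim=scenario.netgim_path[year] / 1000.0,  # per-mille -> rate
            bm=r / (1.0 + r),
            bf=1.0 / (1.0 + r),
        )

        nxt = age_and_educate(prev, rates)
        boys, girls = compute_births(prev.females(), rates.fer, rates.bm, rates.bf)
        nxt.counts[:, 0, 0, 0] = boys
        nxt.counts[:, 1, 0, 0] = girls
        states.append(nxt)
        logs.append(YearLog(year, f_scale, m_scales, mig_factor))
        logger.debug(
            "year %d: fertility scale %.6f, migration factor %.6f",
            year, f_scale, mig_factor,
        )
    return states, logs
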