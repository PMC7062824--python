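"""Core containers for the multi-state population projection.

The population state is a dense array of person counts indexed by
province × sex × single-year age (0..99 plus an open "100+" group) ×
education stage.  Education uses the seven stages of the Chinese census:

====  =================  ==========  ===========
code  stage              entry age   output code
====  =================  ==========  ===========
1     illiterate         —           E0
2     primary school     6           E1
3     junior high        13          E2
4     senior high        16          E3
5     college            19          E4
6     bachelor           19          E5
7     master and above   23          E6
====  =================  ==========  ===========

Internally stages are 0-based array indices (stage code − 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

N_AGE = 101  # ages 0..99 and the open interval "100+"
N_EDU = 7
N_SEX = 2  # 0 = male, 1 = female
SEX_CODES = ("M", "F")
EDU_CODES = tuple(f"E{i}" for i in range(N_EDU))
AGE_LABELS = tuple(str(a) for a in range(100)) + ("100+",)

#: fertile age window (inclusive) used for the TFR summation
FERTILE_AGES = (15, 49)

#: education transitions as (source stage index, destination stage index,
#: entry age of the destination stage).  Senior high feeds both college and
#: bachelor; bachelor feeds master — a stage DAG rather than a linear chain.
TRANSITIONS: tuple[tuple[int, int, int], ...] = (
    (0, 1, 6),    # illiterate -> primary (enrolment)
    (1, 2, 13),   # primary -> junior high
    (2, 3, 16),   # junior -> senior high
    (3, 4, 19),   # senior -> college
    (3, 5, 19),   # senior -> bachelor
    (5, 6, 23),   # bachelor -> master+
)
N_TRANSITIONS = len(TRANSITIONS)
TRANSITION_NAMES = (
    "enrolment",
    "primary_to_junior",
    "junior_to_senior",
    "senior_to_college",
    "senior_to_bachelor",
    "bachelor_to_master",
)

#: stage entry ages keyed by destination stage index (stage 0 has none)
ENTRY_AGES = {dst: age for _, dst, age in TRANSITIONS}


class PopcastError(Exception):
    """Base error for the package."""


class ConfigurationError(PopcastError):
    pass


class CalibrationError(PopcastError):
    pass


class DimensionError(PopcastError):
    pass


def _min_stage_age(edu: int) -> int:
    """Youngest age at which a person can hold education stage ``edu``."""
    return 0 if edu == 0 else ENTRY_AGES[edu]


#: boolean (age, edu) matrix: True where the age/education combination is
#: attainable given the stage entry ages.
AGE_EDU_FEASIBLE = np.zeros((N_AGE, N_EDU), dtype=bool)
for _e in range(N_EDU):
    AGE_EDU_FEASIBLE[_min_stage_age(_e):, _e] = True


@dataclass
class PopulationState:
    """Person counts for one calendar year.

    Parameters
    ----------
    counts
        Array of shape (n_provinces, 2, 101, 7); non-negative person counts.
    year
        Calendar year the counts refer to.
    provinces
        Province names, length ``n_provinces``.
    """

    counts: np.ndarray
    year: int
    provinces: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.provinces = tuple(self.provinces)
        expected = (len(self.provinces), N_SEX, N_AGE, N_EDU)
        if self.counts.shape != expected:
            raise DimensionError(
                f"counts shape {self.counts.shape} != expected {expected}"
            )
        if np.any(self.counts < 0):
            raise ValueError("population counts must be non-negative")

    @property
    def n_provinces(self) -> int:
        return len(self.provinces)

    def total(self) -> float:
        return float(self.counts.sum())

    def totals_by_province(self) -> np.ndarray:
        return self.counts.sum(axis=(1, 2, 3))

    def females(self) -> np.ndarray:
        """Female counts, shape (n_provinces, 101, 7)."""
        return self.counts[:, 1]

    def copy(self) -> "PopulationState":
        return replace(self, counts=self.counts.copy())


def validate_fertility(fer: np.ndarray) -> None:
    """fer: (P, 101, 7) births/woman-year, zero outside ages 15-49."""
    if np.any(fer < 0):
        raise ValueError("fertility rates must be non-negative")
    lo, hi = FERTILE_AGES
    outside = np.ones(N_AGE, dtype=bool)
    outside[lo:hi + 1] = False
    if np.any(fer[:, outside, :] != 0):
        raise ValueError("fertility must be zero outside ages 15-49")


def validate_mortality(mor: np.ndarray) -> None:
    if np.any((mor < 0) | (mor > 1)):
        raise ValueError("mortality probabilities must lie in [0, 1]")


def validate_progression(g: np.ndarray) -> None:
    if np.any((g < 0) | (g > 1)):
        raise ValueError("progression rates must lie in [0, 1]")
    # joint outflow from senior high (college + bachelor branches) <= 1
    joint = g[..., 3] + g[..., 4]
    if np.any(joint > 1 + 1e-12):
        raise ValueError("senior-high outflow probabilities exceed 1")


@dataclass
class RateSet:
    """Demographic rates for one projection year.

    Attributes
    ----------
    fer
        Fertility, shape (P, 101, 7); births per woman-year, nonzero only for
        ages 15-49.
    mor
        Mortality probability per year, shape (P, 2, 101); applies across
        education stages.
    g
        Education progression probabilities, shape (P, 2, n_transitions),
        in transition order ``TRANSITION_NAMES``.  Each transition fires for
        the cohort that reaches its destination-stage entry age.
    netpim
        Net provincial in-migration rate per year; any shape broadcastable
        to (P, 2, 101, 7).  Must exceed −1.
    netgim
        National net international migration rate per year (scalar, as a
        plain rate, not per-mille).
    bm, bf
        Newborn sex fractions per province, shape (P,); bm + bf = 1.
    """

    fer: np.ndarray
    mor: np.ndarray
    g: np.ndarray
    netpim: np.ndarray
    netgim: float
    bm: np.ndarray
    bf: np.ndarray

    def __post_init__(self) -> None:
        self.fer = np.asarray(self.fer, dtype=float)
        self.mor = np.asarray(self.mor, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.netpim = np.asarray(self.netpim, dtype=float)
        self.bm = np.atleast_1d(np.asarray(self.bm, dtype=float))
        self.bf = np.atleast_1d(np.asarray(self.bf, dtype=float))
        p = self.fer.shape[0]
        if self.fer.shape != (p, N_AGE, N_EDU):
            raise DimensionError(f"fer shape {self.fer.shape}")
        if self.mor.shape != (p, N_SEX, N_AGE):
            raise DimensionError(f"mor shape {self.mor.shape}")
        if self.g.shape != (p, N_SEX, N_TRANSITIONS):
            raise DimensionError(f"g shape {self.g.shape}")
        validate_fertility(self.fer)
        validate_mortality(self.mor)
        validate_progression(self.g)
        if np.any(self.netpim <= -1):
            raise ValueError("NetPIM rates must exceed -1")
        if not np.allclose(self.bm + self.bf, 1.0, atol=1e-12):
            raise ValueError("Bm + Bf must equal 1")
        np.broadcast_to(self.netpim, (p, N_SEX, N_AGE, N_EDU))  # raises if not

    @property
    def n_provinces(self) -> int:
        return self.fer.shape[0]

    def netpim_full(self) -> np.ndarray:
        """NetPIM broadcast to the full (P, 2, 101, 7) index."""
        p = self.n_provinces
        return np.broadcast_to(self.netpim, (p, N_SEX, N_AGE, N_EDU))

    def copy(self) -> "RateSet":
        return RateSet(
            fer=self.fer.copy(), mor=self.mor.copy(), g=self.g.copy(),
            netpim=self.netpim.copy(), netgim=self.netgim,
            bm=self.bm.copy(), bf=self.bf.copy(),
        )


def implied_tfr(fer: np.ndarray, female_counts: np.ndarray) -> float:
    """National TFR implied by a fertility matrix and female population.

    For each single-year age the age-specific rate is the female-population
    weighted mean of ``fer`` across provinces and education stages; the TFR
    is the sum of these over ages 15-49.  Ages with no women fall back to the
    unweighted mean so an empty cohort cannot zero out the schedule.
    """
    fer = np.asarray(fer, dtype=float)
    w = np.asarray(female_counts, dtype=float)
    lo, hi = FERTILE_AGES
    tfr = 0.0
    for a in range(lo, hi + 1):
        wa = w[:, a, :]
        tot = wa.sum()
        if tot > 0:
            tfr += float((fer[:, a, :] * wa).sum() / tot)
        else:
            tfr += float(fer[:, a, :].mean())
    return tfr


def implied_tfr_by_province(fer: np.ndarray, female_counts: np.ndarray) -> np.ndarray:
    """Per-province TFR with each province's own female weighting."""
    p = fer.shape[0]
    return np.array([
        implied_tfr(fer[i:i + 1], female_counts[i:i + 1]) for i in range(p)
    ])
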