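"""Entity generation: waiting-list patients, CRLM candidates, and donor livers.

The national program is represented by two patient groups.  "Status Quo"
patients are those currently eligible for listing, stratified over the six
most frequent indications (HCC, PBC, PSC, ALF, AC and a pooled "Others"
class).  CRLM patients (nonresectable colorectal liver-only metastases) are
the candidate expansion group; under strategy 1 they receive palliative
chemotherapy off-list, under strategy 2 they join the list and follow the
same transplantation pathway as everyone else.

Arrivals of patients and donor livers are Poisson processes, i.e.
exponentially distributed interarrival times with means estimated from
national registry throughput (3.55 days between listings, 3.18 days between
livers, about 103 listings and 115 livers per year).  Each arriving entity
draws its categorical attributes from recorded uniforms so that the exact
same population can be replayed across scenarios (common random numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

from .errors import InputError, LogicError, ParameterError

BLOOD_TYPES = ("A", "B", "AB", "0")
DIAGNOSES = ("HCC", "PBC", "PSC", "ALF", "AC", "Others")

#: share of first listings per indication; "Others" is the complement of the
#: five named indications (100 - 56.8 = 43.2%).
DEFAULT_DIAGNOSIS_MIX = {
    "HCC": 0.137,
    "PBC": 0.067,
    "PSC": 0.180,
    "ALF": 0.083,
    "AC": 0.101,
    "Others": 0.432,
}

#: blood-type distribution of the Norwegian population.
DEFAULT_PATIENT_BLOOD_MIX = {"A": 0.49, "B": 0.08, "AB": 0.04, "0": 0.39}

#: blood-type mix of arriving donor livers.  Starts from the population mix
#: but is calibrated (see calibration.calibrate_liver_blood_mix) so that the
#: simulated blood-type-specific median waits reproduce the national ones;
#: under identical-type matching the adjustment absorbs the compatibility
#: releases that happen in practice.
DEFAULT_LIVER_BLOOD_MIX = {"A": 0.4775, "B": 0.08, "AB": 0.0075, "0": 0.435}

#: median age at listing per indication (years); ages are static attributes,
#: waits are weeks to months so on-list ageing is negligible.
AGE_AT_LISTING = {
    "HCC": 61.0,
    "PBC": 57.0,
    "PSC": 43.0,
    "ALF": 43.0,
    "AC": 57.0,
    "Others": 57.0,
    "CRLM": 57.0,
}

DAYS_PER_YEAR = 365.25


def next_arrival(interarrival_mean: float, u: float) -> float:
    """Days until the next Poisson arrival, by inverse transform."""
    if interarrival_mean <= 0:
        raise ParameterError("interarrival mean must be positive")
    if not 0.0 <= u < 1.0:
        raise ParameterError(f"uniform draw must be in [0, 1), got {u}")
    return -interarrival_mean * math.log1p(-u)


def _assign_categorical(u: float, probs: Sequence[float], labels: Sequence[str]) -> str:
    if abs(sum(probs) - 1.0) > 1e-9:
        raise InputError(f"category probabilities must sum to 1, got {sum(probs)}")
    cum = 0.0
    for p, lab in zip(probs, labels):
        cum += p
        if u < cum:
            return lab
    return labels[-1]


def assign_diagnosis(u: float, mix: Optional[dict] = None) -> str:
    """Categorical diagnosis draw in the fixed order HCC, PBC, PSC, ALF, AC,
    Others."""
    mix = DEFAULT_DIAGNOSIS_MIX if mix is None else mix
    return _assign_categorical(u, [mix[d] for d in DIAGNOSES], DIAGNOSES)


def assign_blood_type(u: float, mix: Optional[dict] = None) -> str:
    """Categorical blood-type draw in the fixed order A, B, AB, 0."""
    mix = DEFAULT_PATIENT_BLOOD_MIX if mix is None else mix
    return _assign_categorical(u, [mix[b] for b in BLOOD_TYPES], BLOOD_TYPES)


@dataclass
class Patient:
    group: str                      # "StatusQuo" | "CRLM"
    diagnosis: str                  # one of DIAGNOSES or "CRLM"
    blood_type: str
    age_at_listing: float
    listing_time: float             # days, simulation clock
    priority: bool
    tracked: bool
    draws: tuple                    # pre-drawn uniforms, see engine._DRAWS
    # mutable waiting-list state
    spell: int = 0                  # 1 = first listing, 2 = retransplant listing
    spell_start: float = 0.0
    on_list: bool = False
    pid: int = -1                   # per-replication patient id (exit log)

    def __post_init__(self):
        if self.blood_type not in BLOOD_TYPES:
            raise InputError(f"unknown blood type {self.blood_type!r}")


@dataclass(frozen=True)
class Liver:
    blood_type: str
    arrival_time: float


@dataclass
class ScenarioConfig:
    """Everything that defines one policy scenario.

    ``strategy`` 1 keeps CRLM patients off-list (palliative chemotherapy);
    strategy 2 lists them.  ``crlm_per_year`` sets the CRLM arrival rate in
    both strategies — under strategy 1 the cohort is simulated in parallel,
    off the queue, so matched (common-random-numbers) comparisons are
    possible.  ``criteria`` selects which trial-based post-transplant
    survival stratum CRLM transplant recipients draw from.
    """

    strategy: int = 1
    crlm_per_year: float = 0.0
    criteria: str = "SECA2"
    patient_interarrival_days: float = 3.55
    liver_interarrival_days: float = 3.18
    registry: Optional[object] = None        # SurvivalRegistry; default built lazily
    life_table: Optional[object] = None      # LifeTable; default built lazily
    diagnosis_mix: dict = field(default_factory=lambda: dict(DEFAULT_DIAGNOSIS_MIX))
    patient_blood_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_PATIENT_BLOOD_MIX))
    liver_blood_mix: dict = field(
        default_factory=lambda: dict(DEFAULT_LIVER_BLOOD_MIX))
    p_relist: float = 0.134          # listed for retransplantation
    p_qualify: float = 0.749         # receive retransplant given listed
    withdrawal_annual: float = 0.06  # withdrawal probability (see withdrawal_mode)
    #: "fraction": 6% of listings withdraw, at an exponentially distributed
    #: time (mean withdrawal_time_mean_days) independent of queue state —
    #: reproduces the registry's observed withdrawal count, which is a
    #: fixed share of listings rather than of waiting time.
    #: "hazard": a 6%/year exponential withdrawal hazard while listed.
    withdrawal_mode: str = "fraction"
    withdrawal_time_mean_days: float = 30.0
    abo_rule: str = "compatible"     # or "identical"
    switch_years: float = 10.0       # post-transplant switch to background mortality

    def __post_init__(self):
        if self.strategy not in (1, 2):
            raise InputError("strategy must be 1 or 2")
        if self.crlm_per_year < 0:
            raise InputError("crlm_per_year must be non-negative")
        if self.criteria not in ("SECA1", "SECA2"):
            raise InputError("criteria must be 'SECA1' or 'SECA2'")
        if self.patient_interarrival_days <= 0 or self.liver_interarrival_days <= 0:
            raise InputError("interarrival means must be positive")
        if self.abo_rule not in ("identical", "compatible"):
            raise InputError("abo_rule must be 'identical' or 'compatible'")
        if self.withdrawal_mode not in ("fraction", "hazard"):
            raise InputError("withdrawal_mode must be 'fraction' or 'hazard'")

    @property
    def crlm_interarrival_days(self) -> float:
        if self.crlm_per_year <= 0:
            return math.inf
        return 365.0 / self.crlm_per_year

    @property
    def withdrawal_rate_per_day(self) -> float:
        """Daily hazard matching the stated annual withdrawal probability."""
        return -math.log1p(-self.withdrawal_annual) / 365.0

    def resolved(self) -> "ScenarioConfig":
        """Return a copy with default registry and life table filled in."""
        if self.registry is not None and self.life_table is not None:
            return self
        from .calibration import default_life_table, default_registry

        lt = self.life_table or default_life_table()
        reg = self.registry or default_registry(life_table=lt)
        return replace(self, registry=reg, life_table=lt)

    def with_livers_per_year(self, n: float) -> "ScenarioConfig":
        """Liver-availability scenarios are stated as annual totals; rescale
        the interarrival mean accordingly."""
        if n <= 0:
            raise InputError("livers per year must be positive")
        return replace(self, liver_interarrival_days=365.0 / n)


def make_patient(group: str, clock: float, scenario: ScenarioConfig,
                 draws: tuple, tracked: bool) -> Patient:
    """Build a patient entity from its pre-drawn uniforms.

    ``draws[0]`` assigns the diagnosis (Status Quo only), ``draws[1]`` the
    blood type; the remaining uniforms drive waiting-list exits and the
    post-transplant pathway and are consumed by the engine.
    """
    if group == "CRLM":
        if scenario.strategy == 1 and scenario.crlm_per_year <= 0:
            raise LogicError("CRLM patient generated with a zero CRLM rate")
        diagnosis = "CRLM"
        priority = False
    elif group == "StatusQuo":
        diagnosis = assign_diagnosis(draws[0], scenario.diagnosis_mix)
        priority = diagnosis == "ALF"
    else:
        raise InputError(f"unknown patient group {group!r}")
    blood = assign_blood_type(draws[1], scenario.patient_blood_mix)
    return Patient(
        group=group,
        diagnosis=diagnosis,
        blood_type=blood,
        age_at_listing=AGE_AT_LISTING[diagnosis],
        listing_time=clock,
        priority=priority,
        tracked=tracked,
        draws=draws,
    )
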