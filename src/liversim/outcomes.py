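"""Life-years accounting, outcome aggregation, and break-even analysis.

Post-transplant survival is drawn from the recipient's diagnosis-specific
stratum (trial-based SECA I / SECA II strata for CRLM recipients).  Beyond
10 years post-transplant the disease-specific curve is replaced by national
age-specific background mortality — long-term recipients are assumed to
carry no excess transplant mortality.  Patients removed from the list
(death, dropout, withdrawal, or failing to qualify for a regraft) accrue
life-years only up to removal; this understates absolute life-years
slightly and symmetrically in both strategies.

Life expectancy is measured from listing time, the only time origin shared
by the transplant and palliative arms.

The policy question is summarised by a net-benefit curve over the number of
CRLM patients listed per year: life-years gained by CRLM patients
(transplant pathway minus their matched palliative counterfactual) against
life-years lost by currently eligible patients through longer waits, both
totalled over the 10-year enrollment cohort.  The break-even point is the
smallest listing rate at which the net crosses zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import ComparisonError, InputError
from .population import BLOOD_TYPES, DAYS_PER_YEAR, ScenarioConfig


def apply_background_switch(death_time_from_transplant: float,
                            age_at_transplant: float, life_table, draw: float,
                            switch_years: float = 10.0) -> float:
    """Replace the disease-specific tail beyond the switch horizon.

    If the sampled post-transplant death time exceeds ``switch_years``, the
    patient instead dies at ``switch_years`` plus a background-mortality
    remaining lifetime sampled at the age they reach the switch.
    """
    if death_time_from_transplant <= switch_years:
        return death_time_from_transplant
    return switch_years + life_table.background_death_time(
        age_at_transplant + switch_years, draw)


def posttransplant_life_years(stratum, age_at_transplant: float, life_table,
                              u_survival: float, u_background: float,
                              switch_years: float = 10.0) -> float:
    """Years from transplant to death for a successful graft."""
    t = stratum.quantile(u_survival)
    return apply_background_switch(t, age_at_transplant, life_table,
                                   u_background, switch_years)


def palliative_life_years(registry, life_table, age: float, u: float,
                          u_background: float,
                          switch_years: float = 10.0) -> float:
    """Years from listing-equivalent time to death under palliative
    chemotherapy (no transplant pathway; the same >10-year background
    switch applies)."""
    stratum = registry.treatment_stratum("palliative")
    t = stratum.quantile(u)
    return apply_background_switch(t, age, life_table, u_background,
                                   switch_years)


# ----------------------------------------------------------------------
# Aggregation
# ----------------------------------------------------------------------

_COUNT_KEYS = {
    "enlisted": ("enlisted_StatusQuo",),
    "enlisted_crlm": ("enlisted_CRLM",),
    "first_transplants": ("first_tx_StatusQuo", "first_tx_CRLM"),
    "first_transplants_sq": ("first_tx_StatusQuo",),
    "retransplants": ("retx",),
    "withdrawals": ("withdrawal_StatusQuo", "withdrawal_CRLM"),
    "deathdrop_sq": ("deathdrop_StatusQuo",),
    "deathdrop_crlm": ("deathdrop_CRLM",),
    "exported": ("exported_window",),
    "livers": ("livers_window",),
}


@dataclass
class ExperimentSummary:
    """Replication-averaged outcomes of one scenario.

    ``median_wait_days`` holds the mean over replications of the per-
    replication median first-transplant wait (overall and per blood type);
    ``wait_range_days`` the min/max individual wait across all
    replications.  ``annual`` holds yearly averages over the enrollment
    window; ``annual_range`` min/max per-replication annual values.
    ``mean_le`` is remaining life expectancy from listing, in years, per
    group; the ``CRLM_SECA1``/``CRLM_SECA2`` entries are matched surfaces
    computed from the same replications, and ``CRLM_palliative`` is the
    matched no-transplant counterfactual of the same CRLM cohort.
    """

    strategy: int
    crlm_per_year: float
    criteria: str
    seed: int
    replications: int
    enrollment_years: float
    median_wait_days: Dict[str, float]
    wait_range_days: Dict[str, tuple]
    annual: Dict[str, float]
    annual_range: Dict[str, tuple]
    mean_le: Dict[str, float]
    enrolled_10y: Dict[str, float]
    mean_spell_wait_days: float = math.nan
    fingerprint: tuple = field(default=())

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "crlm_per_year": self.crlm_per_year,
            "criteria": self.criteria,
            "seed": self.seed,
            "replications": self.replications,
            "median_wait_days": dict(self.median_wait_days),
            "wait_range_days": {k: list(v) for k, v in self.wait_range_days.items()},
            "annual": dict(self.annual),
            "annual_range": {k: list(v) for k, v in self.annual_range.items()},
            "mean_le": dict(self.mean_le),
            "enrolled_10y": dict(self.enrolled_10y),
        }


def summarize(ledgers: Sequence, config, scenario: ScenarioConfig
              ) -> ExperimentSummary:
    """Aggregate per-replication ledgers into an ExperimentSummary."""
    if not ledgers:
        raise InputError("summarize needs at least one replication ledger")
    years = config.enrollment_days / 365.0

    med_acc = {k: [] for k in ("overall", *BLOOD_TYPES)}
    rng_acc = {k: [math.inf, -math.inf] for k in ("overall", *BLOOD_TYPES)}
    annual_acc: Dict[str, list] = {k: [] for k in _COUNT_KEYS}
    annual_acc["avg_waiting"] = []
    annual_acc["listing_spells"] = []
    spell_days, spell_n = 0.0, 0
    le_parts = {k: [0.0, 0] for k in
                ("StatusQuo", "CRLM", "CRLM_SECA1", "CRLM_SECA2",
                 "CRLM_palliative")}
    enrolled = {"StatusQuo": [], "CRLM": []}

    for led in ledgers:
        waits = {k: [] for k in ("overall", *BLOOD_TYPES)}
        for bt, w, _group in led.first_tx_waits:
            waits["overall"].append(w)
            waits[bt].append(w)
        for k in med_acc:
            if waits[k]:
                med_acc[k].append(float(np.median(waits[k])))
                rng_acc[k][0] = min(rng_acc[k][0], min(waits[k]))
                rng_acc[k][1] = max(rng_acc[k][1], max(waits[k]))
        for key, sources in _COUNT_KEYS.items():
            annual_acc[key].append(
                sum(led.counts.get(s, 0) for s in sources) / years)
        annual_acc["avg_waiting"].append(
            led.queue_integral / config.enrollment_days)
        annual_acc["listing_spells"].append(led.spell_count / years)
        spell_days += led.spell_days_sum
        spell_n += led.spell_count
        le_parts["StatusQuo"][0] += led.le_sum_sq
        le_parts["StatusQuo"][1] += led.n_sq
        for key, attr in (("CRLM", "le_sum_crlm"),
                          ("CRLM_SECA1", "le_sum_crlm_seca1"),
                          ("CRLM_SECA2", "le_sum_crlm_seca2"),
                          ("CRLM_palliative", "le_sum_crlm_palliative")):
            le_parts[key][0] += getattr(led, attr)
            le_parts[key][1] += led.n_crlm
        enrolled["StatusQuo"].append(led.n_sq)
        enrolled["CRLM"].append(led.n_crlm)

    def _mean(xs):
        return float(np.mean(xs)) if xs else math.nan

    mean_le = {k: (s / n if n else math.nan) for k, (s, n) in le_parts.items()}
    if scenario.strategy == 1:
        # no CRLM transplant pathway exists under strategy 1
        mean_le["CRLM_SECA1"] = math.nan
        mean_le["CRLM_SECA2"] = math.nan

    return ExperimentSummary(
        strategy=scenario.strategy,
        crlm_per_year=scenario.crlm_per_year,
        criteria=scenario.criteria,
        seed=config.seed,
        replications=len(ledgers),
        enrollment_years=years,
        median_wait_days={k: _mean(v) for k, v in med_acc.items()},
        wait_range_days={k: tuple(v) if v[0] <= v[1] else (math.nan, math.nan)
                         for k, v in rng_acc.items()},
        annual={k: _mean(v) for k, v in annual_acc.items()},
        annual_range={k: (min(v), max(v)) if v else (math.nan, math.nan)
                      for k, v in annual_acc.items()},
        mean_le=mean_le,
        enrolled_10y={k: _mean(v) for k, v in enrolled.items()},
        mean_spell_wait_days=(spell_days / spell_n if spell_n else math.nan),
        fingerprint=(config.seed, len(ledgers), config.burn_in_days,
                     config.enrollment_days),
    )


# ----------------------------------------------------------------------
# Net benefit and break-even
# ----------------------------------------------------------------------


@dataclass
class NetBenefitCurve:
    """Life-years gained/lost/net per CRLM listing rate, totalled over the
    10-year enrollment cohort."""

    criteria: str
    n_values: tuple
    gained: tuple
    lost: tuple

    @property
    def net(self) -> tuple:
        return tuple(g - l for g, l in zip(self.gained, self.lost))

    def as_dict(self) -> dict:
        return {
            "criteria": self.criteria,
            "crlm_per_year": list(self.n_values),
            "life_years_gained_crlm": list(self.gained),
            "life_years_lost_status_quo": list(self.lost),
            "net_life_years": list(self.net),
        }


def net_benefit(summaries: Dict[int, ExperimentSummary],
                baseline: ExperimentSummary,
                criteria: Optional[str] = None) -> NetBenefitCurve:
    """Build the net-benefit curve from strategy-2 summaries and the
    strategy-1 baseline.

    gained(n) = (CRLM life expectancy on-list - matched palliative life
    expectancy) x CRLM patients enrolled over the window;
    lost(n) = (baseline Status Quo life expectancy - Status Quo life
    expectancy at rate n) x Status Quo patients enrolled.  All runs must
    share seed and horizons (common random numbers).
    """
    ns = sorted(summaries)
    gained, lost = [], []
    for n in ns:
        s = summaries[n]
        if s.fingerprint != baseline.fingerprint:
            raise ComparisonError(
                "summaries were produced under different seeds or horizons")
        key = "CRLM" if criteria is None else f"CRLM_{criteria}"
        le_crlm = s.mean_le[key]
        le_pall = s.mean_le["CRLM_palliative"]
        n_crlm = s.enrolled_10y["CRLM"]
        if n == 0 or n_crlm == 0:
            gained.append(0.0)
        else:
            gained.append((le_crlm - le_pall) * n_crlm)
        lost.append((baseline.mean_le["StatusQuo"] - s.mean_le["StatusQuo"])
                    * s.enrolled_10y["StatusQuo"])
    crit = criteria or (summaries[ns[0]].criteria if ns else "SECA2")
    return NetBenefitCurve(criteria=crit, n_values=tuple(ns),
                           gained=tuple(gained), lost=tuple(lost))


def find_break_even(curve: NetBenefitCurve):
    """(peak_n, break_even_n): the rate maximising net life-years, and the
    smallest rate at which the net drops to <= 0 (None if it never does)."""
    ns = [n for n in curve.n_values if n >= 1]
    nets = {n: v for n, v in zip(curve.n_values, curve.net)}
    if not ns:
        raise InputError("curve must cover at least one positive rate")
    peak_n = max(ns, key=lambda n: (nets[n], -n))
    break_even_n = next((n for n in ns if nets[n] <= 0), None)
    return peak_n, break_even_n


def exit_log_dataframe(ledger):
    """Per-replication exit log as a DataFrame (requires running with
    ``record_exit_log=True``); one row per waiting-list departure."""
    import pandas as pd

    return pd.DataFrame(
        ledger.exit_log,
        columns=["patient_id", "group", "diagnosis", "blood_type",
                 "listing_day", "exit_day", "exit_kind"])


def run_policy_sweep(config, n_values: Sequence[int],
                     scenario: Optional[ScenarioConfig] = None
                     ) -> Dict[int, ExperimentSummary]:
    """Run the eligibility-expansion sweep under common random numbers.

    ``n_values`` are CRLM listing rates per year; rate 0 is the
    current-program baseline (strategy 1).  Each summary carries both
    SECA I and SECA II life-expectancy surfaces, so one sweep serves both
    eligibility criteria.
    """
    from dataclasses import replace

    from .engine import run_experiment

    scenario = (scenario or ScenarioConfig()).resolved()
    out = {}
    for n in n_values:
        scn = replace(scenario, strategy=1 if n == 0 else 2,
                      crlm_per_year=float(n))
        out[int(n)] = run_experiment(config, scn)
    return out


# ----------------------------------------------------------------------
# Uncertainty analyses
# ----------------------------------------------------------------------

UNCERTAINTY_VARIANTS = (
    "seca-weibull",
    "palliative-weibull",
    "best-case-livers",
    "worst-case-livers",
    "better-sq-survival",
)


def run_uncertainty(config, scenario: ScenarioConfig, variant: str
                    ) -> ExperimentSummary:
    """Re-run the experiment under one structural or availability variant.

    Family swaps re-anchor the named strata to a Weibull matched at the
    25th and 50th percentiles of the base-case curve (same near-term
    survival, lighter tail, hence poorer long-term survival).  Liver
    availability variants rescale the liver interarrival mean to the stated
    annual totals (121 best case, 103 worst case).
    """
    from dataclasses import replace

    from .engine import run_experiment

    scenario = scenario.resolved()
    if variant == "best-case-livers":
        scenario = scenario.with_livers_per_year(121.0)
    elif variant == "worst-case-livers":
        scenario = scenario.with_livers_per_year(103.0)
    elif variant == "seca-weibull":
        scenario = replace(
            scenario, registry=scenario.registry.with_weibull_tail("SECA1", "SECA2"))
    elif variant == "palliative-weibull":
        scenario = replace(
            scenario, registry=scenario.registry.with_weibull_tail("palliative"))
    elif variant == "better-sq-survival":
        scenario = replace(
            scenario,
            registry=scenario.registry.with_status_quo_strata_set_to("PSC"))
    else:
        raise InputError(
            f"unknown variant {variant!r}; choose from {UNCERTAINTY_VARIANTS}")
    return run_experiment(config, scenario)
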