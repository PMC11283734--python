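"""Discrete-event core: calendar, clock, RNG streams, replications.

One replication simulates the waiting list over a warm-up (burn-in) period,
a 10-year enrollment window, and a tail.  Patients listed during the window
are "tracked": their waits and life-years enter the outcome ledgers, and
they are followed until they leave the list (post-transplant survival needs
no further events — death times are resolved analytically at transplant).
Burn-in and tail arrivals still compete for livers, so tracked patients face
realistic queues at both edges of the window.

Randomness is split into named independent streams (arrivals, CRLM
arrivals, livers, attributes, pretransplant, posttransplant, palliative),
each seeded from the master seed, the stream id and the replication index.
Every patient pre-draws all the uniforms its pathway could ever need at the
moment it is created.  Because patients are created in arrival order and
arrivals are stream-separated, the same master seed reproduces the exact
same population — and the same individual fates — across policy scenarios,
which is what makes small incremental outcomes (a 0.05-year life-expectancy
shift) estimable by differencing (common random numbers).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import SimulationStallError
from .population import (
    DAYS_PER_YEAR,
    Liver,
    ScenarioConfig,
    make_patient,
    next_arrival,
)
from .waitlist import (
    WaitingList,
    match_liver,
    schedule_pretransplant_exits,
    transplant_and_remove,
)

STREAMS = (
    "arrivals",
    "crlm_arrivals",
    "livers",
    "attributes",
    "pretransplant",
    "posttransplant",
    "palliative",
)

# event kinds, processed in (time, insertion sequence) order; a liver
# arriving at the same instant as a listing is inserted later and therefore
# processed after it, so same-day listings can receive same-day livers.
_PATIENT, _CRLM, _LIVER, _EXIT = 0, 1, 2, 3


@dataclass
class ReplicationConfig:
    """Replication-manager settings.

    Defaults follow the base-case analysis design: outcomes counted after a
    1,900-day burn-in, a 10-year (3,650-day) enrollment window, averaged
    over many replications.  ``stream_seeds`` overrides the master seed for
    individual streams (used to verify stream independence and to hold
    arrival processes fixed while perturbing survival draws).
    """

    seed: int = 0
    replications: int = 7000
    burn_in_days: float = 1900.0
    enrollment_days: float = 3650.0
    stream_seeds: dict = field(default_factory=dict)
    max_tail_days: float = 36500.0
    record_exit_log: bool = False

    def __post_init__(self):
        if self.burn_in_days < 0:
            raise ValueError("burn_in_days must be >= 0")
        if self.replications < 1:
            raise ValueError("replications must be >= 1")


class _Buffered:
    """Thin buffer over a Generator so scalar uniform draws are cheap.

    Draw order (hence reproducibility) is identical to calling
    ``Generator.random`` directly for each request.
    """

    __slots__ = ("_gen", "_buf", "_pos")
    _CHUNK = 2048

    def __init__(self, gen: np.random.Generator):
        self._gen = gen
        self._buf = gen.random(self._CHUNK).tolist()
        self._pos = 0

    def random(self, n: Optional[int] = None):
        if n is None:
            if self._pos >= len(self._buf):
                self._buf = self._gen.random(self._CHUNK).tolist()
                self._pos = 0
            v = self._buf[self._pos]
            self._pos += 1
            return v
        if self._pos + n > len(self._buf):
            rest = self._buf[self._pos:]
            self._buf = rest + self._gen.random(self._CHUNK).tolist()
            self._pos = 0
        out = self._buf[self._pos:self._pos + n]
        self._pos += n
        return out


def make_streams(config: ReplicationConfig, rep: int) -> dict:
    out = {}
    for idx, name in enumerate(STREAMS):
        base = config.stream_seeds.get(name, config.seed)
        out[name] = _Buffered(np.random.Generator(
            np.random.PCG64(np.random.SeedSequence((base, idx, rep)))
        ))
    return out


@dataclass
class RepLedger:
    """Raw per-replication outcome ledger (tracked entities only, except for
    the all-time conservation counters)."""

    # (blood_type, wait_days, group) per tracked first transplant
    first_tx_waits: list = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    # life-years sums
    le_sum_sq: float = 0.0
    n_sq: int = 0
    le_sum_crlm: float = 0.0
    le_sum_crlm_seca1: float = 0.0
    le_sum_crlm_seca2: float = 0.0
    le_sum_crlm_palliative: float = 0.0
    n_crlm: int = 0
    queue_integral: float = 0.0     # patient-days over the enrollment window
    spell_days_sum: float = 0.0     # total on-list days of tracked spells
    spell_count: int = 0            # tracked listing spells completed
    # optional per-patient exit log rows:
    # (patient id, group, diagnosis, blood type, listing day, exit day, kind)
    exit_log: list = field(default_factory=list)
    # all-time (burn-in + window + tail) conservation counters
    livers_total: int = 0
    transplants_total: int = 0
    exported_total: int = 0
    residual_waiting: int = 0

    def count(self, key: str, by: int = 1):
        self.counts[key] = self.counts.get(key, 0) + by


def _draw_patient_uniforms(streams, group: str) -> tuple:
    """Pre-draw the full uniform vector one patient can consume.

    Layout: [0] diagnosis, [1] blood type (attributes stream);
    [2-4] first-spell death/dropout/withdrawal, [5-7] relist-spell ditto
    (pretransplant stream); [8] retransplant listing, [9] qualification,
    [10-11] first-graft survival + background switch, [12-13] regraft ditto
    (posttransplant stream); CRLM only: [14-15] palliative survival +
    background switch (palliative stream).
    """
    a = streams["attributes"].random(2)
    p = streams["pretransplant"].random(6)
    q = streams["posttransplant"].random(6)
    if group == "CRLM":
        r = streams["palliative"].random(2)
        return (*a, *p, *q, *r)
    return (*a, *p, *q, math.nan, math.nan)


def run_replication(config: ReplicationConfig, scenario: ScenarioConfig,
                    rep: int = 0) -> RepLedger:
    """Run one replication and return its raw ledger."""
    from .outcomes import palliative_life_years, posttransplant_life_years

    scenario = scenario.resolved()
    streams = make_streams(config, rep)
    registry, life_table = scenario.registry, scenario.life_table

    window_start = config.burn_in_days
    window_end = config.burn_in_days + config.enrollment_days
    horizon = window_end + config.max_tail_days

    ledger = RepLedger()
    wl = WaitingList()
    calendar: list = []
    seq = 0
    tracked_waiting = 0
    last_time = 0.0
    next_pid = 0

    def log_exit(pat, clock, kind):
        if config.record_exit_log:
            ledger.exit_log.append(
                (pat.pid, pat.group, pat.diagnosis, pat.blood_type,
                 pat.listing_time, clock, kind))

    def push(time, kind, payload=None):
        nonlocal seq
        heapq.heappush(calendar, (time, seq, kind, payload))
        seq += 1

    def in_window(t):
        return window_start <= t < window_end

    # prime the arrival processes
    push(next_arrival(scenario.patient_interarrival_days,
                      streams["arrivals"].random()), _PATIENT)
    if scenario.crlm_per_year > 0:
        push(next_arrival(scenario.crlm_interarrival_days,
                          streams["crlm_arrivals"].random()), _CRLM)
    push(next_arrival(scenario.liver_interarrival_days,
                      streams["livers"].random()), _LIVER)

    def list_patient(pat, clock):
        nonlocal tracked_waiting
        wl.add(pat, clock)
        if pat.tracked:
            tracked_waiting += 1
        t_exit, kind = schedule_pretransplant_exits(
            pat, registry, scenario, spell=pat.spell)
        if math.isfinite(t_exit):
            push(clock + t_exit, _EXIT, (pat, pat.spell, kind))

    def relist_patient(pat, clock):
        nonlocal tracked_waiting
        wl.add(pat, clock, priority=True)
        if pat.tracked:
            tracked_waiting += 1
        t_exit, kind = schedule_pretransplant_exits(
            pat, registry, scenario, spell=2)
        if math.isfinite(t_exit):
            push(clock + t_exit, _EXIT, (pat, pat.spell, kind))

    def off_list(pat):
        nonlocal tracked_waiting
        wl.remove(pat)
        if pat.tracked:
            tracked_waiting -= 1

    def settle_transplant(pat, clock):
        """Resolve a matched transplant: retransplant branching, survival."""
        rec_spell = pat.spell
        off_list(pat)
        wait_days = clock - pat.spell_start
        ledger.transplants_total += 1
        log_exit(pat, clock, "transplant" if rec_spell == 1 else "retransplant")
        if pat.tracked:
            ledger.spell_days_sum += wait_days
            ledger.spell_count += 1
        if rec_spell == 1:
            if pat.tracked:
                ledger.count(f"first_tx_{pat.group}")
                ledger.first_tx_waits.append((pat.blood_type, wait_days, pat.group))
            if pat.draws[8] < scenario.p_relist:
                if pat.draws[9] < scenario.p_qualify:
                    relist_patient(pat, clock)   # prioritised regraft listing
                    return
                # does not qualify: removed, life-years credited to removal
                if pat.tracked:
                    ledger.count("relist_nonqualified")
                    _credit_life_years(pat, (clock - pat.listing_time) / DAYS_PER_YEAR)
                return
        else:
            if pat.tracked:
                ledger.count("retx")
        # successful graft: draw post-transplant survival, 10-y background switch
        u_s, u_b = (pat.draws[10], pat.draws[11]) if rec_spell == 1 else \
                   (pat.draws[12], pat.draws[13])
        wait_years = (clock - pat.listing_time) / DAYS_PER_YEAR
        if pat.group == "CRLM":
            if pat.tracked:
                # book both eligibility criteria from the same survival draw
                # so one run yields matched SECA I and SECA II surfaces
                for crit, attr in (("SECA1", "le_sum_crlm_seca1"),
                                   ("SECA2", "le_sum_crlm_seca2")):
                    t_post = posttransplant_life_years(
                        registry.treatment_stratum(crit), pat.age_at_listing,
                        life_table, u_s, u_b, scenario.switch_years)
                    setattr(ledger, attr, getattr(ledger, attr) + wait_years + t_post)
            stratum = registry.treatment_stratum(scenario.criteria)
        else:
            stratum = registry.treatment_stratum(pat.diagnosis)
        t_post = posttransplant_life_years(
            stratum, pat.age_at_listing, life_table, u_s, u_b,
            scenario.switch_years)
        if pat.tracked:
            _credit_life_years(pat, wait_years + t_post, both_criteria=False)

    def _credit_life_years(pat, le, both_criteria=True):
        if pat.group == "CRLM":
            ledger.le_sum_crlm += le
            if both_criteria:
                # non-transplant outcomes are criteria-independent
                ledger.le_sum_crlm_seca1 += le
                ledger.le_sum_crlm_seca2 += le
        else:
            ledger.le_sum_sq += le
            ledger.n_sq += 1

    while calendar:
        time, _, kind, payload = heapq.heappop(calendar)
        if time > horizon:
            raise SimulationStallError(
                f"tracked patients still waiting at {time:.0f} d "
                f"(horizon {horizon:.0f} d)")
        # queue-length time integral over the enrollment window
        lo, hi = max(last_time, window_start), min(time, window_end)
        if hi > lo:
            ledger.queue_integral += wl.n_waiting * (hi - lo)
        last_time = time

        if kind == _PATIENT:
            push(time + next_arrival(scenario.patient_interarrival_days,
                                     streams["arrivals"].random()), _PATIENT)
            draws = _draw_patient_uniforms(streams, "StatusQuo")
            pat = make_patient("StatusQuo", time, scenario, draws, in_window(time))
            pat.pid, next_pid = next_pid, next_pid + 1
            if pat.tracked:
                ledger.count("enlisted_StatusQuo")
            list_patient(pat, time)

        elif kind == _CRLM:
            push(time + next_arrival(scenario.crlm_interarrival_days,
                                     streams["crlm_arrivals"].random()), _CRLM)
            draws = _draw_patient_uniforms(streams, "CRLM")
            pat = make_patient("CRLM", time, scenario, draws, in_window(time))
            pat.pid, next_pid = next_pid, next_pid + 1
            if pat.tracked:
                ledger.n_crlm += 1
                ledger.le_sum_crlm_palliative += palliative_life_years(
                    registry, life_table, pat.age_at_listing,
                    pat.draws[14], pat.draws[15], scenario.switch_years)
            if scenario.strategy == 2:
                if pat.tracked:
                    ledger.count("enlisted_CRLM")
                list_patient(pat, time)
            elif pat.tracked:
                # strategy 1: palliative pathway off the queue
                ledger.le_sum_crlm += palliative_life_years(
                    registry, life_table, pat.age_at_listing,
                    pat.draws[14], pat.draws[15], scenario.switch_years)

        elif kind == _LIVER:
            push(time + next_arrival(scenario.liver_interarrival_days,
                                     streams["livers"].random()), _LIVER)
            liver = Liver(
                blood_type=_liver_blood_type(streams["livers"].random(),
                                             scenario.liver_blood_mix),
                arrival_time=time)
            ledger.livers_total += 1
            if in_window(time):
                ledger.count("livers_window")
            pat = match_liver(liver, wl, time, scenario.abo_rule)
            if pat is None:
                ledger.exported_total += 1
                if in_window(time):
                    ledger.count("exported_window")
            else:
                settle_transplant(pat, time)

        else:  # _EXIT
            pat, spell, exit_kind = payload
            if not pat.on_list or pat.spell != spell:
                continue  # stale: the patient was transplanted meanwhile
            off_list(pat)
            log_exit(pat, time, exit_kind)
            if pat.tracked:
                key = "withdrawal" if exit_kind == "withdrawal" else "deathdrop"
                ledger.count(f"{key}_{pat.group}")
                ledger.spell_days_sum += time - pat.spell_start
                ledger.spell_count += 1
                _credit_life_years(pat, (time - pat.listing_time) / DAYS_PER_YEAR)

        if time >= window_end and tracked_waiting == 0:
            break

    if tracked_waiting > 0:
        raise SimulationStallError(
            "event calendar exhausted with tracked patients still waiting")
    ledger.residual_waiting = wl.n_waiting
    return ledger


def _liver_blood_type(u: float, mix: dict) -> str:
    from .population import assign_blood_type

    return assign_blood_type(u, mix)


def run_experiment(config: ReplicationConfig, scenario: ScenarioConfig,
                   progress: Optional[callable] = None):
    """Run all replications and aggregate them into an ExperimentSummary.

    Deterministic given ``config.seed``: the same seed yields bit-identical
    summaries.
    """
    from .outcomes import summarize

    scenario = scenario.resolved()
    ledgers = []
    for rep in range(config.replications):
        ledgers.append(run_replication(config, scenario, rep))
        if progress is not None:
            progress(rep)
    return summarize(ledgers, config, scenario)
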