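"""The waiting list: competing pretransplant exits and liver matching.

Matching follows the national practice the model abstracts: when a liver
arrives it goes to the longest-waiting blood-group-eligible patient, except
that acute-liver-failure patients and patients relisted for a retransplant
are prioritised (longest-waiting priority patient first).  A liver with no
eligible recipient leaves the pool immediately — exported to a partner
country within the shared Scandinavian allocation program.

While waiting, each patient carries three competing exit clocks drawn at
listing: disease-specific death and dropout (from the registry's
waiting-list strata) and an administrative withdrawal with a 6%/year
exponential hazard.  Whichever fires first before a transplant removes the
patient from the list.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Optional

from .errors import ConfigurationError, LogicError
from .population import BLOOD_TYPES, Patient

#: donor blood group -> recipient groups that can accept it, in search order.
ABO_COMPATIBLE = {
    "0": ("0", "A", "B", "AB"),
    "A": ("A", "AB"),
    "B": ("B", "AB"),
    "AB": ("AB",),
}


def withdrawal_time(u: float, scenario) -> float:
    """Days until administrative withdrawal for one listing spell.

    ``fraction`` mode: a share ``withdrawal_annual`` of listings withdraw,
    at an exponential time (mean ``withdrawal_time_mean_days``) that does
    not depend on queue state; the single uniform drives both the Bernoulli
    gate and, rescaled, the timing.  ``hazard`` mode: an exponential
    withdrawal clock with annual probability ``withdrawal_annual``
    (rate -ln(1 - p)/365 per day).
    """
    p = scenario.withdrawal_annual
    if p <= 0:
        return math.inf
    if scenario.withdrawal_mode == "fraction":
        if u >= p:
            return math.inf
        v = u / p  # conditional uniform, reused for the timing
        return -scenario.withdrawal_time_mean_days * math.log1p(-v)
    return -math.log1p(-u) / scenario.withdrawal_rate_per_day


def schedule_pretransplant_exits(patient: Patient, registry, scenario,
                                 spell: int = 1):
    """Competing exit times (days after the spell start) for a listing spell.

    Returns ``(time_days, kind)`` of the earliest of the three competing
    exits; the engine schedules only that one.  Uses the patient's
    pre-drawn uniforms so the same fate replays across scenarios.
    """
    death_dist = registry.waitlist_stratum(patient.diagnosis, "death")
    drop_dist = registry.waitlist_stratum(patient.diagnosis, "dropout")
    if spell == 1:
        u_death, u_drop, u_with = patient.draws[2], patient.draws[3], patient.draws[4]
    else:
        u_death, u_drop, u_with = patient.draws[5], patient.draws[6], patient.draws[7]
    t_death = death_dist.quantile(u_death)
    t_drop = drop_dist.quantile(u_drop)
    t_with = withdrawal_time(u_with, scenario)
    best, kind = t_death, "death"
    if t_drop < best:
        best, kind = t_drop, "dropout"
    if t_with < best:
        best, kind = t_with, "withdrawal"
    return best, kind


@dataclass
class ExitRecord:
    patient: Patient
    exit_kind: str       # transplant | death | dropout | withdrawal
    exit_time: float
    wait_days: float


class WaitingList:
    """Per-blood-type FIFO queues with a separate priority lane.

    Appends happen in clock order, so each deque is ordered by spell start
    (= waiting the longest at the front).  Removal on transplant or exit is
    lazy: entries are skipped once the patient is no longer on the list or
    the entry's spell is stale.
    """

    def __init__(self):
        self._regular = {bt: deque() for bt in BLOOD_TYPES}
        self._priority = {bt: deque() for bt in BLOOD_TYPES}
        self.n_waiting = 0

    def add(self, patient: Patient, clock: float, priority: Optional[bool] = None):
        if patient.on_list:
            raise LogicError("patient is already on the waiting list")
        patient.on_list = True
        patient.spell += 1
        patient.spell_start = clock
        lane = self._priority if (patient.priority if priority is None else priority) \
            else self._regular
        lane[patient.blood_type].append((patient, patient.spell))
        self.n_waiting += 1

    def remove(self, patient: Patient):
        """Mark a patient as off-list; the queue entry is dropped lazily."""
        if not patient.on_list:
            raise LogicError("patient is not on the waiting list")
        patient.on_list = False
        self.n_waiting -= 1

    def _peek(self, lane: dict, blood_type: str):
        q = lane[blood_type]
        while q:
            patient, spell = q[0]
            if patient.on_list and patient.spell == spell:
                return patient
            q.popleft()
        return None

    def longest_waiting(self, blood_types) -> Optional[Patient]:
        """Longest-waiting eligible patient, priority lane first."""
        for lane in (self._priority, self._regular):
            best = None
            for bt in blood_types:
                cand = self._peek(lane, bt)
                if cand is not None and (
                    best is None or cand.spell_start < best.spell_start
                ):
                    best = cand
            if best is not None:
                return best
        return None


def match_liver(liver, waitlist: WaitingList, clock: float,
                rule: str = "identical"):
    """Match an arriving liver; returns the chosen patient or ``None``
    (liver exported)."""
    if liver.arrival_time != clock:
        raise LogicError("liver matched at a time other than its arrival")
    if rule == "identical":
        eligible = (liver.blood_type,)
    else:
        eligible = ABO_COMPATIBLE[liver.blood_type]
    return waitlist.longest_waiting(eligible)


def transplant_and_remove(patient: Patient, liver, waitlist: WaitingList,
                          clock: float) -> ExitRecord:
    """Remove a matched patient from the list and emit the transplant record.

    ``wait_days`` is measured from the start of the current listing spell
    (first listing or retransplant relisting)."""
    waitlist.remove(patient)
    return ExitRecord(
        patient=patient,
        exit_kind="transplant",
        exit_time=clock,
        wait_days=clock - patient.spell_start,
    )
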