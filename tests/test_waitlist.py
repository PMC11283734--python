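"""Waiting-list mechanics: competing exits, matching, priority."""

import math

import numpy as np
import pytest

from liversim import ScenarioConfig
from liversim.errors import LogicError
from liversim.population import Liver, Patient
from liversim.waitlist import (
    WaitingList,
    match_liver,
    schedule_pretransplant_exits,
    transplant_and_remove,
    withdrawal_time,
)


def mk_patient(blood="A", priority=False, diagnosis="PSC", draws=None,
               listing=0.0):
    return Patient(group="StatusQuo", diagnosis=diagnosis, blood_type=blood,
                   age_at_listing=43.0, listing_time=listing,
                   priority=priority, tracked=True,
                   draws=draws or tuple([0.5] * 16))


class TestWithdrawalClock:
    def test_hazard_mode_annual_probability(self):
        """Under the hazard mode, the fraction withdrawing within a year
        is the stated 6%."""
        scn = ScenarioConfig(withdrawal_mode="hazard")
        u = np.random.default_rng(0).random(10**6)
        frac = np.mean([withdrawal_time(v, scn) <= 365.0 for v in u[:200000]])
        assert abs(frac - 0.06) < 0.002
        # exact closed form: t(u) <= 365 iff u <= 0.06
        assert withdrawal_time(0.06 - 1e-12, scn) <= 365.0 + 1e-6
        assert withdrawal_time(0.06 + 1e-9, scn) > 365.0

    def test_fraction_mode_caps_withdrawers(self):
        scn = ScenarioConfig(withdrawal_mode="fraction")
        assert math.isinf(withdrawal_time(0.061, scn))
        assert math.isfinite(withdrawal_time(0.059, scn))
        u = np.random.default_rng(1).random(100000)
        finite = [withdrawal_time(v, scn) for v in u]
        finite = [t for t in finite if math.isfinite(t)]
        assert len(finite) / 100000 == pytest.approx(0.06, abs=0.003)
        assert np.mean(finite) == pytest.approx(
            scn.withdrawal_time_mean_days, rel=0.05)

    def test_zero_probability_never_withdraws(self):
        scn = ScenarioConfig(withdrawal_annual=0.0)
        assert math.isinf(withdrawal_time(0.5, scn))


class TestCompetingExits:
    def test_earliest_exit_wins(self, registry):
        scn = ScenarioConfig(withdrawal_mode="hazard")
        # death draw tiny, others large -> death fires first
        draws = (0.5, 0.5, 0.0001, 0.9, 0.9, *([0.5] * 11))
        pat = mk_patient(draws=draws)
        t, kind = schedule_pretransplant_exits(pat, registry, scn)
        assert kind == "death"
        assert t == pytest.approx(
            registry.waitlist_stratum("PSC", "death").quantile(0.0001))

    def test_no_exit_when_clocks_effectively_infinite(self, registry):
        scn = ScenarioConfig(withdrawal_annual=0.0)
        draws = (0.5, 0.5, 1e-12, 1e-12, 0.99, *([0.5] * 11))
        pat = mk_patient(draws=draws)
        t, _ = schedule_pretransplant_exits(pat, registry, scn)
        assert t < 1.0  # quantile of ~0 is ~0; sanity of plumbing
        draws_far = (0.5, 0.5, 0.999999, 0.999999, 0.5, *([0.5] * 11))
        t_far, _ = schedule_pretransplant_exits(
            mk_patient(draws=draws_far), registry, scn)
        assert t_far > 365.0 * 20

    def test_crlm_uses_aliased_stratum(self, registry):
        assert registry.waitlist_stratum("CRLM", "dropout").params == \
            registry.waitlist_stratum("HCC", "dropout").params


class TestMatching:
    def test_empty_list_exports(self):
        wl = WaitingList()
        liver = Liver(blood_type="A", arrival_time=5.0)
        assert match_liver(liver, wl, 5.0) is None

    def test_priority_beats_waiting_time(self):
        wl = WaitingList()
        psc = mk_patient("A", priority=False, listing=0.0)
        alf = mk_patient("A", priority=True, diagnosis="ALF", listing=99.0)
        wl.add(psc, 0.0)
        wl.add(alf, 99.0)
        liver = Liver(blood_type="A", arrival_time=100.0)
        assert match_liver(liver, wl, 100.0) is alf

    def test_longest_waiting_wins_without_priority(self):
        wl = WaitingList()
        p_old = mk_patient("A", listing=10.0)
        p_new = mk_patient("A", listing=30.0)
        wl.add(p_old, 10.0)
        wl.add(p_new, 30.0)
        liver = Liver(blood_type="A", arrival_time=40.0)
        assert match_liver(liver, wl, 40.0) is p_old

    def test_identical_rule_ignores_compatible_types(self):
        wl = WaitingList()
        wl.add(mk_patient("A"), 0.0)
        liver = Liver(blood_type="0", arrival_time=1.0)
        assert match_liver(liver, wl, 1.0, rule="identical") is None

    def test_compatible_rule_follows_abo(self):
        wl = WaitingList()
        a_pat = mk_patient("A", listing=0.0)
        wl.add(a_pat, 0.0)
        assert match_liver(Liver("0", 1.0), wl, 1.0, rule="compatible") is a_pat
        wl2 = WaitingList()
        wl2.add(mk_patient("AB"), 0.0)
        # AB recipients accept everything; 0 recipients only 0
        assert match_liver(Liver("B", 1.0), wl2, 1.0, rule="compatible") \
            is not None
        wl3 = WaitingList()
        wl3.add(mk_patient("0"), 0.0)
        assert match_liver(Liver("A", 1.0), wl3, 1.0, rule="compatible") is None

    def test_liver_must_arrive_now(self):
        with pytest.raises(LogicError):
            match_liver(Liver("A", 1.0), WaitingList(), 2.0)


class TestTransplantAndRemove:
    def test_wait_is_clock_minus_spell_start(self):
        wl = WaitingList()
        pat = mk_patient("B", listing=50.0)
        wl.add(pat, 50.0)
        rec = transplant_and_remove(pat, Liver("B", 90.0), wl, 90.0)
        assert rec.exit_kind == "transplant"
        assert rec.wait_days == pytest.approx(40.0)
        assert not pat.on_list
        assert wl.n_waiting == 0

    def test_removed_patient_not_matchable(self):
        wl = WaitingList()
        pat = mk_patient("B", listing=0.0)
        wl.add(pat, 0.0)
        transplant_and_remove(pat, Liver("B", 10.0), wl, 10.0)
        assert match_liver(Liver("B", 20.0), wl, 20.0) is None

    def test_double_removal_is_logic_error(self):
        wl = WaitingList()
        pat = mk_patient()
        wl.add(pat, 0.0)
        wl.remove(pat)
        with pytest.raises(LogicError):
            wl.remove(pat)

    def test_stale_spell_entries_skipped(self):
        """A relisted patient's old queue entry must not shadow the new."""
        wl = WaitingList()
        pat = mk_patient("A", listing=0.0)
        wl.add(pat, 0.0)
        transplant_and_remove(pat, Liver("A", 5.0), wl, 5.0)
        wl.add(pat, 5.0, priority=True)   # retransplant listing
        assert pat.spell == 2
        got = match_liver(Liver("A", 8.0), wl, 8.0)
        assert got is pat
        rec = transplant_and_remove(pat, Liver("A", 8.0), wl, 8.0)
        assert rec.wait_days == pytest.approx(3.0)
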