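"""Post-transplant pathway, net benefit, break-even, uncertainty variants."""

import dataclasses
import math

import numpy as np
import pytest

from liversim import (
    ParametricSurvival,
    ReplicationConfig,
    ScenarioConfig,
    find_break_even,
    net_benefit,
    run_experiment,
    run_uncertainty,
)
from liversim.calibration import expected_life_years_with_switch
from liversim.errors import ComparisonError, InputError
from liversim.outcomes import (
    NetBenefitCurve,
    apply_background_switch,
    palliative_life_years,
)


class TestBackgroundSwitch:
    def test_below_switch_untouched(self, life_table):
        assert apply_background_switch(4.2, 57.0, life_table, 0.5) == 4.2

    def test_forced_switch_death_within_a_year(self):
        from liversim import LifeTable

        lt = LifeTable([67], [1.0])
        t = apply_background_switch(30.0, 57.0, lt, 0.7)
        assert 10.0 <= t < 11.0

    def test_analytic_decomposition(self, registry, life_table):
        """E[LE] = E[min(T,10)] + P(T>10) * e(age+10); 1e5 draws agree."""
        dist = registry.treatment_stratum("SECA2")
        rng = np.random.default_rng(8)
        u, ub = rng.random(10**5), rng.random(10**5)
        draws = [apply_background_switch(dist.quantile(a), 57.0, life_table, b)
                 for a, b in zip(u, ub)]
        analytic = expected_life_years_with_switch(dist, 57.0, life_table)
        assert np.mean(draws) == pytest.approx(analytic, abs=0.05)


class TestPalliativePathway:
    def test_point_mass_stratum_returns_constant(self, registry, life_table):
        from liversim.calibration import SurvivalRegistry

        treatment = dict(registry.treatment)
        # sigma -> 0 log-normal: effectively a point mass at exp(mu)
        m = 3.7
        treatment["palliative"] = ParametricSurvival(
            "log-normal", (math.log(m), 1e-12))
        reg = SurvivalRegistry(treatment, registry.waitlist)
        got = palliative_life_years(reg, life_table, 57.0, 0.42, 0.5)
        assert got == pytest.approx(m, rel=1e-6)

    def test_quartile_survival_fraction(self, registry, life_table):
        """75% of palliative patients outlive the published 1.18-year
        anchor by construction."""
        dist = registry.treatment_stratum("palliative")
        u = np.random.default_rng(1).random(20000)
        le = np.array([palliative_life_years(registry, life_table, 57.0, a, 0.5)
                       for a in u])
        assert np.mean(le >= 1.18) == pytest.approx(0.75, abs=0.01)
        assert dist.quantile(0.25) == pytest.approx(1.18, abs=1e-9)


class TestNetBenefit:
    def make_curve(self, nets):
        n = tuple(range(len(nets)))
        return NetBenefitCurve("SECA1", n, tuple(nets),
                               tuple(0.0 for _ in nets))

    def test_identical_summaries_give_zero_net(self, base_scenario):
        cfg = ReplicationConfig(seed=6, replications=3)
        s = run_experiment(cfg, base_scenario)
        curve = net_benefit({0: s}, s)
        assert curve.net == (0.0,)

    def test_net_is_gained_minus_lost(self):
        curve = NetBenefitCurve("SECA2", (1, 2), (100.0, 200.0), (30.0, 90.0))
        assert curve.net == (70.0, 110.0)

    def test_mismatched_fingerprints_rejected(self, base_scenario):
        a = run_experiment(ReplicationConfig(seed=6, replications=2),
                           base_scenario)
        b = run_experiment(ReplicationConfig(seed=7, replications=2),
                           base_scenario)
        with pytest.raises(ComparisonError):
            net_benefit({2: b}, a)

    def test_break_even_and_peak(self):
        curve = self.make_curve([0, 10, 30, 25, -5, -20])
        peak, brk = find_break_even(curve)
        assert peak == 2
        assert brk == 4
        all_neg = self.make_curve([0, -1, -2])
        assert find_break_even(all_neg) == (1, 1)
        increasing = self.make_curve([0, 1, 2, 3])
        assert find_break_even(increasing) == (3, None)


class TestUncertaintyVariants:
    def test_liver_availability_rescaling(self, base_scenario):
        cfg = ReplicationConfig(seed=4, replications=3)
        best = run_uncertainty(cfg, base_scenario, "best-case-livers")
        worst = run_uncertainty(cfg, base_scenario, "worst-case-livers")
        assert best.annual["livers"] == pytest.approx(121.0, rel=0.05)
        assert worst.annual["livers"] == pytest.approx(103.0, rel=0.05)
        assert worst.median_wait_days["overall"] > \
            best.median_wait_days["overall"]

    def test_better_sq_survival_uses_psc_curve(self, base_scenario):
        cfg = ReplicationConfig(seed=4, replications=3)
        s = run_uncertainty(cfg, base_scenario, "better-sq-survival")
        base = run_experiment(cfg, base_scenario)
        assert s.mean_le["StatusQuo"] > base.mean_le["StatusQuo"]

    def test_weibull_swap_preserves_anchor(self, base_scenario):
        reg = base_scenario.registry.with_weibull_tail("SECA1", "SECA2",
                                                       "palliative")
        for name in ("SECA1", "SECA2", "palliative"):
            d = reg.treatment_stratum(name)
            assert d.family == "weibull"
            assert d.quantile(0.25) == pytest.approx(
                base_scenario.registry.treatment_stratum(name).quantile(0.25))

    def test_unknown_variant_rejected(self, base_scenario):
        with pytest.raises(InputError):
            run_uncertainty(ReplicationConfig(seed=1, replications=1),
                            base_scenario, "no-such-variant")


class TestStrategyComparisons:
    def test_strategy2_at_zero_equals_strategy1(self, registry, life_table):
        cfg = ReplicationConfig(seed=12, replications=4)
        s1 = run_experiment(cfg, ScenarioConfig(
            strategy=1, registry=registry, life_table=life_table))
        s2 = run_experiment(cfg, ScenarioConfig(
            strategy=2, crlm_per_year=0.0, registry=registry,
            life_table=life_table))
        d1, d2 = s1.to_dict(), s2.to_dict()
        for key in ("median_wait_days", "annual", "enrolled_10y"):
            assert d1[key] == d2[key]
        assert s1.mean_le["StatusQuo"] == s2.mean_le["StatusQuo"]

    def test_spillover_monotonicity(self, registry, life_table):
        """With common random numbers, more CRLM listings mean longer
        overall waits and no higher Status Quo life expectancy."""
        cfg = ReplicationConfig(seed=14, replications=40)
        res = {}
        for n in (0, 4, 10):
            scn = ScenarioConfig(strategy=2 if n else 1, crlm_per_year=float(n),
                                 registry=registry, life_table=life_table)
            res[n] = run_experiment(cfg, scn)
        assert res[0].median_wait_days["overall"] <= \
            res[4].median_wait_days["overall"] <= \
            res[10].median_wait_days["overall"]
        assert res[0].mean_le["StatusQuo"] >= res[4].mean_le["StatusQuo"] >= \
            res[10].mean_le["StatusQuo"]
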