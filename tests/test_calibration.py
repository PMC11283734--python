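"""Synthetic cohorts, registry calibration, and its published anchors."""

import math

import numpy as np
import pytest

from liversim import (
    ParametricSurvival,
    SurvivalRegistry,
    calibrate_registry,
    fit_mle,
    generate_cohort,
)
from liversim.calibration import (
    LE_ANCHORS_YEARS,
    Q75_TARGETS_YEARS,
    TREATMENT_STRATA,
    default_shape_policy,
    expected_life_years_with_switch,
    match_weibull_at_quantiles,
    params_for_quantile,
    solve_shape_for_life_expectancy,
)
from liversim.errors import CalibrationError, ConfigurationError
from liversim.population import AGE_AT_LISTING, DEFAULT_DIAGNOSIS_MIX


class TestGenerateCohort:
    def test_uncensored_has_all_events(self):
        c = generate_cohort("weibull", (1.5, 100.0), n=100, seed=0)
        assert len(c) == 100
        assert c.events.all()
        assert (c.times > 0).all()

    def test_median_censoring_splits_in_half(self):
        c = generate_cohort("exponential", (100.0,),
                            censor_time=100.0 * math.log(2), n=10**5, seed=1)
        frac = 1.0 - c.events.mean()
        assert abs(frac - 0.5) < 0.005

    def test_same_seed_is_bit_identical(self):
        a = generate_cohort("gompertz", (0.1, 0.01), n=500, seed=9)
        b = generate_cohort("gompertz", (0.1, 0.01), n=500, seed=9)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.events, b.events)
        c = generate_cohort("gompertz", (0.1, 0.01), n=500, seed=10)
        assert not np.array_equal(a.times, c.times)

    def test_round_trip_with_fitting(self):
        """Cohort generation and MLE fitting invert each other (10% at
        n=2000) for every family — the end-to-end machinery check."""
        cases = {
            "exponential": (120.0,),
            "weibull": (1.5, 1000.0),
            "log-logistic": (2.0, 400.0),
            "log-normal": (2.0, 0.8),
            "gompertz": (0.02, 0.005),
        }
        for family, true in cases.items():
            c = generate_cohort(family, true, n=2000, seed=21)
            fit = fit_mle(c.times, c.events, family)
            for est, tru in zip(fit.params, true):
                assert est == pytest.approx(tru, rel=0.10)


class TestRegistryCalibration:
    def test_all_strata_present(self, registry):
        for name in TREATMENT_STRATA:
            assert registry.treatment_stratum(name) is not None
        with pytest.raises(ConfigurationError):
            registry.treatment_stratum("nope")

    def test_quantile_targets_hit_exactly(self, registry):
        """Every stratum's 75%-survival time reproduces its published
        anchor (CRLM SECA I 2.64 y, palliative 1.18 y, ...)."""
        for name, target in Q75_TARGETS_YEARS.items():
            assert registry.seventy_five_percent_survival(name) == pytest.approx(
                target, abs=1e-6)

    def test_exponential_closed_form(self):
        reg = calibrate_registry(family="exponential",
                                 shape_policy={s: 1.0 for s in TREATMENT_STRATA})
        for name, target in Q75_TARGETS_YEARS.items():
            scale = reg.treatment_stratum(name).params[0]
            assert scale == pytest.approx(target / math.log(4 / 3), rel=1e-9)

    def test_recalibration_is_idempotent(self, registry, life_table):
        achieved = {s: registry.seventy_five_percent_survival(s)
                    for s in Q75_TARGETS_YEARS}
        shapes = {s: registry.treatment_stratum(s).params[0]
                  for s in Q75_TARGETS_YEARS}
        again = calibrate_registry(targets=achieved, shape_policy=shapes,
                                   life_table=life_table)
        for s in Q75_TARGETS_YEARS:
            assert again.treatment_stratum(s).params == pytest.approx(
                registry.treatment_stratum(s).params, rel=1e-9)

    def test_life_expectancy_anchors_solved(self, registry, life_table):
        """The shape policy reproduces the group-level life-expectancy
        anchors analytically (palliative exactly; the Status Quo mixture
        through the queue-adjusted target)."""
        pall = registry.treatment_stratum("palliative")
        assert expected_life_years_with_switch(
            pall, 57.0, life_table) == pytest.approx(
                LE_ANCHORS_YEARS["palliative"], abs=1e-6)
        mix_le = sum(
            w * expected_life_years_with_switch(
                registry.treatment_stratum(dx), AGE_AT_LISTING[dx], life_table)
            for dx, w in DEFAULT_DIAGNOSIS_MIX.items())
        from liversim.calibration import _anchor_adjusted

        assert mix_le == pytest.approx(
            _anchor_adjusted(LE_ANCHORS_YEARS["StatusQuoMixture"]), abs=1e-6)

    def test_unattainable_target_raises(self, life_table):
        with pytest.raises(CalibrationError):
            solve_shape_for_life_expectancy(2.0, 500.0, 57.0, life_table)
        with pytest.raises(CalibrationError):
            calibrate_registry(targets={**Q75_TARGETS_YEARS, "HCC": -1.0})

    def test_yaml_round_trip(self, tmp_path, registry):
        path = tmp_path / "registry.yaml"
        registry.to_yaml(path)
        again = SurvivalRegistry.from_yaml(path)
        for s in TREATMENT_STRATA:
            assert again.treatment_stratum(s).params == pytest.approx(
                registry.treatment_stratum(s).params)
        assert again.waitlist_stratum("CRLM", "death").params == \
            registry.waitlist_stratum("HCC", "death").params


class TestQuantileAnchoring:
    @pytest.mark.parametrize("family,shape", [
        ("exponential", 1.0), ("weibull", 1.7), ("log-logistic", 2.2),
        ("log-normal", 0.9), ("gompertz", 0.3),
    ])
    def test_params_for_quantile(self, family, shape):
        for p, target in ((0.25, 2.64), (0.5, 10.0)):
            dist = ParametricSurvival(
                family, params_for_quantile(family, shape, p, target))
            assert dist.quantile(p) == pytest.approx(target, rel=1e-9)

    def test_weibull_tail_swap_matches_at_quantiles(self, registry):
        base = registry.treatment_stratum("SECA2")
        wb = match_weibull_at_quantiles(base)
        assert wb.family == "weibull"
        assert wb.quantile(0.25) == pytest.approx(base.quantile(0.25), rel=1e-9)
        assert wb.quantile(0.5) == pytest.approx(base.quantile(0.5), rel=1e-9)
        # lighter tail than the log-logistic base: poorer long-term survival
        assert wb.sf(20.0) < base.sf(20.0)


def test_default_shape_policy_covers_all_strata(life_table):
    policy = default_shape_policy(life_table)
    assert set(policy) == set(Q75_TARGETS_YEARS)
    assert all(v > 0 for v in policy.values())


def test_registry_report_lists_achieved_quantiles(registry):
    rep = registry.report()
    assert set(rep) == set(TREATMENT_STRATA)
    assert rep["SECA1"]["q75_years"] == pytest.approx(2.64, abs=1e-6)
    assert rep["palliative"]["family"] == "log-logistic"


def test_liver_mix_calibration_fixed_point(registry, life_table):
    """If the base mix already meets the wait targets, it is returned
    unchanged (and normalised to sum 1)."""
    from liversim import ReplicationConfig, ScenarioConfig, run_experiment
    from liversim.calibration import calibrate_liver_blood_mix
    from liversim.population import DEFAULT_LIVER_BLOOD_MIX

    scn = ScenarioConfig(strategy=1, registry=registry, life_table=life_table)
    probe = run_experiment(ReplicationConfig(seed=99, replications=6), scn)
    targets = {b: probe.median_wait_days[b] for b in ("A", "B", "AB", "0")}
    mix, report = calibrate_liver_blood_mix(
        targets, base_mix=dict(DEFAULT_LIVER_BLOOD_MIX), sim_budget=2,
        scenario=scn, replications=6, seed=99)
    assert mix == pytest.approx(DEFAULT_LIVER_BLOOD_MIX)
    assert sum(mix.values()) == pytest.approx(1.0, abs=1e-12)
    assert not report["warning"]
    assert report["evaluations"] <= 2
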