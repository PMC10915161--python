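"""Preset protocols: intensity-zone presets, all-out, TTE curve, step/ramp
tests, AOD-duration curve, intermittent recovery and record calibration."""

import numpy as np
import pytest

from hydrotwin import (
    PowerRecord,
    ValidationError,
    all_out,
    aod_duration_curve,
    calibrate_against_record,
    constant_power_zone_sim,
    critical_power,
    generate_synthetic_race,
    intermittent_recovery,
    lactate_concentration,
    nonox_capacity_physio,
    pc_concentration,
    power_for_tte,
    ramp_test,
    step_test_obla,
    tte_curve,
)

approx = pytest.approx


class TestZonePresets:
    def test_moderate_zone(self, twin1):
        res = constant_power_zone_sim(twin1, 0.95, "lt1", 600.0)
        s = res.summary
        assert s["zone"] == "moderate" and not s["exhausted"]
        assert s["final_l"] <= twin1.theta
        assert s["final_pc_mmolkg"] == approx(12.0, abs=1.0)

    def test_heavy_zone(self, twin1):
        s = constant_power_zone_sim(twin1, 0.80, "pcrit", 600.0).summary
        assert s["zone"] == "heavy" and not s["exhausted"]
        assert twin1.theta <= s["final_l"] <= twin1.l_crit
        assert s["final_pc_mmolkg"] == approx(11.0, abs=1.0)
        assert s["final_la_mmolkg"] == approx(6.0, abs=1.0)

    def test_severe_zone_exhausts_below_critical_drain(self, twin1):
        s = constant_power_zone_sim(twin1, 1.05, "pcrit", 1200.0).summary
        assert s["zone"] == "severe" and s["exhausted"]
        assert s["t_exhaustion_s"] < 1200.0
        assert s["final_l"] < twin1.l_crit
        assert s["final_pc_mmolkg"] == approx(9.0, abs=1.5)
        assert s["final_la_mmolkg"] == approx(18.0, abs=1.5)

    def test_summary_recomputable_from_trace(self, twin1, constants):
        res = constant_power_zone_sim(twin1, 0.8, "pcrit", 120.0)
        tr = res.traces[0]
        assert res.summary["final_pc_mmolkg"] == approx(
            float(pc_concentration(tr.h[-1], constants)))
        assert res.summary["final_la_mmolkg"] == approx(
            float(lactate_concentration(tr.l[-1], twin1, constants)))

    def test_bad_arguments(self, twin1):
        with pytest.raises(ValidationError):
            constant_power_zone_sim(twin1, -0.5)
        with pytest.raises(ValidationError):
            constant_power_zone_sim(twin1, 0.9, "obla")


class TestAllOut:
    def test_three_minute_trial(self, twin1):
        res = all_out(twin1, 180.0)
        s = res.summary
        assert s["peak_power_mec_w"] == approx(twin1.eta * twin1.m_p)
        crit = critical_power(twin1, mechanical=True)
        assert s["end_power_mec_w"] == approx(crit, rel=0.05)
        p = res.traces[0].p_physio
        assert np.all(np.diff(p) <= 1e-9)  # monotone nonincreasing

    def test_longer_trial_converges_closer_to_critical_power(self, twin1):
        crit = critical_power(twin1, mechanical=True)
        e180 = abs(all_out(twin1, 180.0).summary["end_power_mec_w"] - crit)
        e600 = abs(all_out(twin1, 600.0).summary["end_power_mec_w"] - crit)
        assert e600 < e180

    def test_nonox_work_estimate_near_capacity(self, twin1):
        s = all_out(twin1, 180.0).summary
        cap_mec = twin1.eta * nonox_capacity_physio(twin1)
        assert s["w_nonox_estimate_j"] == approx(cap_mec, rel=0.1)


class TestTTECurve:
    def test_monotone_with_subcritical_marked(self, twin1):
        crit = critical_power(twin1, mechanical=True)
        res = tte_curve(twin1, [0.9 * crit, 1.1 * crit, 1.3 * crit, 2.0 * crit])
        tte = res.summary["tte_s"]
        assert np.isnan(tte[0])
        assert tte[1] > tte[2] > tte[3] > 0

    def test_product_with_margin_grows_but_stays_bounded(self, twin1):
        """(p - p_crit)·TTE is not a constant W': near critical power the
        time to exhaustion diverges only logarithmically, so the product
        shrinks toward zero there and grows with the power margin — while
        never exceeding the mechanical non-oxidative capacity."""
        crit = critical_power(twin1, mechanical=True)
        fracs = (1.05, 1.1, 1.2, 1.4)
        prods = []
        for f in fracs:
            res = tte_curve(twin1, [f * crit])
            prods.append((f - 1) * crit * res.summary["tte_s"][0])
        assert all(p > 0 for p in prods)
        assert all(a < b for a, b in zip(prods, prods[1:]))
        cap_mec = twin1.eta * nonox_capacity_physio(twin1)
        assert all(p < cap_mec for p in prods)


class TestStepTest:
    def test_lactate_nondecreasing_and_obla_fraction(self, twin1):
        res = step_test_obla(twin1)
        la = res.summary["stage_end_la_mmolkg"]
        assert la[0] <= la[1] <= la[2]
        # second stage sits at the OBLA definition: ~60% of VO2max
        assert res.summary["stage_end_pct_vo2max"][1] == approx(0.60, abs=0.01)

    def test_rest_stages_clear_lactate(self, twin1, constants):
        res = step_test_obla(twin1)
        tr = res.traces[0]
        # end of first rest (t=300) vs end of first stage (t=180)
        i_work = np.searchsorted(tr.t, 180.0)
        i_rest = np.searchsorted(tr.t, 300.0)
        la = lactate_concentration(tr.l, twin1, constants)
        assert la[i_rest] < la[i_work]

    def test_obla_below_delta_rejected(self, twin1):
        with pytest.raises(ValidationError, match="not positive"):
            step_test_obla(twin1, delta_w=1e6)


class TestRampTest:
    def test_lactate_increases_across_samples(self, twin1):
        res = ramp_test(twin1)
        la = res.summary["la_mmolkg"]
        assert all(res.summary["reached"])
        assert la[0] == approx(1.5)
        assert all(a < b for a, b in zip(la, la[1:]))

    def test_slower_ramp_accumulates_more_lactate(self, twin1):
        fast = ramp_test(twin1, increment_w_per_min=20.0)
        slow = ramp_test(twin1, increment_w_per_min=10.0)
        for a, b in zip(slow.summary["la_mmolkg"][1:], fast.summary["la_mmolkg"][1:]):
            assert a >= b


class TestAODCurve:
    def test_curve_shape_bound_and_plateau(self, twin1, constants):
        res = aod_duration_curve(twin1)
        s = res.summary
        aod = np.asarray(s["aod_ml"])
        assert np.all(np.isfinite(aod))
        assert np.all(np.diff(aod) >= -1e-9)
        assert s["aod_sup_ml"] <= s["bound_ml"] * (1 + 1e-6)
        # plateau (95% of supremum) in the low minutes, far above the
        # shortest trials
        assert 120.0 <= s["plateau_duration_s"] <= 300.0
        assert aod[0] < 0.90 * s["aod_sup_ml"]

    def test_supremum_approaches_drainable_energy(self, twin1, constants):
        res = aod_duration_curve(twin1, duration_targets=(600.0, 720.0))
        assert res.summary["aod_sup_ml"] == approx(res.summary["bound_ml"], rel=0.02)

    def test_power_for_tte_hits_target(self, twin1):
        p, tte = power_for_tte(twin1, 240.0)
        assert abs(tte - 240.0) <= 1.0
        assert p > critical_power(twin1, mechanical=True)

    def test_out_of_range_targets_rejected(self, twin1):
        with pytest.raises(ValidationError):
            aod_duration_curve(twin1, duration_targets=(10.0,))


class TestIntermittentRecovery:
    def test_zero_recovery_time_gives_zero_recovery(self, twin1):
        s = intermittent_recovery(twin1, recovery_duration=0.0).summary
        assert s["pct_recovery"] == approx(0.0, abs=1.0)

    def test_monotone_in_duration_and_fraction(self, twin1):
        base = dict(recovery_fraction=0.5)
        r_short = intermittent_recovery(twin1, recovery_duration=120.0, **base)
        r_long = intermittent_recovery(twin1, recovery_duration=480.0, **base)
        assert r_long.summary["pct_recovery"] >= r_short.summary["pct_recovery"]
        r_low = intermittent_recovery(twin1, recovery_fraction=0.2, recovery_duration=240.0)
        r_high = intermittent_recovery(twin1, recovery_fraction=0.8, recovery_duration=240.0)
        assert r_low.summary["pct_recovery"] >= r_high.summary["pct_recovery"]

    def test_long_easy_recovery_approaches_full(self, twin1):
        s = intermittent_recovery(twin1, recovery_fraction=0.05,
                                  recovery_duration=3000.0).summary
        assert s["pct_recovery"] > 95.0
        assert s["pct_recovery"] <= 100.0 + 1e-6

    def test_subcritical_work_power_rejected(self, twin1):
        with pytest.raises(ValidationError, match="critical"):
            intermittent_recovery(
                twin1, p_work=0.9 * critical_power(twin1, mechanical=True))


class TestCalibration:
    def test_constant_submaximal_record_has_wide_margin(self, twin1):
        crit = critical_power(twin1, mechanical=True)
        t = np.arange(0.0, 301.0, 1.0)
        rec = PowerRecord(t, np.full(t.size, 0.90 * crit), source="test")
        s = calibrate_against_record(twin1, rec).summary
        assert not s["exhausted"]
        # increments keeping demand below critical power can never exhaust
        assert s["margin_w"] > 0.09 * crit

    def test_synthetic_near_limit_race_has_small_margin(self, twin1):
        rec = generate_synthetic_race(twin1, duration=300.0, seed=3, drain_target=0.99)
        s = calibrate_against_record(twin1, rec).summary
        assert not s["exhausted"]
        assert s["margin_w"] is not None and s["margin_w"] <= 10.0
        assert not s["needs_adjustment"]

    def test_gap_detection(self, twin1):
        rec = PowerRecord(np.array([0.0, 1.0, 20.0]), np.array([100.0, 100.0, 100.0]))
        with pytest.raises(ValidationError, match="gaps"):
            calibrate_against_record(twin1, rec)
        calibrate_against_record(twin1, rec, interpolate=True)  # no raise
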