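"""Twin-building pipeline: per-stage formulas, the published parameter sets
round-trip, and structural invariants."""

import dataclasses
import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydrotwin import (
    AthleteTestData,
    TwinParameters,
    ValidationError,
    build_twin,
    compute_AG,
    compute_capacities,
    compute_direct_flows,
    compute_efficiency,
    compute_glycolytic_flows,
    compute_heights,
    compute_l_crit,
    compute_muscle_mass,
    load_fixture,
    reconcile_muscle_mass,
)

approx = pytest.approx


def athlete(**over):
    """A plausible endurance cyclist as a baseline test subject."""
    base = dict(
        m_athlete=64.0, pct_muscle=0.40, pct_muscle_for_task=0.50,
        vo2max=66.67, p_max_mec=1000.0, p_lt1_mec=210.0, alpha=0.60,
        p_crit_mec=290.0, w_nonox_mec=17000.0,
    )
    base.update(over)
    return AthleteTestData(**base)


class TestStages:
    def test_muscle_mass_is_product_of_fractions(self):
        assert compute_muscle_mass(athlete()) == approx(12.8)
        d = athlete(pct_muscle=0.999999, pct_muscle_for_task=1.0)
        assert compute_muscle_mass(d) == approx(64.0, rel=1e-5)

    @pytest.mark.parametrize("bad", [
        dict(pct_muscle=0.0), dict(pct_muscle=1.2),
        dict(pct_muscle_for_task=0.0), dict(m_athlete=-60.0),
    ])
    def test_fraction_validation(self, bad):
        with pytest.raises(ValidationError):
            athlete(**bad)

    def test_efficiency_at_lt1_working_point(self):
        # eta = P_LT1 / (alpha · VO2max · C1) = 210/(0.60·66.67·20.9)
        eta = compute_efficiency(athlete())
        assert eta == approx(0.2512, abs=2e-4)

    def test_efficiency_is_linear_in_lt1_power_and_one_at_parity(self):
        e1 = compute_efficiency(athlete())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            e2 = compute_efficiency(athlete(p_lt1_mec=2 * 210.0, p_crit_mec=500.0,
                                            p_max_mec=1200.0))
            assert e2 == approx(2 * e1)
            # alpha·vo2max·C1 == p_lt1 -> ratio of equal quantities
            d = athlete(alpha=0.999999, vo2max=210.0 / 20.9)
            assert compute_efficiency(d) == approx(1.0, rel=1e-5)

    def test_efficiency_warns_outside_typical_range(self):
        with pytest.warns(UserWarning, match="efficiency"):
            compute_efficiency(athlete(p_lt1_mec=100.0))

    def test_direct_flows(self):
        d = athlete(vo2max=68.33)
        m_o, m_p = compute_direct_flows(d, eta=0.25)
        assert m_o == approx(1428.1, abs=0.5)   # VO2max 4.1 L/min in energy units
        assert m_p == approx(4000.0)
        _, m_p1 = compute_direct_flows(d, eta=1.0)
        assert m_p1 == approx(d.p_max_mec)

    def test_heights_recover_first_published_column(self):
        theta, lam = compute_heights(0.6143, 0.8192, 1340.0, 4480.0, 0.30)
        assert theta == approx(0.43, abs=1e-3)
        assert lam == approx(0.38, abs=1e-3)

    def test_heights_limit_when_thresholds_coincide(self):
        theta, lam = compute_heights(0.6, 0.6 + 1e-12, 1340.0, 4480.0, 0.30)
        assert lam == approx(1 - theta, abs=1e-6)

    def test_theta_linear_in_alpha(self):
        t1, _ = compute_heights(0.3, 0.8, 1340.0, 4480.0, 0.30)
        t2, _ = compute_heights(0.6, 0.8, 1340.0, 4480.0, 0.30)
        assert t2 == approx(2 * t1)

    def test_heights_degenerate_geometry_rejected(self):
        # 1/beta <= M_O/M_P: tap cannot express the critical threshold
        with pytest.raises(ValidationError, match="degenerate"):
            compute_heights(0.5, 0.9, 5000.0, 4200.0, 0.30)

    def test_l_crit_published_value_and_limits(self, twin1):
        assert compute_l_crit(twin1) == approx(0.5734, abs=1e-3)
        # algebraic limits of the fatigue law: demand at M_P leaves no margin
        # (l -> theta); zero demand drains the whole main section (l -> 1-lam)
        span = 1 - twin1.lam - twin1.theta
        assert (1 - twin1.lam) - twin1.m_p * span / twin1.m_p == approx(twin1.theta)
        assert (1 - twin1.lam) - 0.0 * span / twin1.m_p == approx(1 - twin1.lam)

    def test_capacities(self, constants):
        a_p, _ = compute_capacities(32.09, 0.43, constants)
        assert a_p == approx(27790.0, rel=2e-4)
        _, a_t = compute_capacities(38.2, 0.55, constants)
        assert a_t == approx(10418.0, rel=1e-3)  # vs printed 10.37 kJ
        with pytest.raises(ValidationError):
            compute_capacities(0.0, 0.43, constants)

    def test_ag_round_trip_on_first_cyclist(self, twin1):
        w_over_eta = (twin1.a_g * (twin1.l_crit - twin1.theta)
                      + twin1.a_p * twin1.l_crit + twin1.a_t * twin1.theta)
        assert w_over_eta == approx(66.7e3, rel=1e-3)
        a_g = compute_AG(w_over_eta * twin1.eta, twin1.eta, twin1.a_p, twin1.a_t,
                         twin1.theta, twin1.l_crit)
        assert a_g == approx(twin1.a_g, rel=1e-9)

    def test_ag_boundary_and_linearity(self, twin1):
        w_eta_boundary = twin1.a_p * twin1.l_crit + twin1.a_t * twin1.theta
        with pytest.raises(ValidationError, match="too small"):
            compute_AG(w_eta_boundary * twin1.eta, twin1.eta, twin1.a_p, twin1.a_t,
                       twin1.theta, twin1.l_crit)
        a1 = compute_AG(60e3, 0.25, twin1.a_p, twin1.a_t, twin1.theta, twin1.l_crit)
        a2 = compute_AG(70e3, 0.25, twin1.a_p, twin1.a_t, twin1.theta, twin1.l_crit)
        slope = (a2 - a1) / 10e3
        assert slope == approx(1 / (0.25 * (twin1.l_crit - twin1.theta)), rel=1e-9)

    def test_glycolytic_flows(self, constants):
        m_g, m_r = compute_glycolytic_flows(32.09, constants)
        assert m_g == approx(9145.6, abs=0.5)
        assert m_r == approx(m_g / 2.5)
        m_g4, m_r4 = compute_glycolytic_flows(32.3, constants, m_g_override=6130.0)
        assert m_g4 == 6130.0 and m_r4 == approx(2452.0)


class TestPublishedTwins:
    """Round-trip: back-derived inputs rebuild every printed parameter."""

    PRINTED_FIELDS = {
        "phi": "phi", "theta": "theta", "lambda": "lam",
        "m_o": "m_o", "m_p": "m_p", "m_g": "m_g", "m_r": "m_r",
        "a_p": "a_p", "a_g": "a_g", "a_t": "a_t",
    }

    def test_round_trip_within_one_percent(self, each_fixture):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rebuilt = build_twin(each_fixture.athlete)
        for key, field in self.PRINTED_FIELDS.items():
            printed = each_fixture.printed[key]
            scale = 1.0 if key in ("phi", "theta", "lambda") else 1e3
            assert getattr(rebuilt, field) / scale == approx(printed, rel=0.01), key

    def test_mr_is_mg_over_two_and_a_half(self, each_fixture):
        p = each_fixture.printed
        # holds to the rounding of the printed 3-significant-figure values
        assert p["m_r"] == approx(p["m_g"] / 2.5, rel=5e-3)

    def test_height_ordering(self, each_fixture):
        t = each_fixture.twin
        assert t.theta + t.lam < 1
        assert t.theta < t.l_crit < 1 - t.lam

    def test_build_is_deterministic(self, cyclist1):
        a = build_twin(cyclist1.athlete)
        b = build_twin(cyclist1.athlete)
        assert a == b  # bit-identical dataclass equality


class TestReconciliation:
    def test_first_cyclist_is_self_consistent(self, cyclist1):
        rec = reconcile_muscle_mass(cyclist1.twin)
        assert rec.m_from_a_p == approx(32.1, abs=0.1)
        assert rec.max_rel_deviation < 0.01
        assert not rec.flagged

    def test_fourth_cyclist_glycolytic_flow_is_flagged(self):
        fx = load_fixture("cyclist_4")
        with pytest.warns(UserWarning, match="disagree"):
            rec = reconcile_muscle_mass(fx.twin)
        assert rec.m_from_m_g == approx(21.5, abs=0.1)
        assert rec.max_rel_deviation > 0.30
        assert rec.flagged

    def test_freshly_built_twin_reconciles_exactly(self):
        rec = reconcile_muscle_mass(build_twin(athlete()))
        assert rec.max_rel_deviation == approx(0.0, abs=1e-12)


class TestValidation:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValidationError, match="thresholds"):
            athlete(p_crit_mec=1100.0)

    def test_beta_above_one_warns_but_far_above_errors(self):
        with pytest.warns(UserWarning, match="beta"):
            athlete(beta=1.02)
        with pytest.raises(ValidationError):
            athlete(beta=1.2)

    def test_capillary_must_be_smaller_than_main_section(self, twin1):
        with pytest.raises(ValidationError, match="a_t"):
            dataclasses.replace(twin1, a_t=twin1.a_g * 2)

    def test_mr_ratio_enforced_on_twins(self, twin1):
        with pytest.raises(ValidationError, match="M_G/M_R"):
            dataclasses.replace(twin1, m_r=twin1.m_g / 2.0)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(c=st.floats(min_value=0.5, max_value=2.0))
def test_power_scale_homogeneity(c):
    """Scaling all measured powers, VO2max and W_nonox by c scales every flow
    and capacity by c and leaves the dimensionless geometry untouched."""
    base = athlete()
    scaled = AthleteTestData(
        m_athlete=base.m_athlete * c, pct_muscle=base.pct_muscle,
        pct_muscle_for_task=base.pct_muscle_for_task,
        vo2max=base.vo2max * c, p_max_mec=base.p_max_mec * c,
        p_lt1_mec=base.p_lt1_mec * c, alpha=base.alpha,
        p_crit_mec=base.p_crit_mec * c, w_nonox_mec=base.w_nonox_mec * c,
    )
    t0, t1 = build_twin(base), build_twin(scaled)
    for f in ("phi", "theta", "lam", "eta"):
        assert getattr(t1, f) == approx(getattr(t0, f), rel=1e-9)
    for f in ("m_o", "m_p", "m_g", "m_r", "a_p", "a_g", "a_t"):
        assert getattr(t1, f) == approx(c * getattr(t0, f), rel=1e-9)


def test_scaled_twin_constructor(twin1):
    t2 = twin1.scaled(1.5)
    assert isinstance(t2, TwinParameters)
    assert t2.l_crit == approx(twin1.l_crit, rel=1e-12)
    assert t2.m_o == approx(1.5 * twin1.m_o)
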