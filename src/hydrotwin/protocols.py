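"""Preset exercise protocols.

Each protocol runs the simulator under a standard exercise prescription and
summarizes the physiologically interesting scalars.  Summaries are always
recomputable from the returned traces — protocols keep no hidden state.

Included: constant power in the three intensity domains, the 3-min all-out
trial, time-to-exhaustion curves, a three-stage OBLA step test, a continuous
incremental ramp with lactate sampling, the accumulated-oxygen-deficit
versus duration curve, work/recovery/work intermittent bouts, and
calibration of a twin against a recorded maximal effort.

Mechanical powers are the user-facing currency here; conversion to the
physiological demand (division by the efficiency) happens on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS, PhysioConstants
from .dynamics import (
    DEFAULT_DT,
    HydraulicState,
    SimulationTrace,
    critical_power,
    lt1_power,
    simulate,
    steady_state,
    time_to_exhaustion,
)
from .errors import ValidationError
from .io import PowerRecord
from .observables import (
    accumulated_o2_deficit,
    lactate_concentration,
    pc_concentration,
    vo2_of,
)
from .twin import TwinParameters

__all__ = [
    "ProtocolResult",
    "constant_power_zone_sim",
    "all_out",
    "tte_curve",
    "step_test_obla",
    "ramp_test",
    "aod_duration_curve",
    "intermittent_recovery",
    "calibrate_against_record",
    "nonox_capacity_physio",
    "drain_fraction",
    "power_for_tte",
]


@dataclass
class ProtocolResult:
    """Traces plus protocol-specific scalar summary."""

    name: str
    params: dict
    traces: list[SimulationTrace]
    summary: dict = field(default_factory=dict)


def nonox_capacity_physio(twin: TwinParameters) -> float:
    """Total drainable non-oxidative energy down to the critical level, J:
    ``A_P·l_crit + A_T·theta + A_G·(l_crit - theta)``."""
    return (
        twin.a_p * twin.l_crit
        + twin.a_t * twin.theta
        + twin.a_g * (twin.l_crit - twin.theta)
    )


def drain_fraction(h: float, l: float, twin: TwinParameters) -> float:
    """Fraction of the critical-level non-oxidative capacity drained at (h, l)."""
    drained = (
        twin.a_p * h
        + twin.a_t * min(l, twin.theta)
        + twin.a_g * max(l - twin.theta, 0.0)
    )
    return drained / nonox_capacity_physio(twin)


# ---------------------------------------------------------------------------
# Constant power
# ---------------------------------------------------------------------------

def constant_power_zone_sim(
    twin: TwinParameters,
    p_fraction: float,
    reference: str = "lt1",
    duration: float = 600.0,
    dt: float = DEFAULT_DT,
    k: PhysioConstants = DEFAULT_CONSTANTS,
) -> ProtocolResult:
    """Constant-power bout at a fraction of a threshold power.

    ``reference`` is ``'lt1'`` (first lactate threshold) or ``'pcrit'``
    (critical power); the demand is ``p_fraction`` times it, expressed
    physiologically so the intensity domain does not depend on efficiency.
    """
    if p_fraction <= 0:
        raise ValidationError(f"p_fraction must be > 0, got {p_fraction}")
    if reference not in ("lt1", "pcrit"):
        raise ValidationError(f"reference must be 'lt1' or 'pcrit', got {reference!r}")
    ref = lt1_power(twin) if reference == "lt1" else critical_power(twin)
    p_physio = p_fraction * ref
    tr = simulate(p_physio, twin, duration, dt=dt)
    if p_physio <= lt1_power(twin):
        zone = "moderate"
    elif p_physio <= critical_power(twin):
        zone = "heavy"
    else:
        zone = "severe"
    ss = steady_state(p_physio, twin)
    fin = tr.final
    summary = {
        "zone": zone,
        "p_physio_w": p_physio,
        "p_mec_w": p_physio * twin.eta,
        "exhausted": tr.exhausted,
        "t_exhaustion_s": tr.t_exhaustion,
        "final_h": fin.h,
        "final_l": fin.l,
        "final_pc_mmolkg": float(pc_concentration(fin.h, k)),
        "final_la_mmolkg": float(lactate_concentration(fin.l, twin, k)),
        "steady_h": ss[0] if ss else None,
        "steady_l": ss[1] if ss else None,
    }
    return ProtocolResult(
        "constant_power", {"p_fraction": p_fraction, "reference": reference,
                           "duration": duration, "dt": dt},
        [tr], summary,
    )


# ---------------------------------------------------------------------------
# All-out and TTE
# ---------------------------------------------------------------------------

def all_out(
    twin: TwinParameters,
    duration: float = 180.0,
    dt: float = DEFAULT_DT,
) -> ProtocolResult:
    """All-out trial: the demand tracks the fatigue-limited maximum.

    The end power estimates the critical power; the work above end power
    estimates the non-oxidative capacity; the first sample is the true
    maximal power without prior fatigue.
    """
    if duration <= 0:
        raise ValidationError(f"duration must be > 0, got {duration}")
    tr = simulate(0.0, twin, duration, dt=dt, all_out=True)
    p_mec = twin.eta * tr.p_physio
    end_power = float(p_mec[-1])
    w_above_end = float(np.trapezoid(p_mec - end_power, tr.t))
    summary = {
        "peak_power_mec_w": float(p_mec[0]),
        "end_power_mec_w": end_power,
        "critical_power_estimate_mec_w": end_power,
        "critical_power_analytic_mec_w": critical_power(twin, mechanical=True),
        "w_nonox_estimate_j": w_above_end,
    }
    return ProtocolResult("all_out", {"duration": duration, "dt": dt}, [tr], summary)


def tte_curve(
    twin: TwinParameters,
    power_grid: list[float] | np.ndarray,
    t_cap: float = 1800.0,
    dt: float = DEFAULT_DT,
) -> ProtocolResult:
    """Time to exhaustion over a grid of mechanical powers.

    Grid points at or below critical power are marked unsustainable-never
    (``nan`` in the summary).
    """
    powers = [float(p) for p in power_grid]
    ttes = [time_to_exhaustion(p, twin, t_cap=t_cap, dt=dt) for p in powers]
    summary = {
        "powers_mec_w": powers,
        "tte_s": [t if t is not None else float("nan") for t in ttes],
        "critical_power_mec_w": critical_power(twin, mechanical=True),
    }
    return ProtocolResult("tte_curve", {"t_cap": t_cap, "dt": dt}, [], summary)


# ---------------------------------------------------------------------------
# Literature protocols
# ---------------------------------------------------------------------------

def _chained(
    twin: TwinParameters,
    stages: list[tuple[float, float]],
    dt: float,
) -> tuple[SimulationTrace, list[int]]:
    """Simulate mechanical-power stages back to back; return the joined
    trace and the sample index of each stage end."""
    state = HydraulicState(0.0, 0.0, 0.0)
    full: SimulationTrace | None = None
    ends: list[int] = []
    for dur, p_mec in stages:
        tr = simulate(p_mec / twin.eta, twin, dur, dt=dt,
                      stop_on_exhaustion=False, initial_state=state)
        state = tr.final
        full = tr if full is None else full.concat(tr)
        ends.append(len(full) - 1)
    return full, ends


def step_test_obla(
    twin: TwinParameters,
    delta_w: float = 50.0,
    stage_s: float = 180.0,
    rest_s: float = 120.0,
    dt: float = DEFAULT_DT,
    k: PhysioConstants = DEFAULT_CONSTANTS,
) -> ProtocolResult:
    """Three-stage step test around the onset of blood lactate accumulation.

    OBLA power is taken as 60% of the V̇O₂max-equivalent mechanical power
    (``0.60·eta·M_O``); the protocol runs 3 min at OBLA-50 W, 2 min rest,
    3 min at OBLA, 2 min rest, 3 min at OBLA+50 W.  Muscle lactate and
    %V̇O₂max are read at each work-stage end.
    """
    p_obla = 0.60 * twin.eta * twin.m_o
    if p_obla - delta_w <= 0:
        raise ValidationError(
            f"OBLA power {p_obla:.0f} W minus {delta_w:.0f} W is not positive"
        )
    stages = [
        (stage_s, p_obla - delta_w), (rest_s, 0.0),
        (stage_s, p_obla), (rest_s, 0.0),
        (stage_s, p_obla + delta_w),
    ]
    tr, ends = _chained(twin, stages, dt)
    work_ends = [ends[0], ends[2], ends[4]]
    la = [float(lactate_concentration(tr.l[i], twin, k)) for i in work_ends]
    pct = [float(vo2_of(tr.h[i], twin, k)[1]) for i in work_ends]
    summary = {
        "p_obla_mec_w": p_obla,
        "stage_powers_mec_w": [p_obla - delta_w, p_obla, p_obla + delta_w],
        "stage_end_la_mmolkg": la,
        "stage_end_pct_vo2max": pct,
        "exhausted": tr.exhausted,
    }
    return ProtocolResult(
        "step_test_obla",
        {"delta_w": delta_w, "stage_s": stage_s, "rest_s": rest_s, "dt": dt},
        [tr], summary,
    )


def ramp_test(
    twin: TwinParameters,
    increment_w_per_min: float = 13.6,
    sample_at: tuple[float, ...] = (0.0, 0.80, 0.95, 1.10),
    reference: str = "pcrit",
    dt: float = DEFAULT_DT,
    k: PhysioConstants = DEFAULT_CONSTANTS,
) -> ProtocolResult:
    """Continuous incremental ramp with muscle-lactate sampling.

    Power rises from 0 W at a constant rate; muscle lactate is read when the
    instantaneous power crosses each requested fraction of the reference
    threshold (critical power by default, standing in for the second
    lactate / "anaerobic" threshold).
    """
    if increment_w_per_min <= 0:
        raise ValidationError("increment must be > 0")
    if reference not in ("lt1", "pcrit"):
        raise ValidationError(f"reference must be 'lt1' or 'pcrit', got {reference!r}")
    p_ref = (lt1_power if reference == "lt1" else critical_power)(twin, mechanical=True)
    rate = increment_w_per_min / 60.0  # W/s, mechanical
    t_end = max(sample_at) * p_ref / rate + 2 * dt
    tr = simulate(lambda t: rate * t / twin.eta, twin, t_end, dt=dt,
                  stop_on_exhaustion=True)
    la, reached = [], []
    for frac in sample_at:
        t_cross = frac * p_ref / rate
        i = int(round(t_cross / dt))
        if i < len(tr):
            la.append(float(lactate_concentration(tr.l[i], twin, k)))
            reached.append(True)
        else:
            la.append(float("nan"))
            reached.append(False)
    summary = {
        "sample_fractions": list(sample_at),
        "sample_powers_mec_w": [f * p_ref for f in sample_at],
        "la_mmolkg": la,
        "reached": reached,
        "exhausted": tr.exhausted,
        "t_exhaustion_s": tr.t_exhaustion,
    }
    return ProtocolResult(
        "ramp_test",
        {"increment_w_per_min": increment_w_per_min, "reference": reference, "dt": dt},
        [tr], summary,
    )


# ---------------------------------------------------------------------------
# AOD-duration curve
# ---------------------------------------------------------------------------

def power_for_tte(
    twin: TwinParameters,
    target_s: float,
    dt: float = DEFAULT_DT,
    tol_s: float = 1.0,
) -> tuple[float, float] | None:
    """Bisect the constant mechanical power whose time to exhaustion equals
    ``target_s`` within ``tol_s``.  Returns (power, tte) or None when the
    target is unattainable (shorter than the fastest possible exhaustion)."""
    lo = critical_power(twin, mechanical=True) * (1.0 + 1e-6)
    hi = twin.eta * twin.m_p
    t_cap = target_s * 2.0 + 120.0
    tte_hi = time_to_exhaustion(hi, twin, t_cap=t_cap, dt=dt)
    if tte_hi is not None and tte_hi > target_s:
        return None  # even maximal power lasts longer than the target
    best = None
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        tte = time_to_exhaustion(mid, twin, t_cap=t_cap, dt=dt)
        if tte is None or tte > target_s:
            lo = mid
        else:
            hi = mid
            best = (mid, tte)
        if tte is not None and abs(tte - target_s) <= tol_s:
            return mid, tte
        if hi - lo < 1e-4:
            break
    return best


def aod_duration_curve(
    twin: TwinParameters,
    duration_targets: tuple[float, ...] = tuple(60.0 * m for m in range(1, 13)),
    dt: float = DEFAULT_DT,
    plateau_fraction: float = 0.95,
    k: PhysioConstants = DEFAULT_CONSTANTS,
) -> ProtocolResult:
    """Accumulated O2 deficit at exhaustion versus exhaustion duration.

    For each target duration the constant power is found by bisection so the
    time to exhaustion matches it (1 s tolerance); the AOD is then read at
    exhaustion.  The summary reports the shortest duration whose AOD reaches
    ``plateau_fraction`` of the curve's supremum, and the theoretical bound
    (total drainable non-oxidative energy over C1).
    """
    for target in duration_targets:
        if not 30.0 <= target <= 900.0:
            raise ValidationError(f"duration target {target} s outside 0.5-15 min")
    durations, powers, aods = [], [], []
    traces = []
    for target in duration_targets:
        found = power_for_tte(twin, target, dt=dt)
        if found is None:
            durations.append(target)
            powers.append(float("nan"))
            aods.append(float("nan"))
            continue
        p_mec, tte = found
        tr = simulate(p_mec / twin.eta, twin, tte + 60.0, dt=dt)
        traces.append(tr)
        durations.append(target)
        powers.append(p_mec)
        aods.append(accumulated_o2_deficit(tr, k))
    aod_arr = np.asarray(aods)
    sup = float(np.nanmax(aod_arr))
    plateau = None
    for d, a in zip(durations, aod_arr):
        if np.isfinite(a) and a >= plateau_fraction * sup:
            plateau = d
            break
    summary = {
        "durations_s": durations,
        "powers_mec_w": powers,
        "aod_ml": aods,
        "aod_sup_ml": sup,
        "plateau_duration_s": plateau,
        "bound_ml": nonox_capacity_physio(twin) / k.c1,
    }
    return ProtocolResult(
        "aod_duration_curve",
        {"duration_targets": list(duration_targets), "dt": dt,
         "plateau_fraction": plateau_fraction},
        traces, summary,
    )


# ---------------------------------------------------------------------------
# Intermittent recovery
# ---------------------------------------------------------------------------

def intermittent_recovery(
    twin: TwinParameters,
    p_work: float | None = None,
    recovery_fraction: float = 0.50,
    recovery_duration: float = 360.0,
    tte1_target: float = 240.0,
    dt: float = DEFAULT_DT,
) -> ProtocolResult:
    """Work-to-exhaustion / recovery / work-to-exhaustion bouts.

    Both work bouts use the same supra-critical mechanical power ``p_work``
    (bisected so the first bout lasts ``tte1_target`` seconds when not
    given); the recovery phase runs at ``recovery_fraction`` of critical
    power.  The percentage recovery is the second-to-first bout time ratio,
    ``100·TTE2/TTE1`` — under the linearized tank model with equal-power
    bouts, this equals the fraction of the non-oxidative capacity
    reconstituted during recovery.
    """
    if not 0.0 <= recovery_fraction < 1.0:
        raise ValidationError(f"recovery_fraction must lie in [0,1), got {recovery_fraction}")
    if recovery_duration < 0:
        raise ValidationError("recovery_duration must be >= 0")
    if p_work is None:
        found = power_for_tte(twin, tte1_target, dt=dt)
        if found is None:
            raise ValidationError(f"no power yields a {tte1_target:.0f}-s first bout")
        p_work = found[0]
    p_crit_mec = critical_power(twin, mechanical=True)
    if p_work <= p_crit_mec:
        raise ValidationError(
            f"p_work ({p_work:.0f} W) must exceed critical power ({p_crit_mec:.0f} W)"
        )
    p_physio = p_work / twin.eta
    bout1 = simulate(p_physio, twin, 3600.0, dt=dt)
    if not bout1.exhausted:
        raise ValidationError("first bout did not reach exhaustion")
    tte1 = bout1.t_exhaustion
    traces = [bout1]
    state = bout1.final
    if recovery_duration > 0:
        rec = simulate(recovery_fraction * p_crit_mec / twin.eta, twin,
                       recovery_duration, dt=dt, initial_state=state)
        traces.append(rec)
        state = rec.final
    bout2 = simulate(p_physio, twin, tte1 * 1.5 + 60.0, dt=dt, initial_state=state)
    traces.append(bout2)
    if bout2.exhausted:
        tte2 = bout2.t_exhaustion - state.t
    else:
        tte2 = bout2.final.t - state.t  # conservative: cap reached
    summary = {
        "p_work_mec_w": p_work,
        "recovery_power_mec_w": recovery_fraction * p_crit_mec,
        "tte1_s": tte1,
        "tte2_s": tte2,
        "pct_recovery": 100.0 * tte2 / tte1,
    }
    return ProtocolResult(
        "intermittent_recovery",
        {"recovery_fraction": recovery_fraction,
         "recovery_duration": recovery_duration, "dt": dt},
        traces, summary,
    )


# ---------------------------------------------------------------------------
# Record calibration
# ---------------------------------------------------------------------------

def calibrate_against_record(
    twin: TwinParameters,
    power_record: PowerRecord,
    margin_step: float = 5.0,
    interpolate: bool = False,
    dt: float = DEFAULT_DT,
) -> ProtocolResult:
    """Check a twin against a recorded maximal effort.

    Simulates the recorded mechanical demand and reports whether exhaustion
    occurred; then finds the smallest uniform power increment (in
    ``margin_step`` units) that makes the twin exhaust before the finish.  A
    well-calibrated twin survives the record itself but fails within a few
    watts.  Twins that exhaust well before the finish, or survive very large
    increments, are flagged for parameter adjustment.
    """
    if margin_step <= 0:
        raise ValidationError("margin_step must be > 0")
    gaps = np.diff(power_record.time_s)
    if gaps.size and float(np.max(gaps)) > 5.0 and not interpolate:
        raise ValidationError(
            f"record has gaps up to {float(np.max(gaps)):.1f} s > 5 s; "
            "enable interpolation to proceed"
        )
    base_fn = power_record.demand_fn()
    t0 = float(power_record.time_s[0])
    duration = power_record.duration
    eta = twin.eta

    def run(extra_w: float) -> SimulationTrace:
        return simulate(lambda t: (base_fn(t0 + t) + extra_w) / eta, twin,
                        duration, dt=dt, record=False)

    base = run(0.0)
    exhausted_early = base.exhausted and base.t_exhaustion < 0.95 * duration
    margin = None
    if base.exhausted:
        margin = 0.0
    else:
        k_max = int(np.ceil(twin.eta * twin.m_p / margin_step)) + 1
        k_lo, k_hi = 0, 1
        while k_hi <= k_max and not run(k_hi * margin_step).exhausted:
            k_lo = k_hi
            k_hi *= 2
        if k_hi <= k_max:
            while k_hi - k_lo > 1:
                k_mid = (k_lo + k_hi) // 2
                if run(k_mid * margin_step).exhausted:
                    k_hi = k_mid
                else:
                    k_lo = k_mid
            margin = k_hi * margin_step
    trace = simulate(lambda t: base_fn(t0 + t) / eta, twin, duration, dt=dt,
                     stop_on_exhaustion=True)
    summary = {
        "duration_s": duration,
        "exhausted": base.exhausted,
        "t_exhaustion_s": base.t_exhaustion,
        "margin_w": margin,
        "needs_adjustment": bool(
            exhausted_early or margin is None or margin > 10.0 * margin_step
        ),
    }
    return ProtocolResult(
        "calibrate_against_record",
        {"margin_step": margin_step, "dt": dt, "source": power_record.source},
        [trace], summary,
    )
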