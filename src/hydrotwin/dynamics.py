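"""Time integration of the three-tank hydraulic system.

State is the pair of emptying levels ``(h, l)``: ``h`` measures how far the
phosphagen tank P has been drawn down from the top (0 = full, 1 = empty) and
``l`` the drawdown of the glycolytic tank G (0 = full, 1 - lam = empty).
The oxidative tank O has infinite capacity and therefore no state variable.

Flow laws
---------
* O→P flux rises linearly with ``h`` and saturates at ``M_O`` once the P
  surface falls below the bottom of O: ``d_op = M_O · min(h, 1-phi)/(1-phi)``.
* The G↔P exchange is a linear conductance in the head difference ``h - l``:
  forward gain ``M_G`` per unit head (the cap ``M_G`` is attained only at the
  unreachable extreme ``h = 1, l = 0``), reverse gain ``M_R/(1-lam)`` per unit
  head (cap attained at the maximal physical head ``l = 1-lam, h = 0``).
* The fatigue-limited maximal power is proportional to the fluid remaining in
  the main section of G: ``p_max = M_P · (1-lam-l)/(1-lam-theta)`` for
  ``l > theta`` and ``M_P`` below.

Integration is a fixed-step trapezoidal (Crank–Nicolson family) scheme with
one functional iteration — an explicit predictor/corrector.  Any step in
which ``l`` crosses the capillary/main-section junction ``theta`` is split at
the crossing so each partial step sees a single cross-section; this removes
O(dt) artifacts at the junction.  The default step is 0.05 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import SimulationError, ValidationError
from .twin import TwinParameters

__all__ = [
    "HydraulicState",
    "FlowState",
    "SimulationTrace",
    "p_max_of",
    "flow_o_to_p",
    "flow_g_p",
    "g_cross_section",
    "step",
    "simulate",
    "steady_state",
    "critical_power",
    "lt1_power",
    "time_to_exhaustion",
]

#: Default integration step, s.
DEFAULT_DT = 0.05

#: Relative tolerance above which demand > p_max flags exhaustion.
EXHAUSTION_RTOL = 1e-9

#: A single step moving either level by more than this is treated as unstable.
MAX_LEVEL_STEP = 0.25


@dataclass(frozen=True)
class HydraulicState:
    """Instantaneous tank levels at time ``t`` (s)."""

    t: float
    h: float
    l: float


@dataclass(frozen=True)
class FlowState:
    """Instantaneous flows, W: O→P flux, net G→P flux (negative = refill),
    demanded physiological power and current fatigue-limited maximum."""

    d_op: float
    d_gp: float
    p_physio: float
    p_max: float


# ---------------------------------------------------------------------------
# Elementary laws
# ---------------------------------------------------------------------------

def p_max_of(l: float, twin: TwinParameters) -> float:
    """Fatigue-limited maximal physiological power at G drain level ``l``."""
    if l <= twin.theta:
        return twin.m_p
    return twin.m_p * (1.0 - twin.lam - l) / (1.0 - twin.lam - twin.theta)


def flow_o_to_p(h: float, twin: TwinParameters) -> float:
    """Oxidative flux into P, W; linear in ``h`` and capped at ``M_O``."""
    return twin.m_o * min(h, 1.0 - twin.phi) / (1.0 - twin.phi)


def flow_g_p(h: float, l: float, twin: TwinParameters) -> float:
    """Signed net G→P flux, W.  Positive drains G; negative refills it."""
    head = h - l
    if head >= 0.0:
        return min(twin.m_g * head, twin.m_g)
    return max(twin.m_r * head / (1.0 - twin.lam), -twin.m_r)


def g_cross_section(l: float, twin: TwinParameters) -> float:
    """Cross-section feeding ``dl/dt``: capillary A_T below ``theta``,
    main section A_G from ``theta`` on (right-continuous)."""
    return twin.a_t if l < twin.theta else twin.a_g


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------

def _advance(
    h: float,
    l: float,
    p0: float,
    p1: float,
    dt: float,
    twin: TwinParameters,
    all_out: bool,
) -> tuple[float, float]:
    """One trapezoidal step of length ``dt``, split at the ``theta`` junction.

    ``p0``/``p1`` are the demanded physiological powers at the start and end
    of the step; in all-out mode they are ignored and the demand tracks
    ``p_max_of(l)``.
    """
    theta = twin.theta
    lam1 = 1.0 - twin.lam
    phi1 = 1.0 - twin.phi
    m_o, m_g, m_r, m_p, a_p = twin.m_o, twin.m_g, twin.m_r, twin.m_p, twin.a_p
    pslope = m_p / (lam1 - theta)

    remaining = dt
    frac_done = 0.0
    for _ in range(4):  # at most a handful of junction crossings per step
        # flows at segment start
        d_op1 = m_o * min(h, phi1) / phi1
        head = h - l
        d_gp1 = min(m_g * head, m_g) if head >= 0.0 else max(m_r * head / lam1, -m_r)
        if all_out:
            p0s = m_p if l <= theta else pslope * (lam1 - l)
        else:
            p0s = p0 + (p1 - p0) * frac_done
        # cross-section frozen for this segment, chosen by side (by direction
        # of motion when sitting exactly on the junction)
        if l > theta or (l == theta and d_gp1 >= 0.0):
            area = twin.a_g
        else:
            area = twin.a_t
        dh1 = (p0s - d_op1 - d_gp1) / a_p
        dl1 = d_gp1 / area

        hp = h + remaining * dh1
        lp = l + remaining * dl1
        d_op2 = m_o * min(max(hp, 0.0), phi1) / phi1
        head2 = hp - lp
        d_gp2 = min(m_g * head2, m_g) if head2 >= 0.0 else max(m_r * head2 / lam1, -m_r)
        if all_out:
            p1s = m_p if lp <= theta else pslope * (lam1 - max(lp, 0.0))
        else:
            p1s = p0 + (p1 - p0) * (frac_done + remaining / dt)
        dh2 = (p1s - d_op2 - d_gp2) / a_p
        dl2 = d_gp2 / area

        dh = 0.5 * remaining * (dh1 + dh2)
        dl = 0.5 * remaining * (dl1 + dl2)
        if abs(dh) > MAX_LEVEL_STEP or abs(dl) > MAX_LEVEL_STEP:
            raise SimulationError(
                f"level change {max(abs(dh), abs(dl)):.3f} in one step of {dt} s: "
                "integration unstable, reduce dt"
            )
        l2 = l + dl
        if (l < theta < l2) or (l2 < theta < l):
            f = (theta - l) / dl
            # land exactly on the junction, then finish the step on the far side
            sub = remaining * f
            h, l = _advance(h, l, p0s, p0s + (p1s - p0s) * f, sub, twin, all_out)[0:2]
            l = theta
            frac_done += sub / dt
            remaining -= sub
            if remaining <= 0.0:
                break
            continue
        h = h + dh
        l = l2
        break

    # clamp into physical ranges
    if h < 0.0:
        h = 0.0
    elif h > 1.0:
        h = 1.0
    if l < 0.0:
        l = 0.0
    elif l > lam1:
        l = lam1
    return h, l


def step(
    state: HydraulicState,
    p_physio_demand: float,
    dt: float,
    twin: TwinParameters,
    all_out: bool = False,
) -> tuple[HydraulicState, FlowState, bool]:
    """Advance one step; return the new state, the flows at the *start* of
    the step, and whether the demand exceeded the fatigue-limited maximum."""
    if dt <= 0:
        raise ValidationError(f"dt must be > 0, got {dt}")
    if not (math.isfinite(state.h) and math.isfinite(state.l) and math.isfinite(p_physio_demand)):
        raise SimulationError(f"non-finite state or demand: {state}, {p_physio_demand}")
    pm = p_max_of(state.l, twin)
    if all_out:
        demand = pm
        exhausted = False
    else:
        demand = p_physio_demand
        exhausted = demand > pm * (1.0 + EXHAUSTION_RTOL)
    flows = FlowState(
        d_op=flow_o_to_p(state.h, twin),
        d_gp=flow_g_p(state.h, state.l, twin),
        p_physio=demand,
        p_max=pm,
    )
    h, l = _advance(state.h, state.l, demand, demand, dt, twin, all_out)
    return HydraulicState(state.t + dt, h, l), flows, exhausted


# ---------------------------------------------------------------------------
# Trace container
# ---------------------------------------------------------------------------

@dataclass
class SimulationTrace:
    """Sampled time series of one simulation.

    All series are aligned on ``t``; flows are the instantaneous values at
    each sample.  ``p_physio`` is the accepted physiological demand (the
    fatigue-limited maximum itself in all-out mode).
    """

    t: np.ndarray
    h: np.ndarray
    l: np.ndarray
    p_physio: np.ndarray
    p_max: np.ndarray
    d_op: np.ndarray
    d_gp: np.ndarray
    twin: TwinParameters
    dt: float
    exhausted: bool = False
    t_exhaustion: float | None = None
    all_out: bool = False

    def __len__(self) -> int:
        return len(self.t)

    @property
    def final(self) -> HydraulicState:
        return HydraulicState(float(self.t[-1]), float(self.h[-1]), float(self.l[-1]))

    def concat(self, other: "SimulationTrace") -> "SimulationTrace":
        """Join two back-to-back traces (other starts where self ends)."""
        if abs(float(other.t[0]) - float(self.t[-1])) > 1e-9:
            raise ValidationError("traces are not contiguous in time")
        j = slice(1, None)  # drop duplicated boundary sample
        return SimulationTrace(
            t=np.concatenate([self.t, other.t[j]]),
            h=np.concatenate([self.h, other.h[j]]),
            l=np.concatenate([self.l, other.l[j]]),
            p_physio=np.concatenate([self.p_physio, other.p_physio[j]]),
            p_max=np.concatenate([self.p_max, other.p_max[j]]),
            d_op=np.concatenate([self.d_op, other.d_op[j]]),
            d_gp=np.concatenate([self.d_gp, other.d_gp[j]]),
            twin=self.twin,
            dt=self.dt,
            exhausted=self.exhausted or other.exhausted,
            t_exhaustion=self.t_exhaustion if self.t_exhaustion is not None else other.t_exhaustion,
            all_out=self.all_out and other.all_out,
        )


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def simulate(
    demand_fn: Callable[[float], float] | float,
    twin: TwinParameters,
    t_end: float,
    dt: float = DEFAULT_DT,
    stop_on_exhaustion: bool = True,
    all_out: bool = False,
    initial_state: HydraulicState | None = None,
    record: bool = True,
) -> SimulationTrace:
    """Integrate the tank system under a physiological power demand.

    Parameters
    ----------
    demand_fn:
        Either a constant physiological power (W) or a function of time
        returning one.  Ignored when ``all_out`` is true (the demand then
        tracks the fatigue-limited maximum at every step).
    t_end, dt:
        Horizon and fixed step, s.
    stop_on_exhaustion:
        Stop at the first step whose demand exceeds the current maximal
        power beyond tolerance.  When false, the accepted demand is clamped
        to the maximum and integration continues (the first exhaustion time
        is still recorded).
    initial_state:
        Defaults to rest, ``h = l = 0`` at ``t = 0``.
    record:
        When false, only the initial and final samples are kept (fast path
        for bisection searches).

    The result is reproducible: there is no randomness anywhere.
    """
    if dt <= 0 or t_end <= 0:
        raise ValidationError(f"t_end and dt must be > 0, got {t_end}, {dt}")
    if isinstance(demand_fn, (int, float)):
        const_demand = float(demand_fn)
        demand = None
    else:
        const_demand = None
        demand = demand_fn

    s0 = initial_state or HydraulicState(0.0, 0.0, 0.0)
    h, l = s0.h, s0.l
    if not (0.0 <= h <= 1.0 and 0.0 <= l <= 1.0 - twin.lam):
        raise ValidationError(f"initial levels out of range: h={h}, l={l}")
    t0 = s0.t
    n = max(1, int(round(t_end / dt)))

    theta, lam1, phi1 = twin.theta, 1.0 - twin.lam, 1.0 - twin.phi
    m_o, m_g, m_r, m_p = twin.m_o, twin.m_g, twin.m_r, twin.m_p
    pslope = m_p / (lam1 - theta)
    rtol1 = 1.0 + EXHAUSTION_RTOL

    if record:
        T = np.empty(n + 1)
        H = np.empty(n + 1)
        L = np.empty(n + 1)
        P = np.empty(n + 1)
        PM = np.empty(n + 1)
        DOP = np.empty(n + 1)
        DGP = np.empty(n + 1)

    exhausted = False
    t_exh: float | None = None
    i = 0
    while True:
        t = t0 + i * dt
        pm = m_p if l <= theta else pslope * (lam1 - l)
        if all_out:
            p = pm
        else:
            p = const_demand if demand is None else float(demand(t))
            if p > pm * rtol1:
                if not exhausted:
                    exhausted = True
                    t_exh = t
                p = pm  # clamp if we keep integrating
        d_op = m_o * min(h, phi1) / phi1
        head = h - l
        d_gp = min(m_g * head, m_g) if head >= 0.0 else max(m_r * head / lam1, -m_r)

        if record:
            T[i], H[i], L[i] = t, h, l
            P[i], PM[i], DOP[i], DGP[i] = p, pm, d_op, d_gp
        last = (i == n) or (exhausted and stop_on_exhaustion and t_exh == t)
        if last:
            i += 1
            break
        if h != h or l != l:  # NaN guard
            raise SimulationError(f"non-finite state at t={t:.3f}")
        if all_out:
            p1 = p
        else:
            p1 = const_demand if demand is None else float(demand(t + dt))
            if p1 > pm * rtol1:  # keep both stages within the accepted cap
                p1 = pm
        h, l = _advance(h, l, p, p1, dt, twin, all_out)
        i += 1

    if record:
        tr = SimulationTrace(
            t=T[:i].copy(), h=H[:i].copy(), l=L[:i].copy(),
            p_physio=P[:i].copy(), p_max=PM[:i].copy(),
            d_op=DOP[:i].copy(), d_gp=DGP[:i].copy(),
            twin=twin, dt=dt, exhausted=exhausted, t_exhaustion=t_exh,
            all_out=all_out,
        )
    else:
        t_last = t0 + (i - 1) * dt
        pm = m_p if l <= theta else pslope * (lam1 - l)
        d_op = m_o * min(h, phi1) / phi1
        head = h - l
        d_gp = min(m_g * head, m_g) if head >= 0.0 else max(m_r * head / lam1, -m_r)
        p = pm if all_out else (const_demand if demand is None else float(demand(t_last)))
        tr = SimulationTrace(
            t=np.array([t0, t_last]), h=np.array([s0.h, h]), l=np.array([s0.l, l]),
            p_physio=np.array([p, min(p, pm)]), p_max=np.array([p_max_of(s0.l, twin), pm]),
            d_op=np.array([flow_o_to_p(s0.h, twin), d_op]),
            d_gp=np.array([flow_g_p(s0.h, s0.l, twin), d_gp]),
            twin=twin, dt=dt, exhausted=exhausted, t_exhaustion=t_exh,
            all_out=all_out,
        )
    return tr


# ---------------------------------------------------------------------------
# Analytic oracles
# ---------------------------------------------------------------------------

def critical_power(twin: TwinParameters, mechanical: bool = False) -> float:
    """Critical power: the largest demand with a steady state, beta·M_O."""
    p = twin.beta * twin.m_o
    return p * twin.eta if mechanical else p


def lt1_power(twin: TwinParameters, mechanical: bool = False) -> float:
    """First-lactate-threshold power, alpha·M_O."""
    p = twin.alpha * twin.m_o
    return p * twin.eta if mechanical else p


def steady_state(p_physio: float, twin: TwinParameters) -> tuple[float, float] | None:
    """Closed-form steady levels for a constant demand, or None above
    critical power.

    At equilibrium the G↔P exchange vanishes (pressure equalization,
    ``l* = h*``) and the oxidative inflow balances the demand, so
    ``h* = p · (1-phi) / M_O``.
    """
    if p_physio < 0:
        raise ValidationError(f"p_physio must be >= 0, got {p_physio}")
    if p_physio > critical_power(twin) * (1.0 + 1e-12):
        return None
    h = p_physio * (1.0 - twin.phi) / twin.m_o
    return h, h


def time_to_exhaustion(
    p_mec: float,
    twin: TwinParameters,
    t_cap: float = 1800.0,
    dt: float = DEFAULT_DT,
) -> float | None:
    """Time to exhaustion at constant mechanical power, or None if the power
    is sustainable (at or below critical power, or no exhaustion within
    ``t_cap`` seconds)."""
    if not math.isfinite(t_cap):
        raise ValidationError("t_cap must be finite")
    p_physio = p_mec / twin.eta
    if p_physio <= critical_power(twin):
        return None
    tr = simulate(p_physio, twin, t_cap, dt=dt, stop_on_exhaustion=True, record=False)
    return tr.t_exhaustion
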