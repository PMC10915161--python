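"""Physiological observables derived from hydraulic states and flows.

The tank levels map onto muscle metabolite concentrations through the energy
equivalents: ``h`` (phosphagen drawdown) onto muscle phosphocreatine, ``l``
(glycolytic drawdown) onto accumulated muscle lactate, and the O→P flux onto
oxygen uptake.  The modeled V̇O₂ covers the task muscles only and excludes
resting metabolism; the lactate series includes the resting offset so that
the LT1 drain level maps onto the literature LT1 concentration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysioConstants
from .dynamics import SimulationTrace
from .errors import ValidationError
from .twin import TwinParameters

__all__ = [
    "pc_concentration",
    "lactate_concentration",
    "vo2_of",
    "power_partition",
    "aod_series",
    "accumulated_o2_deficit",
    "rmse",
    "trace_to_frame",
    "TRACE_COLUMNS",
]

#: Column order of an exported trace file.
TRACE_COLUMNS = [
    "t_s", "h", "l", "p_mec_w", "p_max_w", "d_op_w", "d_gp_w",
    "pc_mmolkg", "la_mmolkg", "vo2_ml_s", "p_vo2_w", "p_lact_w", "p_pc_w",
    "aod_ml",
]


def pc_concentration(h, k: PhysioConstants = DEFAULT_CONSTANTS):
    """Muscle phosphocreatine, mmol/kg wet weight: full stores scaled by the
    remaining P fraction, ``pc_max · (1 - h)``."""
    return k.pc_max * (1.0 - np.asarray(h, dtype=float))


def lactate_concentration(l, twin: TwinParameters, k: PhysioConstants = DEFAULT_CONSTANTS):
    """Muscle lactate, mmol/kg wet weight, including the resting offset.

    The energy drained from G (capillary below ``theta``, main section above)
    is converted back to millimoles per kg of task muscle:
    ``la_rest + (A_T·min(l,theta) + A_G·max(l-theta,0)) / (C2·m_muscle)``.
    By construction of A_T, ``l = theta`` maps exactly onto the LT1 value.
    """
    l = np.asarray(l, dtype=float)
    drained = twin.a_t * np.minimum(l, twin.theta) + twin.a_g * np.maximum(l - twin.theta, 0.0)
    return k.la_rest + drained / (k.c2 * twin.m_muscle)


def vo2_of(h, twin: TwinParameters, k: PhysioConstants = DEFAULT_CONSTANTS):
    """Oxygen uptake of the task muscles: ``(vo2 mL/s, fraction of V̇O₂max)``.

    Excludes resting metabolism — the model accounts for task power only.
    """
    h = np.asarray(h, dtype=float)
    pct = np.minimum(h, 1.0 - twin.phi) / (1.0 - twin.phi)
    return pct * twin.m_o / k.c1, pct


def power_partition(trace: SimulationTrace):
    """Mechanical power split by pathway: ``(p_vo2, p_lact, p_pc)``, W.

    The oxidative share is ``eta·d_op``, the non-oxidative lactic share is
    ``eta·max(d_gp, 0)`` and the alactic (phosphagen) share is the residual,
    so the three sum to the demanded mechanical power exactly at every
    sample.  During recovery (``d_gp < 0``) the lactic share is zero and the
    refill energy is debited from the residual term.
    """
    eta = trace.twin.eta
    p_mec = eta * trace.p_physio
    p_vo2 = eta * trace.d_op
    p_lact = eta * np.maximum(trace.d_gp, 0.0)
    p_pc = p_mec - p_vo2 - p_lact
    return p_vo2, p_lact, p_pc


def aod_series(trace: SimulationTrace, k: PhysioConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Accumulated oxygen deficit along the trace, mL O2.

    Trapezoidal integral of the positive part of the oxygen-demand shortfall
    ``(p_physio - d_op)/C1``.  The positive part makes the deficit a
    nondecreasing tally of energy supplied by non-oxidative pathways: during
    recovery the oxidative surplus repays the stores but does not erase the
    deficit already accumulated.
    """
    if len(trace) == 0:
        raise ValidationError("empty trace")
    shortfall = trace.p_physio - trace.d_op
    rate = 0.5 * (shortfall[1:] + shortfall[:-1])
    np.maximum(rate, 0.0, out=rate)
    out = np.empty(len(trace))
    out[0] = 0.0
    np.cumsum(rate * np.diff(trace.t), out=out[1:])
    return out / k.c1


def accumulated_o2_deficit(
    trace: SimulationTrace, k: PhysioConstants = DEFAULT_CONSTANTS
) -> float:
    """Total accumulated oxygen deficit of a trace, mL O2."""
    return float(aod_series(trace, k)[-1])


def rmse(simulated_power, recorded_power) -> tuple[float, float]:
    """Root-mean-square difference between two aligned power series, W.

    Returns ``(rmse, relative)`` where ``relative`` is the RMSE divided by
    the mean recorded power (the average error rate).
    """
    a = np.asarray(simulated_power, dtype=float)
    b = np.asarray(recorded_power, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValidationError("empty series")
    err = float(np.sqrt(np.mean((a - b) ** 2)))
    mean_rec = float(np.mean(b))
    rel = err / mean_rec if mean_rec > 0 else float("inf")
    return err, rel


def trace_to_frame(
    trace: SimulationTrace, k: PhysioConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Assemble the full observable table for a trace (see TRACE_COLUMNS)."""
    twin = trace.twin
    vo2, _ = vo2_of(trace.h, twin, k)
    p_vo2, p_lact, p_pc = power_partition(trace)
    return pd.DataFrame(
        {
            "t_s": trace.t,
            "h": trace.h,
            "l": trace.l,
            "p_mec_w": twin.eta * trace.p_physio,
            "p_max_w": twin.eta * trace.p_max,
            "d_op_w": trace.d_op,
            "d_gp_w": trace.d_gp,
            "pc_mmolkg": pc_concentration(trace.h, k),
            "la_mmolkg": lactate_concentration(trace.l, twin, k),
            "vo2_ml_s": vo2,
            "p_vo2_w": p_vo2,
            "p_lact_w": p_lact,
            "p_pc_w": p_pc,
            "aod_ml": aod_series(trace, k),
        },
        columns=TRACE_COLUMNS,
    )
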