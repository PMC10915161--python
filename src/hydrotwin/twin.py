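"""Digital-twin parameterization: from exercise-test values to tank geometry.

The hydraulic model describes the energy systems of the muscles engaged in a
task as three communicating fluid compartments (oxidative O, glycolytic G,
phosphagen P).  This module converts an athlete's laboratory/field test
values — body mass, V̇O₂max, maximal power, power and %V̇O₂max at the first
lactate threshold (LT1), critical power and non-oxidative work capacity —
into the ten geometrical/flow parameters of that model, plus the mechanical
efficiency and the task muscle mass.

All internal units are SI: energies in J, powers in W, times in s, oxygen
uptake in mL/s.  kJ conversions happen only at the I/O boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

from .constants import DEFAULT_CONSTANTS, PhysioConstants
from .errors import TwinBuildError, ValidationError

__all__ = [
    "AthleteTestData",
    "TwinParameters",
    "MassReconciliation",
    "compute_muscle_mass",
    "compute_efficiency",
    "compute_direct_flows",
    "compute_heights",
    "compute_l_crit",
    "compute_capacities",
    "compute_AG",
    "compute_glycolytic_flows",
    "build_twin",
    "reconcile_muscle_mass",
]

#: Plausible range of gross cycling efficiency; values outside trigger a warning.
EFFICIENCY_RANGE = (0.18, 0.30)

#: Relative slack tolerated on the M_R = M_G / mr_ratio identity (printed
#: parameter tables are rounded to three significant figures).
MR_RATIO_RTOL = 5e-3


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class AthleteTestData:
    """Measured characteristics that seed a digital twin.

    Attributes
    ----------
    m_athlete:
        Body mass, kg.
    pct_muscle:
        Whole-body muscle fraction, in (0, 1).
    pct_muscle_for_task:
        Fraction of the muscle mass engaged in the task, in (0, 1].
    vo2max:
        Maximal oxygen uptake, mL O2 per second.
    p_max_mec:
        Maximal mechanical power without prior fatigue, W.
    p_lt1_mec:
        Mechanical power at the first lactate threshold, W.
    alpha:
        Fraction of V̇O₂max at LT1, in (0, 1).
    p_crit_mec:
        Critical mechanical power, W.
    w_nonox_mec:
        Maximal non-oxidative mechanical work above critical power, J.
    beta:
        Fraction of V̇O₂max at critical power.  If ``None`` it is derived
        downstream as ``p_crit_mec / (eta · M_O)``.
    m_g_override:
        Optional explicit maximal glycolytic flow M_G, W.  When given, the
        generic per-kg scaling is bypassed (M_R still follows as
        M_G / mr_ratio), mirroring the per-athlete calibration loop.
    """

    m_athlete: float
    pct_muscle: float
    pct_muscle_for_task: float
    vo2max: float
    p_max_mec: float
    p_lt1_mec: float
    alpha: float
    p_crit_mec: float
    w_nonox_mec: float
    beta: float | None = None
    m_g_override: float | None = None

    def __post_init__(self) -> None:
        _require(self.m_athlete > 0, f"m_athlete must be > 0, got {self.m_athlete}")
        _require(0 < self.pct_muscle < 1, f"pct_muscle must lie in (0,1), got {self.pct_muscle}")
        _require(
            0 < self.pct_muscle_for_task <= 1,
            f"pct_muscle_for_task must lie in (0,1], got {self.pct_muscle_for_task}",
        )
        _require(self.vo2max > 0, f"vo2max must be > 0, got {self.vo2max}")
        _require(self.w_nonox_mec > 0, f"w_nonox_mec must be > 0, got {self.w_nonox_mec}")
        _require(
            0 < self.p_lt1_mec < self.p_crit_mec < self.p_max_mec,
            "power thresholds must satisfy 0 < P_LT1 < P_crit < P_max, got "
            f"{self.p_lt1_mec}, {self.p_crit_mec}, {self.p_max_mec}",
        )
        _require(0 < self.alpha < 1, f"alpha must lie in (0,1), got {self.alpha}")
        if self.beta is not None:
            _require(self.alpha < self.beta, f"beta ({self.beta}) must exceed alpha ({self.alpha})")
            _warn_beta(self.beta)
        if self.m_g_override is not None:
            _require(self.m_g_override > 0, "m_g_override must be > 0")


def _warn_beta(beta: float) -> None:
    # %VO2max at critical power cannot physiologically exceed 1; published
    # parameter sets occasionally imply values a hair above it (rounding of
    # the underlying thresholds), so tolerate a small excess with a warning.
    if beta > 1.05:
        raise ValidationError(f"beta = {beta:.4f} implies VO2 at critical power >5% above VO2max")
    if beta > 1.0:
        warnings.warn(
            f"beta = {beta:.4f} > 1: V̇O₂ at critical power above V̇O₂max; "
            "check the measured thresholds",
            stacklevel=3,
        )


@dataclass(frozen=True)
class TwinParameters:
    """The complete hydraulic geometry of one athlete for one task.

    Heights (``phi``, ``theta``, ``lam``) are dimensionless fractions of the
    total system height (1).  Cross-sections (``a_p``, ``a_g``, ``a_t``) carry
    units of energy (J) per unit height.  Flows (``m_o``, ``m_p``, ``m_g``,
    ``m_r``) are maximal powers in W.  ``l_crit`` — the drain level of G at
    the critical-power steady state — is derived from the other parameters at
    construction and cached.
    """

    phi: float
    theta: float
    lam: float
    m_o: float
    m_p: float
    m_g: float
    m_r: float
    a_p: float
    a_g: float
    a_t: float
    eta: float
    m_muscle: float
    l_crit: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("phi", "theta", "lam"):
            v = getattr(self, name)
            _require(0 < v < 1, f"{name} must lie in (0,1), got {v}")
        _require(
            self.theta + self.lam < 1,
            f"theta + lam = {self.theta + self.lam:.4f} must be < 1 "
            "(main glycolytic section needs positive height)",
        )
        for name in ("m_o", "m_p", "m_g", "m_r", "a_p", "a_g", "a_t", "eta", "m_muscle"):
            v = getattr(self, name)
            _require(v > 0, f"{name} must be strictly positive, got {v}")
        _require(
            self.a_t < self.a_g,
            f"capillary section a_t ({self.a_t:.4g}) must be smaller than main section "
            f"a_g ({self.a_g:.4g})",
        )
        ratio = self.m_g / self.m_r
        _require(
            abs(ratio - DEFAULT_CONSTANTS.mr_ratio) <= MR_RATIO_RTOL * DEFAULT_CONSTANTS.mr_ratio,
            f"M_G/M_R = {ratio:.4f} deviates from {DEFAULT_CONSTANTS.mr_ratio} by more than 0.5%",
        )
        if math.isnan(self.l_crit):
            object.__setattr__(self, "l_crit", compute_l_crit(self))
        _require(
            self.theta < self.l_crit < 1 - self.lam,
            f"l_crit = {self.l_crit:.4f} must lie in (theta, 1-lam) = "
            f"({self.theta:.4f}, {1 - self.lam:.4f}): twin inconsistent",
        )

    # -- threshold fractions implied by the geometry ---------------------
    @property
    def alpha(self) -> float:
        """%V̇O₂max at LT1 implied by the geometry: theta / (1 - phi)."""
        return self.theta / (1.0 - self.phi)

    @property
    def beta(self) -> float:
        """%V̇O₂max at critical power implied by the geometry."""
        r = self.m_o / self.m_p
        return (1.0 - self.lam) / ((1.0 - self.phi) + r * (1.0 - self.theta - self.lam))

    def scaled(self, c: float) -> "TwinParameters":
        """Return a twin with all flows and capacities scaled by ``c > 0``.

        Heights and efficiency are homogeneous of degree zero in the power
        scale, so they are left untouched.
        """
        _require(c > 0, "scale factor must be > 0")
        return replace(
            self,
            m_o=c * self.m_o,
            m_p=c * self.m_p,
            m_g=c * self.m_g,
            m_r=c * self.m_r,
            a_p=c * self.a_p,
            a_g=c * self.a_g,
            a_t=c * self.a_t,
            m_muscle=c * self.m_muscle,
            l_crit=float("nan"),
        )


# ---------------------------------------------------------------------------
# Pipeline stages
# ---------------------------------------------------------------------------

def compute_muscle_mass(d: AthleteTestData) -> float:
    """Task muscle mass, kg: body mass × muscle fraction × task fraction."""
    return d.m_athlete * d.pct_muscle * d.pct_muscle_for_task


def compute_efficiency(d: AthleteTestData, k: PhysioConstants = DEFAULT_CONSTANTS) -> float:
    """Mechanical efficiency from the LT1 working point.

    At LT1 the oxidative pathway supplies essentially all the power, so the
    efficiency is the ratio of mechanical power to the oxidative energy flux:
    eta = P_LT1_mec / (alpha · V̇O₂max · C1).
    """
    denom = d.alpha * d.vo2max * k.c1
    if denom <= 0:
        raise ValidationError("alpha · vo2max · C1 must be > 0")
    eta = d.p_lt1_mec / denom
    lo, hi = EFFICIENCY_RANGE
    if not lo <= eta <= hi:
        warnings.warn(
            f"efficiency {eta:.3f} outside the typical cycling range [{lo}, {hi}]",
            stacklevel=2,
        )
    return eta


def compute_direct_flows(
    d: AthleteTestData, eta: float, k: PhysioConstants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    """Directly measurable maximal flows (M_O, M_P), W.

    M_O is the ceiling of the oxidative flux (V̇O₂max in energy units);
    M_P is the maximal physiological power without prior fatigue.
    """
    _require(eta > 0, "eta must be > 0")
    return d.vo2max * k.c1, d.p_max_mec / eta


def compute_heights(
    alpha: float, beta: float, m_o: float, m_p: float, phi: float
) -> tuple[float, float]:
    """Solve the two threshold equations for (theta, lam).

    The LT1 fraction fixes the depth of G's main section,
    theta = alpha·(1-phi); the critical-power fraction then fixes the
    elevation of G's bottom:

        lam = 1 - theta · (1/alpha - M_O/M_P) / (1/beta - M_O/M_P)
    """
    _require(0 < alpha < beta, f"need 0 < alpha < beta, got {alpha}, {beta}")
    _require(m_o > 0 and m_p > 0, "flows must be positive")
    _require(0 < phi < 1, f"phi must lie in (0,1), got {phi}")
    r = m_o / m_p
    if 1.0 / beta <= r:
        raise ValidationError(
            f"degenerate geometry: 1/beta = {1 / beta:.4f} <= M_O/M_P = {r:.4f}"
        )
    theta = alpha * (1.0 - phi)
    lam = 1.0 - theta * (1.0 / alpha - r) / (1.0 / beta - r)
    _require(
        theta + lam < 1.0,
        f"theta + lam = {theta + lam:.4f} >= 1: thresholds inconsistent with flows",
    )
    return theta, lam


def compute_l_crit(twin: TwinParameters) -> float:
    """Drain level of G at which the fatigue-limited maximal power equals
    the critical physiological power beta·M_O.

    Inverts the fatigue law M_P·(1-lam-l)/(1-lam-theta) = beta·M_O.
    """
    p_crit = twin.beta * twin.m_o
    l = (1.0 - twin.lam) - p_crit * (1.0 - twin.lam - twin.theta) / twin.m_p
    if not twin.theta < l < 1.0 - twin.lam:
        raise ValidationError(
            f"l_crit = {l:.4f} outside (theta, 1-lam): inconsistent twin"
        )
    return l


def compute_capacities(
    m_muscle: float, theta: float, k: PhysioConstants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    """Cross-sections (A_P, A_T), J per unit height.

    A_P holds the full phosphocreatine store; A_T (the capillary of G) is
    sized so that draining it down to depth theta corresponds to the
    above-rest lactate accumulation observed at LT1
    (la_lt1 - la_rest, per kg, converted to J).
    """
    _require(m_muscle > 0, f"m_muscle must be > 0, got {m_muscle}")
    _require(0 < theta < 1, f"theta must lie in (0,1), got {theta}")
    a_p = k.pc_max * m_muscle * k.c3
    a_t = (k.la_lt1 - k.la_rest) / theta * m_muscle * k.c2
    return a_p, a_t


def compute_AG(
    w_nonox_mec: float,
    eta: float,
    a_p: float,
    a_t: float,
    theta: float,
    l_crit: float,
) -> float:
    """Main G cross-section, adjusted to absorb the measured non-oxidative
    work capacity:

        A_G = (W_nonox/eta - A_P·l_crit - A_T·theta) / (l_crit - theta)
    """
    _require(l_crit > theta, f"l_crit ({l_crit}) must exceed theta ({theta})")
    a_g = (w_nonox_mec / eta - a_p * l_crit - a_t * theta) / (l_crit - theta)
    if a_g <= 0:
        raise ValidationError(
            "non-oxidative capacity too small for geometry: computed A_G "
            f"= {a_g:.4g} <= 0"
        )
    return a_g


def compute_glycolytic_flows(
    m_muscle: float,
    k: PhysioConstants = DEFAULT_CONSTANTS,
    m_g_override: float | None = None,
) -> tuple[float, float]:
    """Maximal glycolytic outflow and recovery inflow (M_G, M_R), W."""
    _require(m_muscle > 0, "m_muscle must be > 0")
    m_g = m_g_override if m_g_override is not None else k.mg_specific * m_muscle
    return m_g, m_g / k.mr_ratio


def build_twin(d: AthleteTestData, k: PhysioConstants = DEFAULT_CONSTANTS) -> TwinParameters:
    """Run the full deterministic chain from test data to a validated twin.

    Order: muscle mass → efficiency → direct flows → heights → l_crit →
    capacities → A_G → glycolytic flows.  Each stage failure is re-raised as
    a :class:`TwinBuildError` naming the stage.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValidationError as exc:
            raise TwinBuildError(name, str(exc)) from exc

    m_muscle = stage("muscle_mass", compute_muscle_mass, d)
    eta = stage("efficiency", compute_efficiency, d, k)
    m_o, m_p = stage("direct_flows", compute_direct_flows, d, eta, k)
    beta = d.beta
    if beta is None:
        beta = d.p_crit_mec / (eta * m_o)
        if beta <= d.alpha:
            raise TwinBuildError(
                "beta", f"derived beta {beta:.4f} does not exceed alpha {d.alpha:.4f}"
            )
        _warn_beta(beta)
    theta, lam = stage("heights", compute_heights, d.alpha, beta, m_o, m_p, k.phi_default)
    # l_crit from the fatigue law before A_G exists: it only needs heights+flows.
    p_crit_physio = beta * m_o
    l_crit = (1.0 - lam) - p_crit_physio * (1.0 - lam - theta) / m_p
    if not theta < l_crit < 1.0 - lam:
        raise TwinBuildError("l_crit", f"l_crit = {l_crit:.4f} outside (theta, 1-lam)")
    a_p, a_t = stage("capacities", compute_capacities, m_muscle, theta, k)
    a_g = stage("a_g", compute_AG, d.w_nonox_mec, eta, a_p, a_t, theta, l_crit)
    m_g, m_r = stage("glycolytic_flows", compute_glycolytic_flows, m_muscle, k, d.m_g_override)
    try:
        twin = TwinParameters(
            phi=k.phi_default, theta=theta, lam=lam,
            m_o=m_o, m_p=m_p, m_g=m_g, m_r=m_r,
            a_p=a_p, a_g=a_g, a_t=a_t,
            eta=eta, m_muscle=m_muscle, l_crit=l_crit,
        )
    except ValidationError as exc:
        raise TwinBuildError("validation", str(exc)) from exc
    return twin


# ---------------------------------------------------------------------------
# Consistency audit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MassReconciliation:
    """Three independent muscle-mass estimates recovered from a twin."""

    m_from_a_p: float
    m_from_a_t: float
    m_from_m_g: float
    max_rel_deviation: float

    @property
    def flagged(self) -> bool:
        """True when the estimates disagree by more than 5%."""
        return self.max_rel_deviation > 0.05


def reconcile_muscle_mass(
    twin: TwinParameters, k: PhysioConstants = DEFAULT_CONSTANTS
) -> MassReconciliation:
    """Audit a twin by back-deriving the muscle mass three independent ways.

    A self-consistent twin (built by :func:`build_twin` without an M_G
    override) yields identical estimates; published parameter sets with a
    per-athlete M_G adjustment show up as a large ``m_from_m_g`` deviation.
    Report-only: never raises, but warns when flagged.
    """
    masses = (
        twin.a_p / (k.pc_max * k.c3),
        twin.a_t * twin.theta / ((k.la_lt1 - k.la_rest) * k.c2),
        twin.m_g / k.mg_specific,
    )
    dev = 0.0
    for i in range(3):
        for j in range(i + 1, 3):
            dev = max(dev, abs(masses[i] - masses[j]) / max(masses[i], masses[j]))
    rec = MassReconciliation(*masses, dev)
    if rec.flagged:
        warnings.warn(
            f"muscle-mass estimates disagree by {dev:.1%} "
            f"(A_P: {masses[0]:.1f} kg, A_T: {masses[1]:.1f} kg, M_G: {masses[2]:.1f} kg)",
            stacklevel=2,
        )
    return rec
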