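"""Synthetic race power records.

Real calibration data are recordings of maximal competitive efforts.  This
generator builds a structurally similar record directly from a twin: a start
surge, a long cruise near critical power, and a finishing sprint, globally
scaled (by bisection against the simulator itself) so the bout drains a
requested fraction of the twin's non-oxidative capacity without exhausting,
then overlaid with seeded bounded noise.  Records are deterministic given
the seed.
"""

from __future__ import annotations

import numpy as np

from .dynamics import DEFAULT_DT, simulate
from .errors import ValidationError
from .io import PowerRecord
from .protocols import drain_fraction
from .twin import TwinParameters

__all__ = ["generate_synthetic_race"]

#: Relative amplitude of the multiplicative noise added to the clean profile.
NOISE_AMPLITUDE = 0.03


def _race_shape(duration: float, dt_record: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit-scale race profile: surge, cruise, sprint."""
    t = np.arange(0.0, duration + 0.5 * dt_record, dt_record)
    surge_end = min(15.0, 0.1 * duration)
    sprint_start = duration - min(20.0, 0.15 * duration)
    shape = np.ones_like(t)
    shape[t < surge_end] = 1.6
    sprint = t >= sprint_start
    shape[sprint] = 1.0 + 0.8 * (t[sprint] - sprint_start) / max(duration - sprint_start, 1.0)
    return t, shape


def generate_synthetic_race(
    twin: TwinParameters,
    duration: float = 300.0,
    seed: int = 0,
    drain_target: float = 0.99,
    dt_record: float = 1.0,
    dt: float = DEFAULT_DT,
    with_profile: bool = False,
) -> PowerRecord | tuple[PowerRecord, PowerRecord]:
    """Build a maximal-effort power record tailored to a twin.

    Parameters
    ----------
    twin:
        The athlete the record is constructed for.
    duration:
        Race length, s.
    seed:
        Seed of the bounded noise; same seed, same record.
    drain_target:
        Fraction of the twin's critical-level non-oxidative capacity that
        the simulated bout must have drained at the finish, in (0, 1].
    with_profile:
        Also return the noise-free profile the record was built from.

    Raises if no scaling of the profile can reach the target drain without
    exhausting before the finish.
    """
    if not 0.0 < drain_target <= 1.0:
        raise ValidationError(f"drain_target must lie in (0,1], got {drain_target}")
    if duration <= 30.0:
        raise ValidationError(f"duration must exceed 30 s, got {duration}")
    t, shape = _race_shape(duration, dt_record)
    eta = twin.eta

    def final_drain(scale: float) -> float | None:
        """Drain fraction at the finish, or None if exhausted early."""
        powers = scale * shape

        def demand(x: float) -> float:
            i = min(int(x / dt_record), powers.size - 1)
            return powers[i] / eta

        tr = simulate(demand, twin, duration, dt=dt, record=False)
        if tr.exhausted:
            return None
        fin = tr.final
        return drain_fraction(fin.h, fin.l, twin)

    # bracket: find a scale that exhausts, then bisect on the drain fraction
    lo, hi = 0.0, twin.eta * twin.beta * twin.m_o  # cruise at critical power
    for _ in range(30):
        d = final_drain(hi)
        if d is None or d >= drain_target:
            break
        lo = hi
        hi *= 1.3
    else:
        raise ValidationError(
            f"drain target {drain_target} infeasible within {duration:.0f} s"
        )
    best = None
    for _ in range(45):
        mid = 0.5 * (lo + hi)
        d = final_drain(mid)
        if d is None or d > drain_target:
            hi = mid
        else:
            lo = mid
            best = (mid, d)
        if d is not None and abs(d - drain_target) < 1e-4:
            best = (mid, d)
            break
    if best is None:
        raise ValidationError(
            f"drain target {drain_target} infeasible within {duration:.0f} s"
        )
    scale = best[0]
    clean = PowerRecord(t, scale * shape, source=f"synthetic clean profile ({twin.m_muscle:.1f} kg twin)")

    rng = np.random.default_rng(seed)
    amp = NOISE_AMPLITUDE
    for _ in range(6):
        noisy = scale * shape * (1.0 + amp * rng.uniform(-1.0, 1.0, size=shape.size))
        powers = noisy

        def demand(x: float) -> float:
            i = min(int(x / dt_record), powers.size - 1)
            return powers[i] / eta

        if not simulate(demand, twin, duration, dt=dt, record=False).exhausted:
            break
        amp *= 0.5  # noise must preserve non-exhaustion
    else:
        noisy = scale * shape
    record = PowerRecord(
        t, noisy,
        source=f"synthetic race (seed={seed}, drain_target={drain_target})",
    )
    return (record, clean) if with_profile else record
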