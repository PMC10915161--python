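# Methods

## Model

The simulator integrates a three-compartment hydraulic analogue of muscle
energetics applied to the muscles engaged in one motor task. State is the
pair of emptying levels `(h, l)` of the phosphagen tank P and the glycolytic
tank G; the oxidative tank O has infinite capacity and no state. All
internal quantities are SI (J, W, s, mL O₂/s); published-table units
(kJ, kJ/s, L/min) are converted at the I/O boundary only.

Assumptions inherited from the model family:

- constant mechanical efficiency `eta` (no fatigue- or cadence-dependence);
- power is the only mechanical variable (no force/velocity components);
- the oxidative store is unlimited on the 1–20 min horizon; fat oxidation is
  negligible at the intensities considered;
- metabolite mappings are linear: `[PC] = pc_max·(1-h)`, lactate
  accumulation proportional to the energy drained from G, V̇O₂ proportional
  to the O→P flux. Modeled V̇O₂ covers the task muscles only and excludes
  resting metabolism; modeled lactate is *muscle* lactate (blood lactate
  lags it and is out of scope).

## Flow laws

The body of the model family's literature fixes the endpoint anchors but not
the full inter-tank flow laws. The package uses linear conductances in the
head difference:

- forward (G→P): `M_G·(h-l)`, so the cap `M_G` is attained exactly at the
  stated extreme `h = 1, l = 0` (instantaneously emptied P over a full G) —
  unreachable in practice;
- reverse (P→G, recovery): `M_R·(l-h)/(1-lam)`, cap attained at the maximal
  physical head `l = 1-lam, h = 0`.

These choices reproduce the whole printed steady-state algebra — the two
threshold expressions, pressure-equalized steady states `h* = l*`, and the
critical drain level `l_crit` — exactly. Transient *shapes* are where the
freedom lives; consequences we have measured and accept as this package's
behavior:

- `(p - p_crit)·TTE` is not a constant "W′": time to exhaustion diverges
  logarithmically (not hyperbolically) at critical power, so the product
  shrinks toward zero there and grows with the power margin, bounded by the
  mechanical non-oxidative capacity.
- the accumulated-oxygen-deficit curve plateaus (95% of supremum) at 3 min
  of exhaustion duration for the first packaged cyclist (published worked
  example: ≈4 min). The plateau position is a deterministic consequence of
  the conductances; we report what the model computes.

## Twin construction

Pipeline (each stage a pure function, errors tagged with the stage name):
muscle mass → efficiency (`p_lt1/(alpha·vo2max·C1)`, warn outside
0.18–0.30) → direct flows `M_O, M_P` → heights `theta = alpha·(1-phi)`,
`lam` from the critical-power expression → `l_crit` by inverting the
fatigue law → capacities `A_P = pc_max·m·C3` and
`A_T = (la_lt1-la_rest)/theta·m·C2` → `A_G` absorbing the measured
non-oxidative work → glycolytic flows `M_G = 285·m` (explicit per-athlete
override allowed), `M_R = M_G/2.5`.

Two deliberate choices:

- **A_T uses the above-rest lactate accumulation** (3 − 1.5 = 1.5 mmol/kg
  ww at LT1), not the absolute LT1 concentration: only this form reproduces
  all four published capillary sections (within 0.7%) and makes `l = theta`
  map exactly onto the LT1 lactate value with the resting offset included.
- **beta (fraction of V̇O₂max at critical power) is an input**, back-derived
  as `p_crit/(eta·M_O)` when not measured. The second published cyclist's
  geometry implies `beta = 1.016 > 1`; validation warns rather than errors
  for `beta` up to 1.05 because published parameter sets land there through
  rounding of the underlying thresholds. For such a twin the closed-form
  critical power exceeds `M_O`, no true steady state exists at it, and the
  simulated (bisection) critical power saturates ≈1.6% lower — the
  simulated-vs-analytic equivalence is therefore only claimed for twins with
  `beta ≤ 1`.

The fixtures back-fill the two unpublished columns: task muscle mass from
`A_P/(pc_max·C3)` (≈32 kg for a 64-kg athlete — physiologically implausible
as a literal mass; we treat it, like the source data, as a model-internal
scaling constant) and a representative cycling efficiency of 0.25. Every
physiological-power quantity is independent of that efficiency.

## Numerics

- Fixed-step explicit trapezoidal rule (Heun; the Crank–Nicolson family with
  one functional iteration), default `dt = 0.05 s`. Halving the step changes
  the terminal levels of 10-min scenarios by < 1e-9 (the tested invariant
  demands < 1e-4).
- Steps in which `l` crosses the capillary/main-section junction `theta` are
  split at the crossing so each partial step uses one cross-section
  (right-continuous: `A_G` at `l = theta`; direction decides when sitting
  exactly on the junction). This removes O(dt) artifacts at the junction.
- Exhaustion: demand exceeding `p_max(l)·(1 + 1e-9)` at a step start. In
  all-out mode the demand *is* `p_max(l)`, so the flag cannot trigger.
- Levels are clamped to their physical ranges after each step; a step moving
  a level by more than 0.25 raises an instability error suggesting a
  smaller `dt`.
- Initial condition is rest (`h = l = 0`); resting lactate enters only as
  the observable offset (1.5 mmol/kg ww).
- AOD integrates the positive part of `(p_physio - D_{O→P})/C1`: a
  nondecreasing tally of non-oxidatively supplied energy (oxidative surplus
  during recovery repays the stores but does not erase the deficit).
- Bisections (power for a target time to exhaustion, synthetic-race scale)
  stop at 1 s / 1e-4 drain-fraction tolerances; `time_to_exhaustion` treats
  a 30-min cap as "no exhaustion".

## Protocol conventions

- The severe-domain preset runs at 105% of **critical power** (a demand
  labeled relative to LT1 would be sub-critical and could not exhaust).
- OBLA step test: OBLA power taken as 60% of the V̇O₂max-equivalent
  mechanical power, stages ±50 W around it, 3 min work / 2 min rest.
- Ramp test: 13.6 W/min from 0 W, lactate sampled when power crosses 0, 80,
  95, 110% of critical power (standing in for the "anaerobic threshold").
- Intermittent recovery: % recovery = `100·TTE₂/TTE₁` for equal-power bouts
  (under the linearized tank model this is the reconstituted fraction of the
  non-oxidative capacity); the default work power is bisected for a 4-min
  first bout.
- AOD plateau criterion: shortest duration reaching 95% of the curve's
  supremum, on a 1–12 min grid of exhaustion durations.

## Synthetic race generator

Stands in for recorded maximal competition efforts (which cannot be
shipped): a surge/cruise/sprint profile scaled by bisection *against the
simulator itself* so the finish-line drain of the non-oxidative capacity
equals a target (default 99%), then overlaid with seeded ±3% multiplicative
noise that is verified (and if necessary attenuated) to preserve
non-exhaustion. It emulates the macroscopic structure and sample noise of a
race power file; it does **not** emulate pedal-stroke power variation,
cadence drift, terrain autocorrelation, or measurement dropouts — so tests
passing on it show the calibration logic is self-consistent, not that the
model fits any real athlete's file.

## Known limitations

- Constant efficiency is the strongest physiological simplification; it is
  why all-out end power slightly overestimates field critical power in the
  source data.
- Muscle-to-blood lactate kinetics, V̇O₂ slow component, and efforts beyond
  ~20 min are out of scope.
- `M_R` (recovery flow) is literature-anchored, not individualized; the
  intermittent-recovery percentages are accordingly generic.
- The published parameter sets are reproduced to printed rounding (1%); the
  second cyclist's `beta > 1` inconsistency is inherited, flagged, and
  documented rather than repaired.
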