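"""Literature-anchored physiological constants.

These are the handful of numbers that tie the hydraulic geometry to muscle
biochemistry: energy equivalents of oxygen, lactate and phosphocreatine,
typical metabolite concentrations, and the glycolytic flux scaling.  They are
cohort-level values from the exercise-physiology literature, not per-athlete
measurements, so they live in one frozen record with fixed defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

from .errors import ValidationError


@dataclass(frozen=True)
class PhysioConstants:
    """Energy equivalents and reference concentrations.

    Attributes
    ----------
    c1:
        Energy equivalent of oxygen, J per mL O2.
    c2:
        Energy equivalent of accumulated muscle lactate, J per mmol.
    c3:
        Energy equivalent of phosphocreatine, J per mmol.
    pc_max:
        Maximal muscle phosphocreatine concentration, mmol per kg wet weight.
    la_rest:
        Resting muscle lactate, mmol per kg wet weight.
    la_lt1:
        Muscle lactate at the first lactate threshold, mmol per kg wet weight.
    mg_specific:
        Maximal glycolytic flux per unit task muscle mass, J/s per kg.
    mr_ratio:
        Ratio of maximal glycolytic outflow to maximal recovery inflow
        (M_G / M_R), dimensionless; anchored on the H/M-LDH isoform kinetics.
    phi_default:
        Default elevation of the oxidative compartment, dimensionless.
    """

    c1: float = 20.9
    c2: float = 100.0
    c3: float = 43.3
    pc_max: float = 20.0
    la_rest: float = 1.5
    la_lt1: float = 3.0
    mg_specific: float = 285.0
    mr_ratio: float = 2.5
    phi_default: float = 0.30

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise ValidationError(f"constant {f.name} must be strictly positive, got {v!r}")
        if self.la_lt1 <= self.la_rest:
            raise ValidationError(
                f"la_lt1 ({self.la_lt1}) must exceed la_rest ({self.la_rest})"
            )
        if not 0.0 < self.phi_default < 1.0:
            raise ValidationError(f"phi_default must lie in (0,1), got {self.phi_default}")


#: Module-level default constants shared across the package.
DEFAULT_CONSTANTS = PhysioConstants()
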