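"""File formats: athlete configs, twin files, power records and traces.

Everything is plain diffable text: YAML key-value for configs, ``key: value``
lines for twin files and summaries, CSV with a header for records and traces.
Units at the file boundary follow field conventions (L/min, W, kJ); they are
converted to internal SI (mL/s, W, J) on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, RecordError
from .twin import AthleteTestData, TwinParameters

__all__ = [
    "PowerRecord",
    "read_athlete_config",
    "read_power_record",
    "write_power_record",
    "resample_record",
    "write_twin",
    "read_twin",
    "write_summary",
]

# key -> (AthleteTestData field, conversion to SI)
_CONFIG_KEYS: dict[str, tuple[str, float]] = {
    "body_mass_kg": ("m_athlete", 1.0),
    "muscle_fraction": ("pct_muscle", 1.0),
    "task_muscle_fraction": ("pct_muscle_for_task", 1.0),
    "vo2max_l_min": ("vo2max", 1000.0 / 60.0),  # L/min -> mL/s
    "p_max_w": ("p_max_mec", 1.0),
    "p_lt1_w": ("p_lt1_mec", 1.0),
    "pct_vo2max_lt1": ("alpha", 1.0),
    "p_crit_w": ("p_crit_mec", 1.0),
    "w_nonox_kj": ("w_nonox_mec", 1000.0),
    "m_g_override_kj_s": ("m_g_override", 1000.0),
}
_OPTIONAL_KEYS = {"m_g_override_kj_s"}

# twin file keys <-> TwinParameters fields, with kJ scaling at the boundary
_TWIN_KEYS: dict[str, tuple[str, float]] = {
    "phi": ("phi", 1.0),
    "theta": ("theta", 1.0),
    "lambda": ("lam", 1.0),
    "m_o_kj_s": ("m_o", 1e3),
    "m_p_kj_s": ("m_p", 1e3),
    "m_g_kj_s": ("m_g", 1e3),
    "m_r_kj_s": ("m_r", 1e3),
    "a_p_kj": ("a_p", 1e3),
    "a_g_kj": ("a_g", 1e3),
    "a_t_kj": ("a_t", 1e3),
    "eta": ("eta", 1.0),
    "m_muscle_kg": ("m_muscle", 1.0),
}


@dataclass(frozen=True)
class PowerRecord:
    """An ordered mechanical power time series (s, W) with a provenance tag."""

    time_s: np.ndarray
    power_w: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        p = np.asarray(self.power_w, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "power_w", p)
        if t.ndim != 1 or t.shape != p.shape or t.size == 0:
            raise RecordError("record needs matching, non-empty 1-D time and power arrays")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(p)):
            raise RecordError("record contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise RecordError("record times must be strictly increasing")
        if np.any(p < 0):
            raise RecordError("record powers must be non-negative")

    def __len__(self) -> int:
        return int(self.time_s.size)

    @property
    def duration(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def demand_fn(self):
        """Zero-order-hold interpolant ``t -> power`` over the record span."""
        t, p = self.time_s, self.power_w

        def fn(x: float) -> float:
            i = int(np.searchsorted(t, x, side="right")) - 1
            return float(p[min(max(i, 0), p.size - 1)])

        return fn


def read_athlete_config(path: str | Path) -> AthleteTestData:
    """Parse an athlete YAML config into validated test data (SI units)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping of keys to numbers")
    unknown = sorted(set(raw) - set(_CONFIG_KEYS))
    if unknown:
        raise ConfigError(f"{path}: unknown keys: {', '.join(unknown)}")
    missing = sorted(set(_CONFIG_KEYS) - _OPTIONAL_KEYS - set(raw))
    if missing:
        raise ConfigError(f"{path}: missing keys: {', '.join(missing)}")
    kwargs = {}
    for key, value in raw.items():
        field, scale = _CONFIG_KEYS[key]
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ConfigError(f"{path}: key '{key}': expected a number, got {value!r}")
        kwargs[field] = float(value) * scale
    try:
        return AthleteTestData(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def read_power_record(path: str | Path) -> PowerRecord:
    """Read a ``time_s,power_w`` CSV record."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise RecordError(f"{path}: {exc}") from exc
    if list(df.columns[:2]) != ["time_s", "power_w"]:
        raise RecordError(f"{path}: expected header 'time_s,power_w', got {list(df.columns)}")
    try:
        return PowerRecord(df["time_s"].to_numpy(float), df["power_w"].to_numpy(float),
                           source=str(path))
    except RecordError as exc:
        raise RecordError(f"{path}: {exc}") from exc


def write_power_record(record: PowerRecord, path: str | Path) -> None:
    """Write a record as ``time_s,power_w`` CSV (round-trip lossless)."""
    pd.DataFrame({"time_s": record.time_s, "power_w": record.power_w}).to_csv(
        Path(path), index=False, float_format="%.6g"
    )


def resample_record(record: PowerRecord, dt: float) -> PowerRecord:
    """Linearly resample a record onto a fixed grid of step ``dt`` seconds.

    Endpoints are preserved; the source tag is flagged with the resampling.
    """
    if dt <= 0:
        raise RecordError(f"dt must be > 0, got {dt}")
    t0, t1 = float(record.time_s[0]), float(record.time_s[-1])
    n = int(round((t1 - t0) / dt))
    t = t0 + dt * np.arange(n + 1)
    t[-1] = t1
    p = np.interp(t, record.time_s, record.power_w)
    return PowerRecord(t, p, source=f"{record.source} [resampled dt={dt}]")


def write_twin(twin: TwinParameters, path: str | Path) -> None:
    """Export a twin as flat ``key: value`` text (kJ at the boundary)."""
    lines = []
    for key, (field, scale) in _TWIN_KEYS.items():
        lines.append(f"{key}: {getattr(twin, field) / scale:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_twin(path: str | Path) -> TwinParameters:
    """Read a twin file written by :func:`write_twin`."""
    path = Path(path)
    values: dict[str, float] = {}
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ConfigError(f"{path}:{ln}: expected 'key: value', got {line!r}")
        key, _, val = line.partition(":")
        key = key.strip()
        if key not in _TWIN_KEYS:
            raise ConfigError(f"{path}:{ln}: unknown twin key {key!r}")
        try:
            values[key] = float(val)
        except ValueError as exc:
            raise ConfigError(f"{path}:{ln}: non-numeric value {val.strip()!r}") from exc
    missing = sorted(set(_TWIN_KEYS) - set(values))
    if missing:
        raise ConfigError(f"{path}: missing twin keys: {', '.join(missing)}")
    kwargs = {field: values[key] * scale for key, (field, scale) in _TWIN_KEYS.items()}
    try:
        return TwinParameters(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_summary(summary: dict, path: str | Path) -> None:
    """Write a protocol summary as machine-diffable ``key: value`` lines."""
    lines = []
    for key, value in summary.items():
        if isinstance(value, float):
            lines.append(f"{key}: {value:.6g}")
        elif isinstance(value, (list, tuple, np.ndarray)):
            lines.append(f"{key}: {', '.join(f'{v:.6g}' for v in np.asarray(value).ravel())}")
        else:
            lines.append(f"{key}: {value}")
    Path(path).write_text("\n".join(lines) + "\n")
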