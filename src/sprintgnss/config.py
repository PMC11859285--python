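"""Pipeline configuration.

Every numeric choice of the processing chain lives here so a run can be
serialized (YAML) and reproduced. Defaults follow the published processing
chain: a zero-phase 4th-order 5 Hz Butterworth low-pass for the GNSS
trajectory, a 2nd-order 70 Hz low-pass for ankle accelerometry, exclusion of
the first five steps, and a 400 m target distance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class FilterConfig:
    """GNSS trajectory low-pass filter (applied to u, e and n identically)."""

    cutoff_hz: float = 5.0
    order: int = 4


@dataclass
class DetectConfig:
    """Minima-detection constraints and per-step bookkeeping.

    min_separation_s caps step frequency at 6 Hz, above any human sprint SF.
    The prominence floors reject cm-level (Fix) noise while passing the
    3-7 cm vertical oscillation a spring-mass runner produces.
    """

    min_separation_s: float = 0.167
    min_prominence_pos_m: float = 0.005
    min_prominence_vel_ms: float = 0.05
    exclude_first_steps: int = 5
    target_distance_m: float = 400.0


@dataclass
class ImuConfig:
    """Ankle-IMU filtering and initial-contact onset detection."""

    filter_cutoff_hz: float = 70.0
    filter_order: int = 2
    ic_threshold_mad: float = 3.0
    ic_min_exceedance: float = 0.5 * 9.80665  # m/s^2; impacts are multi-g
    refractory_s: float = 0.25
    baseline_window_s: float = 0.5


@dataclass
class SyncConfig:
    """Jump-signature cross-correlation synchronization."""

    window_s: tuple[float, float] | None = None
    max_lag_s: float = 2.0
    resample_hz: float = 200.0
    min_peak_corr: float = 0.5


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    imu: ImuConfig = field(default_factory=ImuConfig)
    sync: SyncConfig = field(default_factory=SyncConfig)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for section, payload in (d or {}).items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section: {section!r}")
            sub = getattr(cfg, section)
            for key, val in (payload or {}).items():
                if not hasattr(sub, key):
                    raise KeyError(f"unknown config key: {section}.{key}")
                if key == "window_s" and val is not None:
                    val = tuple(float(v) for v in val)
                setattr(sub, key, val)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        w = d["sync"]["window_s"]
        if w is not None:
            d["sync"]["window_s"] = list(w)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
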