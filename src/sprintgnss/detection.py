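"""Step-event detection from the GNSS trajectory and per-step parameters.

Two detectors, both grounded in the spring-mass model of running:

* **Method 1 — vertical-position minima.** The centre of mass is lowest at
  mid-stance, so local minima of the filtered vertical position mark
  mid-stance once per step.
* **Method 2 — vertical-velocity minima.** The centre of mass descends
  through flight and is decelerated by the leg after touchdown, so the
  vertical velocity is most negative at initial contact (IC); local minima
  of the differentiated vertical position mark IC.

Either event train defines steps: the interval between successive events is
the step time, its reciprocal the step frequency (SF), the planar
displacement between the event positions the step length (SL), and
velocity = SF x SL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .errors import DataError
from .geodesy import time_at_distance
from .kinematics import KinematicSeries

log = logging.getLogger("sprintgnss")


class Method(Enum):
    POSITION_MIN = "POSITION_MIN"
    VELOCITY_MIN = "VELOCITY_MIN"
    IMU_IC = "IMU_IC"
    CAMERA_IC = "CAMERA_IC"


class Leg(Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    UNKNOWN = "UNKNOWN"


class Quality(Enum):
    FIX = "FIX"
    FLOAT_TOUCHED = "FLOAT_TOUCHED"


class Section(Enum):
    CURVE = "CURVE"
    STRAIGHT = "STRAIGHT"
    TRANSITION = "TRANSITION"


@dataclass(frozen=True)
class StepEvent:
    """One detected gait event."""

    t: float
    sample_index: int
    method: Method
    leg: Leg = Leg.UNKNOWN
    quality: Quality = Quality.FIX


@dataclass(frozen=True)
class StepRecord:
    """Per-step parameters for the interval between two successive events.

    Parameters are attributed to the interval's *end* event; ``step_index``
    is 1-based (athletics convention).
    """

    step_index: int
    t_start: float
    t_end: float
    step_time: float
    sf: float          # Hz, = 1/step_time
    sl: float          # m, planar chord between the two event positions
    velocity: float    # m/s, = sf * sl exactly
    cum_dist: float    # m, cumulative distance at t_end
    leg: Leg = Leg.UNKNOWN
    section: Section = Section.TRANSITION
    quality: Quality = Quality.FIX


# Track-section ranges of cumulative distance [m]: two curves, two straights;
# everything else (including the first 5 m and the gaps between ranges) is a
# transition zone excluded from section-stratified statistics.
CURVE_RANGES = ((5.0, 115.0), (205.0, 315.0))
STRAIGHT_RANGES = ((125.0, 195.0), (325.0, 400.0))


def detect_minima(x, rate: float, min_separation: float,
                  min_prominence: float) -> np.ndarray:
    """Indices of local minima with prominence and separation constraints.

    Among candidate minima closer than ``min_separation`` the deeper one is
    kept (ties: the earlier). Flat minima resolve to the first sample of the
    flat run. An empty result is allowed.
    """
    x = np.asarray(x, dtype=float)
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    distance = max(1, int(round(min_separation * rate)))
    _, props = sps.find_peaks(-x, prominence=min_prominence,
                              plateau_size=(1, None))
    # find_peaks reports the plateau midpoint; the contract is its first sample
    cand = props["left_edges"].astype(int)
    if len(cand) == 0:
        return cand
    depth = -x[cand]
    # greedy: deepest first, earlier index breaks ties; drop anything within
    # min_separation of an already-accepted minimum
    order = np.lexsort((cand, -depth))
    accepted: list[int] = []
    for k in order:
        c = int(cand[k])
        if all(abs(c - a) >= distance for a in accepted):
            accepted.append(c)
    return np.array(sorted(accepted), dtype=int)


def _interval_quality(status: np.ndarray, i: int, j: int) -> Quality:
    """FLOAT_TOUCHED if any epoch in [i, j] ran on a Float solution."""
    return (Quality.FLOAT_TOUCHED if np.any(status[i:j + 1] == "FLOAT")
            else Quality.FIX)


def _refine_minimum_time(x: np.ndarray, t: np.ndarray, k: int) -> float:
    """Sub-sample minimum location by a parabola through the three samples
    around ``k``; the sampling grid (10 ms at 100 Hz) would otherwise
    quantize event times and alias into per-step SF."""
    if not 0 < k < len(x) - 1:
        return float(t[k])
    y0, y1, y2 = x[k - 1], x[k], x[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom <= 0:
        return float(t[k])
    delta = float(np.clip(0.5 * (y0 - y2) / denom, -0.5, 0.5))
    dt = t[k + 1] - t[k] if delta >= 0 else t[k] - t[k - 1]
    return float(t[k] + delta * dt)


def _events_from_minima(kin: KinematicSeries, x: np.ndarray,
                        indices: np.ndarray, method: Method) -> list[StepEvent]:
    events = []
    prev = 0
    for k in indices:
        k = int(k)
        events.append(StepEvent(
            t=_refine_minimum_time(x, kin.t, k), sample_index=k, method=method,
            quality=_interval_quality(kin.status, prev, k)))
        prev = k
    return events


def method1_events(kin: KinematicSeries, cfg: PipelineConfig | None = None) -> list[StepEvent]:
    """Mid-stance events: minima of the filtered vertical position."""
    cfg = cfg or PipelineConfig()
    idx = detect_minima(kin.u_f, kin.rate, cfg.detect.min_separation_s,
                        cfg.detect.min_prominence_pos_m)
    return _events_from_minima(kin, kin.u_f, idx, Method.POSITION_MIN)


def method2_events(kin: KinematicSeries, cfg: PipelineConfig | None = None) -> list[StepEvent]:
    """Initial-contact events: minima of the vertical velocity."""
    cfg = cfg or PipelineConfig()
    idx = detect_minima(kin.v_u, kin.rate, cfg.detect.min_separation_s,
                        cfg.detect.min_prominence_vel_ms)
    return _events_from_minima(kin, kin.v_u, idx, Method.VELOCITY_MIN)


def classify_section(d: float) -> Section:
    """Track section at cumulative distance ``d`` metres from the start."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    for lo, hi in CURVE_RANGES:
        if lo <= d <= hi:
            return Section.CURVE
    for lo, hi in STRAIGHT_RANGES:
        if lo <= d <= hi:
            return Section.STRAIGHT
    return Section.TRANSITION


def assign_legs(events: list[StepEvent], first_leg: Leg) -> list[StepEvent]:
    """Label events with strictly alternating legs starting at ``first_leg``."""
    if first_leg not in (Leg.LEFT, Leg.RIGHT):
        raise ValueError("first_leg must be LEFT or RIGHT")
    other = Leg.RIGHT if first_leg is Leg.LEFT else Leg.LEFT
    return [replace(ev, leg=first_leg if k % 2 == 0 else other)
            for k, ev in enumerate(events)]


def build_step_records(events: list[StepEvent], kin: KinematicSeries) -> list[StepRecord]:
    """Per-step parameters from consecutive events.

    Record k spans events k -> k+1: step time is the event interval,
    SF = 1/step time, SL the planar chord between the event positions, and
    velocity = SF x SL. Section is classified at the end event's cumulative
    distance; leg and quality come from the end event / the spanned epochs.
    """
    if len(events) < 2:
        raise DataError(f"need at least 2 events to form steps, got {len(events)}")
    records = []
    t_ev = np.array([ev.t for ev in events])
    e_ev = np.interp(t_ev, kin.t, kin.e_f)
    n_ev = np.interp(t_ev, kin.t, kin.n_f)
    d_ev = np.interp(t_ev, kin.t, kin.cum_dist)
    for k in range(len(events) - 1):
        a, b = events[k], events[k + 1]
        i, j = a.sample_index, b.sample_index
        dt = b.t - a.t
        sf = 1.0 / dt
        sl = float(np.hypot(e_ev[k + 1] - e_ev[k], n_ev[k + 1] - n_ev[k]))
        d_end = float(d_ev[k + 1])
        records.append(StepRecord(
            step_index=k + 1, t_start=a.t, t_end=b.t, step_time=dt,
            sf=sf, sl=sl, velocity=sf * sl, cum_dist=d_end, leg=b.leg,
            section=classify_section(d_end),
            quality=_interval_quality(kin.status, i, j)))
    return records


def exclude_initial_steps(records: list[StepRecord], k: int = 5) -> list[StepRecord]:
    """Drop the first ``k`` steps (transient block-start mechanics)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= len(records):
        log.warning("excluding %d steps from a series of %d leaves nothing",
                    k, len(records))
        return []
    return records[k:]


@dataclass
class SprintSummary:
    """Whole-run summary derived from one event train."""

    total_steps: int
    total_time: float          # s, from run start to the target distance
    target_distance: float     # m
    float_fraction: float      # fraction of epochs on a Float solution
    step_t: np.ndarray         # per-step end times [s]
    step_cum_dist: np.ndarray  # per-step cumulative distance [m]
    step_velocity: np.ndarray  # per-step velocity [m/s]
    step_sf: np.ndarray        # per-step SF [Hz]
    step_sl: np.ndarray        # per-step SL [m]
    step_quality: list[Quality]


def sprint_summary(kin: KinematicSeries, records: list[StepRecord],
                   target_distance: float = 400.0,
                   t_start: float | None = None) -> SprintSummary:
    """Total step count and the time to cover ``target_distance``.

    The total time interpolates the cumulative-distance series at the target
    (e.g. 400 m) and subtracts the run start (first sample unless given).
    Each record ends at a footstrike and the first record's start event is a
    footstrike too, so the step count is ``len(records) + 1``.
    """
    t0 = float(kin.t[0]) if t_start is None else float(t_start)
    t_fin = time_at_distance(kin.t, kin.cum_dist, target_distance)
    return SprintSummary(
        total_steps=len(records) + 1 if records else 0,
        total_time=t_fin - t0,
        target_distance=target_distance,
        float_fraction=float(np.mean(kin.status == "FLOAT")),
        step_t=np.array([r.t_end for r in records]),
        step_cum_dist=np.array([r.cum_dist for r in records]),
        step_velocity=np.array([r.velocity for r in records]),
        step_sf=np.array([r.sf for r in records]),
        step_sl=np.array([r.sl for r in records]),
        step_quality=[r.quality for r in records],
    )
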