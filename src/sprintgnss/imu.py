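"""Reference initial-contact events from ankle IMUs and stream synchronization.

The resultant acceleration sqrt(ax^2 + ay^2 + az^2) is orientation-free, so
no gravity removal is needed: at rest it sits at 1 g, and foot strike shows
as a sharp transient. IC is taken as the *onset* of that transient — the
first sample exceeding a rolling-median baseline by a multiple of the local
MAD — with a refractory period of one stride so each foot fires once per
stride.

Cross-stream synchronization exploits the pre-run vertical jump: the jump
produces matching signatures in the GNSS vertical velocity and the head-IMU
resultant, and normalized cross-correlation with parabolic sub-sample
refinement recovers the clock offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .config import PipelineConfig
from .detection import Leg, Method, StepEvent
from .kinematics import butterworth_zero_phase

log = logging.getLogger("sprintgnss")


@dataclass
class ResultantSeries:
    t: np.ndarray
    a_r: np.ndarray     # m/s^2, >= 0
    side: str = "UNKNOWN"

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))


@dataclass
class SyncResult:
    """Clock offset between two streams.

    ``offset`` is the time at which stream B sees a feature minus the time
    stream A sees the same feature (t_B - t_A): subtract it from B's
    timestamps to express them on A's clock.
    """

    offset: float       # s, t_B - t_A
    peak_corr: float    # normalized correlation at the peak, in [-1, 1]
    reliable: bool


def resultant_acceleration(t, ax, ay, az, side: str = "UNKNOWN") -> ResultantSeries:
    """Euclidean norm of the three axes; gravity is deliberately retained."""
    ax, ay, az = (np.asarray(v, dtype=float) for v in (ax, ay, az))
    if not (len(ax) == len(ay) == len(az) == len(t)):
        raise ValueError("axis arrays must share one length")
    return ResultantSeries(t=np.asarray(t, dtype=float),
                           a_r=np.sqrt(ax**2 + ay**2 + az**2), side=side)


def filter_imu(a_r, rate: float, cutoff: float = 70.0, order: int = 2) -> np.ndarray:
    """Zero-phase low-pass for the resultant acceleration (default 70 Hz, order 2)."""
    if rate <= 2 * cutoff:
        raise ValueError(f"IMU rate {rate} Hz must exceed twice the {cutoff} Hz cutoff")
    return butterworth_zero_phase(a_r, rate, cutoff, order)


def detect_ic_imu(a_r_filtered, rate: float, cfg: PipelineConfig | None = None,
                  t0: float = 0.0, side: str = "UNKNOWN") -> list[StepEvent]:
    """Initial contacts as impact-transient onsets in the filtered resultant.

    A sample fires when it first exceeds baseline + k*MAD, where both the
    baseline (rolling median) and the MAD (rolling median absolute deviation)
    are computed over ``baseline_window_s``; subsequent crossings within the
    refractory period (default 0.25 s, under half the slowest stride) are
    suppressed. The threshold never drops below an absolute exceedance floor
    (default 0.5 g above baseline): on a quiet sensor k*MAD approaches the
    noise quantiles and would fire on noise, while true footstrike
    transients are several g.
    """
    cfg = cfg or PipelineConfig()
    x = np.asarray(a_r_filtered, dtype=float)
    win = max(3, int(round(cfg.imu.baseline_window_s * rate)) | 1)  # odd
    baseline = ndimage.median_filter(x, size=win, mode="nearest")
    dev = np.abs(x - baseline)
    mad = ndimage.median_filter(dev, size=win, mode="nearest")
    mad = np.maximum(mad, 1e-9)
    exceed = np.maximum(cfg.imu.ic_threshold_mad * mad, cfg.imu.ic_min_exceedance)
    above = x > baseline + exceed
    onsets = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    refractory = int(round(cfg.imu.refractory_s * rate))
    events, last = [], -np.inf
    leg = Leg[side] if side in Leg.__members__ else Leg.UNKNOWN
    for k in onsets:
        if k - last >= refractory:
            events.append(StepEvent(t=t0 + k / rate, sample_index=int(k),
                                    method=Method.IMU_IC, leg=leg))
            last = k
    return events


def estimate_offset(sig_a, sig_b, rate: float, max_lag: float,
                    min_peak_corr: float = 0.5) -> SyncResult:
    """Clock offset of stream B relative to stream A by cross-correlation.

    Both signals must share ``rate`` and cover the same nominal window. If B
    shows the same feature d seconds later than A, the returned offset is +d
    (offset = t_B - t_A); subtract it from B's timestamps to align with A.
    The correlation peak is refined by fitting a parabola through its three
    surrounding samples.
    """
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    a = (a - a.mean())
    b = (b - b.mean())
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return SyncResult(offset=0.0, peak_corr=0.0, reliable=False)
    corr = sps.correlate(a, b, mode="full") / denom
    lags = sps.correlation_lags(len(a), len(b), mode="full")
    max_lag_n = int(round(max_lag * rate))
    keep = np.abs(lags) <= max_lag_n
    corr, lags = corr[keep], lags[keep]
    k = int(np.argmax(corr))
    peak = float(corr[k])
    lag = float(lags[k])
    if 0 < k < len(corr) - 1:
        y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
        denom2 = y0 - 2 * y1 + y2
        if denom2 != 0:
            lag += 0.5 * (y0 - y2) / denom2
    reliable = peak >= min_peak_corr
    if not reliable:
        log.warning("synchronization unreliable: peak correlation %.3f < %.2f",
                    peak, min_peak_corr)
    return SyncResult(offset=-lag / rate, peak_corr=peak, reliable=reliable)


def sync_streams(t_a, x_a, t_b, x_b, window: tuple[float, float],
                 resample_hz: float = 200.0, max_lag: float = 2.0,
                 min_peak_corr: float = 0.5) -> SyncResult:
    """Resample two unevenly clocked signals over a window and estimate offset.

    Typical use: ``x_a`` = GNSS vertical velocity, ``x_b`` = head-IMU
    resultant deviation from rest, ``window`` bracketing the pre-run jump.
    """
    lo, hi = window
    grid = np.arange(lo, hi, 1.0 / resample_hz)
    a = np.interp(grid, np.asarray(t_a, float), np.asarray(x_a, float))
    b = np.interp(grid, np.asarray(t_b, float), np.asarray(x_b, float))
    return estimate_offset(a, b, resample_hz, max_lag, min_peak_corr)


def sync_gnss_head(kin, head: ResultantSeries, window: tuple[float, float],
                   resample_hz: float = 200.0, max_lag: float = 2.0,
                   min_peak_corr: float = 0.5) -> SyncResult:
    """Clock offset between the GNSS stream and the head IMU from the jump.

    Correlates like with like: the magnitude of the GNSS vertical
    acceleration (derivative of the vertical velocity) against the head
    resultant's deviation from rest — both trace |vertical CoM acceleration|
    during the jump, so the correlation peak is sharp.
    """
    rate = 1.0 / float(np.median(np.diff(kin.t)))
    acc = np.gradient(np.asarray(kin.v_u, float), 1.0 / rate)
    dev = np.abs(head.a_r - np.median(head.a_r))
    return sync_streams(kin.t, np.abs(acc), head.t, dev, window,
                        resample_hz=resample_hz, max_lag=max_lag,
                        min_peak_corr=min_peak_corr)


def match_events(test_events: list[StepEvent], ref_events,
                 tol: float | None = None) -> tuple[list[tuple], int, int]:
    """Greedy nearest-neighbour pairing of two time-sorted event lists.

    Pairs within ``tol`` seconds (default: 40% of the median reference step
    time), each event used at most once. Returns (pairs, n_test_unmatched,
    n_ref_unmatched) where each pair is (test_event, ref_event).
    """
    t_test = np.array([e.t for e in test_events])
    t_ref = np.array([e.t for e in ref_events])
    if tol is None:
        if len(t_ref) < 2:
            raise ValueError("cannot derive default tol from < 2 reference events")
        tol = 0.4 * float(np.median(np.diff(t_ref)))
    if len(t_test) == 0 or len(t_ref) == 0:
        return [], len(t_test), len(t_ref)
    dt = np.abs(t_test[:, None] - t_ref[None, :])
    cand = np.argwhere(dt <= tol)
    order = np.argsort(dt[cand[:, 0], cand[:, 1]], kind="stable")
    used_t, used_r, pairs = set(), set(), []
    for i, j in cand[order]:
        if i not in used_t and j not in used_r:
            used_t.add(int(i))
            used_r.add(int(j))
            pairs.append((test_events[int(i)], ref_events[int(j)]))
    pairs.sort(key=lambda p: p[0].t)
    return pairs, len(t_test) - len(used_t), len(t_ref) - len(used_r)
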