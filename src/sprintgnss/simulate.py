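"""Synthetic 400 m sprint generator with spring-mass vertical structure.

The generator produces exactly the signal features the two GNSS detectors
exploit, with known ground truth:

* **Vertical motion.** Each step is a stance phase followed by flight. The
  stance is a half-sine compression dip (depth ``osc_amp``, scaled per leg by
  1 +/- ``asym``), so the centre of mass is lowest at mid-stance. Flight is a
  ballistic parabola anchored at the initial-contact height with its apex at
  mid-flight. Position is continuous everywhere; the vertical velocity drops
  discontinuously at touchdown (the impact), which pins the per-cycle
  velocity minimum exactly at IC. (Exact velocity continuity with a free dip
  depth is dynamically over-determined: a half-sine of depth A leaves stance
  at A*pi/ts while a 0->0 parabola of duration tf must launch at g*tf/2, and
  the two agree only at one amplitude. Real touchdown is an impact, so the
  kink is the physical choice, not a shortcut.)
* **Asymmetry.** A more compliant ("weak") leg compresses deeper *and*
  stays grounded longer: ``asym`` scales dip depth and stance duration
  together. The unequal flight arcs flanking each stance break the local
  mirror symmetry of the position waveform about mid-stance — this is the
  mechanism by which left-right asymmetry perturbs position-minimum (Method
  1) timing while the velocity minimum stays pinned at IC. A pure amplitude
  scale without the duration coupling would leave the waveform exactly
  mirror-symmetric about every mid-stance and shift nothing.
* **Horizontal motion.** The runner advances along a lane-1-like 400 m path
  (curve, straight, curve, straight; default radius 36.80 m, straights
  84.39 m) by the scheduled step length per step, with a smoothstep
  within-step progression. SF and SL follow ramp-to-peak / linear-decay
  schedules whose end values are solved so the totals match the scenario.
* **Noise.** AR(1)-correlated Gaussian noise per local axis (RTK errors are
  temporally correlated; white noise would understate minima jitter), with
  cm-level SDs on Fix spans and 10x that on Float spans.
* **IMU streams.** Ankle accelerometers carry a 1 g baseline plus a decaying
  exponential impact transient at each IC of the matching leg; the head unit
  carries the CoM vertical acceleration. An optional pre-run vertical jump
  is written into both the trajectory and the head IMU for clock sync.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import Leg, Method, StepEvent
from .errors import ConfigError
from .geodesy import enu_to_geodetic
from .io import ImuStream, GnssSample, GnssTrajectory, SolutionStatus

G = 9.80665  # m/s^2


# ---------------------------------------------------------------------------
# configuration

@dataclass
class TrackGeometry:
    # default straights solved from the radius so the lap closes at 400 m
    straight_len: float = 0.5 * (400.0 - 2.0 * np.pi * 36.80)  # ~84.389 m
    curve_radius: float = 36.80   # m

    @property
    def lap_length(self) -> float:
        return 2 * self.straight_len + 2 * np.pi * self.curve_radius


@dataclass
class NoiseConfig:
    fix_sd_h: float = 0.01    # m, horizontal SD on Fix solutions
    fix_sd_v: float = 0.02    # m, vertical SD on Fix solutions
    float_sd_h: float = 0.10  # m, decimetre-level Float regime (10x Fix)
    float_sd_v: float = 0.20
    ar1_rho: float = 0.9      # lag-1 autocorrelation at the GNSS rate (Fix)
    float_ar1_rho: float = 0.999  # Float errors drift over ~10 s, not 0.1 s


@dataclass
class GaitSchedule:
    """Ramp-to-peak then linear-decay schedules for SL and step time."""

    start_sl: float = 1.30    # m
    peak_sl: float = 2.00     # m
    end_sl: float = 1.90      # m
    start_sf: float = 3.20    # Hz
    peak_sf: float = 3.80     # Hz
    end_sf: float = 3.40      # Hz
    ramp_steps: int = 15


@dataclass
class SimConfig:
    n_steps: int = 100
    rate_gnss: float = 100.0
    rate_imu: float = 1000.0
    track: TrackGeometry = field(default_factory=TrackGeometry)
    gait: GaitSchedule = field(default_factory=GaitSchedule)
    duty_factor: float = 0.5      # fraction of step time in stance
    osc_amp: float = 0.05         # m, stance dip depth (literature-typical)
    asym: float = 0.0             # fractional left-right difference
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    float_spans: tuple[tuple[float, float], ...] = ()
    origin: tuple[float, float, float] = (35.0, 135.0, 100.0)
    first_leg: Leg = Leg.RIGHT
    lead_in_s: float = 0.0        # standing time before the gun
    jump: bool = False            # pre-run sync jump during the lead-in
    jump_height: float = 0.20     # m
    imu_clock_offset_s: float = 0.0   # IMU clocks read GNSS time minus this
    impact_amp_g: float = 8.0
    impact_tau_s: float = 0.02
    imu_noise_g: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.duty_factor < 1:
            raise ConfigError("duty_factor must lie in (0, 1)")
        if not abs(self.asym) < 1:
            raise ConfigError("|asym| must be < 1")
        if self.osc_amp <= 0:
            raise ConfigError("osc_amp must be positive")
        for name in ("fix_sd_h", "fix_sd_v", "float_sd_h", "float_sd_v"):
            if getattr(self.noise, name) < 0:
                raise ConfigError(f"noise.{name} must be >= 0")
        if self.jump and self.lead_in_s < 2.0:
            raise ConfigError("jump requires a lead-in of at least 2 s")


@dataclass
class SimTruth:
    """Ground truth for every quantity the detectors estimate.

    One entry per footstrike: ``ic_times[k]`` is the k-th initial contact
    (``total_steps`` of them; the final one crosses the target line), and the
    per-step parameters are attributed to the interval *ending* at that
    strike — for k = 0 the interval runs from the gun, so
    ``sf_true[1:] == 1/np.diff(ic_times)``. ``legs[k]`` is the striking leg
    and ``midstance_times[k]`` the centre of the stance that follows.
    """

    ic_times: np.ndarray          # s, length n
    midstance_times: np.ndarray   # s, length n
    legs: list[Leg]               # length n
    sf_true: np.ndarray           # Hz, length n
    sl_true: np.ndarray           # m, chord between event positions, length n
    v_true: np.ndarray            # m/s, = sf_true * sl_true, length n
    cum_dist_true: np.ndarray     # m, arc distance at each IC, length n
    t_start: float                # s, the gun (end of lead-in)
    total_time: float             # s, gun to the final IC (= the target line)
    total_steps: int

    def ic_events(self) -> list[StepEvent]:
        """Reference IC events (camera-style ground truth)."""
        return [StepEvent(t=float(t), sample_index=k, method=Method.CAMERA_IC,
                          leg=leg)
                for k, (t, leg) in enumerate(zip(self.ic_times, self.legs))]


@dataclass
class SimResult:
    traj: GnssTrajectory
    imu_left: ImuStream
    imu_right: ImuStream
    imu_head: ImuStream
    truth: SimTruth
    clean_enu: tuple[np.ndarray, np.ndarray, np.ndarray]  # (e, n, u) noise-free


# ---------------------------------------------------------------------------
# track path

def make_track_path(track: TrackGeometry):
    """Arclength-parameterized lane path: curve, straight, curve, straight.

    Returns ``path(s) -> (e, n)`` for s in [0, lap_length], starting at the
    origin heading east into the first (counter-clockwise) curve.
    """
    total = track.lap_length
    if abs(total - 400.0) > 1.0:
        raise ConfigError(
            f"track geometry sums to {total:.2f} m; expected 400 +/- 1 m")
    r, length = track.curve_radius, track.straight_len
    c1_end = np.pi * r
    s1_end = c1_end + length
    c2_end = s1_end + np.pi * r

    def path(s):
        s = np.asarray(s, dtype=float)
        e = np.empty_like(s)
        n = np.empty_like(s)
        m = s <= c1_end
        th = s[m] / r
        e[m], n[m] = r * np.sin(th), r * (1 - np.cos(th))
        m = (s > c1_end) & (s <= s1_end)
        e[m], n[m] = -(s[m] - c1_end), 2 * r
        m = (s > s1_end) & (s <= c2_end)
        ph = (s[m] - s1_end) / r
        e[m], n[m] = -length - r * np.sin(ph), r + r * np.cos(ph)
        m = s > c2_end
        e[m], n[m] = -length + (s[m] - c2_end), np.zeros(int(np.sum(m)))
        return e, n

    return path


# ---------------------------------------------------------------------------
# schedules

def _schedule(n: int, start: float, peak: float, end: float, ramp: int) -> np.ndarray:
    """Per-step values: linear ramp start->peak over ``ramp`` steps, then
    linear decay peak->end over the rest."""
    ramp = min(max(ramp, 1), n)
    v = np.empty(n)
    if ramp == 1:
        v[0] = peak
    else:
        v[:ramp] = np.linspace(start, peak, ramp)
    if n > ramp:
        v[ramp:] = peak + (end - peak) * np.arange(1, n - ramp + 1) / (n - ramp)
    return v


def _solve_end(n: int, start: float, peak: float, ramp: int, target_sum: float) -> float:
    """End value making the schedule sum hit ``target_sum`` (sum is linear in end)."""
    s0 = _schedule(n, start, peak, peak, ramp).sum()
    s1 = _schedule(n, start, peak, peak + 1.0, ramp).sum()
    if s1 == s0:
        return peak
    return peak + (target_sum - s0) / (s1 - s0)


def solve_gait_schedule(n_steps: int, peak_sl: float, peak_sf: float,
                        total_distance: float, total_time: float,
                        start_sl: float, start_sf: float,
                        ramp_steps: int) -> GaitSchedule:
    """Build a schedule whose SL sum and step-time sum hit the scenario totals."""
    end_sl = _solve_end(n_steps, start_sl, peak_sl, ramp_steps, total_distance)
    end_t = _solve_end(n_steps, 1.0 / start_sf, 1.0 / peak_sf, ramp_steps, total_time)
    if end_sl <= 0 or end_t <= 0:
        raise ConfigError("scenario totals are unreachable with this ramp")
    return GaitSchedule(start_sl=start_sl, peak_sl=peak_sl, end_sl=end_sl,
                        start_sf=start_sf, peak_sf=peak_sf, end_sf=1.0 / end_t,
                        ramp_steps=ramp_steps)


def step_schedules(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(step_times, step_lengths), each of length n_steps."""
    g = cfg.gait
    sl = _schedule(cfg.n_steps, g.start_sl, g.peak_sl, g.end_sl, g.ramp_steps)
    st = _schedule(cfg.n_steps, 1.0 / g.start_sf, 1.0 / g.peak_sf,
                   1.0 / g.end_sf, g.ramp_steps)
    return st, sl


# ---------------------------------------------------------------------------
# simulation

def _smoothstep(x):
    return x * x * (3.0 - 2.0 * x)


def _leg_sign(leg: Leg) -> float:
    # left = the more compliant leg for asym > 0
    return 1.0 if leg is Leg.LEFT else -1.0


def _ar1_noise(rng, sd: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """AR(1) with per-sample stationary SD ``sd`` and autocorrelation ``rho``."""
    n = len(sd)
    out = np.empty(n)
    innov = rng.standard_normal(n)
    out[0] = sd[0] * innov[0]
    scale = np.sqrt(1.0 - rho * rho)
    for k in range(1, n):
        out[k] = rho[k] * out[k - 1] + sd[k] * scale[k] * innov[k]
    return out


def simulate_sprint(cfg: SimConfig) -> SimResult:
    """Generate GNSS and IMU streams plus ground truth for one sprint.

    Phase layout (one IC and one stance per step, ``n`` of each):
    standing lead-in | drive (gun -> IC 0, flat u, smoothstep advance by
    SL[0]) | for each IC k: half-sine stance dip, then a ballistic flight
    landing at IC k+1 | after the last stance: level running-out tail. The
    k-th scheduled step time spans the interval *ending* at IC k, so the
    final IC sits exactly at gun + sum(step times) = the target-line time.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    step_t, step_sl = step_schedules(cfg)
    n = cfg.n_steps

    # IC times (one per footstrike; interval k ends at ic[k]) and legs
    t0 = cfg.lead_in_s
    ic = t0 + np.cumsum(step_t)                                 # length n
    legs = [cfg.first_leg if k % 2 == 0
            else (Leg.LEFT if cfg.first_leg is Leg.RIGHT else Leg.RIGHT)
            for k in range(n)]

    # stance durations and dip depths; asym couples depth and contact time.
    # The stance at IC k occupies the start of the interval ending at IC k+1.
    t_next = np.concatenate([step_t[1:], [step_t[-1]]])
    scale = np.array([1.0 + cfg.asym * _leg_sign(leg) for leg in legs])
    ts = np.minimum(cfg.duty_factor * t_next * scale, 0.95 * t_next)
    amp = cfg.osc_amp * scale
    midstance = ic + ts / 2.0

    # arc distance at each IC, and per-interval chord truth (from the start
    # position for interval 0)
    s_ic = np.cumsum(step_sl)                                   # length n
    path = make_track_path(cfg.track)
    e_ic, n_ic = path(np.minimum(np.concatenate([[0.0], s_ic]),
                                 cfg.track.lap_length))
    sl_chord = np.hypot(np.diff(e_ic), np.diff(n_ic))
    sf_true = 1.0 / step_t

    tail = 4.0 * float(ts[-1]) + 0.3
    duration = float(ic[-1]) + tail
    tg = np.arange(0.0, duration, 1.0 / cfg.rate_gnss)

    # --- clean vertical position and path distance on the GNSS grid
    u = np.zeros_like(tg)
    s = np.zeros_like(tg)
    # drive phase: smoothstep advance to the first strike; the last part is a
    # small ballistic hop so IC 0 is approached in flight like every other IC
    m = (tg >= t0) & (tg < ic[0])
    s[m] = step_sl[0] * _smoothstep((tg[m] - t0) / step_t[0])
    tf_drive = (1.0 - cfg.duty_factor) * step_t[0]
    md = m & (tg >= ic[0] - tf_drive)
    tau_d = tg[md] - (ic[0] - tf_drive)
    u[md] = 0.5 * G * tau_d * (tf_drive - tau_d)
    # per-sample IC index: phase k spans [ic[k], ic[k+1])
    kidx = np.clip(np.searchsorted(ic, tg, side="right") - 1, 0, n - 1)
    for k in range(n):
        m = (tg >= ic[k]) & (kidx == k)
        if not np.any(m):
            continue
        tau = tg[m] - ic[k]
        uk = np.zeros(len(tau))
        if k < n - 1:
            in_stance = tau < ts[k]
            uk[in_stance] = -amp[k] * np.sin(np.pi * tau[in_stance] / ts[k])
            t_int = step_t[k + 1]          # interval IC k -> IC k+1
            tf = t_int - ts[k]
            fl = ~in_stance & (tau < t_int)
            tau_f = tau[fl] - ts[k]
            uk[fl] = 0.5 * G * tau_f * (tf - tau_f)
            s[m] = s_ic[k] + step_sl[k + 1] * _smoothstep(
                np.clip(tau / t_int, 0.0, 1.0))
        else:
            # final strike: a full symmetric stance dip (so its filtered
            # minimum stays centred on mid-stance), then a half-cosine
            # velocity settle from the stance exit velocity to zero. The
            # acceleration is continuous through the whole run-out (the
            # half-sine stance exits with zero curvature and the settle
            # starts and ends with zero curvature), so the zero-phase filter
            # has nothing to ring on and no spurious minima appear, and the
            # vertical velocity never goes negative after the last IC.
            in_stance = tau < ts[k]
            uk[in_stance] = -amp[k] * np.sin(np.pi * tau[in_stance] / ts[k])
            v_exit = amp[k] * np.pi / ts[k]
            w_set = 2.0 * ts[k]
            st = ~in_stance & (tau < ts[k] + w_set)
            tau_s = tau[st] - ts[k]
            uk[st] = 0.5 * v_exit * (tau_s + (w_set / np.pi)
                                     * np.sin(np.pi * tau_s / w_set))
            uk[tau >= ts[k] + w_set] = 0.5 * v_exit * w_set
            # past the line: keep stepping along the path (virtual steps of
            # the final length/rate) so horizontal speed stays continuous
            vstep = np.floor(tau / step_t[-1])
            frac = tau / step_t[-1] - vstep
            s[m] = s_ic[k] + step_sl[-1] * (vstep + _smoothstep(frac))
        u[m] = uk

    # optional pre-run jump (smooth sin^2 bump) for synchronization
    jump_t = 0.5 * cfg.lead_in_s
    jump_w = 0.6
    u_jump_acc = np.zeros_like(tg)
    if cfg.jump:
        ph = (tg - jump_t) / jump_w
        m = (ph >= 0) & (ph <= 1)
        u[m] += cfg.jump_height * np.sin(np.pi * ph[m]) ** 2
        u_jump_acc[m] = (2.0 * cfg.jump_height * (np.pi / jump_w) ** 2
                         * np.cos(2 * np.pi * ph[m]))

    e, nn = path(np.minimum(s, cfg.track.lap_length - 1e-9))

    # --- solution status and AR(1) noise
    status = np.full(len(tg), "FIX", dtype=object)
    for lo, hi in cfg.float_spans:
        if lo < 0 or hi > duration or hi <= lo:
            raise ConfigError(f"float span ({lo}, {hi}) outside run duration "
                              f"[0, {duration:.2f}]")
        status[(tg >= lo) & (tg < hi)] = "FLOAT"
    is_float = status == "FLOAT"
    sd_h = np.where(is_float, cfg.noise.float_sd_h, cfg.noise.fix_sd_h)
    sd_v = np.where(is_float, cfg.noise.float_sd_v, cfg.noise.fix_sd_v)
    rho = np.where(is_float, cfg.noise.float_ar1_rho, cfg.noise.ar1_rho)
    e_obs = e + _ar1_noise(rng, sd_h, rho)
    n_obs = nn + _ar1_noise(rng, sd_h, rho)
    u_obs = u + _ar1_noise(rng, sd_v, rho)

    lat, lon, h = enu_to_geodetic(e_obs, n_obs, u_obs, cfg.origin)
    samples = [GnssSample(float(t), float(la), float(lo_), float(hh),
                          SolutionStatus[st])
               for t, la, lo_, hh, st in zip(tg, lat, lon, h, status)]
    traj = GnssTrajectory(samples=samples, nominal_rate=cfg.rate_gnss)

    # --- IMU streams (timestamps on the IMU clock)
    ti = np.arange(0.0, duration, 1.0 / cfg.rate_imu)
    noise_sd = cfg.imu_noise_g * G

    def ankle(side: Leg) -> ImuStream:
        az = np.full(len(ti), G) + noise_sd * rng.standard_normal(len(ti))
        ax = noise_sd * rng.standard_normal(len(ti))
        ay = noise_sd * rng.standard_normal(len(ti))
        for t_ic, leg in zip(ic, legs):
            if leg is not side:
                continue
            m = (ti >= t_ic) & (ti < t_ic + 8 * cfg.impact_tau_s)
            az[m] += (cfg.impact_amp_g * G
                      * np.exp(-(ti[m] - t_ic) / cfg.impact_tau_s))
        return ImuStream(ti - cfg.imu_clock_offset_s, ax, ay, az,
                         side=side.value)

    # head unit: gravity + CoM vertical acceleration (stance sine / flight -g)
    az_head = np.full(len(ti), G)
    ki = np.clip(np.searchsorted(ic, ti, side="right") - 1, 0, n - 1)
    for k in range(n):
        m = (ti >= ic[k]) & (ki == k)
        if not np.any(m):
            continue
        tau = ti[m] - ic[k]
        acc = np.zeros(len(tau))
        if k < n - 1:
            in_stance = tau < ts[k]
            acc[in_stance] = (amp[k] * (np.pi / ts[k]) ** 2
                              * np.sin(np.pi * tau[in_stance] / ts[k]))
            fl = ~in_stance & (tau < step_t[k + 1])
            acc[fl] = -G
        else:
            in_stance = tau < ts[k]
            acc[in_stance] = (amp[k] * (np.pi / ts[k]) ** 2
                              * np.sin(np.pi * tau[in_stance] / ts[k]))
            v_exit = amp[k] * np.pi / ts[k]
            w_set = 2.0 * ts[k]
            st = ~in_stance & (tau < ts[k] + w_set)
            acc[st] = (0.5 * v_exit * np.pi / w_set
                       * np.sin(np.pi * (tau[st] - ts[k]) / w_set))
        az_head[m] += acc
    if cfg.jump:
        az_head += np.interp(ti, tg, u_jump_acc)
    az_head += noise_sd * rng.standard_normal(len(ti))
    imu_head = ImuStream(ti - cfg.imu_clock_offset_s,
                         noise_sd * rng.standard_normal(len(ti)),
                         noise_sd * rng.standard_normal(len(ti)),
                         az_head, side="HEAD")

    truth = SimTruth(
        ic_times=ic, midstance_times=midstance, legs=legs,
        sf_true=sf_true, sl_true=sl_chord, v_true=sf_true * sl_chord,
        cum_dist_true=s_ic, t_start=t0,
        total_time=float(ic[-1] - t0), total_steps=n)
    assert len(ic) == len(sl_chord) == n
    return SimResult(traj=traj, imu_left=ankle(Leg.LEFT),
                     imu_right=ankle(Leg.RIGHT), imu_head=imu_head,
                     truth=truth, clean_enu=(e, nn, u))


def sim_config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a (YAML-loaded) mapping with nested sections."""
    d = dict(d or {})
    kwargs = {}
    if "track" in d:
        kwargs["track"] = TrackGeometry(**d.pop("track"))
    if "gait" in d:
        kwargs["gait"] = GaitSchedule(**d.pop("gait"))
    if "noise" in d:
        kwargs["noise"] = NoiseConfig(**d.pop("noise"))
    if "float_spans" in d:
        kwargs["float_spans"] = tuple(tuple(float(v) for v in span)
                                      for span in d.pop("float_spans"))
    if "origin" in d:
        kwargs["origin"] = tuple(float(v) for v in d.pop("origin"))
    if "first_leg" in d:
        kwargs["first_leg"] = Leg[str(d.pop("first_leg")).upper()]
    for key, val in d.items():
        if key not in SimConfig.__dataclass_fields__:
            raise ConfigError(f"unknown SimConfig field {key!r}")
        kwargs[key] = val
    cfg = SimConfig(**kwargs)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# presets

def preset(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Named scenario configurations.

    * ``subjectA_like`` — 200 steps peaking at SL 2.10 m / SF 4.00 Hz over
      400 m in ~55 s, with Float spans covering about half the run.
    * ``subjectB_like`` — 242 steps peaking at SL 1.86 m / SF 3.57 Hz over
      400 m in ~73 s, Fix throughout.
    * ``clean_unit_test`` — 20 steps, zero noise, for exact-recovery tests.
    """
    if name == "subjectA_like":
        gait = solve_gait_schedule(200, peak_sl=2.10, peak_sf=4.00,
                                   total_distance=400.0, total_time=55.06,
                                   start_sl=1.30, start_sf=3.20, ramp_steps=25)
        cfg = SimConfig(n_steps=200, gait=gait, seed=seed,
                        float_spans=((8.0, 18.0), (24.0, 34.0), (41.0, 49.0)))
    elif name == "subjectB_like":
        gait = solve_gait_schedule(242, peak_sl=1.86, peak_sf=3.57,
                                   total_distance=400.0, total_time=73.07,
                                   start_sl=1.20, start_sf=3.00, ramp_steps=25)
        cfg = SimConfig(n_steps=242, gait=gait, seed=seed)
    elif name == "clean_unit_test":
        gait = GaitSchedule(start_sl=1.40, peak_sl=2.00, end_sl=1.95,
                            start_sf=3.20, peak_sf=3.80, end_sf=3.60,
                            ramp_steps=6)
        cfg = SimConfig(n_steps=20, gait=gait, seed=seed,
                        noise=NoiseConfig(fix_sd_h=0.0, fix_sd_v=0.0,
                                          float_sd_h=0.0, float_sd_v=0.0),
                        imu_noise_g=0.0)
    else:
        raise ConfigError(f"unknown preset {name!r}")
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown SimConfig field {key!r}")
        setattr(cfg, key, val)
    return cfg


# ---------------------------------------------------------------------------
# truth serialization

def write_truth_csv(truth: SimTruth, path) -> None:
    """Per-step ground truth as CSV (one row per footstrike).

    Row k carries the interval ending at IC k: its start is the previous IC
    (the gun for the first row).
    """
    starts = np.concatenate([[truth.t_start], truth.ic_times[:-1]])
    df = pd.DataFrame({
        "step_index": np.arange(1, truth.total_steps + 1),
        "t_ic_start_s": starts,
        "t_ic_end_s": truth.ic_times,
        "t_midstance_s": truth.midstance_times,
        "leg": [leg.value for leg in truth.legs],
        "sf_hz": truth.sf_true,
        "sl_m": truth.sl_true,
        "velocity_ms": truth.v_true,
        "cum_dist_m": truth.cum_dist_true,
    })
    df.to_csv(path, index=False, float_format="%.6f")


def read_truth_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
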