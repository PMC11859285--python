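"""Readers and writers for GNSS, IMU and event streams.

Two GNSS dialects are supported:

* ``csv`` — header ``t_s,lat_deg,lon_deg,h_m,status`` with status FIX/FLOAT
  (case-insensitive); unambiguous and diff-able.
* ``rtklib_pos`` — whitespace-delimited RTKLIB solution files: ``%`` comment
  lines are skipped, epochs are either GPST week + seconds-of-week or a
  ``YYYY/MM/DD HH:MM:SS.sss`` stamp, and the solution-quality flag maps
  Q=1 -> FIX, Q=2 -> FLOAT (other Q values are rejected and counted).

IMU CSVs carry ``t_s,ax,ay,az`` preceded by a unit declaration line
(``# unit=g`` or ``# unit=m/s2``); accelerations are normalised to m/s^2
internally (1 g = 9.80665 m/s^2).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .detection import Leg, Quality, Section, StepRecord
from .errors import ConfigError, ParseError, ValidationError

log = logging.getLogger("sprintgnss")

STANDARD_GRAVITY = 9.80665  # m/s^2 per g

GNSS_CSV_COLUMNS = ["t_s", "lat_deg", "lon_deg", "h_m", "status"]
STEP_CSV_COLUMNS = ["step_index", "t_event_s", "step_time_s", "sf_hz", "sl_m",
                    "velocity_ms", "cum_dist_m", "leg", "section", "quality"]


class SolutionStatus(Enum):
    FIX = "FIX"
    FLOAT = "FLOAT"


@dataclass(frozen=True)
class GnssSample:
    t: float      # s, monotonic epoch time
    lat: float    # deg WGS-84
    lon: float    # deg WGS-84
    h: float      # m ellipsoidal height
    status: SolutionStatus

    def __post_init__(self):
        if not -90.0 <= self.lat <= 90.0:
            raise ValidationError(f"latitude {self.lat} out of [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValidationError(f"longitude {self.lon} out of [-180, 180]")


@dataclass
class GnssTrajectory:
    samples: list[GnssSample]
    nominal_rate: float  # Hz

    def __post_init__(self):
        t = np.array([s.t for s in self.samples])
        if len(t) >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                k = int(np.argmax(dt <= 0))
                raise ValidationError(
                    f"time not strictly increasing at sample {k + 1} "
                    f"(t={t[k + 1]:.6f} after t={t[k]:.6f})")
            med = float(np.median(dt))
            if abs(med - 1.0 / self.nominal_rate) > 0.1 / self.nominal_rate:
                raise ValidationError(
                    f"median interval {med:.4f} s inconsistent with nominal "
                    f"rate {self.nominal_rate} Hz")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class ImuSample:
    t: float
    ax: float  # m/s^2
    ay: float
    az: float


class ImuStream:
    """Ordered accelerometer samples with array views for vector maths."""

    def __init__(self, t, ax, ay, az, side: str = "UNKNOWN"):
        self.t = np.asarray(t, dtype=float)
        self.ax = np.asarray(ax, dtype=float)
        self.ay = np.asarray(ay, dtype=float)
        self.az = np.asarray(az, dtype=float)
        self.side = side
        if not (len(self.t) == len(self.ax) == len(self.ay) == len(self.az)):
            raise ValidationError("IMU arrays must share one length")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("IMU time must be strictly increasing")

    @property
    def rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, k: int) -> ImuSample:
        return ImuSample(float(self.t[k]), float(self.ax[k]),
                         float(self.ay[k]), float(self.az[k]))


@dataclass(frozen=True)
class ReferenceEvent:
    t: float
    leg: Leg = Leg.UNKNOWN
    label: str = "IC"

    def __post_init__(self):
        if not np.isfinite(self.t):
            raise ValidationError("reference event time must be finite")


def _infer_rate(t: np.ndarray) -> float:
    if len(t) < 2:
        return 1.0
    med = float(np.median(np.diff(t)))
    if med <= 0:
        raise ValidationError("time not strictly increasing")
    rate = 1.0 / med
    return float(round(rate)) if rate >= 1.0 else rate


def _parse_status(token: str, line_no: int) -> SolutionStatus:
    try:
        return SolutionStatus[token.strip().upper()]
    except KeyError:
        raise ParseError(f"line {line_no}: unknown status {token!r}") from None


def _read_gnss_csv(path: Path) -> list[GnssSample]:
    samples = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip() for c in header] != GNSS_CSV_COLUMNS:
            raise ParseError(f"line 1: expected header {','.join(GNSS_CSV_COLUMNS)}")
        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 5:
                raise ParseError(f"line {line_no}: expected 5 fields, got {len(row)}")
            try:
                t, lat, lon, h = (float(v) for v in row[:4])
            except ValueError:
                raise ParseError(f"line {line_no}: non-numeric field in {row!r}") from None
            samples.append(GnssSample(t, lat, lon, h, _parse_status(row[4], line_no)))
    return samples


def _pos_epoch(tokens: list[str], line_no: int) -> tuple[tuple, int]:
    """Return ((week, seconds) or (None, Timestamp), #tokens consumed)."""
    if "/" in tokens[0]:
        try:
            ts = pd.Timestamp(f"{tokens[0]} {tokens[1]}")
        except ValueError:
            raise ParseError(f"line {line_no}: bad date/time "
                             f"{tokens[0]} {tokens[1]}") from None
        return (None, ts), 2
    try:
        week, sow = float(tokens[0]), float(tokens[1])
    except ValueError:
        raise ParseError(f"line {line_no}: bad GPST epoch {tokens[:2]!r}") from None
    return (week, sow), 2


def _rebase_epochs(epochs: list[tuple]) -> list[float]:
    """Seconds from the first epoch, computed difference-first so GPST
    week-seconds keep full sub-millisecond precision."""
    w0, s0 = epochs[0]
    out = []
    for w, s in epochs:
        if w0 is None:
            out.append(float((s - s0).total_seconds()))
        else:
            out.append((w - w0) * 604800.0 + (s - s0))
    return out


def _read_rtklib_pos(path: Path) -> list[GnssSample]:
    epochs: list[tuple] = []
    rows: list[tuple[float, float, float, int]] = []
    rejected = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            tokens = line.split()
            if len(tokens) < 6:
                raise ParseError(f"line {line_no}: expected epoch, lat, lon, "
                                 f"height and Q fields, got {len(tokens)} tokens")
            epoch, k = _pos_epoch(tokens, line_no)
            try:
                lat, lon, h = (float(v) for v in tokens[k:k + 3])
                q = int(tokens[k + 3])
            except ValueError:
                raise ParseError(f"line {line_no}: non-numeric field") from None
            if q in (1, 2):
                epochs.append(epoch)
                rows.append((lat, lon, h, q))
            else:
                rejected += 1
    if rejected:
        log.info("rtklib_pos: rejected %d rows with Q outside {1, 2}", rejected)
    if not rows:
        raise ParseError("no usable solution rows in file")
    return [GnssSample(t, lat, lon, h,
                       SolutionStatus.FIX if q == 1 else SolutionStatus.FLOAT)
            for t, (lat, lon, h, q) in zip(_rebase_epochs(epochs), rows)]


def read_gnss(path, dialect: str = "csv",
              nominal_rate: float | None = None) -> GnssTrajectory:
    """Read a GNSS position stream; see the module docstring for dialects."""
    path = Path(path)
    if dialect == "csv":
        samples = _read_gnss_csv(path)
    elif dialect == "rtklib_pos":
        samples = _read_rtklib_pos(path)
    else:
        raise ConfigError(f"unknown GNSS dialect {dialect!r}")
    if not samples:
        raise ParseError("no data rows in file")
    if nominal_rate is None:
        nominal_rate = _infer_rate(np.array([s.t for s in samples]))
    traj = GnssTrajectory(samples=samples, nominal_rate=nominal_rate)
    # report tolerated dropped-epoch gaps (processing aborts later if > 5)
    dt = np.diff([s.t for s in samples])
    gaps = np.round(dt * nominal_rate).astype(int) - 1
    n_gaps = int(np.sum(gaps > 0))
    if n_gaps:
        log.info("GNSS stream has %d gaps (longest %d missing epochs)",
                 n_gaps, int(gaps.max()))
    return traj


def read_imu(path, side: str = "UNKNOWN") -> ImuStream:
    """Read an IMU CSV; the unit declaration line is mandatory."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    unit = None
    if first.startswith("#"):
        decl = first.lstrip("#").strip().replace(":", "=")
        if decl.lower().startswith("unit"):
            unit = decl.split("=", 1)[1].strip().lower() if "=" in decl else None
    if unit is None:
        raise ConfigError(f"{path}: first line must declare the unit, "
                          "e.g. '# unit=g' or '# unit=m/s2'")
    if unit not in ("g", "m/s2", "ms2", "m s-2"):
        raise ConfigError(f"{path}: unknown acceleration unit {unit!r}")
    df = pd.read_csv(path, comment="#")
    for col in ("t_s", "ax", "ay", "az"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    scale = STANDARD_GRAVITY if unit == "g" else 1.0
    return ImuStream(df["t_s"].to_numpy(), scale * df["ax"].to_numpy(),
                     scale * df["ay"].to_numpy(), scale * df["az"].to_numpy(),
                     side=side)


def read_reference_events(path) -> list[ReferenceEvent]:
    """Read a reference event list (``t_s`` and optional ``leg`` columns)."""
    df = pd.read_csv(path, comment="#")
    if "t_s" not in df.columns:
        raise ParseError(f"{path}: missing column 't_s'")
    legs = (df["leg"].astype(str).str.upper() if "leg" in df.columns
            else ["UNKNOWN"] * len(df))
    events = [ReferenceEvent(float(t), Leg[leg] if leg in Leg.__members__ else Leg.UNKNOWN)
              for t, leg in zip(df["t_s"], legs)]
    if any(events[k + 1].t <= events[k].t for k in range(len(events) - 1)):
        raise ValidationError(f"{path}: reference event times must increase")
    return events


def write_step_records(records: list[StepRecord], path) -> None:
    """Write per-step parameters as CSV (values round-trip to 1e-6)."""
    if not records:
        raise ValueError("no step records to write")
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(STEP_CSV_COLUMNS)
        for r in records:
            w.writerow([r.step_index, f"{r.t_end:.6f}", f"{r.step_time:.6f}",
                        f"{r.sf:.6f}", f"{r.sl:.6f}", f"{r.velocity:.6f}",
                        f"{r.cum_dist:.6f}", r.leg.value, r.section.value,
                        r.quality.value])


def write_gnss_csv(traj: GnssTrajectory, path) -> None:
    """Write a trajectory in the ``csv`` dialect (lat/lon to 1e-11 deg ~ 1e-6 m)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(GNSS_CSV_COLUMNS)
        for s in traj.samples:
            w.writerow([f"{s.t:.4f}", f"{s.lat:.11f}", f"{s.lon:.11f}",
                        f"{s.h:.6f}", s.status.value])


def write_imu_csv(stream: ImuStream, path, unit: str = "m/s2") -> None:
    """Write an IMU stream with the mandatory unit declaration line."""
    if unit not in ("g", "m/s2"):
        raise ConfigError(f"unknown acceleration unit {unit!r}")
    scale = 1.0 / STANDARD_GRAVITY if unit == "g" else 1.0
    with open(path, "w", newline="") as fh:
        fh.write(f"# unit={unit}\n")
        w = csv.writer(fh)
        w.writerow(["t_s", "ax", "ay", "az"])
        for k in range(len(stream)):
            w.writerow([f"{stream.t[k]:.4f}", f"{scale * stream.ax[k]:.6f}",
                        f"{scale * stream.ay[k]:.6f}", f"{scale * stream.az[k]:.6f}"])


def read_step_records(path) -> list[StepRecord]:
    """Read a per-step CSV written by :func:`write_step_records`."""
    df = pd.read_csv(path)
    missing = [c for c in STEP_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        t_end = float(row.t_event_s)
        dt = float(row.step_time_s)
        records.append(StepRecord(
            step_index=int(row.step_index), t_start=t_end - dt, t_end=t_end,
            step_time=dt, sf=float(row.sf_hz), sl=float(row.sl_m),
            velocity=float(row.velocity_ms), cum_dist=float(row.cum_dist_m),
            leg=Leg[row.leg], section=Section[row.section],
            quality=Quality[row.quality]))
    return records
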