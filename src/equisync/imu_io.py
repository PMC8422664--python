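"""Reading, writing and time-aligning paired 9-DoF IMU logs.

The field setup is two independently clocked loggers — one on the horse's
back, one on the rider's head/helmet — each writing a CSV at a nominal
100 Hz.  A shared push-button sync pulse recorded on both devices lets the
two clocks be reconciled after the fact: the first 0->1 transition of the
pulse channel marks the same physical instant on both logs.

Accelerometer units default to g (Razor-class loggers record in g) and are
converted to m/s^2 on read.  Timestamps are seconds since device boot; the
sync pulse makes absolute time irrelevant.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import errors

log = logging.getLogger(__name__)

STANDARD_GRAVITY = 9.80665
PLACEMENTS = ("rider_head", "horse_back")

#: canonical channel key -> default CSV column name
DEFAULT_COLUMNS: dict[str, str] = {
    "t": "t",
    "ax": "ax", "ay": "ay", "az": "az",
    "gx": "gx", "gy": "gy", "gz": "gz",
    "qw": "qw", "qx": "qx", "qy": "qy", "qz": "qz",
    "sync": "sync",
}
_REQUIRED = ("t", "ax", "ay", "az")
_GYRO = ("gx", "gy", "gz")
_QUAT = ("qw", "qx", "qy", "qz")

#: error if more than this fraction of rows is dropped as non-numeric;
#: only enforced above a minimum row count so tiny logs with one corrupt
#: row still parse (the <2-valid-rows check guards the extremes)
MAX_DROP_FRACTION = 0.05
MIN_ROWS_FOR_DROP_CHECK = 20


@dataclass
class ImuRecording:
    """One sensor's raw timestamped 9-DoF log.

    ``acc`` is (n, 3) in m/s^2; ``gyro`` (n, 3) rad/s, ``orientation``
    (n, 4) unit quaternions in (w, x, y, z) order and ``sync_pulse`` (n,)
    binary are optional.  Timestamps are strictly increasing seconds.
    """

    sensor_id: str
    placement: str
    timestamps: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray | None = None
    orientation: np.ndarray | None = None
    sync_pulse: np.ndarray | None = None
    nominal_rate: float = 100.0
    dropped_rows: int = 0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if self.gyro is not None:
            self.gyro = np.asarray(self.gyro, dtype=float)
        if self.orientation is not None:
            self.orientation = np.asarray(self.orientation, dtype=float)
        if self.sync_pulse is not None:
            self.sync_pulse = np.asarray(self.sync_pulse, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.placement not in PLACEMENTS:
            raise errors.ParameterError(
                f"placement must be one of {PLACEMENTS}, got {self.placement!r}")
        n = self.timestamps.shape[0]
        if n < 2:
            raise errors.EmptyRecordingError(
                f"recording {self.sensor_id!r} has {n} sample(s); need >= 2")
        if not np.all(np.isfinite(self.timestamps)):
            raise errors.FormatError("non-finite timestamps")
        if np.any(np.diff(self.timestamps) <= 0):
            raise errors.OrderingError(
                f"timestamps of {self.sensor_id!r} are not strictly increasing")
        if self.acc.shape != (n, 3):
            raise errors.FormatError(
                f"acc must have shape ({n}, 3), got {self.acc.shape}")
        if not np.all(np.isfinite(self.acc)):
            raise errors.FormatError("non-finite accelerometer values")
        if self.gyro is not None and self.gyro.shape != (n, 3):
            raise errors.FormatError("gyro shape mismatch")
        if self.orientation is not None:
            if self.orientation.shape != (n, 4):
                raise errors.FormatError("orientation shape mismatch")
            norms = np.linalg.norm(self.orientation, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-6):
                raise errors.FormatError(
                    "orientation quaternions are not unit norm (tol 1e-6)")
        if self.sync_pulse is not None and self.sync_pulse.shape != (n,):
            raise errors.FormatError("sync_pulse shape mismatch")

    @property
    def n(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def shift_time(self, dt: float) -> "ImuRecording":
        """Return a copy with all timestamps shifted by ``dt`` seconds."""
        return dataclasses.replace(self, timestamps=self.timestamps + dt)


@dataclass
class SessionPair:
    """Synchronized horse + rider recordings for one session.

    ``sync_offset`` is the rider clock minus the horse clock at the shared
    pulse; ``analysis_window`` is [start, end] in horse-clock seconds and
    covers the continuous-riding phase.
    """

    participant_id: str
    session_index: int
    horse: ImuRecording
    rider: ImuRecording
    sync_offset: float
    analysis_window: tuple[float, float]

    def __post_init__(self) -> None:
        if not 1 <= int(self.session_index) <= 8:
            raise errors.ParameterError(
                f"session_index must be in [1, 8], got {self.session_index}")
        start, end = self.analysis_window
        if end - start < 0:
            raise errors.WindowError("analysis_window end precedes start")


@dataclass
class SessionDescriptor:
    """One manifest entry: who, which session, and where the logs live."""

    participant_id: str
    session_index: int
    horse_log: Path
    rider_log: Path
    offset_override: float | None = None


def _resolve_columns(column_map: Mapping[str, str] | None) -> dict[str, str]:
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMNS)
        if unknown:
            raise errors.ParameterError(
                f"unknown channel keys in column_map: {sorted(unknown)}")
        cols.update(column_map)
    return cols


def _infer_rate(timestamps: np.ndarray) -> float:
    dt = float(np.median(np.diff(timestamps)))
    rate = 1.0 / dt
    # snap to an integer rate when the log is nominally regular
    if abs(rate - round(rate)) < 0.01 * max(1.0, rate):
        rate = float(round(rate))
    return rate


def read_razor_log(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    *,
    acc_units: str = "g",
    sensor_id: str | None = None,
    placement: str = "horse_back",
) -> ImuRecording:
    """Read a Razor-style IMU CSV log into an :class:`ImuRecording`.

    Rows with a non-numeric value in any present mapped column are dropped
    and counted (``dropped_rows``); more than 5% dropped raises.  ``acc_units``
    is ``"g"`` (converted by the standard gravity) or ``"m/s2"``.
    """
    path = Path(path)
    if acc_units not in ("g", "m/s2"):
        raise errors.ParameterError(f"acc_units must be 'g' or 'm/s2', got {acc_units!r}")
    cols = _resolve_columns(column_map)
    df = pd.read_csv(path)
    for key in _REQUIRED:
        if cols[key] not in df.columns:
            raise errors.FormatError(
                f"{path.name}: required column {cols[key]!r} (channel {key!r}) missing")

    have_gyro = all(cols[k] in df.columns for k in _GYRO)
    have_quat = all(cols[k] in df.columns for k in _QUAT)
    have_sync = cols["sync"] in df.columns
    keys = list(_REQUIRED) + (list(_GYRO) if have_gyro else []) \
        + (list(_QUAT) if have_quat else []) + (["sync"] if have_sync else [])

    num = pd.DataFrame({k: pd.to_numeric(df[cols[k]], errors="coerce") for k in keys})
    good = num.notna().all(axis=1)
    dropped = int((~good).sum())
    if len(df) >= MIN_ROWS_FOR_DROP_CHECK and dropped / len(df) > MAX_DROP_FRACTION:
        raise errors.FormatError(
            f"{path.name}: {dropped}/{len(df)} rows non-numeric "
            f"(> {MAX_DROP_FRACTION:.0%}); refusing to silently drop")
    num = num[good]
    if len(num) < 2:
        raise errors.EmptyRecordingError(
            f"{path.name}: {len(num)} valid rows after cleaning; need >= 2")

    t = num["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise errors.OrderingError(
            f"{path.name}: timestamps not strictly increasing after cleaning")

    acc = num[["ax", "ay", "az"]].to_numpy(dtype=float)
    if acc_units == "g":
        acc = acc * STANDARD_GRAVITY
    return ImuRecording(
        sensor_id=sensor_id or path.stem,
        placement=placement,
        timestamps=t,
        acc=acc,
        gyro=num[list(_GYRO)].to_numpy(dtype=float) if have_gyro else None,
        orientation=num[list(_QUAT)].to_numpy(dtype=float) if have_quat else None,
        sync_pulse=num["sync"].to_numpy(dtype=float) if have_sync else None,
        nominal_rate=_infer_rate(t),
        dropped_rows=dropped,
    )


def write_razor_log(
    rec: ImuRecording,
    path: str | Path,
    *,
    acc_units: str = "g",
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write a recording back to the CSV dialect :func:`read_razor_log` reads."""
    if acc_units not in ("g", "m/s2"):
        raise errors.ParameterError(f"acc_units must be 'g' or 'm/s2', got {acc_units!r}")
    cols = _resolve_columns(column_map)
    acc = rec.acc / STANDARD_GRAVITY if acc_units == "g" else rec.acc
    data: dict[str, np.ndarray] = {cols["t"]: rec.timestamps}
    for i, k in enumerate(("ax", "ay", "az")):
        data[cols[k]] = acc[:, i]
    if rec.gyro is not None:
        for i, k in enumerate(_GYRO):
            data[cols[k]] = rec.gyro[:, i]
    if rec.orientation is not None:
        for i, k in enumerate(_QUAT):
            data[cols[k]] = rec.orientation[:, i]
    if rec.sync_pulse is not None:
        data[cols["sync"]] = rec.sync_pulse
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def detect_sync_pulse(rec: ImuRecording) -> float:
    """Timestamp of the first 0->1 transition of the sync channel."""
    if rec.sync_pulse is None:
        raise errors.MissingChannelError(
            f"recording {rec.sensor_id!r} has no sync_pulse channel")
    high = rec.sync_pulse > 0.5
    idx = np.flatnonzero(~high[:-1] & high[1:])
    if idx.size == 0:
        raise errors.NoPulseError(
            f"recording {rec.sensor_id!r}: no 0->1 sync transition")
    return float(rec.timestamps[idx[0] + 1])


def align_pair(
    horse: ImuRecording,
    rider: ImuRecording,
    window: tuple[float, float] | None = None,
    *,
    offset: float | None = None,
    participant_id: str = "anon",
    session_index: int = 1,
    window_duration_s: float = 600.0,
    min_overlap_s: float = 60.0,
) -> SessionPair:
    """Assemble a :class:`SessionPair` from two recordings.

    ``sync_offset`` = rider pulse time - horse pulse time (rider clock minus
    horse clock at the shared instant).  The analysis window defaults to
    [horse pulse, pulse + ``window_duration_s``] clipped to the common
    overlap, all in horse-clock seconds.
    """
    if offset is None:
        offset = detect_sync_pulse(rider) - detect_sync_pulse(horse)
    offset = float(offset)

    # common span on the horse clock
    start = max(horse.timestamps[0], rider.timestamps[0] - offset)
    end = min(horse.timestamps[-1], rider.timestamps[-1] - offset)
    if end - start < min_overlap_s:
        raise errors.InsufficientOverlapError(
            f"recordings overlap by {end - start:.1f} s after alignment; "
            f"need >= {min_overlap_s:g} s")

    if window is None:
        anchor = detect_sync_pulse(horse) if horse.sync_pulse is not None else start
        window = (max(start, anchor), min(end, anchor + window_duration_s))
    w0, w1 = float(window[0]), float(window[1])
    if min(w1, end) - max(w0, start) < min_overlap_s:
        raise errors.InsufficientOverlapError(
            f"analysis window [{w0:g}, {w1:g}] overlaps the common span "
            f"[{start:g}, {end:g}] by less than {min_overlap_s:g} s")
    return SessionPair(
        participant_id=participant_id,
        session_index=int(session_index),
        horse=horse,
        rider=rider,
        sync_offset=offset,
        analysis_window=(max(w0, start), min(w1, end)),
    )


def load_session_manifest(path: str | Path) -> list[SessionDescriptor]:
    """Read a YAML session manifest into validated descriptors.

    Each entry: ``{participant, session, horse_log, rider_log,
    offset_override (optional)}``.  Paths are resolved relative to the
    manifest's directory.  Order is preserved.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not raw:
        log.warning("manifest %s is empty", path)
        return []
    if not isinstance(raw, list):
        raise errors.ManifestError(f"{path.name}: manifest must be a YAML list")
    base = path.parent
    out: list[SessionDescriptor] = []
    seen: set[tuple[str, int]] = set()
    for i, entry in enumerate(raw):
        if not isinstance(entry, Mapping):
            raise errors.ManifestError(f"{path.name}: entry {i} is not a mapping")
        missing = {"participant", "session", "horse_log", "rider_log"} - set(entry)
        if missing:
            raise errors.ManifestError(
                f"{path.name}: entry {i} missing keys {sorted(missing)}")
        pid = str(entry["participant"])
        sess = int(entry["session"])
        if not 1 <= sess <= 8:
            raise errors.ManifestError(
                f"{path.name}: entry {i} ({pid}): session {sess} not in [1, 8]")
        if (pid, sess) in seen:
            raise errors.DuplicateEntryError(
                f"{path.name}: duplicate entry for participant {pid!r} session {sess}")
        seen.add((pid, sess))
        hlog = base / str(entry["horse_log"])
        rlog = base / str(entry["rider_log"])
        for p in (hlog, rlog):
            if not p.exists():
                raise errors.ManifestError(
                    f"{path.name}: entry {i} ({pid}, session {sess}): "
                    f"file not found: {p}")
        off = entry.get("offset_override")
        out.append(SessionDescriptor(pid, sess, hlog, rlog,
                                     None if off is None else float(off)))
    return out


def load_pair(
    desc: SessionDescriptor,
    *,
    column_map: Mapping[str, str] | None = None,
    acc_units: str = "g",
    window: tuple[float, float] | None = None,
    **align_kwargs,
) -> SessionPair:
    """Read both logs of a manifest entry and align them."""
    horse = read_razor_log(desc.horse_log, column_map, acc_units=acc_units,
                           placement="horse_back")
    rider = read_razor_log(desc.rider_log, column_map, acc_units=acc_units,
                           placement="rider_head")
    return align_pair(
        horse, rider, window,
        offset=desc.offset_override,
        participant_id=desc.participant_id,
        session_index=desc.session_index,
        **align_kwargs,
    )
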