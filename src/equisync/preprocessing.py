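"""From raw recording to analysis-ready vertical acceleration.

The analyzed channel is the vertical acceleration ACCz — treated as a
mass-normalized proxy for the horse-rider interaction force.  The steps
are: resample onto a uniform grid (logs jitter), take the vertical
component (sensor z-axis by default, or world-frame z via the orientation
quaternions), remove the gravity baseline (sub-1 Hz content is a constant
gravity artifact, not gait), and restrict to the continuous-riding window.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.spatial.transform import Rotation

from . import errors
from .imu_io import ImuRecording

FRAME_MODES = ("sensor_z", "world_z")


@dataclass
class VerticalSignal:
    """Uniformly sampled vertical acceleration, m/s^2.

    Sample ``k`` sits at time ``t0 + k / rate`` (absolute session seconds;
    cropping never re-zeroes phase relationships between horse and rider).
    """

    t0: float
    rate: float
    values: np.ndarray
    baseline_removed: bool
    source_placement: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise errors.ParameterError(f"rate must be > 0, got {self.rate}")
        if not np.all(np.isfinite(self.values)):
            raise errors.FormatError("non-finite signal values")
        if self.baseline_removed and self.values.size:
            scale = max(1.0, float(np.max(np.abs(self.values))))
            if abs(float(np.mean(self.values))) > 1e-6 * scale:
                raise errors.ContractError(
                    "baseline_removed signal has nonzero mean")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    @property
    def duration(self) -> float:
        """Half-open span [t0, t0 + n/rate)."""
        return self.n / self.rate


def _grid(first: float, last: float, rate: float) -> np.ndarray:
    n = int(math.floor((last - first) * rate + 1e-9)) + 1
    return first + np.arange(n) / rate


def resample_uniform(
    rec: ImuRecording,
    rate: float,
    *,
    t_start: float | None = None,
    t_end: float | None = None,
) -> ImuRecording:
    """Linearly interpolate every channel onto a uniform grid.

    The grid is ``t_start + k / rate`` spanning [t_start, t_end] (defaults:
    the recording's first and last timestamps), with
    ``floor((t_end - t_start) * rate) + 1`` samples.  Linear interpolation
    is used for robustness to log jitter (no overshoot); quaternions are
    re-normalized after interpolation.  Anchors outside the recorded span
    clamp to the end samples.
    """
    if rate <= 0:
        raise errors.ParameterError(f"rate must be > 0, got {rate}")
    t = rec.timestamps
    first = float(t[0] if t_start is None else t_start)
    last = float(t[-1] if t_end is None else t_end)
    if last <= first:
        raise errors.ParameterError("t_end must exceed t_start")
    grid = _grid(first, last, rate)

    def interp(col: np.ndarray) -> np.ndarray:
        return np.interp(grid, t, col)

    acc = np.column_stack([interp(rec.acc[:, i]) for i in range(3)])
    gyro = None
    if rec.gyro is not None:
        gyro = np.column_stack([interp(rec.gyro[:, i]) for i in range(3)])
    quat = None
    if rec.orientation is not None:
        quat = np.column_stack([interp(rec.orientation[:, i]) for i in range(4)])
        quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    sync = None
    if rec.sync_pulse is not None:
        sync = (interp(rec.sync_pulse) > 0.5).astype(float)
    return dataclasses.replace(
        rec, timestamps=grid, acc=acc, gyro=gyro, orientation=quat,
        sync_pulse=sync, nominal_rate=float(rate))


def _uniform_rate(rec: ImuRecording) -> float:
    dt = np.diff(rec.timestamps)
    step = float(np.mean(dt))
    if np.max(np.abs(dt - step)) > 1e-6 * step:
        raise errors.ParameterError(
            f"recording {rec.sensor_id!r} is not uniformly sampled; "
            "apply resample_uniform first")
    return 1.0 / step


def extract_vertical(rec: ImuRecording, frame_mode: str = "sensor_z") -> VerticalSignal:
    """Take the vertical acceleration component of a uniform recording.

    ``sensor_z``: third accelerometer component, the study convention.
    ``world_z``: rotate each acceleration vector into the world frame using
    the per-sample orientation quaternion (sensor-to-world, (w, x, y, z))
    and take the vertical component — appropriate when a head-mounted
    sensor tilts.
    """
    if frame_mode not in FRAME_MODES:
        raise errors.ParameterError(
            f"frame_mode must be one of {FRAME_MODES}, got {frame_mode!r}")
    rate = _uniform_rate(rec)
    if frame_mode == "sensor_z":
        values = rec.acc[:, 2].copy()
    else:
        if rec.orientation is None:
            raise errors.MissingChannelError(
                f"recording {rec.sensor_id!r}: world_z requires the "
                "orientation channel")
        # scipy quaternions are (x, y, z, w)
        rot = Rotation.from_quat(rec.orientation[:, [1, 2, 3, 0]])
        values = rot.apply(rec.acc)[:, 2]
    return VerticalSignal(
        t0=float(rec.timestamps[0]), rate=rate, values=values,
        baseline_removed=False, source_placement=rec.placement)


def remove_baseline(sig: VerticalSignal, cutoff: float = 1.0) -> VerticalSignal:
    """High-pass away the gravity baseline and subtract the mean.

    ``cutoff`` = 0 subtracts the mean only; otherwise a 4th-order
    zero-phase (forward-backward) Butterworth high-pass at ``cutoff`` Hz is
    applied first, discarding the sub-cutoff gravity artifact in the time
    domain so correlation and spectral metrics see the same content.
    """
    if not 0 <= cutoff < sig.rate / 2:
        raise errors.ParameterError(
            f"cutoff must be in [0, rate/2) = [0, {sig.rate / 2:g}), got {cutoff}")
    v = sig.values
    if cutoff > 0:
        sos = butter(4, cutoff, btype="highpass", fs=sig.rate, output="sos")
        v = sosfiltfilt(sos, v)
    v = v - np.mean(v)
    return dataclasses.replace(sig, values=v, baseline_removed=True)


def crop_window(
    sig: VerticalSignal,
    window: tuple[float, float],
    *,
    min_overlap_s: float = 60.0,
) -> VerticalSignal:
    """Keep samples with t in the half-open window [start, end).

    If the signal is baseline-removed, the retained window is re-demeaned so
    the zero-mean contract survives cropping (Pearson correlation demeans
    per overlap, so this is metrically neutral).
    """
    start, end = float(window[0]), float(window[1])
    span_end = sig.t0 + sig.n / sig.rate
    if min(end, span_end) - max(start, sig.t0) < min_overlap_s:
        raise errors.WindowError(
            f"window [{start:g}, {end:g}) overlaps the signal span "
            f"[{sig.t0:g}, {span_end:g}) by less than {min_overlap_s:g} s")
    k0 = max(0, int(math.ceil((start - sig.t0) * sig.rate - 1e-9)))
    k1 = min(sig.n, int(math.ceil((end - sig.t0) * sig.rate - 1e-9)))
    v = sig.values[k0:k1]
    if sig.baseline_removed:
        v = v - np.mean(v)
    return dataclasses.replace(sig, t0=sig.t0 + k0 / sig.rate, values=v)
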