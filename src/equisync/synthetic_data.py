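"""Coupled horse-rider gait simulator with known ground truth.

The horse's back at a walk imparts a near-sinusoidal vertical
acceleration with a cadence around 90 steps per minute — a 1.5 Hz
fundamental with decaying harmonics at 3.0 and 4.5 Hz.  The rider's head
is modeled as a linear gain + pure delay response to that signal plus
slow intrinsic postural sway and sensor noise: the simplest structure
under which maximum correlation, lag and harmonic RMSE are all
identifiable.  A session-over-session progression schedule (coupling up,
lag and noise down; functional-test times down) emulates a participant
growing familiar with the horse's movement across eight sessions.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import errors
from .imu_io import ImuRecording, SessionPair, align_pair
from .functional_mobility import FunctionalTestRecord, TEST_SESSIONS

SeedLike = "int | np.random.SeedSequence"


@dataclass
class HorseGaitConfig:
    """Horse-back vertical acceleration model.

    ``cadence_spm`` of 90 steps/min puts the fundamental at 1.5 Hz;
    amplitude ratios 1 : 0.5 : 0.25 give the decaying harmonic spectrum
    seen at a walk.  ``noise_sd`` is additive white sensor noise.
    """

    cadence_spm: float = 90.0
    n_harmonics: int = 3
    amplitudes: tuple[float, ...] = (1.0, 0.5, 0.25)
    phases: tuple[float, ...] | None = None
    gravity_offset: float = 9.81
    noise_sd: float = 0.1
    duration_s: float = 600.0
    rate_hz: float = 100.0
    sync_time_s: float = 1.0

    def validate(self) -> None:
        if self.cadence_spm <= 0:
            raise errors.ConfigError(f"cadence_spm must be > 0, got {self.cadence_spm}")
        if len(self.amplitudes) != self.n_harmonics:
            raise errors.ConfigError(
                f"amplitudes has {len(self.amplitudes)} entries for "
                f"n_harmonics={self.n_harmonics}")
        if any(a <= 0 for a in self.amplitudes):
            raise errors.ConfigError("amplitudes must be positive")
        if self.phases is not None and len(self.phases) != self.n_harmonics:
            raise errors.ConfigError("phases length must equal n_harmonics")
        if self.noise_sd < 0 or self.duration_s <= 0 or self.rate_hz <= 0:
            raise errors.ConfigError("noise_sd >= 0, duration_s > 0, rate_hz > 0 required")


@dataclass
class RiderCouplingConfig:
    """Rider-head response: gain, delay, intrinsic sway, noise.

    ``intrinsic_sway_hz`` defaults to 0.3 Hz — postural sway is slow and
    sits below the 1 Hz analysis band, like the gravity artifact.
    """

    coupling_gain: float = 0.8
    lag_s: float = 0.3
    rider_noise_sd: float = 0.3
    intrinsic_sway_amp: float = 0.2
    intrinsic_sway_hz: float = 0.3

    def validate(self) -> None:
        if not 0.0 <= self.coupling_gain <= 1.0:
            raise errors.ConfigError(
                f"coupling_gain must be in [0, 1], got {self.coupling_gain}")
        if not 0.0 <= self.lag_s < 2.0:
            raise errors.ConfigError(f"lag_s must be in [0, 2), got {self.lag_s}")
        if self.rider_noise_sd < 0 or self.intrinsic_sway_amp < 0:
            raise errors.ConfigError("noise and sway amplitudes must be >= 0")


def default_coupling_schedule(
    sessions: Sequence[int] = tuple(range(1, 9)),
) -> dict[int, RiderCouplingConfig]:
    """Monotone familiarization schedule over sessions 1-8.

    Coupling 0.4 -> 0.9 and lag 0.5 -> 0.2 s linearly; rider noise
    1.2 -> 0.15 m/s^2 geometrically; sway 0.3 -> 0.1 m/s^2 linearly.
    """
    out = {}
    for s in sessions:
        frac = (s - 1) / 7.0
        out[s] = RiderCouplingConfig(
            coupling_gain=0.4 + 0.5 * frac,
            lag_s=0.5 - 0.3 * frac,
            rider_noise_sd=1.2 * (0.15 / 1.2) ** frac,
            intrinsic_sway_amp=0.3 - 0.2 * frac,
        )
    return out


def _default_functional_schedule() -> dict[str, dict[int, tuple[float, float]]]:
    # session -> (mean_s, sd_s); means follow the reported relative declines
    return {
        "TUG": {1: (12.0, 3.5), 4: (9.80, 3.5), 8: (8.70, 3.5)},
        "TENMWT": {1: (30.0, 3.0), 4: (19.02, 3.0), 8: (18.87, 3.0)},
    }


@dataclass
class ProgressionConfig:
    """Session schedule: per-session rider coupling plus functional-test
    time distributions for the test days."""

    sessions: tuple[int, ...] = tuple(range(1, 9))
    horse: HorseGaitConfig = field(default_factory=HorseGaitConfig)
    coupling: Mapping[int, RiderCouplingConfig] | None = None
    functional: Mapping[str, Mapping[int, tuple[float, float]]] = field(
        default_factory=_default_functional_schedule)

    def __post_init__(self) -> None:
        if self.coupling is None:
            self.coupling = default_coupling_schedule(self.sessions)

    def validate(self) -> None:
        self.horse.validate()
        missing = [s for s in self.sessions if s not in self.coupling]
        if missing:
            raise errors.ConfigError(f"coupling schedule missing sessions {missing}")
        for s in self.sessions:
            self.coupling[s].validate()


def generate_horse_walk(cfg: HorseGaitConfig, seed) -> ImuRecording:
    """Synthesize a horse-back recording: gravity offset + harmonic stack
    + white noise, with the sync pulse rising at ``sync_time_s``."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = int(round(cfg.duration_s * cfg.rate_hz)) + 1
    t = np.arange(n) / cfg.rate_hz
    f0 = cfg.cadence_spm / 60.0
    phases = cfg.phases if cfg.phases is not None else (0.0,) * cfg.n_harmonics
    z = np.full(n, cfg.gravity_offset)
    for k in range(cfg.n_harmonics):
        z = z + cfg.amplitudes[k] * np.sin(2 * math.pi * (k + 1) * f0 * t + phases[k])
    z = z + rng.normal(0.0, cfg.noise_sd, n)
    xy_sd = 0.5 * cfg.noise_sd
    acc = np.column_stack([
        rng.normal(0.0, xy_sd, n), rng.normal(0.0, xy_sd, n), z])
    sync = (t >= cfg.sync_time_s).astype(float)
    return ImuRecording(
        sensor_id="synthetic-horse", placement="horse_back",
        timestamps=t, acc=acc, sync_pulse=sync, nominal_rate=cfg.rate_hz)


def generate_rider_response(
    horse: ImuRecording, cfg: RiderCouplingConfig, seed,
) -> ImuRecording:
    """Rider-head recording responding to a horse recording.

    Vertical channel: ``gain * horse_z(t - lag, baseline-removed) + sway
    sinusoid + white noise + gravity``, sharing the horse's sync pulse.
    """
    cfg.validate()
    if cfg.lag_s >= horse.duration:
        raise errors.ParameterError(
            f"lag_s={cfg.lag_s:g} s is not shorter than the horse recording "
            f"({horse.duration:g} s)")
    rng = np.random.default_rng(seed)
    t = horse.timestamps
    hz = horse.acc[:, 2]
    base = float(np.mean(hz))
    delayed = np.interp(t - cfg.lag_s, t, hz - base, left=0.0)
    sway_phase = rng.uniform(0.0, 2 * math.pi)
    z = (cfg.coupling_gain * delayed
         + cfg.intrinsic_sway_amp
         * np.sin(2 * math.pi * cfg.intrinsic_sway_hz * t + sway_phase)
         + rng.normal(0.0, cfg.rider_noise_sd, t.size)
         + base)
    xy_sd = 0.5 * cfg.rider_noise_sd
    acc = np.column_stack([
        rng.normal(0.0, xy_sd, t.size), rng.normal(0.0, xy_sd, t.size), z])
    return ImuRecording(
        sensor_id="synthetic-rider", placement="rider_head",
        timestamps=t.copy(), acc=acc,
        sync_pulse=None if horse.sync_pulse is None else horse.sync_pulse.copy(),
        nominal_rate=horse.nominal_rate)


def _session_seeds(seed, key: tuple[int, ...]) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return np.random.SeedSequence(entropy=seed.entropy, spawn_key=key)
    return np.random.SeedSequence(entropy=seed, spawn_key=key)


def generate_session_series(
    prog: ProgressionConfig, participant_id: str, seed,
) -> tuple[list[SessionPair], dict[int, dict]]:
    """One aligned SessionPair per scheduled session, with independently
    seeded noise, plus the true coupling/lag schedule as ground truth."""
    prog.validate()
    pairs: list[SessionPair] = []
    truth: dict[int, dict] = {}
    for s in prog.sessions:
        hss, rss = _session_seeds(seed, (int(s),)).spawn(2)
        horse = generate_horse_walk(prog.horse, hss)
        rider = generate_rider_response(horse, prog.coupling[s], rss)
        pairs.append(align_pair(horse, rider,
                                participant_id=participant_id,
                                session_index=s))
        c = prog.coupling[s]
        truth[s] = {
            "coupling_gain": c.coupling_gain,
            "lag_s": c.lag_s,
            "rider_noise_sd": c.rider_noise_sd,
            "intrinsic_sway_amp": c.intrinsic_sway_amp,
            "intrinsic_sway_hz": c.intrinsic_sway_hz,
        }
    return pairs, truth


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-match a log-normal to a target mean and sd."""
    var = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - var / 2.0
    return mu, math.sqrt(var)


def generate_functional_times(
    prog: ProgressionConfig,
    participants: Sequence[str | tuple[str, str]],
    seed,
) -> list[FunctionalTestRecord]:
    """Log-normal pre/post test times on the scheduled test days.

    ``participants`` entries are ids (default test TUG) or (id, test)
    pairs.  Times are positive and right-skewed, hence log-normal with
    parameters moment-matched to each session's scheduled mean/sd; a zero
    scheduled sd yields the mean exactly.
    """
    prog.validate()
    records: list[FunctionalTestRecord] = []
    for p_i, part in enumerate(participants):
        pid, test = (part, "TUG") if isinstance(part, str) else part
        schedule = prog.functional[test]
        missing = [s for s in TEST_SESSIONS if s not in schedule]
        if missing:
            raise errors.ConfigError(
                f"functional schedule for {test} missing sessions {missing}")
        for s in TEST_SESSIONS:
            mean, sd = schedule[s]
            for ph_i, phase in enumerate(("pre", "post")):
                rng = np.random.default_rng(
                    _session_seeds(seed, (1000 + p_i, int(s), ph_i)))
                if sd == 0:
                    time = float(mean)
                else:
                    mu, sigma = _lognormal_params(mean, sd)
                    time = float(rng.lognormal(mu, sigma))
                records.append(FunctionalTestRecord(pid, s, phase, test, time))
    return records
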