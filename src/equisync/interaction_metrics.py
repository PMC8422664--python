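"""Horse-rider interaction measures.

The horse-back vertical acceleration is the reference signal; the
rider-head signal is modeled as responding to it.  Three session-level
measures quantify the interaction:

* **max_corr** — the maximum of the lagged, overlap-normalized Pearson
  cross-correlation profile (temporal synchronization; in [-1, 1]).
* **lag_at_max** — the time shift of the reference producing that maximum.
  Positive means the rider's head lags the horse's back.
* **rmse_freq** — root-mean-square error between corresponding dominant
  harmonic peak frequencies of the two Welch spectra (spatial
  synchronization; at a walk the harmonics sit near 1.5, 3.0, 4.5 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal

from . import errors, preprocessing
from .imu_io import SessionPair
from .preprocessing import VerticalSignal


@dataclass
class CorrelationProfile:
    """Pearson correlation r(lag) on a uniform, zero-centered lag grid."""

    lags: np.ndarray   # seconds, strictly increasing, symmetric about 0
    r: np.ndarray      # unitless, each in [-1, 1]

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if self.lags.size and np.any(np.diff(self.lags) <= 0):
            raise errors.FormatError("lags must be strictly increasing")
        if self.r.size and np.any(np.abs(self.r) > 1 + 1e-12):
            raise errors.ContractError("correlation values outside [-1, 1]")


@dataclass
class Spectrum:
    """One-sided Welch power spectral density, 0 to Nyquist."""

    freqs: np.ndarray       # Hz, uniform
    psd: np.ndarray         # power density >= 0, per Hz
    resolution: float       # Hz (= 1 / window length)
    window_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if np.any(self.psd < 0):
            raise errors.FormatError("psd must be non-negative")


@dataclass
class HarmonicSet:
    """K dominant spectral peaks near integer multiples of a fundamental.

    ``peak_freqs[k]`` is NaN and ``missing[k]`` True when no local maximum
    exists within +-30% of (k+1) times the fundamental.
    """

    fundamental: float
    peak_freqs: np.ndarray
    peak_powers: np.ndarray
    missing: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.peak_freqs = np.asarray(self.peak_freqs, dtype=float)
        self.peak_powers = np.asarray(self.peak_powers, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        present = self.peak_freqs[~self.missing]
        if present.size > 1 and np.any(np.diff(present) <= 0):
            raise errors.ContractError("peak frequencies must be increasing")


@dataclass
class SyncMetrics:
    """Per-session interaction outputs."""

    participant_id: str
    session_index: int
    max_corr: float
    lag_at_max: float    # seconds; positive = rider head lags horse back
    rmse_freq: float     # Hz

    def __post_init__(self) -> None:
        if not -1 - 1e-9 <= self.max_corr <= 1 + 1e-9:
            raise errors.ContractError("max_corr outside [-1, 1]")
        if self.rmse_freq < 0:
            raise errors.ContractError("rmse_freq must be >= 0")


@dataclass
class AnalysisParams:
    """Tunable pipeline parameters (YAML-configurable in the CLI)."""

    resample_hz: float = 100.0
    frame_mode: str = "sensor_z"
    highpass_hz: float = 1.0
    max_lag_s: float = 2.0
    welch_window_s: float = 20.0
    welch_overlap: float = 0.5
    band_hz: tuple[float, float] = (1.0, 6.0)
    n_harmonics: int = 3
    rmse_mode: str = "freq"
    min_rel_power: float = 1e-3
    refine_peaks: bool = False
    min_corr_overlap_s: float = 10.0


def _check_corr_inputs(ref: VerticalSignal, target: VerticalSignal) -> float:
    if abs(ref.rate - target.rate) > 1e-9 * max(ref.rate, target.rate):
        raise errors.ParameterError(
            f"rate mismatch: {ref.rate:g} vs {target.rate:g} Hz")
    if not (ref.baseline_removed and target.baseline_removed):
        raise errors.ContractError(
            "cross_correlation requires baseline-removed inputs")
    if abs(ref.t0 - target.t0) > 1e-6 / ref.rate:
        raise errors.ParameterError(
            "signals must share a common time grid (equal t0); "
            "resample both onto the analysis window first")
    return ref.rate


def cross_correlation(
    ref: VerticalSignal,
    target: VerticalSignal,
    max_lag: float = 2.0,
    *,
    min_overlap_s: float = 10.0,
    method: str = "auto",
) -> CorrelationProfile:
    """Lagged Pearson correlation of target against the reference.

    For each lag tau on the sample grid in [-max_lag, +max_lag],
    ``r(tau)`` is the Pearson correlation between ``ref(t)`` and
    ``target(t + tau)`` over their overlap only — no zero padding, so
    |r| is not biased downward at large lags.

    ``method="fft"`` (default for equal-length inputs) computes sliding
    dot products with an FFT and the overlap moments with prefix sums;
    ``"direct"`` evaluates each lag by slicing.  Both are exact.
    """
    rate = _check_corr_inputs(ref, target)
    if max_lag <= 0:
        raise errors.ParameterError("max_lag must be > 0")
    x, y = ref.values, target.values
    N, M = x.size, y.size
    L = int(round(max_lag * rate))
    ds = np.arange(-L, L + 1)
    n = np.minimum(N, M - ds) - np.maximum(0, -ds)
    need = int(np.ceil(min_overlap_s * rate))
    if np.min(n) < need:
        raise errors.ParameterError(
            f"overlap at the extreme lag is {np.min(n)} samples "
            f"(< {min_overlap_s:g} s at {rate:g} Hz)")
    if method == "auto":
        method = "fft" if N == M else "direct"
    if method == "fft":
        if N != M:
            raise errors.ParameterError("method='fft' requires equal lengths")
        r = _corr_fft(x, y, L, n)
    elif method == "direct":
        r = _corr_direct(x, y, ds, n)
    else:
        raise errors.ParameterError(f"unknown method {method!r}")
    return CorrelationProfile(lags=ds / rate, r=np.clip(r, -1.0, 1.0))


def _pearson_from_sums(sxy, sx, sy, sxx, syy, n, scale):
    num = sxy - sx * sy / n
    vx = np.maximum(sxx - sx**2 / n, 0.0)
    vy = np.maximum(syy - sy**2 / n, 0.0)
    tol = 1e-15 * n * scale
    denom = np.sqrt(vx * vy)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where((vx > tol) & (vy > tol), num / denom, 0.0)
    return r


def _corr_fft(x: np.ndarray, y: np.ndarray, L: int, n: np.ndarray) -> np.ndarray:
    N = x.size
    ds = np.arange(-L, L + 1)
    # correlate(y, x, 'full')[N-1+d] = sum_i y[i+d] * x[i]
    sxy = scipy.signal.correlate(y, x, mode="full", method="fft")[N - 1 + ds]
    cx, cxx = np.concatenate(([0.0], np.cumsum(x))), np.concatenate(([0.0], np.cumsum(x * x)))
    cy, cyy = np.concatenate(([0.0], np.cumsum(y))), np.concatenate(([0.0], np.cumsum(y * y)))
    pos = ds >= 0
    sx = np.where(pos, cx[np.minimum(N - ds, N)], cx[N] - cx[np.minimum(-ds, N)])
    sxx_ = np.where(pos, cxx[np.minimum(N - ds, N)], cxx[N] - cxx[np.minimum(-ds, N)])
    sy = np.where(pos, cy[N] - cy[np.minimum(ds, N)], cy[np.minimum(N + ds, N)])
    syy_ = np.where(pos, cyy[N] - cyy[np.minimum(ds, N)], cyy[np.minimum(N + ds, N)])
    scale = max(1.0, float(np.max(np.abs(x)))**2) * max(1.0, float(np.max(np.abs(y)))**2)
    return _pearson_from_sums(sxy, sx, sy, sxx_, syy_, n, np.sqrt(scale))


def _corr_direct(x: np.ndarray, y: np.ndarray, ds: np.ndarray, n: np.ndarray) -> np.ndarray:
    N, M = x.size, y.size
    scale = max(1.0, float(np.max(np.abs(x)))) * max(1.0, float(np.max(np.abs(y))))
    out = np.empty(ds.size)
    for j, d in enumerate(ds):
        i0, i1 = max(0, -d), min(N, M - d)
        xs, ys = x[i0:i1], y[i0 + d:i1 + d]
        out[j] = _pearson_from_sums(
            float(xs @ ys), float(xs.sum()), float(ys.sum()),
            float(xs @ xs), float(ys @ ys), n[j], scale)
    return out


def max_corr_and_lag(profile: CorrelationProfile) -> tuple[float, float]:
    """Global maximum of the profile and its lag.

    Exact ties are broken by smallest |lag|, then negative before positive
    — periodic signals make the argmax ambiguous and the physical prior is
    minimal transmission delay.
    """
    if profile.r.size == 0:
        raise errors.ParameterError("empty correlation profile")
    rmax = float(np.max(profile.r))
    cand = np.flatnonzero(profile.r >= rmax - 1e-12)
    lags = profile.lags[cand]
    order = np.lexsort((lags >= 0, np.abs(lags)))
    best = cand[order[0]]
    return float(profile.r[best]), float(profile.lags[best])


def welch_psd(
    sig: VerticalSignal,
    window_s: float = 20.0,
    overlap: float = 0.5,
) -> Spectrum:
    """Averaged periodogram over tapered, overlapping, detrended segments.

    Hann-tapered segments of ``window_s`` seconds with per-segment linear
    detrend; frequency resolution is 1 / ``window_s``.
    """
    if not 0 <= overlap < 1:
        raise errors.ParameterError(f"overlap must be in [0, 1), got {overlap}")
    nperseg = int(round(window_s * sig.rate))
    if sig.n < 2 * nperseg:
        raise errors.ParameterError(
            f"signal of {sig.n / sig.rate:g} s is shorter than two "
            f"{window_s:g} s windows")
    freqs, psd = scipy.signal.welch(
        sig.values, fs=sig.rate, window="hann", nperseg=nperseg,
        noverlap=int(round(overlap * nperseg)), detrend="linear")
    return Spectrum(
        freqs=freqs, psd=psd, resolution=1.0 / window_s,
        window_meta={"window_s": window_s, "overlap": overlap,
                     "taper": "hann", "detrend": "linear"})


def _local_maxima(psd: np.ndarray) -> np.ndarray:
    """Indices of interior local maxima (strict left, >= right)."""
    if psd.size < 3:
        return np.array([], dtype=int)
    mid = psd[1:-1]
    return 1 + np.flatnonzero((mid > psd[:-2]) & (mid >= psd[2:]))


def _refine(freqs: np.ndarray, psd: np.ndarray, i: int) -> float:
    """Quadratic sub-bin interpolation of a peak location."""
    if not 0 < i < psd.size - 1:
        return float(freqs[i])
    a, b, c = psd[i - 1], psd[i], psd[i + 1]
    denom = a - 2 * b + c
    if denom >= 0:
        return float(freqs[i])
    delta = float(np.clip(0.5 * (a - c) / denom, -0.5, 0.5))
    return float(freqs[i] + delta * (freqs[1] - freqs[0]))


def detect_harmonics(
    spec: Spectrum,
    band: tuple[float, float] = (1.0, 6.0),
    K: int = 3,
    *,
    min_rel_power: float = 1e-3,
    refine: bool = False,
) -> HarmonicSet:
    """Find the gait fundamental and its first K harmonics.

    Candidates are local PSD maxima in ``band`` above a relative power
    floor (``min_rel_power`` of the in-band maximum, so numerical taper
    sidelobes never count as peaks).  The fundamental is the
    highest-power candidate that is not within +-30% of twice another
    higher-or-equal candidate (so a dominant 2nd harmonic of a lower
    fundamental is not mistaken for the fundamental).  The k-th harmonic
    is the highest local maximum within +-30% of k times the fundamental;
    windows with no qualifying maximum are flagged missing.
    """
    f_lo, f_hi = float(band[0]), float(band[1])
    if f_lo < spec.resolution:
        raise errors.ParameterError(
            f"band lower edge {f_lo:g} Hz is below the resolution "
            f"{spec.resolution:g} Hz")
    if f_hi > spec.freqs[-1] or f_lo >= f_hi:
        raise errors.ParameterError(
            f"band [{f_lo:g}, {f_hi:g}] Hz outside spectrum range")
    if K < 1:
        raise errors.ParameterError("K must be >= 1")

    maxima = _local_maxima(spec.psd)
    in_band = maxima[(spec.freqs[maxima] >= f_lo) & (spec.freqs[maxima] <= f_hi)]
    if in_band.size:
        floor = min_rel_power * float(np.max(spec.psd[in_band]))
        cand = in_band[spec.psd[in_band] >= floor]
    else:
        floor = np.inf
        cand = in_band
    if cand.size == 0:
        raise errors.NoPeakError(
            f"no local PSD maximum in band [{f_lo:g}, {f_hi:g}] Hz")

    cf, cp = spec.freqs[cand], spec.psd[cand]
    excluded = np.zeros(cand.size, dtype=bool)
    for i in range(cand.size):
        doubled = 2.0 * cf
        others = (np.abs(cf[i] - doubled) <= 0.3 * doubled) & (cp >= cp[i])
        others[i] = False
        excluded[i] = bool(np.any(others))
    pool = np.flatnonzero(~excluded)
    if pool.size == 0:  # only possible through exact power ties
        pool = np.arange(cand.size)
    fund_idx = cand[pool[np.argmax(cp[pool])]]
    fundamental = _refine(spec.freqs, spec.psd, fund_idx) if refine \
        else float(spec.freqs[fund_idx])

    peak_freqs = np.full(K, np.nan)
    peak_powers = np.full(K, np.nan)
    missing = np.ones(K, dtype=bool)
    for k in range(1, K + 1):
        lo, hi = 0.7 * k * fundamental, 1.3 * k * fundamental
        sel = maxima[(spec.freqs[maxima] >= lo) & (spec.freqs[maxima] <= hi)
                     & (spec.psd[maxima] >= floor)]
        if sel.size == 0:
            continue
        best = sel[np.argmax(spec.psd[sel])]
        peak_freqs[k - 1] = _refine(spec.freqs, spec.psd, best) if refine \
            else float(spec.freqs[best])
        peak_powers[k - 1] = float(spec.psd[best])
        missing[k - 1] = False
    return HarmonicSet(fundamental=fundamental, peak_freqs=peak_freqs,
                       peak_powers=peak_powers, missing=missing, K=K)


def harmonic_rmse(ref: HarmonicSet, target: HarmonicSet, *, mode: str = "freq") -> float:
    """RMSE between corresponding rider and reference harmonic peaks.

    ``mode="freq"`` (default) compares peak frequencies in Hz; smaller
    values read as spatial synchronization.  ``mode="power"`` compares peak
    power densities instead.  Pairs with a missing harmonic on either side
    are dropped with a warning.
    """
    if mode not in ("freq", "power"):
        raise errors.ParameterError(f"mode must be 'freq' or 'power', got {mode!r}")
    if ref.K != target.K:
        raise errors.ParameterError(f"harmonic count mismatch: {ref.K} vs {target.K}")
    valid = ~ref.missing & ~target.missing
    if int(np.sum(~valid)):
        warnings.warn(
            f"dropping {int(np.sum(~valid))} harmonic pair(s) with a missing "
            "peak", stacklevel=2)
    if not np.any(valid):
        raise errors.UndefinedMetricError("no harmonic pairs left to compare")
    a = ref.peak_freqs if mode == "freq" else ref.peak_powers
    b = target.peak_freqs if mode == "freq" else target.peak_powers
    d = b[valid] - a[valid]
    return float(np.sqrt(np.mean(d * d)))


@dataclass
class SessionResult:
    """SyncMetrics plus every intermediate artifact, for inspection."""

    metrics: SyncMetrics
    horse_signal: VerticalSignal
    rider_signal: VerticalSignal
    profile: CorrelationProfile
    horse_spectrum: Spectrum
    rider_spectrum: Spectrum
    horse_harmonics: HarmonicSet
    rider_harmonics: HarmonicSet


def _prepare(rec, pair: SessionPair, params: AnalysisParams) -> VerticalSignal:
    w0, w1 = pair.analysis_window
    uni = preprocessing.resample_uniform(rec, params.resample_hz,
                                         t_start=w0, t_end=w1)
    sig = preprocessing.extract_vertical(uni, params.frame_mode)
    sig = preprocessing.remove_baseline(sig, params.highpass_hz)
    return preprocessing.crop_window(sig, (w0, w1))


def session_metrics(pair: SessionPair, params: AnalysisParams | None = None) -> SessionResult:
    """Run the full per-session analysis on an aligned pair.

    Both recordings are resampled onto the shared analysis-window grid
    (rider timestamps shifted by -sync_offset onto the horse clock),
    reduced to baseline-removed ACCz, correlated with the horse as
    reference, and compared spectrally.
    """
    params = params or AnalysisParams()
    try:
        horse_sig = _prepare(pair.horse, pair, params)
        rider_sig = _prepare(pair.rider.shift_time(-pair.sync_offset), pair, params)
        profile = cross_correlation(horse_sig, rider_sig, params.max_lag_s,
                                    min_overlap_s=params.min_corr_overlap_s)
        mc, lag = max_corr_and_lag(profile)
        hspec = welch_psd(horse_sig, params.welch_window_s, params.welch_overlap)
        rspec = welch_psd(rider_sig, params.welch_window_s, params.welch_overlap)
        hharm = detect_harmonics(hspec, params.band_hz, params.n_harmonics,
                                 min_rel_power=params.min_rel_power,
                                 refine=params.refine_peaks)
        rharm = detect_harmonics(rspec, params.band_hz, params.n_harmonics,
                                 min_rel_power=params.min_rel_power,
                                 refine=params.refine_peaks)
        rmse = harmonic_rmse(hharm, rharm, mode=params.rmse_mode)
    except errors.EquiSyncError as e:
        raise type(e)(
            f"participant {pair.participant_id!r} session "
            f"{pair.session_index}: {e}") from e
    metrics = SyncMetrics(
        participant_id=pair.participant_id,
        session_index=pair.session_index,
        max_corr=mc, lag_at_max=lag, rmse_freq=rmse)
    return SessionResult(metrics, horse_sig, rider_sig, profile,
                         hspec, rspec, hharm, rharm)


def metrics_table(results: list[SessionResult]) -> pd.DataFrame:
    """Flatten session results into the metrics CSV layout."""
    rows = []
    for res in results:
        m = res.metrics
        row = {
            "participant": m.participant_id,
            "session": m.session_index,
            "max_corr": m.max_corr,
            "lag_s": m.lag_at_max,
            "rmse_freq_hz": m.rmse_freq,
            "fundamental_hz_horse": res.horse_harmonics.fundamental,
            "fundamental_hz_rider": res.rider_harmonics.fundamental,
        }
        for k in range(res.horse_harmonics.K):
            row[f"horse_f{k + 1}_hz"] = res.horse_harmonics.peak_freqs[k]
            row[f"rider_f{k + 1}_hz"] = res.rider_harmonics.peak_freqs[k]
        rows.append(row)
    return pd.DataFrame(rows)
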