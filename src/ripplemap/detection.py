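"""Sharp-wave ripple detection on LFP channels.

The detector follows the classical Hilbert-envelope dual-threshold scheme:
the trace is band-passed 120-250 Hz with a zero-phase 6th-order Butterworth
filter, the envelope is the magnitude of the analytic signal, events must
reach ``mean + 5 SD`` of the envelope and their boundaries are the nearest
crossings of ``mean + 2 SD`` on a 5-sample trailing-mean smoothed envelope.
Candidates starting within 50 ms of each other are merged, durations are
gated to the open interval (15 ms, 250 ms), a constant-detrended periodogram
of the raw segment must peak above 100 Hz, and events during running epochs
(standardized speed above its 10th percentile + 0.06) or without behavioral
coverage are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.fft import next_fast_len
from scipy.stats import skew

from .core import LfpRecording, SpeedTrace


@dataclass
class DetectionParams:
    band_low: float = 120.0
    band_high: float = 250.0
    filter_order: int = 6
    peak_threshold_sd: float = 5.0
    boundary_threshold_sd: float = 2.0
    smooth_window_samples: int = 5
    merge_gap_s: float = 0.05
    min_duration_s: float = 0.015
    max_duration_s: float = 0.25
    spectral_floor_hz: float = 50.0
    spectral_peak_hz: float = 100.0
    speed_margin: float = 0.06
    speed_percentile: float = 10.0
    #: "mean_plus_sd": threshold = mean + k*SD of the envelope (default);
    #: "sd_only": threshold = k*SD.
    threshold_mode: str = "mean_plus_sd"
    #: "argmax": spectral peak = argmax of periodogram above the floor;
    #: "local_max": highest local maximum above the floor.
    peak_criterion: str = "argmax"
    #: "rayleigh": noise mean/SD inferred from the envelope median assuming a
    #: Rayleigh envelope (robust to contamination by the ripples themselves);
    #: "moments": plain mean/SD of the envelope.
    stats_estimator: str = "rayleigh"
    #: Channels whose envelope variance (in `envelope_units_per_volt`-scaled
    #: units, squared) falls below this are treated as ripple-free.
    envelope_variance_min: float = 5.0
    envelope_units_per_volt: float = 1e6  # variance filter operates in uV
    strong_percentile: float = 90.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if self.min_duration_s >= self.max_duration_s:
            raise ValueError("min_duration_s must be < max_duration_s")
        for name in ("peak_threshold_sd", "boundary_threshold_sd", "merge_gap_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.threshold_mode not in ("mean_plus_sd", "sd_only"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.peak_criterion not in ("argmax", "local_max"):
            raise ValueError(f"unknown peak_criterion {self.peak_criterion!r}")
        if self.stats_estimator not in ("rayleigh", "moments"):
            raise ValueError(f"unknown stats_estimator {self.stats_estimator!r}")


def bandpass(trace: np.ndarray, fs: float, params: DetectionParams) -> np.ndarray:
    """Zero-phase Butterworth band-pass of one trace."""
    if fs <= 2 * params.band_high:
        raise ValueError(
            f"sampling rate {fs} Hz too low for band_high {params.band_high} Hz"
        )
    trace = np.asarray(trace, dtype=float)
    if trace.size <= 3 * params.filter_order:
        raise ValueError("trace too short for the requested filter order")
    sos = signal.butter(
        params.filter_order,
        [params.band_low, params.band_high],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    return signal.sosfiltfilt(sos, trace)


def envelope(filtered: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (Hilbert transform).

    The FFT is padded to a fast length; the pad is stripped afterwards.
    """
    filtered = np.asarray(filtered, dtype=float)
    n = filtered.size
    analytic = signal.hilbert(filtered, N=next_fast_len(n))
    return np.abs(analytic[:n])


def smooth_envelope(env: np.ndarray, window: int) -> np.ndarray:
    """Trailing moving average, mirroring a rolling-window mean."""
    return (
        pd.Series(env).rolling(window=window, min_periods=1).mean().to_numpy()
    )


def envelope_thresholds(
    env: np.ndarray, params: DetectionParams, valid: np.ndarray | None = None
) -> tuple[float, float, float, float]:
    """(mean, sd, peak threshold, boundary threshold) over valid samples.

    With the default ``rayleigh`` estimator the noise mean/SD are inferred
    from the envelope median: the envelope of band-limited Gaussian noise is
    Rayleigh, whose scale is ``median / sqrt(2 ln 2)``.  The median is almost
    untouched by the ripples themselves, so thresholds do not creep up with
    event density or amplitude (the plain-moments estimator is biased exactly
    that way and is kept as an option).
    """
    if valid is None:
        valid = np.ones(env.size, dtype=bool)
    v = env[valid]
    scale = float(np.median(v)) / np.sqrt(2.0 * np.log(2.0))
    # a vanishing median relative to the envelope range means there is no
    # noise floor to calibrate on (e.g. noiseless traces): use plain moments
    if params.stats_estimator == "rayleigh" and scale > 1e-6 * float(v.max() or 1.0):
        mu = scale * np.sqrt(np.pi / 2.0)
        sd = scale * np.sqrt(2.0 - np.pi / 2.0)
    else:
        # moments estimator, also the fallback for a silent noise floor
        mu, sd = float(v.mean()), float(v.std())
    base = mu if params.threshold_mode == "mean_plus_sd" else 0.0
    return mu, sd, base + params.peak_threshold_sd * sd, base + params.boundary_threshold_sd * sd


def select_best_channel(
    recording: LfpRecording, area: str = "CA1", params: DetectionParams | None = None
) -> str:
    """Channel with the strongest ripple activity in one area.

    Primary criterion is the SD of the band-passed envelope; when several
    channels are local maxima of the SD depth profile (e.g. sharp-wave
    activity in stratum radiatum alongside ripples in stratum pyramidale),
    the local-maximum channel with the highest envelope skewness wins.
    """
    params = params or DetectionParams()
    chans = [ch for ch in recording.channel_info if ch.area == area and not ch.excluded]
    if not chans:
        raise ValueError(f"no usable channels in area {area!r}")
    sds, skews, ids = [], [], []
    for ch in chans:
        env = envelope(bandpass(recording.trace(ch.channel_id), recording.sampling_rate, params))
        sds.append(env.std())
        skews.append(skew(env))
        ids.append(ch.channel_id)
    sds_arr = np.asarray(sds)
    peaks = _local_maxima(sds_arr)
    if len(peaks) <= 1:
        return ids[int(np.argmax(sds_arr))]
    best = max(peaks, key=lambda i: skews[i])
    return ids[best]


def _local_maxima(x: np.ndarray) -> list[int]:
    idx = []
    for i in range(x.size):
        left_ok = i == 0 or x[i] >= x[i - 1]
        right_ok = i == x.size - 1 or x[i] >= x[i + 1]
        if left_ok and right_ok:
            idx.append(i)
    return idx


def detect_candidates(
    env: np.ndarray,
    fs: float,
    params: DetectionParams,
    valid: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """Dual-threshold interval extraction on one envelope.

    Returns half-open ``(start_s, stop_s)`` intervals relative to the first
    sample.  Envelope statistics are computed over ``valid`` samples only
    (artifact-free and non-running); boundaries come from the smoothed
    envelope, the peak criterion from the raw envelope.
    """
    env = np.asarray(env, dtype=float)
    mu, sd, thr_peak, thr_edge = envelope_thresholds(env, params, valid)
    if sd == 0 or env[valid if valid is not None else slice(None)].std() == 0:
        warnings.warn("constant envelope (SD = 0): no events", UserWarning, stacklevel=2)
        return []
    sm = smooth_envelope(env, params.smooth_window_samples)
    above = sm >= thr_edge
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = np.flatnonzero(above[:1]) if above[0] else np.array([], dtype=int)
    run_starts = np.concatenate([starts, edges[~above[edges]] + 1])
    run_stops = np.concatenate(
        [edges[above[edges]] + 1, [env.size] if above[-1] else np.array([], dtype=int)]
    )
    run_starts.sort()
    run_stops.sort()
    # a trailing mean of w samples lags the signal by (w-1)/2 samples;
    # compensate so boundary crossings are unbiased in time
    delay = (params.smooth_window_samples - 1) // 2
    out = []
    for a, b in zip(run_starts, run_stops):
        if env[a:b].max() >= thr_peak:
            out.append((max(a - delay, 0) / fs, max(b - delay, 1) / fs))
    return out


def merge_candidates(
    intervals: list[tuple[float, float]], params: DetectionParams
) -> list[tuple[float, float]]:
    """Join candidates whose start times differ by less than the merge gap.

    The rule is applied transitively: a chain of starts each closer than
    ``merge_gap_s`` to the previous one collapses into a single event
    spanning the earliest start to the latest stop.
    """
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [list(intervals[0])]
    last_start = intervals[0][0]
    for a, b in intervals[1:]:
        if a - last_start < params.merge_gap_s:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
        last_start = a
    return [tuple(m) for m in merged]


def gate_duration(
    intervals: list[tuple[float, float]], params: DetectionParams
) -> list[tuple[float, float]]:
    """Keep events with min_duration < duration < max_duration (strict)."""
    return [
        (a, b)
        for a, b in intervals
        if params.min_duration_s < (b - a) < params.max_duration_s
    ]


def validate_spectrum(
    raw_segment: np.ndarray, fs: float, params: DetectionParams | None = None
) -> tuple[bool, float]:
    """Periodogram check on the raw LFP of one candidate.

    A constant-detrended periodogram is computed on the segment; the event is
    accepted iff the spectral peak above the configured floor exceeds
    ``spectral_peak_hz`` (100 Hz).  Rejects line noise and other
    low-frequency transients that leak into the ripple band.
    """
    params = params or DetectionParams()
    raw_segment = np.asarray(raw_segment, dtype=float)
    if raw_segment.size < 2:
        warnings.warn("segment too short for a periodogram: rejected", UserWarning, stacklevel=2)
        return False, np.nan
    freqs, power = signal.periodogram(raw_segment, fs=fs, detrend="constant")
    sel = freqs >= params.spectral_floor_hz
    if not sel.any():
        return False, np.nan
    freqs, power = freqs[sel], power[sel]
    if params.peak_criterion == "argmax":
        f_peak = float(freqs[np.argmax(power)])
    else:
        peaks, _ = signal.find_peaks(power)
        f_peak = float(freqs[peaks[np.argmax(power[peaks])]]) if peaks.size else float(
            freqs[np.argmax(power)]
        )
    return f_peak > params.spectral_peak_hz, f_peak


def running_threshold(speed: SpeedTrace, params: DetectionParams) -> float:
    z = speed.standardized_speed
    z = z[np.isfinite(z)]
    return float(np.percentile(z, params.speed_percentile)) + params.speed_margin


def exclude_running(
    starts_s: np.ndarray, speed: SpeedTrace | None, params: DetectionParams
) -> np.ndarray:
    """Boolean keep-mask: False where the animal runs or behavior is missing."""
    starts_s = np.atleast_1d(np.asarray(starts_s, dtype=float))
    if speed is None or len(speed) == 0:
        if starts_s.size:
            warnings.warn(
                "no behavioral data available: all events discarded",
                UserWarning,
                stacklevel=2,
            )
        return np.zeros(starts_s.shape, dtype=bool)
    thr = running_threshold(speed, params)
    z = speed.at(starts_s)
    return np.isfinite(z) & (z <= thr)


def compute_metrics(
    start_s: float,
    stop_s: float,
    env: np.ndarray,
    raw_env: np.ndarray,
    fs: float,
    params: DetectionParams,
    rivd_pre_s: float = 0.1,
    rivd_post_s: float = 0.2,
) -> dict:
    """Per-event strength metrics.

    strength (integral of the band-passed envelope over the event, V*s), RIVD
    (integral of the raw-LFP envelope over the -100/+200 ms window around the
    event start, V*s), amplitude (90th envelope percentile in the event) and
    peak time.
    """
    n = env.size
    i0, i1 = int(round(start_s * fs)), int(round(stop_s * fs))
    if i0 < 0 or i1 > n:
        warnings.warn("event window exceeds trace bounds: truncated", UserWarning, stacklevel=2)
        i0, i1 = max(i0, 0), min(i1, n)
    seg = env[i0:i1]
    j0 = int(round((start_s - rivd_pre_s) * fs))
    j1 = int(round((start_s + rivd_post_s) * fs))
    j0, j1 = max(j0, 0), min(j1, n)
    dt = 1.0 / fs
    return {
        "strength": float(np.trapezoid(seg, dx=dt)),
        "rivd": float(np.trapezoid(raw_env[j0:j1], dx=dt)),
        "amplitude": float(np.percentile(seg, 90)) if seg.size else np.nan,
        "peak_time_s": (i0 + int(np.argmax(seg))) / fs if seg.size else np.nan,
    }


def classify_strength(
    events: pd.DataFrame, params: DetectionParams | None = None
) -> pd.DataFrame:
    """Flag the top-decile ∫Ripple events of a reference channel as strong.

    Strict ``>`` at the percentile: ties fall to the common class.  With
    fewer than 10 events everything is common (with a warning).
    """
    params = params or DetectionParams()
    events = events.copy()
    if len(events) < 10:
        warnings.warn("fewer than 10 events: all classified common", UserWarning, stacklevel=2)
        events["is_strong"] = False
        return events
    thr = np.percentile(events["strength"].to_numpy(), params.strong_percentile)
    events["is_strong"] = events["strength"].to_numpy() > thr
    return events


EVENT_COLUMNS = [
    "channel_id",
    "probe_id",
    "start_s",
    "stop_s",
    "peak_time_s",
    "duration_s",
    "amplitude",
    "strength",
    "rivd",
    "spectral_peak_hz",
    "accepted",
]


def detect_on_channel(
    trace: np.ndarray,
    fs: float,
    params: DetectionParams,
    *,
    t0: float = 0.0,
    speed: SpeedTrace | None = None,
    artifact_mask: np.ndarray | None = None,
    channel_id: str = "",
    probe_id: str = "",
) -> pd.DataFrame:
    """Full single-channel detection chain.

    Returns one row per candidate surviving merging, the duration gate, the
    artifact mask and the running exclusion; the ``accepted`` column holds the
    spectral-validation verdict (kept so false-positive control can be
    audited).  Times are absolute (``t0`` + offset).
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.size
    filt = bandpass(trace, fs, params)
    env = envelope(filt)
    raw_env = envelope(trace - trace.mean())

    valid = np.ones(n, dtype=bool)
    if artifact_mask is not None:
        valid &= ~np.asarray(artifact_mask, dtype=bool)
    if speed is not None and len(speed):
        thr = running_threshold(speed, params)
        z = speed.at(t0 + np.arange(n) / fs)
        valid &= np.isfinite(z) & (z <= thr)

    intervals = detect_candidates(env, fs, params, valid=valid)
    intervals = merge_candidates(intervals, params)
    intervals = gate_duration(intervals, params)

    if artifact_mask is not None and intervals:
        am = np.asarray(artifact_mask, dtype=bool)
        intervals = [
            (a, b)
            for a, b in intervals
            if not am[int(round(a * fs)) : int(round(b * fs))].any()
        ]

    if intervals:
        starts = np.array([a for a, _ in intervals]) + t0
        keep = exclude_running(starts, speed, params) if speed is not None else np.ones(
            len(intervals), dtype=bool
        )
        intervals = [iv for iv, k in zip(intervals, keep) if k]

    rows = []
    for a, b in intervals:
        i0, i1 = int(round(a * fs)), int(round(b * fs))
        ok, f_peak = validate_spectrum(trace[i0:i1], fs, params)
        m = compute_metrics(a, b, env, raw_env, fs, params)
        rows.append(
            {
                "channel_id": channel_id,
                "probe_id": probe_id,
                "start_s": t0 + a,
                "stop_s": t0 + b,
                "peak_time_s": t0 + m["peak_time_s"],
                "duration_s": b - a,
                "amplitude": m["amplitude"],
                "strength": m["strength"],
                "rivd": m["rivd"],
                "spectral_peak_hz": f_peak,
                "accepted": ok,
            }
        )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def channel_passes_activity_filter(
    trace: np.ndarray, fs: float, params: DetectionParams
) -> bool:
    """Weak-ripple-activity filter: envelope variance above the configured floor."""
    env = envelope(bandpass(trace, fs, params))
    var = np.var(env * params.envelope_units_per_volt)
    return var >= params.envelope_variance_min


def detect_ripples(
    recording: LfpRecording,
    params: DetectionParams | None = None,
    *,
    speed: SpeedTrace | None = None,
    channel_ids: list[str] | None = None,
    keep_rejected: bool = False,
) -> pd.DataFrame:
    """Detect ripples on several channels of a recording.

    By default only spectrally validated events are returned, sorted by
    channel then start time.
    """
    params = params or DetectionParams()
    if channel_ids is None:
        channel_ids = [
            ch.channel_id for ch in recording.channel_info if not ch.excluded
        ]
    frames = []
    for cid in channel_ids:
        ch = recording.channel_info[recording.channel_index(cid)]
        df = detect_on_channel(
            recording.trace(cid),
            recording.sampling_rate,
            params,
            t0=recording.start_time,
            speed=speed,
            artifact_mask=recording.artifact_mask,
            channel_id=cid,
            probe_id=ch.probe_id,
        )
        frames.append(df)
    events = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=EVENT_COLUMNS)
    )
    if not keep_rejected:
        events = events[events["accepted"]].reset_index(drop=True)
    return events
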