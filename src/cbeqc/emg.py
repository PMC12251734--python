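"""Surface-EMG conditioning chain and per-trial summaries.

The chain is fixed: 50 Hz notch → 20–450 Hz Butterworth bandpass → windowed
RMS (100 ms windows, 50% overlap).  Summaries (overall mean RMS, per-burst
peak RMS) are computed on the un-normalized envelope; the normalized,
500-point resampled and Gaussian-smoothed envelope exists for visualization
and cross-trial comparison only.

All filters are applied forward–backward (zero phase).  The notch is a
second-order IIR notch with quality factor Q = 30; the bandpass is a
4th-order Butterworth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

N_RESAMPLE_POINTS = 500


class SegmentationError(ValueError):
    """Burst segmentation found an unexpected number of repetitions."""

    def __init__(self, detected: int, expected: int):
        self.detected = detected
        self.expected = expected
        super().__init__(f"detected {detected} repetition bursts, expected {expected}")


@dataclass(frozen=True)
class EMGRecording:
    """Single-channel raw sEMG recording in mV.

    ``repetition_markers``, if present, are ground-truth (start_s, end_s)
    intervals of the activation bursts; they must be ordered and
    non-overlapping.
    """

    fs: float
    signal: np.ndarray
    muscle: str = ""
    participant_id: str = ""
    movement_id: str = ""
    condition: str = ""
    repetition_markers: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        sig = np.asarray(self.signal, dtype=float)
        if not np.all(np.isfinite(sig)):
            raise ValueError("sEMG signal must be finite")
        object.__setattr__(self, "signal", sig)
        if self.repetition_markers is not None:
            prev_end = -np.inf
            for start, end in self.repetition_markers:
                if not (start < end and start >= prev_end):
                    raise ValueError("repetition markers must be ordered and non-overlapping")
                prev_end = end

    @property
    def duration_s(self) -> float:
        return len(self.signal) / self.fs


@dataclass(frozen=True)
class RMSEnvelope:
    """Windowed RMS envelope with window metadata."""

    fs: float
    window_ms: float
    overlap: float
    values: np.ndarray
    window_start_s: np.ndarray

    @property
    def hop_s(self) -> float:
        return (self.window_ms / 1000.0) * (1.0 - self.overlap)

    @property
    def n_windows(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class NormalizedEnvelope:
    """Envelope resampled onto 500 points over normalized time (0, 1)."""

    values: np.ndarray
    time_norm: np.ndarray


# ---------------------------------------------------------------------------
# Filters


def notch_filter(x: np.ndarray, fs: float, f0: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase powerline notch at ``f0`` Hz (second-order IIR, Q = 30)."""
    if f0 >= fs / 2:
        raise ValueError(f"notch frequency {f0} Hz must be below Nyquist ({fs / 2} Hz)")
    b, a = sps.iirnotch(f0, q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(x, dtype=float))


def bandpass_filter(x: np.ndarray, fs: float, lo: float = 20.0, hi: float = 450.0,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass removing motion artifacts and HF noise."""
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"invalid band ({lo}, {hi}) Hz for fs = {fs} Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# Envelope


def windowed_rms(x: np.ndarray, fs: float, window_ms: float = 100.0,
                 overlap: float = 0.5) -> RMSEnvelope:
    """Sliding-window RMS; trailing samples that do not fill a window are dropped.

    Window count is ``floor((N - W) / H) + 1`` with W window samples and
    H = W * (1 - overlap) hop samples.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(fs * window_ms / 1000.0))
    if w < 1:
        raise ValueError("window shorter than one sample")
    if len(x) < w:
        raise ValueError(f"signal length {len(x)} shorter than one window ({w} samples)")
    h = int(round(w * (1.0 - overlap)))
    if h < 1:
        raise ValueError("overlap too large: hop would be zero samples")
    n_win = (len(x) - w) // h + 1
    starts = np.arange(n_win) * h
    windows = np.lib.stride_tricks.sliding_window_view(x, w)[::h][:n_win]
    values = np.sqrt(np.mean(windows**2, axis=1))
    return RMSEnvelope(fs=fs, window_ms=window_ms, overlap=overlap,
                       values=values, window_start_s=starts / fs)


def process_recording(rec: EMGRecording, f0: float = 50.0, lo: float = 20.0,
                      hi: float = 450.0, window_ms: float = 100.0,
                      overlap: float = 0.5) -> RMSEnvelope:
    """Full conditioning chain: notch → bandpass → windowed RMS."""
    filtered = bandpass_filter(notch_filter(rec.signal, rec.fs, f0), rec.fs, lo, hi)
    return windowed_rms(filtered, rec.fs, window_ms, overlap)


def normalize_resample(env: RMSEnvelope, n_points: int = N_RESAMPLE_POINTS) -> NormalizedEnvelope:
    """Map window indices affinely onto [0, 1] and linearly resample.

    Aligns trials of different durations onto a common 500-point normalized
    time base; endpoint values are preserved exactly.
    """
    if env.n_windows < 2:
        raise ValueError("need at least 2 windows to resample")
    t = np.linspace(0.0, 1.0, env.n_windows)
    tq = np.linspace(0.0, 1.0, n_points)
    return NormalizedEnvelope(values=np.interp(tq, t, env.values), time_norm=tq)


def gaussian_smooth(values: np.ndarray, sigma: float = 10.0) -> np.ndarray:
    """Unit-area Gaussian smoothing (σ in samples), reflective boundaries."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return gaussian_filter1d(np.asarray(values, dtype=float), sigma, mode="reflect")


# ---------------------------------------------------------------------------
# Summaries


def mean_rms(env: RMSEnvelope) -> float:
    """Overall average RMS across the trial — the muscle activation intensity."""
    if env.n_windows == 0:
        raise ValueError("empty envelope")
    return float(np.mean(env.values))


def markers_to_windows(markers, env: RMSEnvelope) -> list[tuple[int, int]]:
    """Convert (start_s, end_s) markers to half-open window-index spans."""
    segs = []
    for start_s, end_s in markers:
        start_w = int(round(start_s / env.hop_s))
        end_w = int(round(end_s / env.hop_s))
        segs.append((max(0, start_w), min(env.n_windows, max(end_w, start_w + 1))))
    return segs


def segment_repetitions(env: RMSEnvelope, expected: int = 10,
                        markers=None, smooth_sigma: float = 5.0,
                        min_duration_s: float = 0.25) -> list[tuple[int, int]]:
    """Locate repetition bursts on the RMS envelope.

    Explicit markers take precedence and are simply mapped to window
    indices.  Otherwise: smooth the envelope (Gaussian, σ = 5 windows),
    threshold at the midpoint of the 10th and 90th percentiles, merge gaps
    shorter than 0.25 s, drop segments shorter than 0.25 s.  Raises
    :class:`SegmentationError` when the detected count differs from
    ``expected``.
    """
    if env.n_windows == 0:
        raise ValueError("empty envelope")
    if markers is not None:
        return markers_to_windows(markers, env)
    smooth = gaussian_smooth(env.values, smooth_sigma)
    p10, p90 = np.percentile(smooth, [10, 90])
    thr = 0.5 * (p10 + p90)
    active = smooth > thr
    min_w = max(1, int(round(min_duration_s / env.hop_s)))
    segs: list[list[int]] = []
    in_seg = False
    for i, a in enumerate(active):
        if a and not in_seg:
            segs.append([i, i + 1])
            in_seg = True
        elif a:
            segs[-1][1] = i + 1
        else:
            in_seg = False
    # merge short gaps
    merged: list[list[int]] = []
    for seg in segs:
        if merged and seg[0] - merged[-1][1] < min_w:
            merged[-1][1] = seg[1]
        else:
            merged.append(seg)
    final = [(s, e) for s, e in merged if e - s >= min_w]
    if len(final) != expected:
        raise SegmentationError(detected=len(final), expected=expected)
    return final


def peak_rms_per_repetition(env: RMSEnvelope, segments) -> list[float]:
    """Maximum envelope value within each repetition segment."""
    peaks = []
    for start, end in segments:
        if not (0 <= start < end <= env.n_windows):
            raise ValueError(f"segment ({start}, {end}) out of range for {env.n_windows} windows")
        peaks.append(float(np.max(env.values[start:end])))
    return peaks


# ---------------------------------------------------------------------------
# CSV I/O (dialect: header ``time_s,value_mv``)


def write_emg_csv(rec: EMGRecording, path) -> None:
    import pandas as pd

    t = np.arange(len(rec.signal)) / rec.fs
    pd.DataFrame({"time_s": t, "value_mv": rec.signal}).to_csv(path, index=False)


def read_emg_csv(path, fs: float | None = None, **meta) -> EMGRecording:
    """Read an sEMG CSV; the sampling rate is inferred from time_s if not given."""
    import pandas as pd

    df = pd.read_csv(path)
    if not {"time_s", "value_mv"}.issubset(df.columns):
        raise ValueError(f"sEMG CSV {path} must have columns time_s,value_mv")
    if fs is None:
        dt = np.diff(df["time_s"].to_numpy())
        if len(dt) == 0 or not np.allclose(dt, dt[0]):
            raise ValueError(f"cannot infer sampling rate from {path}")
        fs = 1.0 / dt[0]
    return EMGRecording(fs=float(fs), signal=df["value_mv"].to_numpy(), **meta)
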