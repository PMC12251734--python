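"""Windowed time- and frequency-domain features from joint-angle series.

Each angle series is cut into 30-frame windows (1 s at 30 fps) with a
15-frame hop.  Per window, five time-domain statistics (mean, min, max,
median, SD) and five spectral features from a Welch power spectral density
(mean, peak and minimum in-band power, median frequency, SD of power) are
extracted — ten features per window.

The nominal analysis band is 1–20 Hz (slow voluntary movement).  At 30 fps
the Nyquist frequency is 15 Hz, so the band is clipped to [1, fps/2); a
warning is logged when clipping occurs.  The Welch estimate on a 30-sample
window degenerates to a single Hann-tapered, mean-detrended segment.

SD convention: population (denominator n) for both time and spectral SDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import welch

from .kinematics import AngleSeries

logger = logging.getLogger(__name__)

#: Stable feature column order.
FEATURE_COLUMNS = (
    "mean", "minimum", "maximum", "median", "sd",
    "psd_mean", "psd_peak", "psd_min", "psd_sd", "median_freq",
)

KEY_COLUMNS = (
    "participant_id", "movement_id", "condition", "repetition",
    "angle_name", "window_index",
)

LABELS = {"correct": 1, "incorrect": 0}


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout: 30 frames (1 s at 30 fps) with 50% overlap."""

    size_frames: int = 30
    hop_frames: int = 15

    def __post_init__(self) -> None:
        if self.size_frames < 2:
            raise ValueError("window size must be at least 2 frames")
        if not (0 < self.hop_frames <= self.size_frames):
            raise ValueError("hop must be in (0, size]")

    def n_windows(self, n_frames: int) -> int:
        if n_frames < self.size_frames:
            raise ValueError(
                f"series of {n_frames} frames shorter than one window ({self.size_frames})")
        return (n_frames - self.size_frames) // self.hop_frames + 1


def sliding_windows(values: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """(n_windows, size) view of the series; trailing partial windows dropped."""
    values = np.asarray(values, dtype=float)
    n = spec.n_windows(len(values))
    return np.lib.stride_tricks.sliding_window_view(values, spec.size_frames)[:: spec.hop_frames][:n]


def time_features(window: np.ndarray) -> tuple[float, float, float, float, float]:
    """(mean, min, max, median, population SD) of one window."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return (
        float(np.mean(w)), float(np.min(w)), float(np.max(w)),
        float(np.median(w)), float(np.std(w)),
    )


def spectral_features(window: np.ndarray, fps: float,
                      band: tuple[float, float] = (1.0, 20.0)
                      ) -> tuple[float, float, float, float, float]:
    """(psd_mean, psd_peak, psd_min, median_freq, psd_sd) over the in-band bins.

    Welch PSD with a single Hann-tapered segment spanning the whole window,
    mean-detrended.  The band is clipped to [band[0], fps/2); the median
    frequency is the smallest in-band frequency at which the cumulative
    in-band power reaches half of the total in-band power.
    """
    w = np.asarray(window, dtype=float)
    if len(w) < 8:
        raise ValueError("window too short for spectral analysis (need >= 8 samples)")
    lo, hi = band
    eff_hi = min(hi, fps / 2.0)
    if eff_hi < hi:
        logger.debug("clipping analysis band (%g, %g) Hz to (%g, %g) at fps=%g",
                     lo, hi, lo, eff_hi, fps)
    freqs, psd = welch(w, fs=fps, window="hann", nperseg=len(w), detrend="constant")
    mask = (freqs >= lo) & (freqs < eff_hi)
    if not np.any(mask):
        raise ValueError(f"empty analysis band [{lo}, {eff_hi}) Hz at fps={fps}")
    f_in, p_in = freqs[mask], psd[mask]
    total = float(np.sum(p_in))
    cum = np.cumsum(p_in)
    median_freq = float(f_in[np.searchsorted(cum, 0.5 * total)])
    return (
        float(np.mean(p_in)), float(np.max(p_in)), float(np.min(p_in)),
        median_freq, float(np.std(p_in)),
    )


def window_features(window: np.ndarray, fps: float,
                    band: tuple[float, float] = (1.0, 20.0)) -> dict[str, float]:
    """All ten features of one window, keyed by :data:`FEATURE_COLUMNS`."""
    mean, mn, mx, med, sd = time_features(window)
    p_mean, p_peak, p_min, f_med, p_sd = spectral_features(window, fps, band)
    return {
        "mean": mean, "minimum": mn, "maximum": mx, "median": med, "sd": sd,
        "psd_mean": p_mean, "psd_peak": p_peak, "psd_min": p_min,
        "psd_sd": p_sd, "median_freq": f_med,
    }


def series_feature_rows(series: AngleSeries, spec: WindowSpec,
                        band: tuple[float, float] = (1.0, 20.0)) -> list[dict[str, float]]:
    """Feature dicts for every window of one angle series, in window order."""
    rows = []
    for i, w in enumerate(sliding_windows(series.values, spec)):
        feats = window_features(w, series.fps, band)
        feats["window_index"] = i
        rows.append(feats)
    return rows


def build_feature_table(cohort, window_spec: WindowSpec | None = None,
                        angles: dict[str, str] | None = None,
                        band: tuple[float, float] = (1.0, 20.0)) -> pd.DataFrame:
    """Windowed feature table for every trial of a cohort.

    Parameters
    ----------
    cohort:
        A :class:`cbeqc.synth.Cohort` (or any object with ``manifest`` and
        ``landmarks``).  One row is produced per (trial, angle, window).
    window_spec:
        Sliding-window layout; default 30-frame windows, 15-frame hop.
    angles:
        Mapping movement_id -> angle name to extract; default: the target
        angle recorded in the manifest (``angle_name`` column).

    Returns a DataFrame with key columns, the ten feature columns, and a
    binary ``label`` (correct = 1, incorrect = 0), ordered by manifest row
    then window index.
    """
    from .kinematics import compute_angle_series, registry_by_name

    window_spec = window_spec or WindowSpec()
    registry = registry_by_name()
    rows = []
    for _, trial in cohort.manifest.iterrows():
        key = (trial.participant_id, trial.movement_id, trial.condition, int(trial.repetition))
        if key not in cohort.landmarks:
            raise KeyError(f"no landmark series for trial {key}")
        if angles is not None:
            angle_name = angles[trial.movement_id]
        else:
            angle_name = trial.angle_name
        series = compute_angle_series(cohort.landmarks[key], registry[angle_name])
        try:
            feats = series_feature_rows(series, window_spec, band)
        except ValueError as exc:
            raise ValueError(f"cannot extract features for trial {key}: {exc}") from exc
        for f in feats:
            rows.append({
                "participant_id": trial.participant_id,
                "movement_id": trial.movement_id,
                "condition": trial.condition,
                "repetition": int(trial.repetition),
                "angle_name": angle_name,
                **f,
                "label": LABELS[trial.condition],
            })
    df = pd.DataFrame(rows)
    return df[list(KEY_COLUMNS) + list(FEATURE_COLUMNS) + ["label"]]


def write_feature_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = (set(KEY_COLUMNS) | set(FEATURE_COLUMNS) | {"label"}) - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path} missing columns {sorted(missing)}")
    return df
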