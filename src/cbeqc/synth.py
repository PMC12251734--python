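"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes, without
any real recordings:

* landmark trajectories whose target joint angle follows
  ``theta_t = mu_p + eps_t`` with a per-participant level
  ``mu_p ~ N(angle_mean, angle_sd_between)`` and frame-level jitter
  ``eps_t ~ N(0, angle_sd_within)``;
* sEMG trials built from amplitude-modulated band-limited (20–450 Hz) noise
  bursts with 50 Hz powerline contamination and Gaussian baseline noise,
  calibrated so that the overall mean windowed RMS after the full
  conditioning chain equals the participant's strength;
* participant strength pairs (correct, incorrect) drawn from a bivariate
  normal with configurable correlation, floored at a small positive value.

Reproducibility: a single master seed is fanned out with counter-based
sub-seeds per (participant, movement, condition, repetition, stream), so
any trial can be regenerated in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import emg as emg_mod
from . import kinematics as kin
from .profiles import CONDITIONS, MOVEMENTS, MUSCLE_BY_MOVEMENT, CohortSpec, MovementProfile

logger = logging.getLogger(__name__)

# Stream codes for the counter-based seed fan-out.
_STREAM_MU = 0
_STREAM_ANGLE = 1
_STREAM_STRENGTH = 2
_STREAM_CARRIER = 3
_STREAM_NOISE = 4

#: Static base pose (normalized image coordinates, y down): a seated figure
#: viewed from the front-right; non-target landmarks stay at these positions.
BASE_POSE: dict[int, tuple[float, float]] = {
    11: (0.46, 0.22),  # left shoulder
    12: (0.54, 0.22),  # right shoulder
    23: (0.44, 0.50),  # left hip
    24: (0.56, 0.50),  # right hip
    25: (0.42, 0.62),  # left knee
    26: (0.58, 0.62),  # right knee
    27: (0.40, 0.82),  # left ankle
    28: (0.60, 0.82),  # right ankle
}

#: Limb-segment length used when placing the moving endpoint of the target
#: angle (normalized image units); keeps all placements inside the frame.
_SEGMENT_LENGTH = 0.18


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Counter-based sub-stream: independent, order-free, reproducible."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


def _movement_code(movement_id: str) -> int:
    return MOVEMENTS.index(movement_id)


def _condition_code(condition: str) -> int:
    return CONDITIONS.index(condition)


def participant_angle_level(profile: MovementProfile, spec: CohortSpec,
                            participant_index: int) -> float:
    """Per-participant mean angle mu_p, shared across that participant's trials."""
    rng = _rng(spec.seed, participant_index, _movement_code(profile.movement_id),
               _condition_code(profile.condition), 0, _STREAM_MU)
    return float(rng.normal(profile.angle_mean, profile.angle_sd_between))


def generate_landmark_series(profile: MovementProfile, spec: CohortSpec,
                             participant_index: int, repetition_index: int,
                             mu: float | None = None) -> kin.LandmarkSeries:
    """Landmark trajectory whose target angle carries the injected signal.

    The two proximal points of the target angle stay at the base pose; the
    distal point is re-placed each frame so that the registry angle computed
    from the output equals ``mu_p + eps_t`` exactly (up to clipping of
    realizations outside (0, 180), which is logged).
    """
    if mu is None:
        mu = participant_angle_level(profile, spec, participant_index)
    rng = _rng(spec.seed, participant_index, _movement_code(profile.movement_id),
               _condition_code(profile.condition), repetition_index, _STREAM_ANGLE)
    n_frames = int(round(spec.trial_duration * spec.fps))
    theta = mu + rng.normal(0.0, profile.angle_sd_within, size=n_frames)
    n_clipped = int(np.sum((theta <= 0.0) | (theta > 180.0)))
    if n_clipped:
        logger.warning(
            "clipped %d/%d frames of %s/%s angle realizations into (0, 180]",
            n_clipped, n_frames, profile.movement_id, profile.condition,
        )
    theta = np.clip(theta, 1e-6, 180.0)

    angle_spec = kin.registry_by_name()[profile.angle_name]
    ids = tuple(sorted(BASE_POSE))
    coords = np.empty((n_frames, len(ids), 2), dtype=float)
    for j, lid in enumerate(ids):
        coords[:, j, :] = BASE_POSE[lid]
    rad = np.radians(theta)
    if angle_spec.kind == "vertex":
        a_id, b_id, c_id = angle_spec.points
        a = np.asarray(BASE_POSE[a_id])
        b = np.asarray(BASE_POSE[b_id])
        phi = np.arctan2(a[1] - b[1], a[0] - b[0])
        moving = c_id
        pos = np.stack(
            [b[0] + _SEGMENT_LENGTH * np.cos(phi + rad),
             b[1] + _SEGMENT_LENGTH * np.sin(phi + rad)], axis=1)
    else:
        p_id, q_id = angle_spec.points
        p = np.asarray(BASE_POSE[p_id])
        moving = q_id
        # inclination measured from the downward image vertical (y down)
        pos = np.stack(
            [p[0] + _SEGMENT_LENGTH * np.sin(rad),
             p[1] + _SEGMENT_LENGTH * np.cos(rad)], axis=1)
    coords[:, ids.index(moving), :] = pos
    return kin.LandmarkSeries(fps=spec.fps, landmark_ids=ids, coords=coords)


def _burst_envelope(spec: CohortSpec, repetition_count: int, duty: float = 0.6) -> np.ndarray:
    """Hann-windowed amplitude envelope with ``repetition_count`` bursts."""
    n = int(round(spec.trial_duration * spec.emg_fs))
    period = n / repetition_count
    burst_len = int(round(duty * period))
    gap = period - burst_len
    if burst_len < 4 or gap < 1:
        raise ValueError(
            f"trial of {spec.trial_duration} s cannot fit {repetition_count} bursts "
            "with nonzero rest gaps"
        )
    env = np.zeros(n)
    starts = []
    for k in range(repetition_count):
        start = int(round(k * period + 0.5 * gap))
        end = min(start + burst_len, n)
        env[start:end] = np.hanning(burst_len)[: end - start]
        starts.append((start / spec.emg_fs, end / spec.emg_fs))
    return env, tuple(starts)


def generate_emg(profile: MovementProfile, spec: CohortSpec,
                 participant_strength: float, repetition_count: int = 10,
                 participant_index: int = 0, repetition_index: int = 0) -> emg_mod.EMGRecording:
    """One sEMG trial calibrated to a target post-pipeline mean RMS.

    The clean burst train (Hann envelope × unit-RMS 20–450 Hz noise carrier)
    is passed once through the conditioning chain; because the chain is
    positively homogeneous, a single closed-form scale factor
    ``participant_strength / mean_rms(chain(clean))`` makes the overall mean
    windowed RMS match the target exactly before contamination is added.
    """
    if participant_strength <= 0:
        raise ValueError(f"participant_strength must be positive, got {participant_strength}")
    env, markers = _burst_envelope(spec, repetition_count)
    n = len(env)
    rng = _rng(spec.seed, participant_index, _movement_code(profile.movement_id),
               _condition_code(profile.condition), repetition_index, _STREAM_CARRIER)
    carrier = rng.standard_normal(n)
    carrier = emg_mod.bandpass_filter(carrier, spec.emg_fs)
    carrier /= np.sqrt(np.mean(carrier**2))
    clean = env * carrier
    chained = emg_mod.bandpass_filter(emg_mod.notch_filter(clean, spec.emg_fs), spec.emg_fs)
    m0 = emg_mod.mean_rms(emg_mod.windowed_rms(chained, spec.emg_fs))
    signal = (participant_strength / m0) * clean
    noise_rng = _rng(spec.seed, participant_index, _movement_code(profile.movement_id),
                     _condition_code(profile.condition), repetition_index, _STREAM_NOISE)
    if spec.powerline_amplitude > 0:
        t = np.arange(n) / spec.emg_fs
        phase = noise_rng.uniform(0, 2 * np.pi)
        signal = signal + spec.powerline_amplitude * np.sin(
            2 * np.pi * spec.powerline_freq * t + phase)
    if spec.noise_sd > 0:
        signal = signal + noise_rng.normal(0.0, spec.noise_sd, size=n)
    return emg_mod.EMGRecording(
        fs=spec.emg_fs, signal=signal,
        muscle=MUSCLE_BY_MOVEMENT[profile.movement_id],
        participant_id=f"P{participant_index + 1:02d}",
        movement_id=profile.movement_id, condition=profile.condition,
        repetition_markers=markers,
    )


def participant_strengths(correct: MovementProfile, incorrect: MovementProfile,
                          spec: CohortSpec, participant_index: int) -> tuple[float, float]:
    """Correlated (correct, incorrect) strength pair for one participant."""
    rng = _rng(spec.seed, participant_index, _movement_code(correct.movement_id),
               0, 0, _STREAM_STRENGTH)
    mean = [correct.emg_mean, incorrect.emg_mean]
    r = spec.strength_correlation
    cov = [
        [correct.emg_sd_between**2, r * correct.emg_sd_between * incorrect.emg_sd_between],
        [r * correct.emg_sd_between * incorrect.emg_sd_between, incorrect.emg_sd_between**2],
    ]
    draw = rng.multivariate_normal(mean, cov)
    draw = np.maximum(draw, spec.strength_floor)
    return float(draw[0]), float(draw[1])


@dataclass
class Cohort:
    """In-memory synthetic dataset: manifest plus per-trial signals.

    Trials are keyed by ``(participant_id, movement_id, condition,
    repetition)``; ``strengths`` maps ``(participant_id, movement_id)`` to
    the (correct, incorrect) strength pair.
    """

    spec: CohortSpec
    profiles: dict[tuple[str, str], MovementProfile]
    manifest: pd.DataFrame
    landmarks: dict[tuple, kin.LandmarkSeries] = field(default_factory=dict)
    emg: dict[tuple, emg_mod.EMGRecording] = field(default_factory=dict)
    strengths: dict[tuple, tuple[float, float]] = field(default_factory=dict)

    @property
    def movements(self) -> list[str]:
        return sorted({m for m, _ in self.profiles}, key=MOVEMENTS.index)

    def write(self, outdir: str | Path) -> Path:
        """Write landmark/sEMG CSVs and a manifest CSV; returns the manifest path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for _, row in self.manifest.iterrows():
            key = (row.participant_id, row.movement_id, row.condition, row.repetition)
            stem = f"{row.participant_id}_{row.movement_id}_{row.condition}_r{row.repetition:02d}"
            entry = dict(row)
            if key in self.landmarks:
                lm_path = outdir / f"{stem}_landmarks.csv"
                kin.write_landmarks(self.landmarks[key], lm_path)
                entry["landmark_path"] = lm_path.name
            if key in self.emg:
                emg_path = outdir / f"{stem}_emg.csv"
                emg_mod.write_emg_csv(self.emg[key], emg_path)
                entry["emg_path"] = emg_path.name
            rows.append(entry)
        manifest_path = outdir / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest_path, index=False)
        return manifest_path


def generate_cohort(profiles, spec: CohortSpec,
                    signals: tuple[str, ...] = ("landmarks", "emg")) -> Cohort:
    """Generate a full synthetic cohort.

    ``profiles`` must contain exactly one profile per (movement, condition)
    and cover both conditions of every requested movement.  ``signals``
    selects which modalities to synthesize.
    """
    by_key: dict[tuple[str, str], MovementProfile] = {}
    for p in profiles:
        key = (p.movement_id, p.condition)
        if key in by_key:
            raise ValueError(f"duplicate profile for {key}")
        by_key[key] = p
    movements = sorted({m for m, _ in by_key}, key=MOVEMENTS.index)
    for m in movements:
        for c in CONDITIONS:
            if (m, c) not in by_key:
                raise ValueError(f"profiles must cover both conditions: missing ({m}, {c!r})")

    cohort = Cohort(spec=spec, profiles=by_key, manifest=pd.DataFrame())
    rows = []
    for pi in range(spec.n_participants):
        pid = f"P{pi + 1:02d}"
        for m in movements:
            corr_p, incorr_p = by_key[(m, "correct")], by_key[(m, "incorrect")]
            strength = participant_strengths(corr_p, incorr_p, spec, pi)
            cohort.strengths[(pid, m)] = strength
            for ci, cond in enumerate(CONDITIONS):
                prof = by_key[(m, cond)]
                for rep in range(spec.reps_per_condition):
                    key = (pid, m, cond, rep)
                    if "landmarks" in signals:
                        cohort.landmarks[key] = generate_landmark_series(prof, spec, pi, rep)
                    if "emg" in signals:
                        cohort.emg[key] = generate_emg(
                            prof, spec, strength[ci], spec.bursts_per_trial,
                            participant_index=pi, repetition_index=rep)
                    rows.append({
                        "participant_id": pid, "movement_id": m,
                        "condition": cond, "repetition": rep,
                        "angle_name": prof.angle_name,
                        "muscle": MUSCLE_BY_MOVEMENT[m],
                    })
    cohort.manifest = pd.DataFrame(rows)
    return cohort


def load_cohort(manifest_path: str | Path, fps: float = 30.0,
                emg_fs: float | None = None) -> Cohort:
    """Load a written cohort back from its manifest CSV."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    cohort = Cohort(spec=None, profiles={}, manifest=manifest)
    for _, row in manifest.iterrows():
        key = (row.participant_id, row.movement_id, row.condition, int(row.repetition))
        if "landmark_path" in manifest.columns and isinstance(row.get("landmark_path"), str):
            cohort.landmarks[key] = kin.read_landmarks(base / row.landmark_path, fps=fps)
        if "emg_path" in manifest.columns and isinstance(row.get("emg_path"), str):
            cohort.emg[key] = emg_mod.read_emg_csv(
                base / row.emg_path, fs=emg_fs,
                participant_id=row.participant_id, movement_id=row.movement_id,
                condition=row.condition)
    return cohort
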