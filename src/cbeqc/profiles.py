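"""Movement profiles and cohort specification for synthetic data generation.

The reference calibration table summarizes a cohort of 20 community-dwelling
older adults performing eight chair-based exercises in correct and
intentionally incorrect form: per movement and condition, the across-
participant mean ± SD of the target joint angle (degrees) and of the overall
mean sEMG RMS amplitude (mV).  Movement M1 appears twice (M1-A, M1-P)
because dorsiflexion and plantarflexion were measured on different muscles.

The printed SDs are across-participant spreads of per-condition means, so
they populate ``angle_sd_between``/``emg_sd_between``; within-trial
frame-level jitter is not separately reported and defaults to 0.5 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

MOVEMENTS: tuple[str, ...] = ("M1-A", "M1-P", "M2", "M3", "M4", "M5", "M6", "M7", "M8")
CONDITIONS: tuple[str, ...] = ("correct", "incorrect")

#: Default frame-level angle jitter (degrees) — landmark-jitter scale.
DEFAULT_ANGLE_SD_WITHIN = 0.5

#: Target angle per movement in the default six-angle registry.  The
#: assignments are surrogates consistent with each exercise's geometry; the
#: lower-leg inclination (knee–ankle) is the primary feature for M5.
ANGLE_BY_MOVEMENT: dict[str, str] = {
    "M1-A": "right_knee",
    "M1-P": "right_knee",
    "M2": "right_knee",
    "M3": "right_hip",
    "M4": "right_knee",
    "M5": "right_knee_ankle",
    "M6": "right_knee",
    "M7": "right_hip",
    "M8": "right_hip",
}

#: Muscle measured per movement.
MUSCLE_BY_MOVEMENT: dict[str, str] = {
    "M1-A": "anterior_tibialis",
    "M1-P": "peroneal",
    "M2": "quadriceps",
    "M3": "tensor_fasciae_latae",
    "M4": "quadriceps",
    "M5": "peroneal",
    "M6": "quadriceps",
    "M7": "gluteus_medius",
    "M8": "quadriceps",
}


@dataclass(frozen=True)
class MovementProfile:
    """Generator parameters for one (movement, condition) cell.

    ``angle_mean``/``angle_sd_between`` are the across-participant mean and
    SD of the target joint angle; ``angle_sd_within`` the frame-level jitter
    SD.  ``emg_mean``/``emg_sd_between`` parameterize the participant
    strength distribution (overall mean RMS, mV).
    """

    movement_id: str
    condition: str
    angle_mean: float
    angle_sd_between: float
    angle_sd_within: float
    emg_mean: float
    emg_sd_between: float
    angle_name: str

    def __post_init__(self) -> None:
        if self.movement_id not in MOVEMENTS:
            raise ValueError(f"unknown movement {self.movement_id!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not (0.0 < self.angle_mean <= 180.0):
            raise ValueError(f"angle_mean must be in (0, 180], got {self.angle_mean}")
        for name in ("angle_sd_between", "angle_sd_within", "emg_sd_between"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.emg_mean <= 0:
            raise ValueError(f"emg_mean must be positive, got {self.emg_mean}")


# (movement, condition) -> (angle_mean, angle_sd, emg_mean, emg_sd)
_REFERENCE_TABLE: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("M1-A", "correct"): (177.99, 0.93, 0.24, 0.12),
    ("M1-A", "incorrect"): (172.10, 2.15, 0.16, 0.10),
    ("M1-P", "correct"): (178.02, 0.75, 0.10, 0.04),
    ("M1-P", "incorrect"): (173.27, 1.84, 0.08, 0.03),
    ("M2", "correct"): (148.53, 17.63, 0.11, 0.06),
    ("M2", "incorrect"): (125.84, 17.48, 0.06, 0.05),
    ("M3", "correct"): (107.52, 14.31, 0.08, 0.04),
    ("M3", "incorrect"): (131.30, 12.26, 0.03, 0.02),
    ("M4", "correct"): (171.21, 3.43, 0.10, 0.05),
    ("M4", "incorrect"): (176.38, 1.71, 0.05, 0.03),
    ("M5", "correct"): (176.95, 1.10, 0.13, 0.04),
    ("M5", "incorrect"): (173.19, 1.58, 0.09, 0.03),
    ("M6", "correct"): (175.49, 1.75, 0.06, 0.02),
    ("M6", "incorrect"): (170.74, 2.05, 0.05, 0.02),
    ("M7", "correct"): (170.97, 3.41, 0.06, 0.04),
    ("M7", "incorrect"): (175.56, 1.86, 0.03, 0.03),
    ("M8", "correct"): (141.78, 5.39, 0.06, 0.04),
    ("M8", "incorrect"): (166.10, 2.99, 0.02, 0.02),
}


def reference_profile(movement_id: str, condition: str,
                      angle_sd_within: float = DEFAULT_ANGLE_SD_WITHIN) -> MovementProfile:
    """Profile for one (movement, condition) cell of the calibration table."""
    key = (movement_id, condition)
    if key not in _REFERENCE_TABLE:
        raise KeyError(f"no reference profile for {key}")
    angle_mean, angle_sd, emg_mean, emg_sd = _REFERENCE_TABLE[key]
    return MovementProfile(
        movement_id=movement_id,
        condition=condition,
        angle_mean=angle_mean,
        angle_sd_between=angle_sd,
        angle_sd_within=angle_sd_within,
        emg_mean=emg_mean,
        emg_sd_between=emg_sd,
        angle_name=ANGLE_BY_MOVEMENT[movement_id],
    )


def reference_profiles(movements=None, **kwargs) -> list[MovementProfile]:
    """Profiles (both conditions) for the requested movements, default all nine."""
    movements = list(movements) if movements is not None else list(MOVEMENTS)
    return [reference_profile(m, c, **kwargs) for m in movements for c in CONDITIONS]


def classifier_profiles(movements=None) -> list[MovementProfile]:
    """Profiles for the classification surrogate design.

    The across-participant spread is folded into frame-level jitter
    (``angle_sd_between = 0``, ``angle_sd_within`` = the printed SD), so the
    class-conditional window features are stationary across participants.
    """
    out = []
    for p in reference_profiles(movements):
        out.append(replace(p, angle_sd_within=p.angle_sd_between, angle_sd_between=0.0))
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Defaults reproduce the reference study conditions: 20 participants,
    10 trials per condition, ~20 s trials at 30 fps video and 1000 Hz sEMG,
    10 activation bursts per trial, 50 Hz powerline contamination, and
    strength pairing (correlation 0.8) between a participant's correct and
    incorrect conditions.
    """

    n_participants: int = 20
    reps_per_condition: int = 10
    trial_duration: float = 20.0
    fps: float = 30.0
    emg_fs: float = 1000.0
    bursts_per_trial: int = 10
    powerline_freq: float = 50.0
    powerline_amplitude: float = 0.02
    noise_sd: float = 0.005
    strength_correlation: float = 0.8
    strength_floor: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if self.reps_per_condition < 1:
            raise ValueError("need at least 1 repetition per condition")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.emg_fs <= 2 * 450.0:
            raise ValueError("sEMG sampling rate must exceed twice the 450 Hz band edge")
        if not (-1.0 <= self.strength_correlation <= 1.0):
            raise ValueError("strength_correlation must be in [-1, 1]")
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.bursts_per_trial < 1:
            raise ValueError("bursts_per_trial must be at least 1")
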