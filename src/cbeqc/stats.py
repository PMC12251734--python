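"""Cohort-level aggregation and paired correct-vs-incorrect statistics.

Works on tidy trial-level summaries (one row per trial with its mean joint
angle and mean sEMG RMS), aggregates them to per-participant means, then to
across-participant condition summaries (mean ± SD, sample convention), and
runs paired t-tests of correct vs incorrect per movement.  Raw p-values are
reported alongside Holm-adjusted ones.  Also emits the tidy tables behind
the usual scatter (correct vs incorrect mean sEMG per participant) and
per-repetition peak-RMS boxplot visualizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from . import emg as emg_mod
from .kinematics import compute_angle_series, mean_angle, registry_by_name


@dataclass(frozen=True)
class ConditionSummary:
    """One cell of the cohort summary: across-participant mean ± SD."""

    movement_id: str
    condition: str
    angle_mean: float
    angle_sd: float
    emg_mean: float
    emg_sd: float
    n_participants: int


@dataclass(frozen=True)
class PairedTestResult:
    movement_id: str
    t_stat: float
    df: int
    p_value: float
    mean_diff: float
    n_pairs: int


def trial_summaries(cohort) -> pd.DataFrame:
    """Per-trial mean angle and mean post-pipeline sEMG RMS.

    Returns one row per manifest trial with whichever of
    ``mean_angle_deg`` / ``mean_rms_mv`` the cohort carries signals for.
    """
    registry = registry_by_name()
    rows = []
    for _, trial in cohort.manifest.iterrows():
        key = (trial.participant_id, trial.movement_id, trial.condition, int(trial.repetition))
        row = {
            "participant_id": trial.participant_id,
            "movement_id": trial.movement_id,
            "condition": trial.condition,
            "repetition": int(trial.repetition),
        }
        if key in cohort.landmarks:
            series = compute_angle_series(cohort.landmarks[key], registry[trial.angle_name])
            row["mean_angle_deg"] = mean_angle(series)
        if key in cohort.emg:
            env = emg_mod.process_recording(cohort.emg[key])
            row["mean_rms_mv"] = emg_mod.mean_rms(env)
        rows.append(row)
    return pd.DataFrame(rows)


def per_participant_means(trials: pd.DataFrame) -> pd.DataFrame:
    """Average the trial summaries over repetitions.

    One row per (participant, movement, condition); raises if any
    participant is missing one condition of a movement it appears in.
    """
    value_cols = [c for c in ("mean_angle_deg", "mean_rms_mv") if c in trials.columns]
    if not value_cols:
        raise ValueError("trial table has no summary value columns")
    out = (trials.groupby(["participant_id", "movement_id", "condition"], sort=True)
           [value_cols].mean().reset_index())
    conds = out.groupby(["participant_id", "movement_id"])["condition"].nunique()
    incomplete = conds[conds < 2]
    if len(incomplete):
        pid, mov = incomplete.index[0]
        raise ValueError(f"participant {pid} is missing a condition for movement {mov}")
    return out


def summarize_conditions(per_participant: pd.DataFrame) -> list[ConditionSummary]:
    """Across-participant mean and sample SD per (movement, condition)."""
    summaries = []
    for (mov, cond), grp in per_participant.groupby(["movement_id", "condition"], sort=True):
        n = len(grp)
        if n < 2:
            raise ValueError(f"need >= 2 participants to summarize ({mov}, {cond})")
        angle = grp["mean_angle_deg"] if "mean_angle_deg" in grp else pd.Series(dtype=float)
        emg = grp["mean_rms_mv"] if "mean_rms_mv" in grp else pd.Series(dtype=float)
        summaries.append(ConditionSummary(
            movement_id=mov, condition=cond,
            angle_mean=float(angle.mean()) if len(angle) else float("nan"),
            angle_sd=float(angle.std(ddof=1)) if len(angle) else float("nan"),
            emg_mean=float(emg.mean()) if len(emg) else float("nan"),
            emg_sd=float(emg.std(ddof=1)) if len(emg) else float("nan"),
            n_participants=n,
        ))
    return summaries


def summary_table(summaries: list[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def paired_ttest(correct, incorrect, movement_id: str = "") -> PairedTestResult:
    """Two-sided paired t-test on participant-matched condition values.

    Identical vectors (all differences zero) return t = 0, p = 1; a
    degenerate zero-variance difference with nonzero mean raises instead,
    since t would be unbounded.
    """
    correct = np.asarray(correct, dtype=float)
    incorrect = np.asarray(incorrect, dtype=float)
    if correct.shape != incorrect.shape:
        raise ValueError("paired samples must have equal length")
    n = len(correct)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = correct - incorrect
    if np.std(diff, ddof=1) == 0.0:
        if np.mean(diff) == 0.0:
            return PairedTestResult(movement_id, 0.0, n - 1, 1.0, 0.0, n)
        raise ValueError("zero-variance differences with nonzero mean: t undefined")
    t, p = sps.ttest_rel(correct, incorrect)
    return PairedTestResult(movement_id, float(t), n - 1, float(p), float(np.mean(diff)), n)


def paired_tests_by_movement(per_participant: pd.DataFrame,
                             value: str = "mean_rms_mv") -> pd.DataFrame:
    """Per-movement paired t-tests with raw and Holm-adjusted p-values."""
    results = []
    for mov, grp in per_participant.groupby("movement_id", sort=True):
        wide = grp.pivot(index="participant_id", columns="condition", values=value)
        res = paired_ttest(wide["correct"].to_numpy(), wide["incorrect"].to_numpy(), mov)
        results.append(res)
    df = pd.DataFrame([r.__dict__ for r in results])
    if len(df):
        df["p_holm"] = multipletests(df["p_value"].to_numpy(), method="holm")[1]
    return df


def scatter_table(per_participant: pd.DataFrame, movement_id: str,
                  value: str = "mean_rms_mv") -> pd.DataFrame:
    """Per-participant (correct, incorrect) pairs with a below-identity flag."""
    grp = per_participant[per_participant["movement_id"] == movement_id]
    wide = grp.pivot(index="participant_id", columns="condition", values=value)
    if "correct" not in wide or "incorrect" not in wide:
        raise ValueError(f"both conditions required for movement {movement_id}")
    out = pd.DataFrame({
        "participant_id": wide.index,
        "correct_mean_mv": wide["correct"].to_numpy(),
        "incorrect_mean_mv": wide["incorrect"].to_numpy(),
    })
    out["below_identity"] = out["incorrect_mean_mv"] < out["correct_mean_mv"]
    return out.reset_index(drop=True)


def boxplot_table(peaks_by_condition: dict[str, list[float]]) -> pd.DataFrame:
    """Tidy per-repetition peak values plus quartiles per condition.

    Quantiles use linear interpolation between order statistics.
    """
    rows = []
    for cond, peaks in peaks_by_condition.items():
        peaks = np.asarray(peaks, dtype=float)
        if len(peaks) < 1:
            raise ValueError(f"condition {cond!r} has no repetitions")
        q1, med, q3 = np.percentile(peaks, [25, 50, 75])
        for i, p in enumerate(peaks):
            rows.append({
                "condition": cond, "repetition": i, "peak_mv": float(p),
                "q1": float(q1), "median": float(med), "q3": float(q3),
                "iqr": float(q3 - q1),
            })
    return pd.DataFrame(rows)
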