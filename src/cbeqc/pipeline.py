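"""End-to-end pipeline: synthesize → kinematics → features → classify → stats.

One YAML config drives the five stages; all randomness flows from a single
master seed, so re-running with the same config reproduces identical
outputs.  Each stage writes its outputs plus a checksum sidecar; a re-run
reuses a stage's cached outputs only when the checksum of its configuration
(and thus of its deterministic inputs) matches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import SVMParams, loocv, report_to_table
from .features import WindowSpec, build_feature_table, read_feature_table, write_feature_table
from .profiles import MOVEMENTS, CohortSpec, reference_profiles
from .stats import (paired_tests_by_movement, per_participant_means, scatter_table,
                    summarize_conditions, summary_table, trial_summaries)
from .synth import generate_cohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full run."""

    out_dir: str
    movements: tuple[str, ...] = MOVEMENTS
    cohort: CohortSpec = field(default_factory=CohortSpec)
    window: WindowSpec = field(default_factory=WindowSpec)
    svm: SVMParams = field(default_factory=SVMParams)
    granularity: str = "sample"
    write_synthetic: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.movements) - set(MOVEMENTS)
        if unknown:
            raise ValueError(f"unknown movements {sorted(unknown)}")
        if self.granularity not in ("sample", "participant"):
            raise ValueError(f"unknown granularity {self.granularity!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "out_dir" in raw:
            kwargs["out_dir"] = raw["out_dir"]
        if "movements" in raw:
            kwargs["movements"] = tuple(raw["movements"])
        if "cohort" in raw:
            kwargs["cohort"] = CohortSpec(**raw["cohort"])
        if "window" in raw:
            kwargs["window"] = WindowSpec(**raw["window"])
        if "svm" in raw:
            kwargs["svm"] = SVMParams(**raw["svm"])
        for key in ("granularity", "write_synthetic"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _stage_cached(out: Path, stage: str, digest: str, outputs: list[Path]) -> bool:
    sidecar = out / f".{stage}.hash"
    return (sidecar.exists() and sidecar.read_text().strip() == digest
            and all(p.exists() for p in outputs))


def _mark_stage(out: Path, stage: str, digest: str) -> None:
    (out / f".{stage}.hash").write_text(digest + "\n")


def run_all(config: RunConfig) -> dict:
    """Execute the five stages in order; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("cbeqc")
    root.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
               for h in root.handlers):
        root.addHandler(logging.StreamHandler(sys.stderr))
    root.setLevel(logging.INFO)
    digest = config.digest()
    manifest: dict = {
        "version": __version__,
        "seed": config.cohort.seed,
        "config_digest": digest,
        "stages": {},
    }
    try:
        # ------------------------------------------------ stage 1: synthesize
        stage = "synth"
        profiles = reference_profiles(config.movements)
        cohort = generate_cohort(profiles, config.cohort)
        entry = {"n_trials": len(cohort.manifest)}
        if config.write_synthetic:
            synth_dir = out / "synthetic"
            if not _stage_cached(out, stage, digest, [synth_dir / "manifest.csv"]):
                entry["manifest"] = str(cohort.write(synth_dir))
                _mark_stage(out, stage, digest)
            else:
                entry["manifest"] = str(synth_dir / "manifest.csv")
                logger.info("stage synth: cached")
        manifest["stages"][stage] = entry
        logger.info("stage synth: %d trials", len(cohort.manifest))

        # ------------------------------------------------ stage 2: kinematics
        stage = "trials"
        trials_path = out / "trials.csv"
        if _stage_cached(out, stage, digest, [trials_path]):
            trials = pd.read_csv(trials_path)
            logger.info("stage trials: cached (%d rows)", len(trials))
        else:
            trials = trial_summaries(cohort)
            trials.to_csv(trials_path, index=False)
            _mark_stage(out, stage, digest)
            logger.info("stage trials: %d rows", len(trials))
        manifest["stages"][stage] = {"path": str(trials_path), "n_rows": len(trials)}

        # ------------------------------------------------ stage 3: features
        stage = "features"
        features_path = out / "features.csv"
        if _stage_cached(out, stage, digest, [features_path]):
            features = read_feature_table(features_path)
            logger.info("stage features: cached (%d rows)", len(features))
        else:
            features = build_feature_table(cohort, config.window)
            write_feature_table(features, features_path)
            _mark_stage(out, stage, digest)
            logger.info("stage features: %d rows", len(features))
        manifest["stages"][stage] = {"path": str(features_path), "n_rows": len(features)}

        # ------------------------------------------------ stage 4: classify
        stage = "classify"
        clf_path = out / "classification.json"
        if _stage_cached(out, stage, digest, [clf_path]):
            results = json.loads(clf_path.read_text())
            logger.info("stage classify: cached")
        else:
            results = {}
            for mov in config.movements:
                sub = features[features["movement_id"] == mov]
                report = loocv(sub, granularity=config.granularity, params=config.svm)
                results[mov] = report.to_dict()
                (out / f"classification_{mov}.txt").write_text(report_to_table(report) + "\n")
                logger.info("stage classify: %s accuracy %.4f", mov, report.accuracy)
            results["mean_accuracy"] = float(
                pd.Series([results[m]["accuracy"] for m in config.movements]).mean())
            clf_path.write_text(json.dumps(results, indent=2))
            _mark_stage(out, stage, digest)
        manifest["stages"][stage] = {"path": str(clf_path),
                                     "mean_accuracy": results["mean_accuracy"]}

        # ------------------------------------------------ stage 5: statistics
        stage = "stats"
        summary_path = out / "table_summary.csv"
        tests_path = out / "paired_tests.csv"
        scatter_paths = {m: out / f"scatter_{m}.csv" for m in config.movements}
        if _stage_cached(out, stage, digest, [summary_path, tests_path]):
            logger.info("stage stats: cached")
        else:
            pp = per_participant_means(trials)
            summary_table(summarize_conditions(pp)).to_csv(summary_path, index=False)
            paired_tests_by_movement(pp).to_csv(tests_path, index=False)
            for mov, path in scatter_paths.items():
                scatter_table(pp, mov).to_csv(path, index=False)
            _mark_stage(out, stage, digest)
            logger.info("stage stats: %d condition summaries", 2 * len(config.movements))
        manifest["stages"][stage] = {
            "summary": str(summary_path), "paired_tests": str(tests_path),
            "scatter": {m: str(p) for m, p in scatter_paths.items()},
        }
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest_path = out / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
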