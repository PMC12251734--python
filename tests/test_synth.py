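"""Synthetic cohort generator: angle round trips, EMG calibration, reproducibility."""

import dataclasses

import numpy as np
import pytest

from cbeqc import emg as emg_mod
from cbeqc import kinematics as kin
from cbeqc import synth
from cbeqc.profiles import CONDITIONS, CohortSpec, reference_profile, reference_profiles


def target_angle_values(profile, spec, participant=0, rep=0):
    series = synth.generate_landmark_series(profile, spec, participant, rep)
    angle_spec = kin.registry_by_name()[profile.angle_name]
    return kin.compute_angle_series(series, angle_spec).values


class TestLandmarkGeneration:
    @pytest.mark.parametrize("movement,expected", [("M5", 176.95), ("M1-A", 177.99),
                                                   ("M8", 141.78), ("M3", 107.52)])
    def test_noiseless_round_trip_recovers_mean(self, movement, expected):
        prof = dataclasses.replace(reference_profile(movement, "correct"),
                                   angle_sd_between=0.0, angle_sd_within=0.0)
        spec = CohortSpec(trial_duration=2.0, seed=1)
        values = target_angle_values(prof, spec)
        np.testing.assert_allclose(values, expected, atol=1e-6)

    def test_noiseless_repetition_mean_is_exact(self):
        prof = dataclasses.replace(reference_profile("M2", "incorrect"),
                                   angle_sd_between=0.0, angle_sd_within=0.0)
        spec = CohortSpec(trial_duration=1.0, seed=9)
        assert np.mean(target_angle_values(prof, spec)) == pytest.approx(125.84, abs=1e-9)

    def test_jitter_matches_injected_draws(self):
        # the recovered angle series equals mu + the generator's own jitter draws
        prof = dataclasses.replace(reference_profile("M5", "correct"),
                                   angle_sd_between=0.0, angle_sd_within=2.0,
                                   angle_mean=150.0)
        spec = CohortSpec(trial_duration=20.0, seed=4)
        values = target_angle_values(prof, spec, participant=1, rep=2)
        rng = synth._rng(spec.seed, 1, synth._movement_code("M5"), 0, 2, synth._STREAM_ANGLE)
        expected = 150.0 + rng.normal(0.0, 2.0, size=600)
        np.testing.assert_allclose(values, expected, atol=1e-6)
        assert np.std(values, ddof=1) == pytest.approx(2.0, abs=0.3)  # ~3 SE at n=600

    def test_landmarks_complete_and_in_frame(self):
        prof = reference_profile("M5", "correct")
        spec = CohortSpec(trial_duration=1.0, seed=0)
        series = synth.generate_landmark_series(prof, spec, 0, 0)
        assert set(kin.REQUIRED_LANDMARKS) <= set(series.landmark_ids)
        assert series.n_frames == 30
        assert np.all(series.coords >= 0.0) and np.all(series.coords <= 1.0)

    def test_participant_level_is_shared_across_repetitions(self):
        prof = reference_profile("M2", "correct")  # large between-participant SD
        spec = CohortSpec(trial_duration=1.0, seed=5)
        mu0 = synth.participant_angle_level(prof, spec, 0)
        mu0_again = synth.participant_angle_level(prof, spec, 0)
        mu1 = synth.participant_angle_level(prof, spec, 1)
        assert mu0 == mu0_again
        assert mu0 != mu1

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError):
            dataclasses.replace(reference_profile("M5", "correct"), angle_mean=-10.0)


class TestEMGGeneration:
    @pytest.mark.parametrize("target", [0.02, 0.10, 0.30])
    def test_calibration_within_five_percent(self, clean_spec, target):
        prof = reference_profile("M2", "correct")
        rec = synth.generate_emg(prof, clean_spec, target, clean_spec.bursts_per_trial)
        env = emg_mod.process_recording(rec)
        assert emg_mod.mean_rms(env) == pytest.approx(target, rel=0.05)

    def test_monotone_in_strength(self, clean_spec):
        prof = reference_profile("M2", "correct")
        means = []
        for target in (0.02, 0.05, 0.10, 0.20):
            rec = synth.generate_emg(prof, clean_spec, target, 4)
            means.append(emg_mod.mean_rms(emg_mod.process_recording(rec)))
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_burst_count_recovered_by_segmentation(self, clean_spec):
        prof = reference_profile("M3", "correct")
        spec = dataclasses.replace(clean_spec, trial_duration=20.0, bursts_per_trial=10)
        rec = synth.generate_emg(prof, spec, 0.08, 10)
        env = emg_mod.process_recording(rec)
        segs = emg_mod.segment_repetitions(env, expected=10)
        assert len(segs) == 10

    def test_markers_match_bursts(self, clean_spec):
        rec = synth.generate_emg(reference_profile("M5", "correct"), clean_spec, 0.1, 4)
        assert len(rec.repetition_markers) == 4
        assert rec.duration_s == pytest.approx(clean_spec.trial_duration)

    def test_too_many_bursts_error(self):
        spec = CohortSpec(trial_duration=0.05, seed=0)
        with pytest.raises(ValueError, match="cannot fit"):
            synth.generate_emg(reference_profile("M5", "correct"), spec, 0.1, 10)

    def test_powerline_is_removed_by_chain(self):
        prof = reference_profile("M5", "correct")
        base = CohortSpec(trial_duration=4.0, bursts_per_trial=4, seed=2,
                          powerline_amplitude=0.0, noise_sd=0.0)
        dirty = dataclasses.replace(base, powerline_amplitude=0.2)
        clean_rms = emg_mod.mean_rms(emg_mod.process_recording(
            synth.generate_emg(prof, base, 0.1, 4)))
        dirty_rms = emg_mod.mean_rms(emg_mod.process_recording(
            synth.generate_emg(prof, dirty, 0.1, 4)))
        assert dirty_rms == pytest.approx(clean_rms, rel=0.02)


class TestCohort:
    def test_manifest_arithmetic(self):
        spec = CohortSpec(n_participants=20, reps_per_condition=10, seed=0)
        cohort = synth.generate_cohort(reference_profiles(["M5"]), spec, signals=())
        assert len(cohort.manifest) == 20 * 2 * 10

    def test_same_seed_identical(self, clean_spec):
        profs = reference_profiles(["M5"])
        c1 = synth.generate_cohort(profs, clean_spec)
        c2 = synth.generate_cohort(profs, clean_spec)
        assert c1.manifest.equals(c2.manifest)
        key = next(iter(c1.landmarks))
        np.testing.assert_array_equal(c1.landmarks[key].coords, c2.landmarks[key].coords)
        np.testing.assert_array_equal(c1.emg[key].signal, c2.emg[key].signal)

    def test_different_seeds_differ(self, clean_spec):
        profs = reference_profiles(["M5"])
        c1 = synth.generate_cohort(profs, clean_spec, signals=("landmarks",))
        c2 = synth.generate_cohort(
            profs, dataclasses.replace(clean_spec, seed=clean_spec.seed + 1),
            signals=("landmarks",))
        key = next(iter(c1.landmarks))
        assert not np.array_equal(c1.landmarks[key].coords, c2.landmarks[key].coords)

    def test_strength_correlation_in_sampling_band(self):
        # M3 amplitudes, r = 0.8, n = 20 -> sample r within its sampling band
        spec = CohortSpec(n_participants=20, reps_per_condition=1,
                          strength_correlation=0.8, seed=11)
        cohort = synth.generate_cohort(reference_profiles(["M3"]), spec, signals=())
        pairs = np.array([cohort.strengths[(f"P{i + 1:02d}", "M3")] for i in range(20)])
        r = np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1]
        assert 0.5 <= r <= 0.95

    def test_strengths_floored_positive(self):
        spec = CohortSpec(n_participants=50, reps_per_condition=1, seed=3)
        cohort = synth.generate_cohort(reference_profiles(["M8"]), spec, signals=())
        vals = np.array(list(cohort.strengths.values()))
        assert np.all(vals >= spec.strength_floor)

    def test_duplicate_profiles_rejected(self, clean_spec):
        profs = reference_profiles(["M5"]) + [reference_profile("M5", "correct")]
        with pytest.raises(ValueError, match="duplicate"):
            synth.generate_cohort(profs, clean_spec)

    def test_missing_condition_rejected(self, clean_spec):
        with pytest.raises(ValueError, match="both conditions"):
            synth.generate_cohort([reference_profile("M5", "correct")], clean_spec)

    def test_write_and_load_round_trip(self, tmp_path):
        spec = CohortSpec(n_participants=2, reps_per_condition=1, trial_duration=1.0,
                          bursts_per_trial=1, seed=6)
        cohort = synth.generate_cohort(reference_profiles(["M5"]), spec)
        manifest_path = cohort.write(tmp_path / "cohort")
        back = synth.load_cohort(manifest_path)
        assert len(back.manifest) == len(cohort.manifest)
        key = next(iter(cohort.landmarks))
        np.testing.assert_allclose(back.landmarks[key].coords,
                                   cohort.landmarks[key].coords, atol=1e-12)
        np.testing.assert_allclose(back.emg[key].signal,
                                   cohort.emg[key].signal, atol=1e-12)
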