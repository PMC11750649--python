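"""Generator contracts: determinism, episode bookkeeping, spectral fidelity,
cohort structure."""

import numpy as np
import pytest
from scipy import stats

from conftest import FS, oracle_band_fraction, oracle_psd
from fogturn import CohortConfig, PhenotypeParams, simulate_cohort, simulate_trial
from fogturn.annotations import SUBGROUPS


class TestSimulateTrial:
    def test_nonfreezer_has_no_episodes(self, nonfreezer_trial):
        _, truth = nonfreezer_trial
        assert truth.episodes == ()

    def test_unsigned_yaw_rotation_matches_rate_times_duration(self):
        """72 deg/s for 60 s of uninterrupted turning integrates to 4320 deg."""
        params = PhenotypeParams(
            is_freezer=False, turn_rate_dps=72.0, gyro_noise_dps=0.0, yaw_osc_dps=0.0
        )
        trial, _ = simulate_trial(params, seed=0)
        total = np.trapezoid(np.abs(trial.lumbar_gyro["yaw"]), dx=1 / FS)
        assert total == pytest.approx(4320.0, abs=1.5)

    def test_trembling_episode_psd_peaks_at_injected_frequency(self):
        """A 10 s trembling episode at 5 Hz dominates the AP spectrum locally."""
        params = PhenotypeParams(
            is_freezer=True,
            episode_rate=1.0,
            mean_episode_dur_s=10.0,
            trembling_fraction=1.0,
            trembling_freq_hz=5.0,
        )
        for seed in range(5):
            trial, truth = simulate_trial(params, seed=seed)
            ep = max(truth.episodes, key=lambda e: e.duration_s)
            if ep.duration_s < 4:
                continue
            i0, i1 = int(ep.start_s * FS), int(ep.end_s * FS)
            seg = trial.shin_left["AP"][i0:i1]
            freqs, psd = oracle_psd(seg - seg.mean(), FS)
            peak = freqs[np.argmax(psd)]
            assert 4.5 <= peak <= 5.5

    def test_episodes_within_trial_and_non_overlapping(self):
        params = PhenotypeParams(is_freezer=True, episode_rate=4.0, mean_episode_dur_s=4.0)
        for seed in range(10):
            _, truth = simulate_trial(params, seed=seed)
            prev_end = -np.inf
            for ep in truth.episodes:
                assert 0 <= ep.start_s < ep.end_s <= 60.0
                assert ep.start_s >= prev_end
                prev_end = ep.end_s

    def test_episode_mask_matches_annotation_within_one_sample(self):
        """Sample-mask %TF and interval %TF agree to one sample period."""
        params = PhenotypeParams(is_freezer=True, episode_rate=2.0)
        for seed in range(5):
            trial, truth = simulate_trial(params, seed=seed)
            mask = np.zeros(trial.n_samples, dtype=bool)
            for ep in truth.episodes:
                mask[int(round(ep.start_s * FS)) : int(round(ep.end_s * FS))] = True
            tf_mask = 100.0 * mask.mean()
            tf_intervals = 100.0 * sum(e.duration_s for e in truth.episodes) / 60.0
            assert abs(tf_mask - tf_intervals) <= 100.0 / trial.n_samples

    def test_spectral_fidelity_inside_and_outside_episodes(self):
        """Locomotion band dominates outside episodes; freeze band inside
        trembling episodes."""
        params = PhenotypeParams(
            is_freezer=True, episode_rate=1.0, mean_episode_dur_s=8.0,
            trembling_fraction=1.0,
        )
        trial, truth = simulate_trial(params, seed=4)
        ep = max(truth.episodes, key=lambda e: e.duration_s)
        ap = trial.shin_left["AP"]
        i0, i1 = int(ep.start_s * FS), int(ep.end_s * FS)
        inside = ap[i0:i1] - ap[i0:i1].mean()
        # a clean non-episode stretch
        clear = ap[: max(0, i0 - int(FS))]
        if clear.size < int(4 * FS):
            clear = ap[i1 + int(FS) :]
        clear = clear - clear.mean()
        assert oracle_band_fraction(clear, FS, (0.5, 3.0)) > oracle_band_fraction(
            clear, FS, (3.0, 8.0)
        )
        assert oracle_band_fraction(inside, FS, (3.0, 8.0)) > oracle_band_fraction(
            inside, FS, (0.5, 3.0)
        )

    def test_akinetic_episode_attenuates_shin_signal(self):
        params = PhenotypeParams(
            is_freezer=True, episode_rate=1.0, mean_episode_dur_s=10.0,
            trembling_fraction=0.0, akinetic_suppression=0.05,
        )
        trial, truth = simulate_trial(params, seed=2)
        ep = max(truth.episodes, key=lambda e: e.duration_s)
        ap = trial.shin_left["AP"]
        i0, i1 = int(ep.start_s * FS), int(ep.end_s * FS)
        rms_in = np.std(ap[i0:i1])
        rms_out = np.std(np.concatenate([ap[:i0], ap[i1:]]))
        assert rms_in < 0.3 * rms_out

    def test_turning_pauses_during_episodes(self):
        params = PhenotypeParams(
            is_freezer=True, episode_rate=1.0, mean_episode_dur_s=10.0,
            gyro_noise_dps=0.0, yaw_osc_dps=0.0,
        )
        trial, truth = simulate_trial(params, seed=6)
        ep = max(truth.episodes, key=lambda e: e.duration_s)
        i0, i1 = int(ep.start_s * FS), int(ep.end_s * FS)
        assert np.all(trial.lumbar_gyro["yaw"][i0:i1] == 0.0)

    def test_determinism_bit_identical(self):
        params = PhenotypeParams(is_freezer=True, episode_rate=2.0)
        t1, g1 = simulate_trial(params, seed=13)
        t2, g2 = simulate_trial(params, seed=13)
        for ch in ("AP", "ML", "V"):
            np.testing.assert_array_equal(t1.shin_left[ch], t2.shin_left[ch])
            np.testing.assert_array_equal(t1.shin_right[ch], t2.shin_right[ch])
        np.testing.assert_array_equal(t1.lumbar_gyro["yaw"], t2.lumbar_gyro["yaw"])
        assert g1.episodes == g2.episodes

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_trial(PhenotypeParams(), duration_s=-1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_trial(PhenotypeParams(), sample_rate_hz=10.0)
        with pytest.raises(ValueError, match="freeze band"):
            PhenotypeParams(trembling_freq_hz=10.0).validate()
        with pytest.raises(ValueError, match="locomotion band"):
            PhenotypeParams(cadence_hz=4.0).validate()


class TestSimulateCohort:
    def test_zero_prevalence_means_no_episodes(self):
        cohort = simulate_cohort(CohortConfig(n_subjects=20, freezer_prevalence=0.0, seed=5))
        assert all(len(truth.episodes) == 0 for _, _, truth in cohort)

    def test_same_seed_bit_identical(self, small_cohort_config):
        a = simulate_cohort(small_cohort_config)
        b = simulate_cohort(small_cohort_config)
        for (ra, ta, ga), (rb, tb, gb) in zip(a, b):
            assert ra == rb
            np.testing.assert_array_equal(ta.shin_left["AP"], tb.shin_left["AP"])
            assert ga == gb

    def test_empirical_prevalence_within_binomial_ci(self):
        """Bernoulli(0.63) over n=1000 stays inside the 99% binomial CI."""
        p = 0.63
        n = 1000
        cohort = simulate_cohort(
            CohortConfig(
                n_subjects=n, freezer_prevalence=p, seed=17,
                trial_duration_s=4.0, sample_rate_hz=32.0,  # tiny trials: only the draw matters
            )
        )
        k = sum(rec.covariates["is_freezer"] for rec, _, _ in cohort)
        lo, hi = stats.binom.interval(0.99, n, p)
        assert lo <= k <= hi

    def test_every_subject_in_exactly_one_subgroup(self, small_cohort_config):
        cohort = simulate_cohort(small_cohort_config)
        for rec, _, truth in cohort:
            assert rec.subgroup in SUBGROUPS
            assert rec.subgroup == truth.true_subgroup
            assert rec.expert_freezer == bool(truth.episodes)
            assert rec.self_report_fog == truth.self_report

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=1).validate()
        with pytest.raises(ValueError):
            CohortConfig(sample_rate_hz=12.0).validate()
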