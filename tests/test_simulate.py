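"""Synthetic mixed-PPG generator: ground truth, raw signals, artifacts."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from tfo.simulate import (
    ArtifactWindow,
    RoundSpec,
    SimConfig,
    generate_truth,
    inject_artifacts,
    simulate_feature_cohort,
    synthesize_recording,
)
from tfo.demodulate import demodulate
from tfo.acdc import extract_dc


class TestGenerateTruth:
    def test_two_step_round_has_six_scheduled_draws(self):
        cfg = SimConfig(round_duration=1200.0, step_duration=600.0, seed=1)
        truth = generate_truth(cfg)
        np.testing.assert_allclose(
            truth.abg_t, [150.0, 300.0, 600.0, 750.0, 900.0, 1200.0]
        )

    def test_constant_trajectory_without_noise(self):
        cfg = SimConfig(
            round_duration=1200.0,
            step_duration=600.0,
            sat_start=50.0,
            sat_end=50.0,
            abg_noise_sd=0.0,
            seed=1,
        )
        truth = generate_truth(cfg)
        np.testing.assert_allclose(truth.abg_fsao2, 50.0)
        assert not truth.labels(truth.t).any()

    def test_deterministic_under_seed(self):
        cfg = SimConfig(round_duration=600.0, seed=42)
        a, b = generate_truth(cfg), generate_truth(cfg)
        np.testing.assert_array_equal(a.fsao2, b.fsao2)
        np.testing.assert_array_equal(a.fhr_bpm, b.fhr_bpm)
        np.testing.assert_array_equal(a.abg_fsao2, b.abg_fsao2)
        other = generate_truth(SimConfig(round_duration=600.0, seed=43))
        assert not np.array_equal(a.fhr_bpm, other.fhr_bpm)

    def test_heart_rates_stay_in_configured_ranges(self):
        cfg = SimConfig(round_duration=1800.0, seed=5)
        truth = generate_truth(cfg)
        assert truth.fhr_bpm.min() >= cfg.fhr_range[0]
        assert truth.fhr_bpm.max() <= cfg.fhr_range[1]
        assert truth.mhr_bpm.min() >= cfg.mhr_range[0]
        assert truth.mhr_bpm.max() <= cfg.mhr_range[1]

    def test_saturation_declines_across_round(self):
        cfg = SimConfig(round_duration=1800.0, seed=5)
        truth = generate_truth(cfg)
        assert truth.fsao2[0] == pytest.approx(cfg.sat_start)
        assert truth.fsao2[-1] == pytest.approx(cfg.sat_end)
        assert np.all(np.diff(truth.fsao2) <= 1e-9)

    def test_round_shorter_than_step_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            generate_truth(SimConfig(round_duration=300.0, step_duration=600.0))

    def test_csv_round_trip(self, tmp_path):
        truth = generate_truth(SimConfig(round_duration=600.0, seed=2))
        truth.to_csv(tmp_path / "truth.csv", tmp_path / "abg.csv")
        from tfo.simulate import GroundTruth

        loaded = GroundTruth.from_csv(tmp_path / "truth.csv", tmp_path / "abg.csv")
        np.testing.assert_allclose(loaded.fsao2, truth.fsao2)
        np.testing.assert_allclose(loaded.abg_t, truth.abg_t)


class TestSynthesizeRecording:
    def test_invalid_modulation_frequencies_rejected(self):
        cfg = SimConfig(mod_freqs={740: 690.0, 850: 690.0})
        with pytest.raises(ValueError, match="distinct"):
            cfg.validate()
        cfg = SimConfig(mod_freqs={740: 690.0, 850: 4500.0})
        with pytest.raises(ValueError, match="fs_raw/2"):
            cfg.validate()

    def test_quiet_scene_demodulates_to_base_power(self):
        # no maternal, respiratory, fetal or noise components: each
        # demodulated channel must be the constant base power
        cfg = SimConfig(
            round_duration=30.0,
            step_duration=30.0,
            maternal_pulsation=0.0,
            resp_amplitude=0.0,
            fetal_delta_c=0.0,
            noise_sd=0.0,
            abg_noise_sd=0.0,
            seed=0,
        )
        truth = generate_truth(cfg)
        rec = synthesize_recording(cfg, truth)
        env = demodulate(rec)
        for lam in (740, 850):
            mid = env[lam][:, 40000:-40000]
            for d in range(cfg.n_detectors):
                expected = cfg.base_power(d, lam)
                np.testing.assert_allclose(mid[d], expected, rtol=1e-3)

    def test_deterministic_under_seed(self):
        cfg = SimConfig(round_duration=20.0, step_duration=20.0, noise_sd=1e-5, seed=9)
        truth = generate_truth(cfg)
        a = synthesize_recording(cfg, truth)
        b = synthesize_recording(cfg, truth)
        np.testing.assert_array_equal(a.signals, b.signals)

    def test_received_power_decays_with_distance(self, clean_round):
        config, _, _, wppg = clean_round
        for lam in (740, 850):
            dc_levels = [wppg.get(d, lam).mean() for d in range(5)]
            assert np.all(np.diff(dc_levels) < 0)

    def test_fetal_pulsation_share_grows_with_distance(self, clean_acdc):
        sl = slice(40 * 80, 200 * 80)
        ratios = []
        for d in range(5):
            s = clean_acdc[(d, 850)]
            ratios.append(s.ac[sl].mean() / s.dc[sl].mean())
        assert np.all(np.diff(ratios) > 0)

    def test_fetal_ac_two_to_four_orders_below_dc(self, clean_acdc):
        sl = slice(40 * 80, 200 * 80)
        for (d, lam), s in clean_acdc.items():
            order = np.log10(s.ac[sl].mean() / s.dc[sl].mean())
            assert -4.0 <= order <= -2.0, (d, lam, order)

    def test_spectrogram_shows_expected_physiological_lines(self, clean_round):
        config, truth, rec, _ = clean_round
        env = demodulate(rec)[850][2]  # mid detector
        f, pxx = sps.welch(env[80000:-80000], fs=config.fs_raw, nperseg=1 << 17)
        background = np.median(pxx[(f > 4.0) & (f < 8.0)])

        def peak_power(freq, half=0.12):
            return pxx[(f > freq - half) & (f < freq + half)].max()

        assert peak_power(config.mrr) > 100 * background  # respiration
        assert peak_power(2 * config.mrr) > 10 * background  # harmonic
        assert peak_power(truth.mhr_bpm.mean() / 60.0) > 100 * background
        assert peak_power(truth.fhr_bpm.mean() / 60.0, half=0.2) > 10 * background

    def test_recording_hdf5_round_trip(self, tmp_path):
        cfg = SimConfig(round_duration=10.0, step_duration=10.0, seed=3)
        truth = generate_truth(cfg)
        rec = synthesize_recording(cfg, truth)
        rec.to_hdf5(tmp_path / "rec.h5")
        from tfo.simulate import RawRecording

        loaded = RawRecording.from_hdf5(tmp_path / "rec.h5")
        np.testing.assert_array_equal(loaded.signals, rec.signals)
        assert loaded.mod_freqs == rec.mod_freqs
        assert loaded.gains == rec.gains


@pytest.fixture(scope="module")
def small_recording():
    cfg = SimConfig(round_duration=60.0, step_duration=60.0, noise_sd=0.0, seed=4)
    truth = generate_truth(cfg)
    return cfg, synthesize_recording(cfg, truth)


class TestInjectArtifacts:

    def test_empty_spec_leaves_recording_unchanged(self, small_recording):
        _, rec = small_recording
        out = inject_artifacts(rec, [], seed=0)
        np.testing.assert_array_equal(out.signals, rec.signals)

    def test_untouched_samples_bit_identical(self, small_recording):
        _, rec = small_recording
        out = inject_artifacts(rec, [ArtifactWindow("burst", 20.0, 30.0, 0.01)], seed=0)
        t = rec.time()
        outside = (t < 20.0) | (t >= 30.0)
        np.testing.assert_array_equal(out.signals[:, outside], rec.signals[:, outside])
        assert not np.array_equal(out.signals[:, ~outside], rec.signals[:, ~outside])

    def test_burst_elevates_broadband_energy(self, small_recording):
        cfg, rec = small_recording
        out = inject_artifacts(rec, [ArtifactWindow("burst", 20.0, 30.0, 0.05)], seed=0)
        f, t_spec, sxx = sps.spectrogram(out.signals[0], fs=cfg.fs_raw, nperseg=4096)
        in_win = (t_spec > 21) & (t_spec < 29)
        out_win = (t_spec > 40) & (t_spec < 55)
        # broadband: compare energy away from the carrier lines
        band = (f > 1500) & (f < 1800)
        assert sxx[np.ix_(band, in_win)].mean() > 100 * sxx[np.ix_(band, out_win)].mean()

    def test_step_shifts_dc_envelope_by_amplitude(self, small_recording):
        cfg, rec = small_recording
        amp = 0.05
        out = inject_artifacts(rec, [ArtifactWindow("step", 30.0, 60.0, amp)], seed=0)
        from tfo.demodulate import process_recording

        before = process_recording(rec)
        after = process_recording(out)
        # the step acts on the summed raw signal; each demodulated channel
        # sees amp scaled by its carrier's mixing gain -- compare DC
        # envelopes of the raw detector signal instead
        dc_b, _ = extract_dc(rec.signals[0][::100], 80.0)
        dc_a, _ = extract_dc(out.signals[0][::100], 80.0)
        shift = dc_a[3200:4000].mean() - dc_b[3200:4000].mean()
        assert shift == pytest.approx(amp, rel=0.05)

    def test_overlapping_windows_merge_with_warning(self, small_recording):
        _, rec = small_recording
        spec = [
            ArtifactWindow("step", 10.0, 20.0, 0.01),
            ArtifactWindow("step", 15.0, 25.0, 0.01),
        ]
        with pytest.warns(UserWarning, match="merged"):
            inject_artifacts(rec, spec, seed=0)

    def test_window_outside_recording_rejected(self, small_recording):
        _, rec = small_recording
        with pytest.raises(ValueError, match="outside"):
            inject_artifacts(rec, [ArtifactWindow("step", 50.0, 90.0, 0.01)], seed=0)


class TestFeatureCohort:
    def test_default_cohort_shape_and_columns(self):
        df = simulate_feature_cohort(seed=0)
        assert set(df["round_id"]) == {0, 1, 2, 3, 4}
        for d in range(1, 6):
            assert {f"pr_d{d}_740", f"pr_d{d}_850", f"phi_d{d}"} <= set(df.columns)
        assert {"t", "label", "valid", "win_start", "win_end"} <= set(df.columns)
        # three mixed rounds and two all-hypoxemic rounds
        per_round = df.groupby("round_id")["label"].mean()
        assert (per_round == 1.0).sum() == 2
        assert ((per_round > 0) & (per_round < 1)).sum() == 3

    def test_deterministic_under_seed(self):
        a = simulate_feature_cohort(seed=7)
        b = simulate_feature_cohort(seed=7)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_feature_cohort(seed=8)
        assert not a["phi_d1"].equals(c["phi_d1"])

    def test_modulation_consistent_with_pulsation_ratios(self):
        df = simulate_feature_cohort(seed=0)
        for d in range(1, 6):
            np.testing.assert_allclose(
                df[f"phi_d{d}"], df[f"pr_d{d}_740"] / df[f"pr_d{d}_850"], rtol=1e-9
            )
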