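import numpy as np
import pytest
from scipy import signal as sps

from physiopipe.eda import eda_quality_index
from physiopipe.simulate import (
    BREATHWORK_478,
    CYCLE_478_S,
    FREE_BREATHING,
    ConfigError,
    SimulationConfig,
    merge_intervals,
    simulate_ecg,
    simulate_eda_emg,
    simulate_respiration,
    simulate_session,
)


class TestRespiration:
    def test_478_complete_cycle_count_and_spacing(self):
        cfg = SimulationConfig(seed=0, protocol=BREATHWORK_478, duration_s=600.0)
        _, gt = simulate_respiration(cfg)
        # 600 / 19 -> 31 complete inhale-hold-exhale cycles
        assert gt.exhalation_onsets_s.size == 31
        assert np.allclose(np.diff(gt.inhalation_onsets_s), CYCLE_478_S)
        assert gt.inhalation_onsets_s[0] == 0.0

    def test_free_breathing_rate_times_time(self):
        cfg = SimulationConfig(
            seed=0, protocol=FREE_BREATHING, base_breath_rate_bpm=15.0, duration_s=120.0
        )
        _, gt = simulate_respiration(cfg)
        assert gt.inhalation_onsets_s.size == 30
        assert np.allclose(np.diff(gt.inhalation_onsets_s), 4.0, atol=1e-6)

    def test_noiseless_waveform_exactly_periodic(self):
        cfg = SimulationConfig(seed=0, protocol=BREATHWORK_478, duration_s=95.0)
        cfg.noise_sd["RESP"] = 0.0
        ch, _ = simulate_respiration(cfg)
        period = int(CYCLE_478_S * ch.fs)
        n_keep = (ch.n // period) * period
        cycles = ch.samples[:n_keep].reshape(-1, period)
        # tolerance covers float jitter of (t mod period) at late times
        np.testing.assert_allclose(cycles - cycles[0], 0.0, atol=1e-9)

    def test_nonpositive_trajectory_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(
                protocol=FREE_BREATHING,
                breath_rate_trajectory=[(0.0, 12.0), (600.0, -1.0)],
            )


class TestEcg:
    def test_peak_count_at_60bpm(self, ecg_60bpm):
        _, gt = ecg_60bpm
        assert abs(gt.r_peaks_s.size - 600) <= 1

    def test_lf_modulation_dominates_truth_tachogram(self):
        """Periodogram of the true RR series peaks inside 0.04-0.15 Hz."""
        cfg = SimulationConfig(seed=5, mean_hr_bpm=60.0, rr_modulation=((0.1, 0.05),))
        _, gt = simulate_ecg(cfg)
        rr = np.diff(gt.r_peaks_s)
        mids = gt.r_peaks_s[:-1] + rr / 2
        grid = np.arange(mids[0], mids[-1], 0.25)
        tach = np.interp(grid, mids, rr)
        f, pxx = sps.periodogram(tach - tach.mean(), fs=4.0)
        f_peak = f[np.argmax(pxx)]
        assert 0.04 <= f_peak <= 0.15

    def test_seeded_determinism(self):
        cfg = SimulationConfig(seed=9)
        a, _ = simulate_ecg(cfg)
        b, _ = simulate_ecg(SimulationConfig(seed=9))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_excessive_modulation_rejected(self):
        cfg = SimulationConfig(mean_hr_bpm=60.0, rr_modulation=((0.1, 1.5),))
        with pytest.raises(ConfigError):
            simulate_ecg(cfg)


class TestEdaEmg:
    def test_pure_tonic_ramp_identity(self):
        cfg = SimulationConfig(
            seed=0,
            duration_s=120.0,
            eda_tonic_trajectory=((0.0, 2.0), (120.0, 8.0)),
            scr_rate_per_min=0.0,
        )
        cfg.noise_sd["EDA"] = 0.0
        eda, _, gt = simulate_eda_emg(cfg)
        np.testing.assert_allclose(eda.samples, gt.tonic_at(eda.times), atol=1e-12)

    def test_artifact_gain_scales_emg_variance(self):
        cfg = SimulationConfig(seed=4, duration_s=120.0, artifact_windows=((50.0, 5.0, 10.0),))
        _, emg, _ = simulate_eda_emg(cfg)
        t = emg.times
        inside = emg.samples[(t >= 50) & (t < 55)]
        outside = emg.samples[(t < 50) | (t >= 55)]
        assert inside.var() >= 25 * outside.var()

    def test_scr_count_poisson_mean(self):
        counts = []
        for seed in range(30):
            cfg = SimulationConfig(seed=seed, scr_rate_per_min=4.0)
            _, _, gt = simulate_eda_emg(cfg)
            counts.append(gt.scr_times_s.size)
        # fixed seed reproducible, mean ~ rate * duration = 40
        _, _, gt0 = simulate_eda_emg(SimulationConfig(seed=0, scr_rate_per_min=4.0))
        assert gt0.scr_times_s.size == counts[0]
        assert abs(np.mean(counts) - 40.0) < 5.0

    def test_overlapping_windows_merged(self):
        assert merge_intervals([(0.0, 5.0), (3.0, 8.0), (10.0, 11.0)]) == [
            (0.0, 8.0),
            (10.0, 11.0),
        ]


class TestSession:
    def test_container_contract(self, breathwork_session):
        rec, _ = breathwork_session
        assert set(rec.channels) == {"ECG", "EDA", "EMG", "RESP"}
        assert len(rec.markers) == 2
        assert rec.marker_time("experience_end") == 600.0

    def test_breathwork_rate_decreases_by_construction(self, breathwork_session):
        _, gt = breathwork_session
        rates = gt.breath_rate_per_window()
        assert rates[-1] < rates[0]

    def test_rain_rate_flat(self, rain_session):
        _, gt = rain_session
        rates = gt.breath_rate_per_window()
        assert np.ptp(rates) <= 1.0

    def test_clean_simulation_qi_is_100(self, rain_session):
        rec, _ = rain_session
        qi, ok = eda_quality_index(rec.channels["EDA"])
        assert qi == 100.0 and ok

    def test_truth_counts_match_configured_rate_within_one(self, rain_session):
        _, gt = rain_session
        expected = 15.0 * 2  # breaths per 2-minute window at the default rate
        counts = gt.breath_rate_per_window() * 2
        assert np.all(np.abs(counts - expected) <= 1)

    def test_seed_determinism_full_session(self):
        cfg = SimulationConfig(seed=77, protocol=BREATHWORK_478)
        a, _ = simulate_session(cfg)
        b, _ = simulate_session(SimulationConfig(seed=77, protocol=BREATHWORK_478))
        for m in a.channels:
            np.testing.assert_array_equal(a.channels[m].samples, b.channels[m].samples)
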