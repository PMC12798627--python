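import numpy as np
import pytest

from physiopipe.io import Channel
from physiopipe.resp import (
    BreathEvents,
    RespParams,
    SmoothedResp,
    breath_rate_series,
    detect_breath_onsets,
    moving_mean_local,
    smooth_respiration,
)
from physiopipe.simulate import FREE_BREATHING, SimulationConfig, simulate_respiration


def _sine_channel(freq_hz=0.25, duration=120.0, fs=25.0, amp=1.0, noise=0.0, seed=0):
    t = np.arange(0, duration, 1 / fs)
    x = amp * np.sin(2 * np.pi * freq_hz * t)
    if noise:
        x = x + np.random.default_rng(seed).normal(0, noise, t.size)
    return Channel("RESP", x, fs=fs), t


class TestSmoothing:
    def test_sine_period_estimates(self):
        ch, _ = _sine_channel()
        sm = smooth_respiration(ch)
        np.testing.assert_allclose(sm.periods_s, 4.0, atol=0.2)

    def test_noisy_sine_recovered(self):
        ch, t = _sine_channel(noise=np.sqrt(1 / (2 * 5)), seed=3)  # SNR 5
        clean = np.sin(2 * np.pi * 0.25 * t)
        sm = smooth_respiration(ch)
        r = np.corrcoef(sm.channel.samples, clean)[0, 1]
        assert r >= 0.95

    def test_constant_input_flat_fallback(self):
        ch = Channel("RESP", np.full(25 * 120, 2.0), fs=25.0)
        sm = smooth_respiration(ch)
        assert np.abs(sm.channel.samples).max() < 1e-6
        assert any("flat spectrum" in n for n in sm.notes)

    def test_too_short_channel_errors(self):
        ch = Channel("RESP", np.zeros(100), fs=25.0)
        with pytest.raises(ValueError):
            smooth_respiration(ch)


class TestOnsets:
    def test_sine_onset_count(self):
        ch, _ = _sine_channel(duration=60.0, fs=25.0)
        # period estimation window equals the 60 s span here
        sm = smooth_respiration(ch)
        ev = detect_breath_onsets(sm)
        assert abs(ev.inhalation_onsets_s.size - 15) <= 1

    def test_matches_bruteforce_crossing_enumeration(self):
        """Onset times equal a direct loop over sign changes of x - mean."""
        rng = np.random.default_rng(5)
        fs = 10.0
        t = np.arange(0, 30, 1 / fs)
        x = np.sin(2 * np.pi * 0.2 * t) + 0.1 * rng.normal(size=t.size)
        ch = Channel("RESP", x / x.std(), fs=fs)
        sm = SmoothedResp(ch, np.array([15.0]), np.array([5.0]))
        p = RespParams(min_amplitude=0.0)
        ev = detect_breath_onsets(sm, p)

        win = np.maximum((5.0 * fs * np.ones(t.size)).astype(int), 3)
        mm = moving_mean_local(x / x.std(), win)
        d = x / x.std() - mm
        events = []
        prev = np.sign(d[0]) or 1.0
        for i in range(1, d.size):
            s = np.sign(d[i]) or prev
            if s != prev:
                tc = t[i - 1] + (t[i] - t[i - 1]) * (-d[i - 1]) / (d[i] - d[i - 1])
                events.append((tc, "inh" if s > 0 else "exh"))
            prev = s
        expect_inh = [tc for tc, k in events if k == "inh"]
        got = np.concatenate([ev.inhalation_onsets_s, ev.exhalation_onsets_s])
        for tc in ev.inhalation_onsets_s:
            assert min(abs(tc - e) for e in expect_inh) < 1e-9

    def test_amplitude_gate_keeps_large_breaths_only(self):
        fs = 25.0
        t = np.arange(0, 120, 1 / fs)
        # alternating large and small oscillations at 0.1 Hz pairs
        x = np.where(
            (t // 10).astype(int) % 2 == 0,
            2.0 * np.sin(2 * np.pi * 0.1 * t),
            0.05 * np.sin(2 * np.pi * 0.1 * t),
        )
        ch = Channel("RESP", x, fs=fs)
        sm = SmoothedResp(ch, np.array([60.0]), np.array([10.0]))
        ev = detect_breath_onsets(sm)
        assert ev.n_breaths > 0
        assert (ev.amplitudes >= 0.25).all()

    def test_amplitude_gate_monotone(self):
        ch, _ = _sine_channel(duration=120.0)
        sm = smooth_respiration(ch)
        counts = []
        for thr in (0.0, 0.25, 1.0, 3.0):
            ev = detect_breath_onsets(sm, RespParams(min_amplitude=thr))
            counts.append(ev.n_breaths)
        assert np.all(np.diff(counts) <= 0)

    def test_time_shift_equivariance(self):
        ch, _ = _sine_channel(duration=120.0, noise=0.02, seed=7)
        sm = smooth_respiration(ch)
        ev = detect_breath_onsets(sm)
        shifted = Channel("RESP", ch.samples, fs=ch.fs, t0=ch.t0 + 5.0)
        sm2 = smooth_respiration(shifted)
        ev2 = detect_breath_onsets(sm2)
        n = min(ev.n_breaths, ev2.n_breaths)
        d = ev2.inhalation_onsets_s[:n] - ev.inhalation_onsets_s[:n]
        assert np.abs(d - 5.0).max() <= 1.0 / ch.fs + 1e-6

    def test_zero_crossings_give_empty_events(self):
        ch = Channel("RESP", np.linspace(0, 1, 3000), fs=25.0)
        sm = SmoothedResp(ch, np.array([60.0]), np.array([4.0]))
        ev = detect_breath_onsets(sm)
        assert ev.n_breaths == 0


class TestBreathRates:
    def test_constant_15bpm_rates_and_counts(self, resp_free_15bpm):
        ch, _ = resp_free_15bpm
        sm = smooth_respiration(ch)
        ev = detect_breath_onsets(sm)
        out = breath_rate_series(ev)
        np.testing.assert_allclose(out.rates_bpm, 15.0, atol=0.5)
        assert abs(out.first5_count - 75) <= 1
        assert abs(out.last5_count - 75) <= 1
        assert out.qa_pass

    def test_478_rates_near_60_over_19(self):
        cfg = SimulationConfig(seed=41, protocol="breathwork_478")
        ch, _ = simulate_respiration(cfg)
        sm = smooth_respiration(ch)
        ev = detect_breath_onsets(sm)
        out = breath_rate_series(ev)
        assert np.abs(out.rates_bpm - 60.0 / 19.0).max() <= 0.6
        assert out.qa_pass

    @pytest.mark.parametrize("bpm, expect_pass", [(15.0, True), (22.0, False)])
    def test_qa_gate(self, bpm, expect_pass):
        cfg = SimulationConfig(
            seed=43, protocol=FREE_BREATHING, base_breath_rate_bpm=bpm
        )
        ch, _ = simulate_respiration(cfg)
        sm = smooth_respiration(ch)
        ev = detect_breath_onsets(sm)
        out = breath_rate_series(ev)
        assert out.qa_pass is expect_pass

    def test_onset_time_recovery_free_breathing(self):
        for bpm in (12.0, 15.0, 18.0):
            cfg = SimulationConfig(
                seed=int(bpm), protocol=FREE_BREATHING, base_breath_rate_bpm=bpm
            )
            ch, gt = simulate_respiration(cfg)
            sm = smooth_respiration(ch)
            ev = detect_breath_onsets(sm)
            err = np.abs(
                ev.inhalation_onsets_s[:, None] - gt.inhalation_onsets_s[None, :]
            ).min(axis=1)
            assert np.median(err) <= 0.5

    def test_windowed_rate_recovery_both_protocols(self):
        for proto, leadin in (("breathwork_478", True), (FREE_BREATHING, False)):
            for seed in range(3):
                cfg = SimulationConfig(seed=seed + 60, protocol=proto)
                ch, gt = simulate_respiration(cfg, with_leadin=leadin)
                sm = smooth_respiration(ch)
                ev = detect_breath_onsets(sm)
                out = breath_rate_series(ev)
                truth = gt.breath_rate_per_window()
                assert np.abs(out.rates_bpm - truth).max() <= 0.5
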