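"""Synthetic multimodal sessions with known ground truth.

Generates 10-minute four-channel recordings (ECG, EDA, EMG, respiration)
that emulate a seated relaxation session under either guided 4-7-8
breathwork (inhale 4 s, hold 7 s, exhale 8 s; 19 s cycle, ~3.16 breaths
per minute) or free breathing at a configurable rate trajectory.  Every
generated event — inhalation/exhalation onsets, R-peak times, skin
conductance responses, motion-artifact windows — is returned as ground
truth so detection and feature-extraction stages can be scored exactly.

The generator is deterministic per seed: each modality draws from its own
child generator of the configured seed, so simulating a single modality in
isolation reproduces the corresponding channel of the full session.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .io import Channel, SessionRecording, EXPERIENCE_START, EXPERIENCE_END

BREATHWORK_478 = "breathwork_478"
FREE_BREATHING = "free_breathing"

#: 4-7-8 pacing: inhale / hold / exhale durations in seconds
INHALE_S, HOLD_S, EXHALE_S = 4.0, 7.0, 8.0
CYCLE_478_S = INHALE_S + HOLD_S + EXHALE_S  # 19 s

_DEF_FS = {"ECG": 250.0, "EDA": 32.0, "EMG": 250.0, "RESP": 25.0}
_DEF_NOISE = {"ECG": 20.0, "EDA": 0.01, "EMG": 10.0, "RESP": 0.05}


class ConfigError(ValueError):
    """Raised when a simulation configuration is physiologically invalid."""


@dataclass
class SimulationConfig:
    """Knobs for one simulated session.

    ``rr_modulation`` entries are (frequency Hz, amplitude s) sinusoidal
    components added to the RR-interval series; the defaults put power in
    both the LF (0.1 Hz) and HF (0.3 Hz) bands.  ``noise_sd['RESP']`` is
    relative to the clean respiration waveform's standard deviation; the
    other noise levels are in device units.  ``artifact_windows`` entries
    are (start_s, duration_s, gain): inside each window the EMG amplitude
    is multiplied by ``gain`` and the EDA receives spiky contamination.
    """

    seed: int = 0
    duration_s: float = 600.0
    protocol: str = FREE_BREATHING
    base_breath_rate_bpm: float = 15.0
    breath_rate_trajectory: Sequence[tuple[float, float]] | None = None
    breathwork_leadin_s: float = 60.0
    mean_hr_bpm: float = 70.0
    rr_modulation: Sequence[tuple[float, float]] = ((0.10, 0.03), (0.30, 0.025))
    eda_tonic_trajectory: Sequence[tuple[float, float]] = ((0.0, 6.0), (600.0, 4.0))
    scr_rate_per_min: float = 4.0
    scr_amplitude_us: float = 0.3
    artifact_windows: Sequence[tuple[float, float, float]] = ()
    fs: dict[str, float] = field(default_factory=lambda: dict(_DEF_FS))
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(_DEF_NOISE))

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.protocol not in (BREATHWORK_478, FREE_BREATHING):
            raise ConfigError(f"unknown protocol {self.protocol!r}")
        if self.mean_hr_bpm <= 0 or self.base_breath_rate_bpm <= 0:
            raise ConfigError("rates must be positive")
        for k, v in self.fs.items():
            if v <= 0:
                raise ConfigError(f"fs[{k}] must be positive")
        for start, dur, gain in self.artifact_windows:
            if dur <= 0 or start < 0 or start + dur > self.duration_s:
                raise ConfigError(
                    f"artifact window ({start}, {dur}) outside [0, {self.duration_s}]"
                )
        if self.breath_rate_trajectory is not None:
            for _, bpm in self.breath_rate_trajectory:
                if bpm <= 0:
                    raise ConfigError("breath rate trajectory reaches <= 0 bpm")

    def rng(self, stream: int) -> np.random.Generator:
        """Child generator for one modality (deterministic per seed)."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


@dataclass
class GroundTruth:
    """Events and trajectories the simulator actually rendered."""

    inhalation_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    exhalation_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    r_peaks_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    scr_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    artifact_windows: list[tuple[float, float]] = field(default_factory=list)
    tonic_trajectory: Sequence[tuple[float, float]] = ()

    def tonic_at(self, t: np.ndarray | float) -> np.ndarray:
        pts = np.asarray(self.tonic_trajectory, dtype=float)
        return np.interp(np.asarray(t, dtype=float), pts[:, 0], pts[:, 1])

    def breath_rate_per_window(
        self, window_s: float = 120.0, duration_s: float = 600.0
    ) -> np.ndarray:
        """True breaths/min per non-overlapping window (counting inhalation onsets)."""
        edges = np.arange(0.0, duration_s + 1e-9, window_s)
        counts, _ = np.histogram(self.inhalation_onsets_s, bins=edges)
        return counts / (window_s / 60.0)

    def hr_per_window(
        self, window_s: float = 60.0, duration_s: float = 600.0
    ) -> np.ndarray:
        """True mean HR (bpm) per window from RR intervals by midpoint."""
        rr = np.diff(self.r_peaks_s)
        mid = self.r_peaks_s[:-1] + rr / 2
        edges = np.arange(0.0, duration_s + 1e-9, window_s)
        out = np.full(len(edges) - 1, np.nan)
        for i in range(len(edges) - 1):
            sel = (mid >= edges[i]) & (mid < edges[i + 1])
            if sel.sum() >= 2:
                out[i] = 60.0 / rr[sel].mean()
        return out


def _merge(ground: GroundTruth, part: GroundTruth) -> GroundTruth:
    for name in (
        "inhalation_onsets_s",
        "exhalation_onsets_s",
        "r_peaks_s",
        "scr_times_s",
    ):
        v = getattr(part, name)
        if v.size:
            setattr(ground, name, v)
    if part.artifact_windows:
        ground.artifact_windows = part.artifact_windows
    if len(part.tonic_trajectory):
        ground.tonic_trajectory = part.tonic_trajectory
    return ground


# ---------------------------------------------------------------------------
# respiration


def _cycle_478(phase_s: np.ndarray) -> np.ndarray:
    """One 4-7-8 cycle as a smooth -1..1 waveform of time within the cycle."""
    y = np.empty_like(phase_s)
    inh = phase_s < INHALE_S
    hold = (phase_s >= INHALE_S) & (phase_s < INHALE_S + HOLD_S)
    exh = ~inh & ~hold
    y[inh] = -np.cos(np.pi * phase_s[inh] / INHALE_S)
    y[hold] = 1.0
    y[exh] = np.cos(np.pi * (phase_s[exh] - INHALE_S - HOLD_S) / EXHALE_S)
    return y


def _resp_segments(cfg: SimulationConfig, with_leadin: bool) -> list[dict]:
    """Protocol as a list of time segments, each free-breathing or 4-7-8."""
    if cfg.protocol == FREE_BREATHING:
        traj = cfg.breath_rate_trajectory or [
            (0.0, cfg.base_breath_rate_bpm),
            (cfg.duration_s, cfg.base_breath_rate_bpm),
        ]
        return [{"kind": "free", "start": 0.0, "end": cfg.duration_s, "traj": traj}]
    lead = min(cfg.breathwork_leadin_s, cfg.duration_s) if with_leadin else 0.0
    segs: list[dict] = []
    if lead > 0:
        segs.append(
            {
                "kind": "free",
                "start": 0.0,
                "end": lead,
                "traj": [(0.0, cfg.base_breath_rate_bpm), (lead, cfg.base_breath_rate_bpm)],
            }
        )
    segs.append({"kind": "478", "start": lead, "end": cfg.duration_s})
    return segs


def simulate_respiration(
    cfg: SimulationConfig, with_leadin: bool = False
) -> tuple[Channel, GroundTruth]:
    """Render the respiration channel and its true breath onsets.

    4-7-8 segments record an inhalation onset at each complete cycle start
    and an exhalation onset at the end of the breath-hold; free-breathing
    segments record onsets at the upward (inhalation) and downward
    (exhalation) turning phases of the sinusoidal waveform.
    """
    fs = cfg.fs["RESP"]
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    y = np.zeros(n)
    inh: list[float] = []
    exh: list[float] = []
    for seg in _resp_segments(cfg, with_leadin):
        sel = (t >= seg["start"]) & (t < seg["end"])
        ts = t[sel] - seg["start"]
        seg_len = seg["end"] - seg["start"]
        if seg["kind"] == "478":
            y[sel] = _cycle_478(np.mod(ts, CYCLE_478_S))
            starts = seg["start"] + CYCLE_478_S * np.arange(
                int(np.ceil(seg_len / CYCLE_478_S))
            )
            # an onset is ground truth once its phase completes in-session
            inh.extend(s for s in starts if s + INHALE_S <= seg["end"] + 1e-9)
            exh.extend(
                s + INHALE_S + HOLD_S
                for s in starts
                if s + INHALE_S + HOLD_S < seg["end"] - 1e-9
            )
        else:
            pts = np.asarray(seg["traj"], dtype=float)
            rate_hz = np.interp(ts, pts[:, 0], pts[:, 1]) / 60.0
            # cumulative phase (cycles); trapezoid keeps onset times exact
            phase = np.concatenate(
                [[0.0], np.cumsum((rate_hz[1:] + rate_hz[:-1]) / 2 / fs)]
            )
            y[sel] = np.sin(2 * np.pi * phase)
            n_c = int(np.ceil(phase[-1])) + 1
            inh.extend(
                seg["start"] + np.interp(np.arange(n_c), phase, ts, left=np.nan)[
                    np.arange(n_c) <= phase[-1]
                ]
            )
            ks = np.arange(n_c) + 0.5
            exh.extend(
                seg["start"] + np.interp(ks, phase, ts, left=np.nan)[ks <= phase[-1]]
            )
    rng = cfg.rng(1)
    sd = cfg.noise_sd["RESP"] * (y.std() or 1.0)
    y = y + rng.normal(0.0, sd, size=n)
    gt = GroundTruth(
        # rounding suppresses float jitter at exact window boundaries
        inhalation_onsets_s=np.round(np.asarray(sorted(inh)), 6),
        exhalation_onsets_s=np.round(np.asarray(sorted(exh)), 6),
    )
    return Channel("RESP", y, fs=fs, units="a.u."), gt


# ---------------------------------------------------------------------------
# ECG


def _qrs_template(fs: float, amplitude: float = 800.0) -> tuple[np.ndarray, int]:
    """Fixed 80 ms biphasic QRS-like pulse; returns (template, index of max)."""
    n = max(int(round(0.08 * fs)), 5)
    x = np.linspace(0.0, 1.0, n)
    # sharp positive peak at 40% of the template, shallow negative overshoot
    tpl = amplitude * np.exp(-(((x - 0.4) / 0.08) ** 2)) - 0.25 * amplitude * np.exp(
        -(((x - 0.62) / 0.10) ** 2)
    )
    return tpl, int(np.argmax(tpl))


def simulate_ecg(cfg: SimulationConfig) -> tuple[Channel, GroundTruth]:
    """Render ECG as QRS templates at modulated R-peak times plus noise.

    RR_i = 60/mean_hr + sum_k a_k sin(2 pi f_k t_i), accumulated from t=0.
    """
    base_rr = 60.0 / cfg.mean_hr_bpm
    if sum(a for _, a in cfg.rr_modulation) >= base_rr:
        raise ConfigError("RR modulation amplitudes exceed the mean RR interval")
    peaks = [0.0]
    while peaks[-1] < cfg.duration_s:
        t_i = peaks[-1]
        rr = base_rr + sum(a * np.sin(2 * np.pi * f * t_i) for f, a in cfg.rr_modulation)
        if rr <= 0:
            raise ConfigError("RR modulation produced a non-positive interval")
        peaks.append(t_i + rr)
    r_peaks = np.asarray(peaks[:-1]) if peaks[-1] > cfg.duration_s else np.asarray(peaks)

    fs = cfg.fs["ECG"]
    n = int(round(cfg.duration_s * fs))
    y = np.zeros(n)
    tpl, i_max = _qrs_template(fs)
    for tp in r_peaks:
        i_peak = int(round(tp * fs))
        lo = i_peak - i_max
        hi = lo + tpl.size
        s0, s1 = max(lo, 0), min(hi, n)
        if s0 < s1:
            y[s0:s1] += tpl[s0 - lo : s1 - lo]
    rng = cfg.rng(2)
    y = y + rng.normal(0.0, cfg.noise_sd["ECG"], size=n)
    return Channel("ECG", y, fs=fs, units="mV"), GroundTruth(r_peaks_s=r_peaks)


# ---------------------------------------------------------------------------
# EDA + EMG


def merge_intervals(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of possibly-overlapping (start, end) intervals, sorted."""
    out: list[tuple[float, float]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _scr_kernel(fs: float, amplitude: float) -> np.ndarray:
    """Phasic skin-conductance response: 1 s half-cosine rise, exponential decay."""
    t = np.arange(int(round(8.0 * fs))) / fs
    k = np.where(
        t < 1.0,
        0.5 * (1 - np.cos(np.pi * t)),
        np.exp(-(t - 1.0) / 1.33),
    )
    return amplitude * k


def simulate_eda_emg(cfg: SimulationConfig) -> tuple[Channel, Channel, GroundTruth]:
    """Render EDA (tonic + phasic + noise) and EMG, with coupled artifacts.

    Inside each configured artifact window the EMG noise amplitude is
    multiplied by the window's gain and the EDA receives spiky
    high-frequency contamination; outside them both channels are clean.
    Overlapping windows are merged.
    """
    fs_eda, fs_emg = cfg.fs["EDA"], cfg.fs["EMG"]
    n_eda = int(round(cfg.duration_s * fs_eda))
    n_emg = int(round(cfg.duration_s * fs_emg))
    t_eda = np.arange(n_eda) / fs_eda

    pts = np.asarray(cfg.eda_tonic_trajectory, dtype=float)
    eda = np.interp(t_eda, pts[:, 0], pts[:, 1])

    rng = cfg.rng(3)
    # homogeneous Poisson process of SCR events
    scr_times: list[float] = []
    if cfg.scr_rate_per_min > 0 and cfg.scr_amplitude_us > 0:
        tt = rng.exponential(60.0 / cfg.scr_rate_per_min)
        while tt < cfg.duration_s:
            scr_times.append(tt)
            tt += rng.exponential(60.0 / cfg.scr_rate_per_min)
        kern = _scr_kernel(fs_eda, cfg.scr_amplitude_us)
        for ts in scr_times:
            i0 = int(round(ts * fs_eda))
            i1 = min(i0 + kern.size, n_eda)
            eda[i0:i1] += kern[: i1 - i0]
    if cfg.noise_sd["EDA"] > 0:
        eda = eda + rng.normal(0.0, cfg.noise_sd["EDA"], size=n_eda)

    emg = rng.normal(0.0, cfg.noise_sd["EMG"], size=n_emg) if cfg.noise_sd[
        "EMG"
    ] > 0 else np.zeros(n_emg)

    windows = merge_intervals([(s, s + d) for s, d, _ in cfg.artifact_windows])
    t_emg = np.arange(n_emg) / fs_emg
    for s, d, gain in cfg.artifact_windows:
        sel_emg = (t_emg >= s) & (t_emg < s + d)
        emg[sel_emg] *= gain
        sel_eda = (t_eda >= s) & (t_eda < s + d)
        n_w = int(sel_eda.sum())
        if n_w:
            spikes = rng.choice([0.0, 1.0], size=n_w, p=[0.7, 0.3])
            eda[sel_eda] += spikes * rng.normal(0.0, 0.4 * gain * 0.1 + 0.5, size=n_w)

    gt = GroundTruth(
        scr_times_s=np.asarray(scr_times),
        artifact_windows=windows,
        tonic_trajectory=tuple(map(tuple, pts)),
    )
    return (
        Channel("EDA", eda, fs=fs_eda, units="uS"),
        Channel("EMG", emg, fs=fs_emg, units="mV"),
        gt,
    )


# ---------------------------------------------------------------------------
# full session


def simulate_session(
    cfg: SimulationConfig,
    participant_id: str = "sim",
    tech: str = "MindGym",
    stim: str | None = None,
) -> tuple[SessionRecording, GroundTruth]:
    """Assemble a full four-channel session with experience markers.

    Breathwork sessions start with a free-breathing lead-in
    (``breathwork_leadin_s``) before 4-7-8 pacing, producing the
    early-to-late breath-rate decrease characteristic of paced slow
    breathing; free-breathing (rain) sessions keep a flat rate trajectory.
    """
    if stim is None:
        stim = "Breathwork" if cfg.protocol == BREATHWORK_478 else "Rain"
    resp, gt_r = simulate_respiration(cfg, with_leadin=True)
    ecg, gt_e = simulate_ecg(cfg)
    eda, emg, gt_a = simulate_eda_emg(cfg)
    gt = GroundTruth()
    for part in (gt_r, gt_e, gt_a):
        _merge(gt, part)
    rec = SessionRecording(
        participant_id=participant_id,
        channels={"ECG": ecg, "EDA": eda, "EMG": emg, "RESP": resp},
        markers=[(EXPERIENCE_START, 0.0), (EXPERIENCE_END, cfg.duration_s)],
        group_labels={"tech": tech, "stim": stim},
    )
    return rec, gt
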