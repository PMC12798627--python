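"""Respiration: period-adaptive smoothing, breath-onset detection, rates.

The chain follows standard impedance-respiration practice: a 0.1 Hz
high-pass removes drift, the signal is resampled to a fixed 100 Hz grid,
and a sliding-window FFT estimates the local respiration period.  The
period guides a moving-average smoother (kernel = quarter period) applied
per window and blended by overlap-add; the smoothed signal is resampled
back to the native rate and normalized to unit standard deviation.
Breath onsets are the crossings between the smoothed signal and its
moving mean (window = one local period): upward crossings are inhalation
onsets, downward crossings exhalation onsets.  Breaths whose
peak-to-trough amplitude falls below 0.25 (in normalized units) are
discarded as non-respiratory fluctuations.  Sessions whose mean rate
reaches 20 breaths/min fail the cleaning QA gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .io import Channel


@dataclass
class RespParams:
    highpass_hz: float = 0.1
    resample_hz: float = 100.0
    est_window_s: float = 60.0
    est_stride_s: float = 15.0
    min_amplitude: float = 0.25  # in unit-SD normalized signal
    qa_max_bpm: float = 20.0
    period_band_hz: tuple[float, float] = (0.05, 1.0)
    # half-period moving average: its first sinc null lands exactly on the
    # 2nd harmonic, whose hold-phase bump otherwise double-counts slow
    # paced breaths
    smooth_kernel_periods: float = 0.5
    moving_mean_periods: float = 1.0
    default_period_s: float = 4.0

    def __post_init__(self) -> None:
        if self.highpass_hz >= self.resample_hz / 2:
            raise ValueError("highpass cutoff must be below the resampled Nyquist")
        if self.qa_max_bpm <= 0:
            raise ValueError("qa_max_bpm must be positive")


@dataclass
class SmoothedResp:
    """Smoothed, unit-SD respiration plus per-window period estimates."""

    channel: Channel
    window_times_s: np.ndarray  # window centers on the channel clock
    periods_s: np.ndarray
    notes: list[str] = field(default_factory=list)

    def period_at(self, t: np.ndarray | float) -> np.ndarray:
        if self.periods_s.size == 0:
            return np.full_like(np.asarray(t, dtype=float), 4.0)
        return np.interp(
            np.asarray(t, dtype=float), self.window_times_s, self.periods_s
        )


@dataclass
class BreathEvents:
    """Retained breaths: paired onsets and per-breath amplitudes."""

    inhalation_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    exhalation_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))
    notes: list[str] = field(default_factory=list)

    @property
    def n_breaths(self) -> int:
        return int(self.inhalation_onsets_s.size)


@dataclass
class BreathRateResult:
    rates_bpm: np.ndarray  # per 2-minute window
    first5_count: int
    last5_count: int
    mean_rate_bpm: float
    qa_pass: bool


def _fft_period(
    seg: np.ndarray,
    fs: float,
    band: tuple[float, float],
    gain: "callable | None" = None,
) -> float | None:
    """Dominant period from the FFT magnitude peak within the search band.

    Uses a Hann taper and parabolic interpolation around the peak bin.
    ``gain`` (the magnitude response of filtering already applied to the
    segment) is divided out before peak picking so a high-passed slow
    rhythm is not mistaken for its harmonics; a subharmonic check then
    prefers f/2 or f/3 when that bin retains at least half the peak
    magnitude, as slow paced breathing has strong harmonics.  Returns
    None for a flat spectrum (no usable peak).
    """
    seg = seg - seg.mean()
    if seg.size < 8 or seg.std() < 1e-10:
        return None
    mag = np.abs(np.fft.rfft(seg * np.hanning(seg.size)))
    freqs = np.fft.rfftfreq(seg.size, d=1.0 / fs)
    if gain is not None:
        mag = mag / np.maximum(gain(freqs), 1e-3)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any() or mag[sel].max() < 1e-9:
        return None
    i = int(np.flatnonzero(sel)[int(np.argmax(mag[sel]))])
    for div in (3, 2):  # prefer the lowest qualifying subharmonic
        j = int(round(i / div))
        if j >= 1 and freqs[j] >= 0.9 * band[0] and mag[j] >= 0.5 * mag[i]:
            i = j
            break
    f = freqs[i]
    if 0 < i < mag.size - 1:
        m0, m1, m2 = mag[i - 1], mag[i], mag[i + 1]
        denom = m0 - 2 * m1 + m2
        if denom != 0:
            delta = 0.5 * (m0 - m2) / denom
            f = f + np.clip(delta, -0.5, 0.5) * (freqs[1] - freqs[0])
    return 1.0 / f if f > 0 else None


def smooth_respiration(ch: Channel, p: RespParams | None = None) -> SmoothedResp:
    """High-pass, resample, estimate periods, smooth, resample back, normalize."""
    p = p or RespParams()
    x = np.asarray(ch.samples, dtype=float)
    if ch.n / ch.fs < p.est_window_s - 1e-9:
        raise ValueError(
            f"channel spans {ch.n / ch.fs:.1f} s < estimation window {p.est_window_s} s"
        )
    gain = None
    if ch.fs > 2 * p.highpass_hz:
        sos = sps.butter(2, p.highpass_hz, btype="highpass", fs=ch.fs, output="sos")
        x = sps.sosfiltfilt(sos, x)

        def gain(freqs: np.ndarray, _sos=sos, _fs=ch.fs) -> np.ndarray:
            # forward-backward filtering squares the magnitude response
            _, h = sps.sosfreqz(_sos, worN=np.maximum(freqs, 1e-6), fs=_fs)
            return np.abs(h) ** 2

    # fixed-rate grid for period estimation and smoothing
    t_native = ch.times
    n_rs = int(round(ch.duration * p.resample_hz)) + 1
    t_rs = ch.t0 + np.arange(n_rs) / p.resample_hz
    y = np.interp(t_rs, t_native, x)

    w = int(round(p.est_window_s * p.resample_hz))
    stride = max(int(round(p.est_stride_s * p.resample_hz)), 1)
    starts = list(range(0, max(y.size - w, 0) + 1, stride))
    if not starts:
        starts = [0]
        w = y.size
    elif starts[-1] + w < y.size:
        starts.append(y.size - w)

    notes: list[str] = []
    centers: list[float] = []
    periods: list[float] = []
    acc = np.zeros(y.size)
    norm = np.zeros(y.size)
    prev_period: float | None = None
    for s0 in starts:
        seg = y[s0 : s0 + w]
        period = _fft_period(seg, p.resample_hz, p.period_band_hz, gain)
        if period is None:
            if prev_period is not None:
                period = prev_period
                notes.append(f"window at {s0 / p.resample_hz:.0f} s: flat spectrum, reused previous period")
            else:
                period = p.default_period_s
                notes.append(f"window at {s0 / p.resample_hz:.0f} s: flat spectrum, default period {period} s")
        prev_period = period
        centers.append(float(t_rs[s0] + (seg.size / 2) / p.resample_hz))
        periods.append(float(period))

        k = max(int(round(p.smooth_kernel_periods * period * p.resample_hz)), 1)
        sm = uniform_filter1d(seg, size=k, mode="nearest")
        wgt = np.bartlett(seg.size) + 1e-6
        acc[s0 : s0 + seg.size] += sm * wgt
        norm[s0 : s0 + seg.size] += wgt
    smooth_rs = np.divide(acc, norm, out=np.zeros_like(acc), where=norm > 0)

    back = np.interp(t_native, t_rs, smooth_rs)
    sd = back.std()
    scale = max(1.0, float(np.abs(ch.samples).max()))
    if sd > 1e-10 * scale:
        back = back / sd
    else:
        # numerically flat (e.g. constant input after DC removal)
        back = np.zeros_like(back)
        notes.append("smoothed signal has zero variance; normalization skipped")
    return SmoothedResp(
        channel=replace(ch, samples=back),
        window_times_s=np.asarray(centers),
        periods_s=np.asarray(periods),
        notes=notes,
    )


def moving_mean_local(
    x: np.ndarray, window_samples: np.ndarray
) -> np.ndarray:
    """Centered moving mean with a per-sample window length (in samples)."""
    n = x.size
    csum = np.concatenate([[0.0], np.cumsum(x)])
    half = np.maximum(window_samples // 2, 1)
    idx = np.arange(n)
    lo = np.clip(idx - half, 0, n)
    hi = np.clip(idx + half + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_breath_onsets(sm: SmoothedResp, p: RespParams | None = None) -> BreathEvents:
    """Mean-crossing onset detection with amplitude gating.

    Crossings of (signal - moving mean) define candidate onsets; the
    moving-mean window tracks the locally estimated period.  Candidates
    are repaired to strict alternation (the earlier of two same-type
    neighbours is dropped), paired into inhale->exhale->next-inhale
    breaths, and breaths below the 0.25 amplitude threshold are deleted
    together with their onsets.
    """
    p = p or RespParams()
    ch = sm.channel
    x = np.asarray(ch.samples, dtype=float)
    t = ch.times
    if x.size < 3:
        return BreathEvents(notes=["signal too short"])
    win = np.maximum(
        (sm.period_at(t) * p.moving_mean_periods * ch.fs).astype(int), 3
    )
    mm = moving_mean_local(x, win)
    d = x - mm
    s = np.sign(d)
    # carry the previous nonzero sign through exact zeros
    for i in range(1, s.size):
        if s[i] == 0:
            s[i] = s[i - 1]
    changes = np.flatnonzero(np.diff(s) != 0)
    events: list[tuple[float, str]] = []
    for i in changes:
        kind = "inh" if s[i + 1] > 0 else "exh"
        # sub-sample crossing time by linear interpolation of signal - mean
        if d[i + 1] != d[i]:
            tc = t[i] + (t[i + 1] - t[i]) * (-d[i]) / (d[i + 1] - d[i])
        else:
            tc = t[i + 1]
        events.append((float(tc), kind))

    # strict alternation: drop the earlier of two same-type neighbours
    repaired: list[tuple[float, str]] = []
    for ev in events:
        if repaired and repaired[-1][1] == ev[1]:
            repaired[-1] = ev
        else:
            repaired.append(ev)

    # pair breaths: inhalation, then exhalation, bounded by the next inhalation
    inh_t: list[float] = []
    exh_t: list[float] = []
    amps: list[float] = []
    i = 0
    while i < len(repaired):
        t_i, kind = repaired[i]
        if kind != "inh":
            i += 1
            continue
        if i + 1 >= len(repaired):
            break  # unmatched trailing inhalation
        t_e = repaired[i + 1][0]
        t_next = repaired[i + 2][0] if i + 2 < len(repaired) else t[-1]
        seg = (t >= t_i) & (t <= t_next)
        amp = float(np.ptp(x[seg])) if seg.any() else 0.0
        if amp >= p.min_amplitude:
            inh_t.append(t_i)
            exh_t.append(t_e)
            amps.append(amp)
        i += 2
    return BreathEvents(
        inhalation_onsets_s=np.asarray(inh_t),
        exhalation_onsets_s=np.asarray(exh_t),
        amplitudes=np.asarray(amps),
        notes=list(sm.notes),
    )


def breath_rate_series(
    ev: BreathEvents,
    span_s: float = 600.0,
    window_s: float = 120.0,
    p: RespParams | None = None,
) -> BreathRateResult:
    """Per-2-minute breath rates, 5-minute counts, and the <20 bpm QA gate.

    A breath is counted in the window containing its inhalation onset.
    The QA verdict fails when the session-mean rate reaches
    ``qa_max_bpm`` (20 breaths/min), mirroring the cleaning-stage
    inclusion rule for respiration data.
    """
    p = p or RespParams()
    edges = np.arange(0.0, span_s + 1e-9, window_s)
    counts, _ = np.histogram(ev.inhalation_onsets_s, bins=edges)
    rates = counts / (window_s / 60.0)
    first5 = int((ev.inhalation_onsets_s < 300.0).sum())
    last5 = int(
        ((ev.inhalation_onsets_s >= span_s - 300.0) & (ev.inhalation_onsets_s < span_s)).sum()
    )
    mean_rate = ev.n_breaths / (span_s / 60.0)
    return BreathRateResult(
        rates_bpm=rates,
        first5_count=first5,
        last5_count=last5,
        mean_rate_bpm=float(mean_rate),
        qa_pass=mean_rate < p.qa_max_bpm,
    )
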