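"""ECG cleaning, acceptability gating, R-peak detection, per-minute HR.

Cleaning follows a fixed chain: sanitation of non-finite samples, a 60 Hz
zero-phase IIR notch, a 0.5-45 Hz zero-phase Butterworth bandpass
(4th-order prototype applied forward-backward), then amplitude gating at
1500 device units with mask-and-interpolate repair.  Acceptability is
decided on baseline wander: the peak-to-peak excursion of the 0.5 Hz
low-pass baseline estimate of the sanitized signal must not exceed 1700
device units.  The device reports "mV" but the thresholds are treated as
raw device units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import maximum_filter1d, uniform_filter1d

from .io import Channel


class UnsupportedRateError(ValueError):
    """ECG sampling rate too low for the configured bandpass."""


@dataclass
class EcgParams:
    notch_hz: float = 60.0
    notch_q: float = 30.0
    bp_low_hz: float = 0.5
    bp_high_hz: float = 45.0
    bp_order: int = 4
    amp_threshold: float = 1500.0  # device units ("mV")
    wander_threshold: float = 1700.0  # device units, peak-to-peak
    refractory_s: float = 0.25
    rr_min_s: float = 0.25
    rr_max_s: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.bp_low_hz < self.bp_high_hz:
            raise ValueError("need 0 < bp_low < bp_high")
        if self.amp_threshold <= 0 or self.wander_threshold <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class CleanEcg:
    """Cleaned channel plus the amplitude-rejection mask."""

    channel: Channel
    mask: np.ndarray  # True where |value| exceeded amp_threshold
    masked_fraction: float
    acceptable: bool
    notes: list[str] = field(default_factory=list)


@dataclass
class RPeakSeries:
    """Detected R-peak times with physiologically gated RR intervals."""

    peak_times_s: np.ndarray
    rr_s: np.ndarray  # durations of retained intervals
    rr_mid_s: np.ndarray  # midpoints of retained intervals
    acceptable: bool = True
    notes: list[str] = field(default_factory=list)

    @property
    def n_peaks(self) -> int:
        return int(self.peak_times_s.size)


def sanitize(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop leading/trailing non-finite samples, interpolate interior ones.

    Returns (clean array, number of leading samples dropped).
    """
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise ValueError("channel contains no finite samples")
    first, last = np.flatnonzero(finite)[[0, -1]]
    x = x[first : last + 1].copy()
    bad = ~np.isfinite(x)
    if bad.any():
        idx = np.arange(x.size)
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return x, int(first)


def _bandpass_sos(fs: float, p: EcgParams) -> np.ndarray:
    return sps.butter(
        p.bp_order, [p.bp_low_hz, p.bp_high_hz], btype="bandpass", fs=fs, output="sos"
    )


def clean_ecg(ch: Channel, p: EcgParams | None = None) -> CleanEcg:
    """Sanitize, notch, bandpass and amplitude-gate one ECG channel.

    Samples whose filtered absolute value exceeds ``amp_threshold`` are
    masked and linearly interpolated so the time grid stays uniform.  If
    more than half the samples are masked the channel is marked
    unacceptable.
    """
    p = p or EcgParams()
    if ch.fs <= 90.0:
        raise UnsupportedRateError(
            f"fs={ch.fs} Hz too low; bandpass to {p.bp_high_hz} Hz needs fs > 90 Hz"
        )
    raw, n_lead = sanitize(ch.samples)
    b, a = sps.iirnotch(p.notch_hz, p.notch_q, fs=ch.fs)
    x = sps.filtfilt(b, a, raw)
    x = sps.sosfiltfilt(_bandpass_sos(ch.fs, p), x)

    # gate on either stage: the bandpass smears a short super-threshold
    # transient below threshold, but the sample is still artifactual
    mask = (np.abs(x) > p.amp_threshold) | (np.abs(raw) > p.amp_threshold)
    notes: list[str] = []
    if mask.any():
        idx = np.arange(x.size)
        if mask.all():
            x = np.zeros_like(x)
            notes.append("all samples exceeded the amplitude threshold")
        else:
            x = x.copy()
            x[mask] = np.interp(idx[mask], idx[~mask], x[~mask])
    frac = float(mask.mean()) if mask.size else 0.0
    acceptable = frac <= 0.5
    if not acceptable:
        notes.append(f"{frac:.0%} of samples amplitude-masked")
    out = replace(ch, samples=x, t0=ch.t0 + n_lead / ch.fs)
    return CleanEcg(out, mask, frac, acceptable, notes)


def baseline_wander(ch: Channel, p: EcgParams | None = None) -> float:
    """Peak-to-peak amplitude of the low-frequency baseline estimate.

    The baseline is the 0.5 Hz low-pass of the sanitized raw signal: the
    slow drift component rather than the QRS content.
    """
    p = p or EcgParams()
    x, _ = sanitize(ch.samples)
    if x.size == 0:
        raise ValueError("empty channel")
    if np.ptp(x) == 0:
        return 0.0
    sos = sps.butter(4, p.bp_low_hz, btype="lowpass", fs=ch.fs, output="sos")
    base = sps.sosfiltfilt(sos, x)
    return float(np.ptp(base))


def assess_ecg_acceptability(
    ch: Channel, p: EcgParams | None = None
) -> tuple[bool, float]:
    """Baseline-wander gate: unacceptable iff wander exceeds 1700 units."""
    p = p or EcgParams()
    wander = baseline_wander(ch, p)
    return wander <= p.wander_threshold, wander


def detect_r_peaks(ch: Channel, p: EcgParams | None = None) -> RPeakSeries:
    """Detect R-peaks on a cleaned ECG channel.

    A squared-derivative detection function smoothed over 100 ms is
    compared against an adaptive threshold (half the rolling 2 s maximum);
    candidate peaks respect a 250 ms refractory period and are refined to
    the local signal maximum within +-50 ms.  RR intervals outside
    [0.25 s, 3 s] are discarded: too-short intervals by removing the later
    peak, too-long ones by dropping the interval from the series.
    """
    p = p or EcgParams()
    x = np.asarray(ch.samples, dtype=float)
    fs = ch.fs
    if x.size < 2 or np.ptp(x) == 0:
        return RPeakSeries(
            np.empty(0), np.empty(0), np.empty(0), acceptable=False,
            notes=["no peaks detectable (flat or empty signal)"],
        )
    det = np.gradient(x) ** 2
    det = uniform_filter1d(det, max(int(round(0.1 * fs)), 1))
    # guard band: filter edge transients and truncated first/last beats
    # otherwise inflate the adaptive threshold and mask nearby beats
    guard = int(round(0.5 * fs))
    if x.size > 4 * guard:
        det[:guard] = 0.0
        det[-guard:] = 0.0
    thr = 0.5 * maximum_filter1d(det, max(int(round(2.0 * fs)), 3))
    cand, _ = sps.find_peaks(det, distance=max(int(round(p.refractory_s * fs)), 1))
    cand = cand[det[cand] >= thr[cand]]

    # refine to the local signal maximum (R apex) within +-50 ms
    half = max(int(round(0.05 * fs)), 1)
    peaks = []
    for i in cand:
        lo, hi = max(i - half, 0), min(i + half + 1, x.size)
        peaks.append(lo + int(np.argmax(x[lo:hi])))
    peaks = np.unique(peaks)

    # enforce refractory after refinement, keeping the larger peak
    keep: list[int] = []
    for i in peaks:
        if keep and (i - keep[-1]) < p.refractory_s * fs:
            if x[i] > x[keep[-1]]:
                keep[-1] = i
        else:
            keep.append(int(i))
    times = ch.t0 + np.asarray(keep, dtype=float) / fs

    # drop later peak of too-short RR pairs
    while times.size >= 2:
        rr = np.diff(times)
        short = np.flatnonzero(rr < p.rr_min_s)
        if short.size == 0:
            break
        times = np.delete(times, short[0] + 1)
    rr = np.diff(times)
    ok = (rr >= p.rr_min_s) & (rr <= p.rr_max_s)
    notes: list[str] = []
    if (~ok).any():
        notes.append(f"{int((~ok).sum())} RR intervals outside physiological range dropped")
    rr_keep = rr[ok]
    mid = (times[:-1] + rr / 2)[ok]

    acceptable = True
    if ch.duration >= 60.0 and times.size < 10:
        acceptable = False
        notes.append(f"only {times.size} peaks in {ch.duration:.0f} s")
    return RPeakSeries(times, rr_keep, mid, acceptable, notes)


def heart_rate_series(
    rp: RPeakSeries, span_s: float = 600.0, window_s: float = 60.0
) -> np.ndarray:
    """Per-minute heart rate: 60 / mean(RR) over intervals by midpoint.

    Ten 1-minute values for a 600 s session.  A trailing partial window is
    evaluated only if it spans at least 30 s; windows with fewer than two
    usable intervals are NaN.
    """
    n_full = int(span_s // window_s)
    rem = span_s - n_full * window_s
    n_win = n_full + (1 if rem >= 30.0 else 0)
    out = np.full(n_win, np.nan)
    for i in range(n_win):
        lo, hi = i * window_s, min((i + 1) * window_s, span_s)
        sel = (rp.rr_mid_s >= lo) & (rp.rr_mid_s < hi)
        if sel.sum() >= 2:
            out[i] = 60.0 / rp.rr_s[sel].mean()
    return out
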