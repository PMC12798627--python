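"""Heart-rate variability: Welch LF/HF band powers on the RR tachogram.

LF is tachogram power in 0.04-0.15 Hz, HF in 0.15-0.4 Hz (the shared
0.15 Hz edge is assigned to HF), and their ratio indexes sympathovagal
balance.  The tachogram is the RR-interval series placed at interval
midpoints, linearly interpolated to a uniform 4 Hz grid and linearly
detrended before Welch estimation (120 s Hann segments, 50% overlap).
Ratios are computed separately for the first and last 5 minutes of a
session.  A literal raw-waveform variant (band power of the ECG signal
itself) is provided for comparison but the tachogram is the default and
the analysis-facing quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .ecg import RPeakSeries
from .io import Channel


@dataclass
class HrvParams:
    lf_band: tuple[float, float] = (0.04, 0.15)
    hf_band: tuple[float, float] = (0.15, 0.4)
    tachogram_rate_hz: float = 4.0
    welch_segment_s: float = 120.0
    welch_overlap: float = 0.5
    min_intervals: int = 60

    def __post_init__(self) -> None:
        if self.tachogram_rate_hz <= 2 * self.hf_band[1]:
            raise ValueError("tachogram rate must exceed twice the HF upper edge")


@dataclass
class HrvSummary:
    """Band powers (s^2) and LF/HF ratio for one 5-minute segment."""

    lf_power: float
    hf_power: float
    lf_hf_ratio: float  # NaN when undefined
    segment: str
    missing: bool = False
    note: str = ""

    @property
    def ratio_defined(self) -> bool:
        return np.isfinite(self.lf_hf_ratio)


def _band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float],
                include_low: bool) -> float:
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi) if include_low else (freqs > lo) & (freqs <= hi)
    if sel.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[sel], freqs[sel]))


def _welch_lf_hf(x: np.ndarray, fs: float, p: HrvParams, segment: str) -> HrvSummary:
    x = sps.detrend(x, type="linear")
    nper = min(int(round(p.welch_segment_s * fs)), x.size)
    freqs, psd = sps.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nper,
        noverlap=int(round(nper * p.welch_overlap)),
        detrend=False,
    )
    # the shared 0.15 Hz boundary belongs to HF only
    sel_lf = (freqs >= p.lf_band[0]) & (freqs < p.lf_band[1])
    lf = float(np.trapezoid(psd[sel_lf], freqs[sel_lf])) if sel_lf.sum() >= 2 else 0.0
    hf = _band_power(freqs, psd, p.hf_band, include_low=True)
    if lf < 1e-12 and hf < 1e-12:
        return HrvSummary(lf, hf, np.nan, segment, note="near-zero variance tachogram")
    if hf <= 0:
        return HrvSummary(lf, hf, np.nan, segment, note="undefined ratio: HF power is zero")
    return HrvSummary(lf, hf, lf / hf, segment)


def lf_hf(
    rp: RPeakSeries,
    interval: tuple[float, float],
    p: HrvParams | None = None,
    segment: str = "segment",
) -> HrvSummary:
    """LF/HF ratio of the RR tachogram restricted to one time interval."""
    p = p or HrvParams()
    sel = (rp.rr_mid_s >= interval[0]) & (rp.rr_mid_s < interval[1])
    if sel.sum() < p.min_intervals:
        return HrvSummary(
            np.nan, np.nan, np.nan, segment, missing=True,
            note=f"only {int(sel.sum())} RR intervals in segment",
        )
    mids = rp.rr_mid_s[sel]
    rr = rp.rr_s[sel]
    grid = np.arange(mids[0], mids[-1], 1.0 / p.tachogram_rate_hz)
    tach = np.interp(grid, mids, rr)
    return _welch_lf_hf(tach, p.tachogram_rate_hz, p, segment)


def lf_hf_from_signal(
    ch: Channel,
    interval: tuple[float, float],
    p: HrvParams | None = None,
    segment: str = "segment",
) -> HrvSummary:
    """Literal variant: LF/HF band power of the raw waveform itself.

    Retained for comparison only; band power of a raw ECG waveform below
    0.4 Hz reflects baseline drift rather than beat-to-beat variability.
    """
    p = p or HrvParams()
    t = ch.times
    sel = (t >= interval[0]) & (t < interval[1])
    if sel.sum() < 16:
        return HrvSummary(np.nan, np.nan, np.nan, segment, missing=True)
    return _welch_lf_hf(ch.samples[sel], ch.fs, p, segment)


def hrv_first_last(
    rp: RPeakSeries, span_s: float = 600.0, p: HrvParams | None = None
) -> tuple[HrvSummary, HrvSummary]:
    """LF/HF for the first and last 5 minutes of the session."""
    p = p or HrvParams()
    if span_s < 300.0:
        return (
            HrvSummary(np.nan, np.nan, np.nan, "first_5min", missing=True,
                       note="session shorter than 5 minutes"),
            HrvSummary(np.nan, np.nan, np.nan, "last_5min", missing=True,
                       note="session shorter than 5 minutes"),
        )
    first = lf_hf(rp, (0.0, 300.0), p, segment="first_5min")
    if span_s < 600.0:
        # the last 5 minutes would overlap the first segment
        last = HrvSummary(np.nan, np.nan, np.nan, "last_5min", missing=True,
                          note=f"session spans {span_s:.0f} s < 600 s")
    else:
        last = lf_hf(rp, (span_s - 300.0, span_s), p, segment="last_5min")
    return first, last
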