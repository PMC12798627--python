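"""EDA cleaning guided by EMG motion artifacts, quality index, tonic level.

Motion artifacts are localized on the EMG channel: the z-scored EMG is cut
into sliding windows and a Local Outlier Factor over (value, first
difference) points flags windows with a high outlier proportion; flagged
windows are merged into artifact intervals.  The EDA channel is median
filtered (8 s kernel), low-passed at 5 Hz, and linearly interpolated
across the artifact intervals.  Signal quality is the proportion of
samples that are within 0.05-60 microsiemens and free of rate-of-change
violations beyond +-10 uS/s over any 1 s interval, mapped to a 0-100
quality index; channels scoring below 50 are rejected.  The tonic level
is a 0.05 Hz low-pass, averaged in non-overlapping 2-minute windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import median_filter
from sklearn.neighbors import LocalOutlierFactor

from .io import Channel
from .simulate import merge_intervals


@dataclass
class EdaParams:
    median_kernel_s: float = 8.0
    lowpass_hz: float = 5.0
    valid_range_us: tuple[float, float] = (0.05, 60.0)
    max_rate_us_per_s: float = 10.0
    rate_window_s: float = 1.0
    qi_reject_below: float = 50.0
    tonic_lowpass_hz: float = 0.05
    lof_window_s: float = 4.0
    lof_stride_s: float = 2.0
    lof_neighbors: int = 20
    lof_subwindow_s: float = 0.5
    lof_score_threshold: float = 4.0
    outlier_fraction_flag: float = 0.10

    def __post_init__(self) -> None:
        lo, hi = self.valid_range_us
        if lo >= hi:
            raise ValueError("valid range lower bound must be below upper bound")
        if not 0 <= self.qi_reject_below <= 100:
            raise ValueError("qi threshold must be in [0, 100]")


@dataclass
class ArtifactWindows:
    """Merged motion-artifact intervals on the session clock (seconds)."""

    intervals: list[tuple[float, float]] = field(default_factory=list)
    outlier_fractions: list[float] = field(default_factory=list)  # per flagged raw window
    notes: list[str] = field(default_factory=list)

    def total_duration(self) -> float:
        return sum(e - s for s, e in self.intervals)

    def coverage(self, span_s: float) -> float:
        return self.total_duration() / span_s if span_s > 0 else 0.0


def detect_motion_windows(
    emg: Channel | None, p: EdaParams | None = None
) -> ArtifactWindows:
    """Flag EMG windows whose LOF outlier proportion is high.

    The EMG is z-scored globally and summarized in short sub-windows
    (default 0.5 s) by amplitude features (RMS and maximum absolute first
    difference).  A Local Outlier Factor fit across all sub-windows of
    the recording scores each against the bulk of quiescent muscle
    activity; sub-windows scoring above ``lof_score_threshold`` mark
    their samples as outliers.  Motion bursts occupy a small fraction of
    a session, so their sub-windows sit in sparse regions of the feature
    space and receive large scores, while a fit restricted to a single
    burst-filled analysis window would see the burst as locally normal.
    Sliding analysis windows (4 s, stride 2 s) whose outlier-sample
    fraction exceeds ``outlier_fraction_flag`` are flagged and merged.
    """
    p = p or EdaParams()
    if emg is None:
        return ArtifactWindows(notes=["EMG absent; no artifact windows detected"])
    x = np.asarray(emg.samples, dtype=float)
    sd = x.std()
    if x.size < 8 or sd == 0:
        return ArtifactWindows(notes=["EMG constant or too short; no outliers definable"])
    z = (x - x.mean()) / sd
    fs = emg.fs

    nb = max(int(round(p.lof_subwindow_s * fs)), 2)
    nbin = z.size // nb
    if nbin < 3:
        return ArtifactWindows(notes=["EMG too short for outlier scoring"])
    seg = z[: nbin * nb].reshape(nbin, nb)
    feats = np.column_stack(
        [np.sqrt((seg**2).mean(axis=1)), np.abs(np.diff(seg, axis=1)).max(axis=1)]
    )
    fsd = feats.std(axis=0)
    fsd[fsd == 0] = 1.0
    feats = (feats - feats.mean(axis=0)) / fsd
    # the neighbourhood must exceed the plausible artifact budget (~10% of
    # the session), or a long burst forms its own dense LOF neighbourhood
    n_nb = min(max(p.lof_neighbors, int(0.1 * nbin)), nbin - 1)
    lof = LocalOutlierFactor(n_neighbors=n_nb)
    lof.fit(feats)
    scores = -lof.negative_outlier_factor_
    out_bins = scores > p.lof_score_threshold

    mask = np.zeros(z.size, dtype=bool)
    for i in np.flatnonzero(out_bins):
        mask[i * nb : (i + 1) * nb] = True

    w = min(int(round(p.lof_window_s * fs)), z.size)
    stride = max(int(round(p.lof_stride_s * fs)), 1)
    starts = list(range(0, z.size - w + 1, stride))
    if not starts:
        starts = [0]
    elif starts[-1] + w < z.size:  # cover the tail
        starts.append(z.size - w)

    flagged: list[tuple[float, float]] = []
    fracs: list[float] = []
    for s0 in starts:
        frac = float(mask[s0 : s0 + w].mean())
        if frac > p.outlier_fraction_flag:
            flagged.append((emg.t0 + s0 / fs, emg.t0 + (s0 + w) / fs))
            fracs.append(frac)
    return ArtifactWindows(intervals=merge_intervals(flagged), outlier_fractions=fracs)


@dataclass
class CleanEda:
    channel: Channel
    acceptable: bool
    artifact_coverage: float
    notes: list[str] = field(default_factory=list)


def clean_eda(
    eda: Channel, windows: ArtifactWindows | None = None, p: EdaParams | None = None
) -> CleanEda:
    """Median filter, low-pass, and interpolate across artifact windows.

    Artifact intervals are replaced by straight lines between the nearest
    clean boundary samples; intervals touching a channel edge are filled
    by extending the nearest clean value.  Channels with more than half
    their span contaminated are marked unacceptable.
    """
    p = p or EdaParams()
    windows = windows or ArtifactWindows()
    x = np.asarray(eda.samples, dtype=float).copy()
    fs = eda.fs
    notes = list(windows.notes)

    k = int(round(p.median_kernel_s * fs))
    k = max(k + (1 - k % 2), 1)  # force odd
    if k > 1 and x.size > k:
        x = median_filter(x, size=k, mode="nearest")
    if fs > 2 * p.lowpass_hz:
        sos = sps.butter(4, p.lowpass_hz, btype="lowpass", fs=fs, output="sos")
        x = sps.sosfiltfilt(sos, x)
    else:
        notes.append(f"low-pass skipped: fs={fs} Hz <= 2x{p.lowpass_hz} Hz cutoff")

    t = eda.times
    bad = np.zeros(x.size, dtype=bool)
    for s, e in windows.intervals:
        bad |= (t >= s) & (t <= e)
    coverage = float(bad.mean()) if bad.size else 0.0
    if bad.any() and not bad.all():
        idx = np.arange(x.size)
        x[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    acceptable = coverage <= 0.5
    if not acceptable:
        notes.append(f"artifact windows cover {coverage:.0%} of the channel")
    return CleanEda(replace(eda, samples=x), acceptable, coverage, notes)


def eda_quality_index(
    eda: Channel, p: EdaParams | None = None
) -> tuple[float, bool]:
    """Quality index 0-100 from range and rate-of-change violations.

    A sample violates if it lies outside the valid conductance range or if
    its maximum slope against any sample within +-1 s exceeds 10 uS/s.
    The index is 100 x (1 - violating fraction); below 50 the channel is
    rejected.  The slope rule is symmetric, so the index is invariant
    under time reversal.
    """
    p = p or EdaParams()
    x = np.asarray(eda.samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty EDA channel")
    lo, hi = p.valid_range_us
    bad = (x < lo) | (x > hi) | ~np.isfinite(x)

    max_lag = max(int(round(p.rate_window_s * eda.fs)), 1)
    for lag in range(1, min(max_lag, x.size - 1) + 1):
        limit = p.max_rate_us_per_s * lag / eda.fs
        v = np.abs(x[lag:] - x[:-lag]) > limit
        bad[: x.size - lag][v] = True
        bad[lag:][v] = True
    qi = 100.0 * (1.0 - float(bad.mean()))
    return qi, qi >= p.qi_reject_below


def tonic_series(
    eda: Channel,
    p: EdaParams | None = None,
    span_s: float = 600.0,
    window_s: float = 120.0,
) -> np.ndarray:
    """Mean tonic (0.05 Hz low-pass) level per non-overlapping 2-min window.

    Five values for a 600 s session; a trailing partial window is included
    only if it spans at least 60 s of data.
    """
    p = p or EdaParams()
    x = np.asarray(eda.samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty EDA channel")
    if eda.fs > 2 * p.tonic_lowpass_hz:
        sos = sps.butter(2, p.tonic_lowpass_hz, btype="lowpass", fs=eda.fs, output="sos")
        tonic = sps.sosfiltfilt(sos, x)
    else:
        tonic = x
    t = eda.times
    n_full = int(span_s // window_s)
    rem = span_s - n_full * window_s
    n_win = n_full + (1 if rem >= 60.0 else 0)
    out = np.full(n_win, np.nan)
    for i in range(n_win):
        sel = (t >= i * window_s) & (t < min((i + 1) * window_s, span_s))
        if sel.any():
            out[i] = tonic[sel].mean()
    return out
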