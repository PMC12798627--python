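# Methods

This note documents the models, parameter choices and numerical
decisions behind physiopipe, in the order the pipeline runs. Defaults
live in the per-module parameter dataclasses (`EcgParams`, `EdaParams`,
`RespParams`, `HrvParams`) and are exposed through `PipelineConfig`.

## Session model and windowing

A session is a set of independently sampled channels (ECG and EMG in
device "mV" units, EDA in μS, respiration in arbitrary impedance units)
plus `experience_start` / `experience_end` markers. All analysis
windows are defined on time relative to `experience_start` (t = 0), so
"first 2 minutes" means [0, 120) s for every modality regardless of
each stream's own clock. Timestamps are treated as authoritative; the
nominal sampling rate is used for filtering and resampling (no
clock-drift correction is attempted). The feature layout for a 600 s
session is fixed: five 2-minute breath rates, ten 1-minute heart rates,
five 2-minute tonic-EDA means, and LF/HF for the first and last
5 minutes, plus initial/change covariates (first window; last minus
first window). Missing values stay missing (empty TSV cells), because a
windowed mean of 0 is physiologically meaningful and must not collide
with missingness.

## ECG

Sanitation drops non-finite leading/trailing samples and linearly
interpolates interior ones, keeping a uniform grid for filtering. The
60 Hz notch is a second-order IIR with quality factor 30 and the
0.5–45 Hz bandpass a 4th-order Butterworth prototype; both run
forward-backward, so the effective bandpass order is 8 and the chain is
zero-phase (verified: zero cross-correlation lag against the input).
Zero phase matters because R-peak *times* feed both HR and HRV.

The 1500-unit amplitude gate masks a sample when it exceeds the
threshold either before or after filtering, then repairs it by linear
interpolation. Gating only after the bandpass would be vacuous for
short transients: an 80 Hz-bandwidth filter smears a single 2000-unit
impulse to roughly 300 units, so the pre-filter check is what actually
catches super-threshold artifacts, while the post-filter check catches
sustained saturation. Channels with more than half their samples masked
are unacceptable.

Baseline wander is the peak-to-peak amplitude of the 0.5 Hz low-pass of
the sanitized (pre-bandpass) signal — the low-frequency envelope the
term refers to, not the raw signal's peak-to-peak, which would be
dominated by QRS amplitude. The 1700-unit rejection threshold and the
1500-unit gate are device-specific magnitudes and are not converted to
SI volts.

R-peak detection squares the first derivative, smooths it over 100 ms,
and thresholds at half the rolling 2 s maximum with a 250 ms refractory
period; candidates are refined to the signal maximum within ±50 ms. The
first and last 0.5 s are excluded from the search: filter edge
transients and beats truncated by the recording boundary otherwise
inflate the adaptive threshold and mask real neighbouring beats. RR
intervals outside [0.25 s, 3 s] are discarded (short ones by removing
the later peak). On simulated sessions at default noise the detector
recovers 600 ± 1 peaks from a 60 bpm 10-minute record with timing error
under 5 ms, and per-minute HR within 1 bpm of truth. HR in a window is
60 / mean(RR) over intervals whose midpoints fall in the window, with
at least two intervals required.

## EDA and EMG-guided artifact repair

Motion artifacts are localized on the EMG channel. The EMG is z-scored
globally and summarized in 0.5 s sub-windows by two amplitude features
(RMS and maximum absolute first difference). A single Local Outlier
Factor model is fit across *all* sub-windows of the recording, and a
sub-window is an outlier when its LOF score exceeds 4. Two sizing rules
make this robust: the score threshold sits an order of magnitude below
the scores measured for gain-10 bursts (≥ ~40) and well above the
quiescent maximum (~3); and the neighbourhood size is at least 10% of
the sub-windows (minimum 20), so a long burst cannot form its own dense
LOF neighbourhood and score as normal. Fitting LOF inside each short
analysis window instead would make a window that a burst *fills* look
locally homogeneous and undetectable — the failure mode that drove this
design. Sliding 4 s windows (stride 2 s) with more than 10% outlier
samples are flagged and merged into artifact intervals.

EDA cleaning is median filter (8 s kernel, forced odd) → zero-phase
4th-order low-pass at 5 Hz → linear interpolation across artifact
intervals between the nearest clean samples (edge-touching intervals
extend the nearest clean value). Interpolation never leaves the range
spanned by the neighbouring clean data. Coverage above 50% of the
channel rejects it.

The quality index counts violating samples after cleaning: outside
0.05–60 μS, or with a maximum pairwise slope against any sample within
±1 s exceeding 10 μS/s. The pairwise-slope estimator is symmetric (the
index is invariant under time reversal) and treats a one-sample step of
a few μS as the rapid change it is, which a fixed 1 s-lag difference
would miss. `qi = 100·(1 − violating fraction)` — the linear mapping —
and channels with qi < 50 are rejected. The tonic component is a
0.05 Hz zero-phase low-pass (the conventional tonic/phasic boundary),
averaged over non-overlapping 2-minute windows; a trailing partial
window needs ≥ 60 s.

## Respiration

The chain is: zero-phase 2nd-order high-pass at 0.1 Hz → linear
resampling to 100 Hz → per-window period estimation → period-guided
moving-average smoothing → resampling back → normalization to unit
standard deviation.

Period estimation uses the FFT magnitude peak (Hann taper, parabolic
bin interpolation) in 0.05–1 Hz over 60 s windows with 15 s stride.
Three details are load-bearing for slow paced breathing (4-7-8: a 19 s
cycle, 1/19 ≈ 0.053 Hz):

- the window must be 60 s — a 30 s window has 0.033 Hz resolution and
  cannot separate the fundamental from its second harmonic;
- the magnitude spectrum is divided by the response of the already
  applied high-pass (|H|² for forward-backward filtering), because the
  0.1 Hz high-pass attenuates the 0.053 Hz fundamental ~14× while
  passing the 0.105 Hz harmonic, otherwise the harmonic wins the peak;
- a subharmonic check prefers f/2 or f/3 when that bin retains at least
  half the peak magnitude.

The smoothing kernel is **half** the estimated period: a moving average
of length T/2 has its first sinc null exactly at the 2nd harmonic 2/T,
cancelling the hold-phase bump of the 4-7-8 waveform that otherwise
produces two mean-crossings per cycle (double-counted breaths), while
only attenuating the fundamental by sinc(1/2) ≈ 0.64. Windows are
blended by overlap-add with triangular cross-fade. Flat windows fall
back to the previous window's period (first window: 4 s default) with a
QC note.

Breath onsets are crossings between the smoothed signal and its moving
mean (window = one local period, interpolated between estimation
windows), classified by slope direction, with sub-sample crossing times
by linear interpolation. Candidates are repaired to strict alternation
(the earlier of two same-type neighbours is dropped), paired as
inhale → exhale → next inhale, and breaths whose peak-to-trough
amplitude is below 0.25 (on the unit-SD signal — the raw impedance
units are arbitrary, so the threshold is defined on the normalized
scale and exposed in config) are deleted with their onsets. A breath is
counted in the 2-minute window containing its inhalation onset; the
QA gate fails a session whose mean rate reaches 20 breaths/min
(evaluated per session, not per window). Measured recovery at default
noise: per-window rates within 0.5 bpm of ground truth for both
protocols (20 seeds each), onset-time median error well under 0.5 s for
free breathing at 12–18 bpm.

## HRV

The RR tachogram (intervals at their midpoints) is linearly
interpolated to a uniform 4 Hz grid, linearly detrended, and fed to
Welch's method with 120 s Hann segments and 50% overlap — long enough
to resolve 0.04 Hz while giving ≥ 3 averages in a 5-minute segment.
Band powers are trapezoidal integrals; the shared 0.15 Hz edge belongs
to HF only (a deterministic assignment is required; which side it lands
on moves negligible power). At least 60 RR intervals are required per
segment; an HF power of zero flags the ratio undefined rather than
dividing. Spectral analysis of the RR tachogram — not of the raw ECG
waveform — is the standard definition of LF/HF; a literal raw-waveform
variant (`lf_hf_from_signal`, `PipelineConfig.hrv_source="raw"`) is
retained for comparison because sub-0.4 Hz power of a raw ECG trace
reflects baseline drift, not beat-to-beat variability.

## Statistics

Wilcoxon signed-rank: zero differences dropped, mid-ranks on |d|,
matched rank-biserial correlation (Σ positive ranks − Σ negative
ranks)/Σ ranks. For n ≤ 12 the two-sided p comes from enumerating all
2ⁿ sign assignments of the observed ranks (ties included naturally);
larger n uses the normal approximation with the rank-based variance
Σrᵢ²/4 (which absorbs tie corrections) and continuity correction.
Mann–Whitney U: mid-ranks, RBC = 2U/(n₁n₂) − 1, exact enumeration of
all C(n₁+n₂, n₁) labelings when n₁n₂ ≤ 100, otherwise the
tie-corrected normal approximation. Both exact paths match scipy's
exact distributions to 1e-12 in the tests and are checked against
independent brute-force oracles.

BH and Holm adjustments delegate to statsmodels within configurable
family labels (families follow the per-measure / per-comparison
grouping of the analysis battery).

The mixed rmANOVA is computed in two strata. Between-subject effects
(Tech, Stim, Tech × Stim; sum-to-zero coding, Type-III sums of squares
by model comparison) are fit on subject means and scaled by the number
of timepoints, with the subject residual as the error term. Within
effects (Time and its interactions with the between factors) are fit on
deviations from subject means, with residual error on
(N − cells)(k − 1) degrees of freedom. For balanced designs this
reproduces the textbook split-plot decomposition; it matches pingouin's
`rm_anova` and `mixed_anova` exactly (F, dfs, p, η²G, ε) on the
cross-check fixtures. Mauchly's W and the Greenhouse–Geisser ε are
computed from the pooled within-cell covariance projected onto an
orthonormal contrast basis; when Mauchly rejects (p < .05) and k > 2,
the GG-scaled dfs and p are reported (both corrected and uncorrected p
are always recorded; k = 2 forces ε = 1). Generalized η² uses
SS_effect / (SS_effect + SS_subject-error + SS_within-error), the form
appropriate when all design factors are manipulated. Type-III
differences are clamped at zero against floating-point cancellation,
and a zero error variance yields F = ∞ (p = 0) rather than garbage —
relevant for noise-free fixtures. Holm post-hocs are paired t-tests per
timepoint contrast (optionally within group levels) with paired
Cohen's d = mean(diff)/sd(diff).

## Synthetic sessions

The generator renders what the pipeline must recover, not biophysical
realism (no P/T waves, no respiratory sinus arrhythmia beyond the
configured RR modulation, no SCR deconvolution model):

- **Respiration**: 4-7-8 segments are smooth ramp/plateau cycles
  (half-cosine ramps) of exactly 4 + 7 + 8 s; free-breathing segments
  are sinusoids following a piecewise-linear rate trajectory. Ground
  truth records an inhalation onset at each cycle start whose 4 s
  inspiration completes within the session, and exhalation onsets at
  hold-end; the trailing partial cycle is rendered, so the truth and
  the waveform agree about every inspiratory event a detector can find.
  Breathwork sessions get a 60 s free-breathing lead-in before pacing,
  producing the early-to-late rate decrease; rain (free-breathing)
  sessions keep a flat trajectory.
- **ECG**: RRᵢ = 60/HR + Σₖ aₖ sin(2π fₖ tᵢ) accumulated from t = 0; a
  fixed 80 ms biphasic QRS-like template (amplitude 800 units, sharp
  apex for unambiguous peak timing) is placed at each R-peak time on a
  flat baseline. Default modulation puts tones in both LF (0.10 Hz,
  30 ms) and HF (0.30 Hz, 25 ms).
- **EDA/EMG**: tonic piecewise-linear trajectory (default 6 → 4 μS over
  the session) + Poisson SCRs (4/min, 0.3 μS, 1 s half-cosine rise,
  1.33 s-constant exponential decay) + Gaussian noise; EMG is white
  noise whose amplitude is multiplied by the configured gain inside
  artifact windows, which also receive spiky EDA contamination.
  Overlapping windows are merged.
- **Noise defaults** (ECG 20 units, EMG 10 units, EDA 0.01 μS, RESP
  5% of signal SD) are set so that clean simulations pass every QC gate
  — artifact windows are then the only contamination, which is what
  makes accept/reject tests sharp. Sampling rates default to 250 Hz
  (ECG, EMG), 32 Hz (EDA), 25 Hz (respiration).

Each modality draws from its own child generator of the configured
seed, so single-modality simulation reproduces the corresponding
channel of the full session bit-for-bit.

What passing tests show — and what they do not: the generator's
waveforms are stylized, so recovery results demonstrate the pipeline's
correctness (filters, detectors, window accounting, statistics) under
known truth, not its robustness to real-world morphology variation,
electrode drift, or coupled physiological rhythms.

## Problem sizes used in the checks

The acceptance checks run at the study's native scales: 10-minute
sessions, 20 seeded sessions per protocol for rate recovery, 50 seeds
for the QA gate, 20 subjects per Tech × Stim cell for the group design.
The test suite uses 100 replicates for the interaction power / tech-null
check and 200 for null calibration; `scripts/acceptance.py` uses 30 and
200 replicates respectively, sizes chosen to give stable percentages on
a single CPU. Group-study subjects draw resting breath rates from
N(15, 1.5²) bpm (clipped to 11–19) as between-subject heterogeneity.

## Known limitations

- XDF reading requires the optional `pyxdf` dependency; the CSV dialect
  is the fully exercised path.
- The rmANOVA's Type-III strata are exact for balanced and mildly
  unbalanced designs; heavily unbalanced cells rely on the effect-coded
  model comparisons and have no independent cross-check here.
- The breath detector's onset times are mean-crossing times, which lag
  the physical inspiration start by a fraction of the inhale ramp for
  strongly asymmetric cycles (≈ 2–4 s for 4-7-8); counts per window are
  unaffected except when a true onset falls within that lag of a window
  boundary (at most one count, 0.5 bpm).
- The quality index's pairwise-slope scan is O(n · fs) and assumes a
  uniform grid.
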