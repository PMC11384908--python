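# Methods

## Scope and data model

`lymphpump` analyzes three recording types from pressurized ex vivo
lymphatic vessels: inner-diameter traces (uniform grid, s / µm), membrane
potential (s / mV, ≥ 1 kHz), and ROS-reporter fluorescence (minute grid,
arbitrary units, ROI + background channels). Time is seconds internally
everywhere; contractions per minute appear only at reporting boundaries.
Protocol segments (baseline, drug, rescue, passive) tile the recording as
half-open `[start, end)` intervals; each segment has an analysis-window rule
(`full`, `last_5_min`, `last_2_min`, or a custom window). Drug and rescue
segments default to their last 5 min — the steady state of a slowly
equilibrating bath — and the default is recorded on the protocol object so
the choice is always explicit. Units are declared in file headers and never
inferred; TSV is canonical on disk and every writer emits a provenance
header (tool version, config hash, seed).

## Contraction detection

Candidate systolic troughs are prominent minima (`scipy.signal.find_peaks`)
of a centered moving average of the diameter trace; reported diameters are
always raw values at the located sample indices. Defaults, all configurable
and surfaced in provenance headers:

| parameter | default | rationale |
|---|---|---|
| smoothing window | 0.2 s | ~7 frames at 30 fps; well below a 1–2 s twitch |
| prominence | 5 µm | nominates candidates above video noise |
| minimum amplitude | 5 µm | movements ≤ 5 µm are residual, not contractions |
| minimum trough spacing | 1 s | below the shortest expected interval (~1.5 s in bursts) |
| EDD lookback | 2.5 s | the end-diastolic peak sits immediately before the fall |

The EDD of each trough is the smoothed-trace maximum in the preceding
interval (bounded by the previous trough and the lookback). When the
diastole is flat, the maximum is a plateau; the **last** plateau sample
(nearest the contraction) is taken, with the plateau tolerance set
adaptively to the estimated noise level (median-absolute-deviation of the
smoothing residual, scaled to the smoothed-trace noise). This tie-break
matters: with a hard argmax, selection among many noisy plateau samples
would bias EDD — and hence amplitude — upward by roughly two smoothed-noise
standard deviations. Ties between equal minima break to the earliest
sample. Windowed frequency counts every event whose trough falls in the
window, burst members individually; window membership is decided by trough
time, so no event can straddle a segment boundary. Burst labeling marks
maximal runs of ≥ 3 events with trough-to-trough intervals at or below a
threshold.

Known limitation: events closer together than the minimum trough spacing
(possible under the Poisson pattern's 0.37 s hard core, not under regular or
bursting defaults) are merged, undercounting absolute frequency by a few
percent in such traces; baseline-normalized ratios are essentially
unaffected because the undercount applies to numerator and denominator
alike.

## Contractile-function statistics

Per-contraction amplitude, normalized amplitude, and ejection fraction are
exact formula applications; window statistics are unweighted means of
per-event values (parameters are computed contraction by contraction, then
averaged), and FPF is the window's mean EF times its frequency. A window
with zero events reports frequency 0, FPF 0, and **absent** amplitude/EF
fields — zero would understate a vessel that still contracts strongly but
rarely. An EDD slightly above D_MAX warns rather than errors, since noise
can push the diastolic peak past the passive estimate. D_MAX is the mean
diameter over the final 60 s of the passive (Ca²⁺-free) segment, discarding
equilibration; a passive segment in which the detector still finds
contractions is rejected. Reported values round half-up to 1 decimal (cpm,
%, µm, mV) or 3 decimals (EF); normalization to baseline is computed at full
precision and rounded only at output.

The baseline average feeding frequency normalization is the mean of
per-minute frequencies over the full baseline window (equivalently the
overall rate when the window is whole minutes). Amplitude normalization can
divide raw means or D_MAX-normalized means; applied consistently the two
coincide, so the `amp_norm_mode` flag documents the choice without changing
results.

## Membrane potential

Traces are corrected for the electrode offset read at retraction before any
analysis (refusing to proceed if no offset was recorded). AP detection
requires a dV/dt excursion above 1 V/s — separating regenerative upstrokes
from slow diastolic depolarization — followed within 0.2 s by a peak at
least 20 mV above the trace-median resting estimate, with a 2 ms refractory
against duplicate crossings; dV/dt is evaluated on a ~2 ms smoothed copy so
single-sample noise does not fire the threshold. Resting V_m over a window
is the median of samples at least 0.15 s away from every AP peak, which
makes the estimate insensitive to spike count (verified by spike-deletion).

## ROS fluorescence

Background is subtracted point-wise on a shared time grid; negative
corrected values are kept (clipping would bias ΔF) and flagged. ΔF(x) =
F(x) − F(0) on the acquisition grid, so ΔF(0) is exactly 0 and ΔF is
invariant to any constant added to both channels. Group summaries are
per-time mean ± SD across vessels; inference is delegated to the stats
module. Image handling is limited to rectangular-ROI means of a frame
stack.

## Group statistics

Group comparisons report means ± SD and use paired t-tests (two paired
conditions), one-way ANOVA with Tukey HSD among all groups, or Dunnett's
test against a declared control, at α = 0.05. Two identical paired samples
define p = 1 (the t statistic is 0/0 otherwise). Any group with fewer than
five vessels is excluded from inference and reported descriptively with a
`not tested (n < 5)` flag. No correction is applied across separate
experiments beyond the chosen post hoc procedure.

## Synthetic data

The generator defines the study conditions under which the pipeline is
validated. Defaults emulate a typical wild-type popliteal vessel at 37 °C
and 3 cmH₂O: baseline EDD 95 µm, amplitude 40 µm (41 % of D_MAX = 97.5 µm),
11 cpm, 30 samples/s, 1 µm additive Gaussian diameter noise (2 µm in the
robustness checks). Patterns: `regular` (exact spacing), `poisson`
(hard-core shifted-exponential intervals whose mean preserves the requested
rate), and `bursting` (clusters of 3–8 contractions at 1.5 s spacing with
pauses sized to preserve the requested mean cpm counting every member).
Segment effects scale frequency and/or amplitude per protocol segment —
e.g. `(drug, 0.22, 1.0)` for frequency-selective suppression; passive
segments sit at D_MAX with no events.

Each twitch is an asymmetric transient parameterized by a half-width
(default 0.9 s): a half-cosine fall lasting one third of the half-width,
then a recovery that mirrors the fall for half a fall-time (making the
trough locally symmetric, so a centered moving average attains its minimum
exactly at the trough sample) before a slower raised cosine returns to
baseline — exactly, with zero slope — within `2·halfwidth − fall`. A purely
exponential recovery was rejected: its maximal slope at the trough biases
smoothed trough localization, and it never exactly reaches baseline, which
would break the exact pipeline-closure property on noise-free traces.
Event times snap to the sample grid; configurations whose events cannot be
rendered distinctly (inter-trough gaps below fall time plus two samples)
are rejected with a clear message. In bursts the realized EDD is the
partially recovered diameter at fall start and is recorded as such in the
ground truth.

Membrane-potential traces fire one AP per contraction, at the contraction
time, from the same seed stream as the diameter generator — the 1:1
pacemaker coupling by construction. Resting V_m (−45 mV), AP peak (+5 mV),
rise/fall times (15/60 ms), and the +3 mV depolarization of suppressed
segments are conventions chosen for plausibility; no numeric values exist
to emulate. Fluorescence series are linear ramps (default 2 a.u./min over
15 min at 1 min intervals) on a constant background, each channel carrying
independent Gaussian noise.

What the generator does **not** emulate: diameter drift and slow tone
changes (a linear drift flag exists but defaults to 0), frequency
adaptation within a segment, pressure–diameter mechanics, AP waveform
diversity, photobleaching, and any ionic pacemaker mechanism. Passing tests
therefore demonstrate correctness of the detection and statistics under
realistic noise and event statistics, not robustness to every artifact of
real recordings.

## Problem sizes and determinism

Validation uses 5 min traces at 30 fps for detector checks (grid of
2–16 cpm × 10–50 µm), 100 seeds for noise-robustness and
sampling-distribution checks, and 8 simulated vessels through a 40 min
baseline/drug/rescue protocol for the end-to-end phenotype check. All
randomness derives from explicit integer seeds via `numpy` seed sequences;
identical configuration and seed give bit-identical traces.
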