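# Methods

This note documents the models, conventions and numerical choices behind
`tripecg`: what the pipeline computes, what the synthetic generator
emulates, which constants are open by nature and how they were fixed, and
what validation on synthetic data does and does not establish.

## Analysis pipeline

**Composite channel and R-peak detection.**  Detection runs on the
per-sample root-sum-of-squares of the 12 leads (each lead median-centred
first) — the same construction as the vector magnitude used later for
delineation, applied at the record level.  This makes detection invariant
to any single lead's polarity or gain.  The detector band-passes the
composite at 5–25 Hz (2nd-order zero-phase Butterworth), squares it, and
thresholds at 0.4 × a rolling 2-s maximum with a 200-ms refractory period;
every detection is then refined to the local maximum of the raw composite
within ±50 ms.  No published constant exists for this stage; the constants
live in `DetectorConfig` and are validated by the requirement that
detections match generator truth within ±2 ms on clean and ±5 ms on noisy
(20 µV broadband) records.

**Beat classification.**  Beats whose full 1.2-s representative window does
not fit the record — or intersects a junction exclusion zone in TCM — are
labelled `artifact`.  The remaining beats are correlated (best lag within
±10 ms) against a deterministic two-pass template: the sample-wise median
of all usable beats of the composite in a ±150 ms window around R.  A beat
is `pvc` when its correlation falls below 0.90, or when it is premature
(RR < 0.80 × the median RR) and its correlation is below 0.95.  These two
thresholds are design constants (`DetectorConfig`), validated only against
the generator's injected PVCs; no claim is made about agreement with any
clinical PVC detector.  The sinus RR series drops gaps exceeding 1.75 × the
median gap, which removes junction-crossing pairs in concatenated records.

**Representative beat.**  The per-lead median over all contributing sinus
beats, aligned on the detected R-peak sample (no sub-sample interpolation:
at 1000 Hz the alignment error is ≤ 0.5 ms, below every tolerance used).
The R peak sits at 400 ms of the 1200-ms window — 400 pre-R / 800 post-R
places both P and T inside the window at sinus rates.  All 12 leads share
one global set of contributing beats, keeping the superimposed beat
time-consistent across leads.  A per-lead baseline (window median) is
subtracted; the window median is a robust isoelectric estimate because the
waves occupy well under half the window, and it removes the residual DC
that baseline wander leaves after beat averaging.  With an even number of
beats the median is the mean of the two central values.

**Fiducials.**  One global set of marks is placed on the vector magnitude,
lightly smoothed with an 8-ms boxcar (reduces sample-level noise ~2.8× while
blurring the steep QRS edges by under 1 ms).  The baseline level is the
median of the smoothed VM over an 80-ms window ending 300 ms before R
(TP/PR territory at the supported PR range).  Each mark is a threshold
crossing at `baseline + fraction × (local peak − baseline)`:

| mark       | fraction | scan                                   | sustain |
|------------|----------|----------------------------------------|---------|
| QRS onset  | 0.04 of R peak | backward from R in [−120, 0] ms  | 10 ms   |
| QRS offset | 0.04 of R peak | forward from R in [0, 200] ms    | 10 ms   |
| T offset   | 0.03 of T peak | forward from the T peak          | 20 ms   |
| P onset    | 0.04 of P peak | backward from the P peak         | 10 ms   |

The T-peak search upper bound (550 ms post-R) scales with √(RR/1000), a
Bazett-like bracket that follows repolarization at slow and fast rates; the
P search window is [−350, −40] ms.  "Sustained" means the VM must stay on
the far side of the threshold for the stated duration — this suppresses
noise chatter and, on the onset side, the narrow pinch the VM can show
between the Q and R lobes where opposite-polarity deflections partially
cancel across leads.  The fractions are genuinely open constants (the
threshold principle, not its values, is what defines the method); they were
fixed once so that mark-recovery errors on the synthetic battery stay
within ±4 ms (QRS marks) and ±6 ms (P onset, T offset) under 20 µV
broadband noise, and they live in `ThresholdConfig`.  A VM whose peak is
below 5× the baseline estimate is rejected as degenerate.  A P (or T) peak
below 25 µV (40 µV) above baseline is treated as absent: P onset becomes
`None` (PR unavailable), a missing T offset makes QT unavailable with a
warning.  Manual overrides replace marks atomically — an edit set that
violates the ordering `p_onset < qrs_onset < qrs_offset < t_offset` is
refused in full — and edited marks are tagged `manual`.

**Measurements.**  PR = QRS onset − P onset; QRS = offset − onset;
QT = T offset − QRS onset; HR = 60000/RR̄ with RR̄ the mean sinus RR.
QTc uses RR̄ in seconds: Fridericia divides by its cube root, Bazett by its
square root.  Per-lead amplitudes are referenced to an isoelectric baseline
estimated as the median of the representative signal over the late PR
segment ([onset − 45, onset − 5) ms); referencing to the value at the onset
sample is available as an option but is sensitive to the onset mark landing
a couple of ms inside the Q lobe.  Sokolow–Lyon uses baseline-referenced
peak amplitudes (S in V1 plus R in V5/V6); the low-voltage rule uses
within-QRS peak-to-peak, with ≤ 500 µV (frontal) / ≤ 1000 µV (precordial)
boundaries inclusive.  Machine outputs keep full precision; display
rounding is 1 ms for intervals, 0.1 ms for QTc, 1 µV for voltages, halves
away from zero.

**Triplicate strategies.**  TCM concatenates the three records in
acquisition order after per-segment, per-lead median subtraction (baseline
alignment), then excludes every beat whose window intersects junction
± 600 ms — one representative-window length, so no pooled beat can straddle
a join.  Junction handling is beat-level exclusion rather than signal
surgery: deterministic and directly testable.  The median beat pools all
accepted sinus beats across segments, and one pooled RR̄ (junction-crossing
pairs excluded) feeds HR and QTc.  TAM analyzes each record independently
and aggregates by the arithmetic mean (median available); the low-voltage
flag aggregates by majority.  TAM's HR is recomputed as 60000 / (mean RR̄)
so the HR–RR identity holds for the aggregate as well.

## Synthetic generator

Beats are sums of Gaussian lobes — one per wave (P, Q, R, S, T), with
per-lead amplitudes and shared timing; the T lobe is asymmetric
(upstroke σ twice the downstroke σ), echoing the slower rise of real
repolarization.  This is a deliberate trade: analytic ground truth over
morphological realism, because every acceptance tolerance needs exact truth.

**Truth convention.**  A lobe's labelled onset/offset is the point where it
reaches ~3.5% of its peak (2.590 σ from center) — the outermost cutoff that
still keeps ≥ 99% of the lobe's mass inside its labelled segment.  Lobe
centers are then solved so the requested intervals are exact: QRS onset at
−0.42·QRS relative to R (offset at +0.58·QRS), with the Q and S lobes
pinned so their outer support edges land exactly on the requested
onset/offset; P onset = QRS onset − PR; T offset = QRS onset + QT.  A
tail-point convention much deeper than this (e.g. 1% of peak) is not
recoverable by any threshold method once the vector magnitude carries a
rectified noise floor (~25–30 µV at 20 µV broadband per lead after beat
averaging), which is why the 2.59 σ point is the defined truth.

Default amplitudes follow textbook morphology (negative main deflection in
aVR, deep S in V1–V2, tall R in V4–V6, Q = −0.18·R); defaults for σ are
Q 2.5, S 3.0, P 8, T downstroke 15 ms, and the R lobe width scales with the
requested QRS so its tails at the QRS edges stay below ~1% of its peak.
Requested intervals must satisfy 80 ≤ PR ≤ 400, 50 ≤ QRS ≤ 250, QT > QRS,
plus a geometric feasibility check for the T lobe.

**Beat train and noise.**  The first R peak is fixed at 500 ms; successive
RR intervals are Normal(RR̄, jitter SD) truncated at ±3 SD; R times are
quantized to the sample grid and those quantized times are the truth.
Noise adds per-lead sinusoidal baseline wander (default 0.3 Hz) and mains
interference (50 Hz) with random phases, plus white broadband noise.  One
explicit random stream per call (RR draws before noise draws) makes every
record bit-reproducible from its seed.  PVCs are interpolated: a single
broad lobe (support = the requested widened QRS) with an inverted,
amplified copy of the template's R pattern and no P/T, inserted without
moving any sinus beat — so sinus truth intervals and RRs are untouched, and
an injection overlapping an existing beat window is refused.

**What the generator does not emulate** — and what passing tests therefore
do not show: respiratory modulation, T-wave alternans, atrial arrhythmia,
pacing, electrode motion artifacts, biphasic or notched waves, U waves, and
real inter-lead timing dispersion.  Agreement with generator truth bounds
the pipeline's numerical behaviour; it is not a clinical validation, and no
numeric agreement with any commercial delineator is claimed.

**Systematic offsets.**  A threshold crossing sits where the signal is a
few percent of the local peak, slightly inside the 2.59 σ truth point, so
each mark carries a small stable offset (about +2.5 ms QRS onset, +0.6 ms
QRS offset, −2 ms T offset, +3.5 ms P onset at default constants), giving
QT a ≈ −4.5 ms offset.  The offsets are template- and noise-stable (the
recovery-error SDs are < 1 ms), so they cancel in every comparison of two
arms that share the convention — which is exactly the setting the
agreement suite addresses.

## Agreement statistics

Differences are oriented (first-named arm − second-named arm).  Bias is the
mean difference; SD uses the n−1 denominator; LOA = bias ± 1.96·SD;
RC = 1.96 × SD of paired within-method differences.  (When the two arms
are distinct readers, some authors scale the repeatability coefficient by
√2 to convert a between-arm SD into a within-arm equivalent; this package
implements the plain 1.96·SD definition throughout.)  Proportional bias is
the OLS slope of differences on pair means with a two-sided t test, skipped
and flagged when the differences are constant.

ICC(2,1) comes from the two-way ANOVA mean squares (subjects × raters):
`(MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE))`, with the F-based
confidence interval of the absolute-agreement single-measure form using
Satterthwaite denominator degrees of freedom; when that df becomes so small
that the F quantile diverges, the interval bound takes its analytic limit.
A zero-variance table has no defined ICC and is reported as such.

The clustered Bland–Altman variant decomposes difference variance into
between-subject, between-timepoint and residual components by the method of
moments (subject means vs pooled within-subject variance, harmonic-mean
cluster sizes for unbalanced data, negative estimates truncated at zero);
the LOA use the square root of the summed components.  Method of moments
was chosen over REML deliberately: it is closed-form, dependency-free and
deterministic, at the price of some efficiency on small unbalanced designs
— the simulation test accepts the components within 30% at 30 subjects × 4
pairs.

TOST non-inferiority on paired differences uses the 90% CI
(mean ± t(0.95, n−1)·SE) with a ±5 ms margin and the additional requirement
that the CI upper bound stay below 10 ms; both one-sided p-values are
reported, and a zero-SD sample collapses the CI to the point value with a
flag.  Benjamini–Hochberg adjustment is the standard step-up with enforced
monotonicity, capped at 1.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to run in
minutes on one CPU while keeping the Monte-Carlo error well below every
tolerance they assert: 50 randomized templates for interval recovery
(recovery-error SDs have ~10% relative precision at that size), 100 noisy
triplicates for the TAM–TCM comparison, 60 subjects for the simulated
two-reader study, 1200 random tables for the ICC oracle grid.  All
randomness flows from explicit seeds (`numpy` `SeedSequence` children), so
every reported number is bit-reproducible.

## Known limitations

* The delineator is tuned for sinus rhythm at 50–110 bpm with the window
  geometry above; atrial flutter/fibrillation, paced rhythms and extreme
  bradycardia are out of scope by design.
* Global fiducials mean no per-lead QT dispersion; the T-end is
  threshold-based, not tangent-based.
* The clustered Bland–Altman is a moment approximation, not a full
  mixed-effects fit.
* CSV (with a JSON metadata sidecar) is the only on-disk format; clinical
  exchange formats (DICOM-ECG, HL7 aECG, SCP-ECG) are not parsed.
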