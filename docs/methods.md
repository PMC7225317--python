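# Methods

## Signal model and measurement chain

Pulse transit time is measured per beat, from the R-wave midpoint on the
ECG to the point where the following plethysmograph upstroke first crosses
half of its amplitude (foot + 0.5·(peak − foot), located by linear
interpolation between samples).  Because the pleth upstroke in the
synthesizer is a raised cosine, its half-maximum sits exactly at the
upstroke midpoint, which pins the planted transit time to sub-sample
accuracy and makes the synthesize→extract round trip a strict test.

The beat-domain series feeds two derived channels:

* **PTT2** (arousal channel): the beat series is linearly interpolated onto
  a uniform 5 Hz grid and smoothed with a centered 17-point moving mean
  (span ≈ 3.4 s).  5 Hz is chosen so that 17 points reproduce the intended
  ~3.5 s window; beat-domain averaging is rejected because the window
  duration would then vary with heart rate.  Grid samples bridging invalid
  beats are masked, as are smoothing windows truncated at the edges or more
  than half masked.
* **Swing channel**: the beat series is interpolated at 1 Hz and smoothed
  with a centered 3-sample moving mean (shrinking to 2-sample means at the
  edges).  "Interpolated for 1 s" is read as 1 Hz sampling, not a 1 s
  kernel.

## Arousal detection

A PTT arousal is a drop of ≥ 15 ms in PTT2 completed within 5–45 s, with
both endpoints inside the 150–500 ms validity range and the whole interval
artifact-free.  Two numerical choices matter:

* **Transition compensation.** A boxcar of N samples widens every
  transition by (N−1) sample periods, so a raw fall of 2 s appears as a
  ≈5.2 s fall on PTT2.  The duration gate is therefore applied to the
  maximum-to-minimum time minus the smoothing span (3.2 s at the
  defaults); without this, the 5 s lower gate would be unreachable by
  construction.  Plateau maxima are located at their falling edge and
  minima at their leading edge for the same reason.
* **Greedy scan with hysteresis.** Local extrema are scanned left to
  right; the first maximum with a qualifying minimum starts an event, and
  the event end then extends to the lowest minimum reached before the
  channel recovers by the drop threshold above it.  Without the extension,
  a single slow 30 ms drop with breathing ripple superimposed is counted
  once per ripple cycle.  Scanning resumes past the accepted minimum.
  The drop is measured max-to-min (not baseline-to-min).

The arousal index divides the event count by **artifact-free** PTT hours,
not elapsed hours: artifact spans are excluded everywhere else in the
protocol, and an elapsed-hours denominator would make the index depend on
how much artifact a child happened to accumulate.

## Artifact rules

On the 5 Hz raw channel a sample is artifactual when the sample-to-sample
jump exceeds 50 ms or the value leaves 150–500 ms (sensor dropout rails the
channel out of range).  Spans are padded by 2 s per side — spikes corrupt
the smoothed channel beyond their own samples — and merged.  Records with
< 3 h artifact-free PTT are excluded from the PTT analysis; < 4 h
artifact-free oximetry excludes the study entirely.

## Respiratory swing

Alternating local minima (inspiratory troughs) and maxima (expiratory
peaks) of the swing channel are found with a 1 ms prominence floor
(suppressing numerical jitter); same-type runs keep the more extreme
member; pairs inside or spanning an artifact interval are discarded.  The
swing is the mean (peak − immediately preceding trough).  A channel with
no pairs raises; the record-level composition maps that to a swing of
0 ms, which is the honest value for a flat channel.

## Oximetry

Baseline saturation is the median of the artifact-free trace — the
whole-night median is robust to the dips themselves and reproducible;
rolling baselines are out of scope.  A desaturation is a maximal
artifact-free span strictly more than 4 points below baseline lasting
> 5 s and < 180 s.  SpO2 artifact is dropout, values below 50%, or changes
faster than 4%/s.  The four-way risk category is applied with precedence
high-risk (min < 80, dip index > 4/h, baseline < 94) → abnormal low-risk
(min ≤ 90) → normal (baseline > 94 and dip index < 4/h) → inconclusive.
The published table's "or" layout is not machine-readable; this
reconstruction is the one that makes the four categories exhaustive,
mutually exclusive, and monotone as the minimum saturation falls (the
low-risk tier absorbs min < 80 when the full high-risk conjunction fails).
"Abnormal" anywhere means either abnormal tier.

## Study classification

With abnormal oximetry: ≥ 1 arousal-linked obstructive episode on video is
OSA (the OSA definition states no count; one episode with abnormal
oximetry suffices); none is "abnormal other".  With normal/inconclusive
oximetry: ≥ 3 arousal-linked episodes is UARS (three episodes, not three
clusters); any snoring or lesser obstruction is primary snoring; otherwise
normal.  Unspecified corners (no snoring with 1–2 episodes; ≥ 3
non-arousal-linked episodes) map to primary snoring.  Video scoring itself
is upstream: annotations are inputs.

## Threshold evaluation

ROC candidate thresholds are midpoints between consecutive sorted unique
values plus ±∞; a positive call is value ≥ threshold, so no observation can
sit exactly on a threshold.  Three operating points are reported: the
largest threshold with sensitivity ≥ 0.90, the smallest with specificity
≥ 0.90, and the maximizer of sensitivity + specificity (ties to the higher
specificity, then the higher threshold).  The 50/50 train/test split is
uniform and unstratified, with odd cohorts favouring training.  Bootstrap
CIs use whole-sample case resampling, 2000 replicates by default,
percentile method; resamples that lose a class are redrawn.  Chi-square is
Pearson without continuity correction (expected counts in the use cases
are large, so the choice is immaterial but documented for
bit-reproducibility).  Rates in printed reports are rounded to 2 dp.

## Synthetic cohort

The generator emulates the study conditions: ~35% UARS/OSA (category mix
0.25/0.40/0.24/0.11), 8 h studies (±15% per child), PTT baseline
N(300, 30) ms, sleeping heart period 0.6–0.75 s, breath period
3.45–3.55 s, beat measurement noise 2 ms, slow ±5 ms baseline drift,
arousal rates 8/h (normal/snoring) vs 25/h (UARS/OSA) with drops of
18–30 ms over 8–25 s, desaturation rates 0.5–8/h with depths that place
normal/snoring/UARS children above 90% minimum saturation and OSA children
in the abnormal tiers (30% of OSA children get the high-risk flavour:
baseline 93%, dips below 80%), artifact spikes 3/h railing the channel
above 500 ms for 1–3 beats, and SpO2 dropouts 0.3/h.

Swing targets are N(12, 3) ms for normal/snoring vs N(22, 4) ms for
UARS/OSA, expressed on the scale of the *measured* statistic: the planted
modulation is pre-compensated by the known gain of the 1 Hz + 3-sample
chain, (1 + 2cos(2π/T))/3 at breath period T, times an empirical 0.785
discretization factor measured once on noiseless sinusoids.  This puts
cohort swing values and selected thresholds on the scale the clinical
protocol uses (cut-offs near 16–18 ms).  The breath period is held near
3.5 s because the two smoothing chains (3-sample at 1 Hz; 17-point at
5 Hz) have nearly identical spans: only near 3.5 s is the arousal
channel's residual breathing ripple (gain ≈ 0.03) small relative to the
swing channel's (gain ≈ 0.19), keeping breathing from crossing the 15 ms
arousal threshold even at the largest planted swings.  A wider 3–5 s
spread would also make the chain gain vary ~2× between children and
destroy the planted-vs-computed swing ordering.  The per-child baseline is
clipped so every planted excursion stays inside the 150–500 ms validity
window.

What the generator does **not** emulate: REM-related artifact bursts and
heart-rate surges, movement artifact correlated with obstructive events,
periodic breathing, oximeter averaging-time effects, or irregular
non-sinusoidal effort waveforms.  Passing recovery tests therefore shows
the rules are implemented faithfully and are mutually consistent at
realistic signal scales — not that the thresholds would transfer to real
recordings.

## Problem sizes and defaults

Cohort-scale tests use 368 children (the reference cohort's PTT sample
size) at 8 h studies; repeated-run checks (100 seeds) generate the PTT
channel only, which is the one the checked statistic uses.  Bootstrap
coverage is assessed over 500 simulated cohorts of 130 positives/negatives
at 400 replicates each.  All randomness flows from explicit integer seeds
through `numpy.random.SeedSequence` spawning, so cohorts are reproducible
child-by-child.

## Known limitations

* The R-peak detector (block-wise 60% of the 99th-percentile amplitude,
  0.25 s refractory) is adequate for clean or synthetic ECG only; it is a
  pluggable stage, not a clinical QRS detector.
* EDF reading goes through `mne` and is untested here; CSV/JSON are the
  tested interfaces.
* The swing statistic's gain depends on breath period; two children with
  identical effort but different respiratory rates measure differently.
  This is a property of the published measurement definition, inherited
  deliberately.
* Bootstrap CIs are percentile intervals; no BCa correction.
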