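# Methods

This note documents the models, numerical choices and limitations behind
`rhythmtag`, in the spirit of a package methods appendix: what is assumed,
what is configurable, and what passing tests do and do not establish.

## Stimulus grammar

A measure is 3000 ms with beats at 0, 750, 1500 and 2250 ms; the fourth
beat is acoustically silent. All measures start with a note at 0 ms and
end with a note at 1875 ms (375 ms after beat 3), so every measure shares
the 1125 ms silent period in which visual targets appear.

High-metricality inter-onset intervals are drawn from {1, 2, 4, 6} × 187.5 ms
with the additional constraints that onset prefix sums pass through 750
and 1500 ms (beats 2–3 acoustically marked) and sum to 1875 ms.
Low-metricality intervals are {7, 24, 38, 60} × 18.75 ms. The printed
forms of these ratios (1:3.43:5.43:8.57) are decimal roundings of
7:24:38:60 over 7; the exact rational form is the only one for which the
intervals can sum to exactly 1875 ms and the silent period to exactly
1125 ms (= 60 ticks), so the package uses it throughout and reports
derived offsets (e.g. 56.25 ms) at full precision.

Two consequences of this arithmetic are load-bearing:

- A high-metricality measure can only have 4, 6 or 8 onsets if a paired
  low-metricality measure with the same onset count is to exist: the
  low-metricality multisets summing to 100 ticks are unique per onset
  count ({38,38,24}, {38,24,24,7,7}, {24,24,24,7,7,7,7}) and no multiset
  with 5 or 7 onsets exists. `compose_measure` therefore samples the
  onset count from {4, 6, 8} per measure id, then samples uniformly among
  the valid interval orders.
- No prefix sum of {7, 24, 38} ticks can equal 40 or 80 ticks (750 or
  1500 ms), so interior low-metricality onsets can never land on the beat
  grid; the constrained shuffle always succeeds on the first try.

Compositions are exemplars of this constraint system, seeded and
reproducible; they are not transcriptions of any particular score.

Targets occupy at most one measure in two (90 of 180 in sound phases, 30
of 60 slots in the 3 min silence phases), 30 (or 10) per position class,
with offsets per participant group: group 1 sees symmetric metrical
(±187.5 ms) and nonmetrical offsets (group 1a the nearer ±131.25 ms,
group 1b the farther ±243.75 ms); group 2 sees one-sided metrical offsets
(2a early, 2b late) flanked by both nonmetrical neighbors. Counterbalance
enumeration nests metricality in regularity and vice versa with all
superordinate and (independently chosen) nested level orders, yielding 16
assignments; the cardinality is emitted, not assumed.

Audio rendering uses a 100 ms exponentially decaying 500 Hz tone
(configurable), peak-normalized to 0.9. The smallest inter-onset interval
(131.25 ms) exceeds the default note duration, so notes never overlap;
overlapping configurations sum with a warning. Loudness calibration is
out of scope.

## Synthetic data

The generators produce data with the statistical structure the analyses
assume — not biophysically realistic signals.

- **Tapping**: one tap per beat, phases von Mises around 0° on the 750 ms
  beat circle, quantized to 1 ms. Defaults κ_high = 0.9 and κ_low = 0.24
  solve I₁(κ)/I₀(κ) = R̄ for the calibration goals R̄ ≈ 0.41 and 0.12.
- **EEG** (500 Hz): gamma-shaped unit-peak kernels for the note-evoked
  temporal P1 (peak 118 ms, 1.5 µV) and the target-evoked occipital N1
  (160 ms, −2 µV, +0.8 µV when background regularity is high — i.e. a
  smaller N1) and P3 (320 ms, +2.5 µV, +0.5 µV under high regularity);
  optional steady-state cosines at 1/3 and 4/3 Hz on the ROI channels to
  emulate cortical amplification; 1/f^α Gaussian noise (α = 1, 1 µV SD)
  plus white noise (0.2 µV); optional injected artifacts (±120–200 µV
  pulses and 8× variance segments) to exercise both rejection rules.
  The N1 and P3 kernels overlap slightly in time, as real components do;
  effect-recovery checks therefore test signs and ordering, not exact
  amplitudes.
- **Behavior**: RT = base (380 ms) + subject offset (SD 30 ms)
  − 20 ms·[high regularity] − 10 ms·[high metricality] + trial noise
  (SD 90 ms), floored at 120 ms; hits at 0.95, false alarms at 0.02 per
  nontarget measure (one opportunity each). These rates put synthetic d′
  near 3.7, inside the plausibility band for an easy detection task, and
  make the regularity effect twice the metricality effect.

What passing tests show: the pipeline recovers the sign and ordering of
every injected effect at the study's sample sizes. What they do not show:
performance on real EEG with ocular artifacts, volume conduction, channel
drift, or non-additive behavioral effects.

## Cochlear model

Order of operations is fixed: resample to 5000 Hz → gammatone filterbank
→ Meddis hair cell → resample to 500 Hz → Hilbert envelope → FFT →
channel average → (downstream) baseline correction. The Hilbert transform
is applied after the 500 Hz downsampling, matching the stated processing
order; 1 s is trimmed at each edge before the 30 s FFT windows are cut to
keep Hilbert edge effects out of the spectra.

Center frequencies are ERB-rate–uniform (EarQ = 9.26449, minBW = 24.7)
between 100 Hz and the intermediate Nyquist; with 128 channels the top
center frequency is ≈ 2455 Hz, safely below Nyquist. Filters are the
fourth-order IIR gammatone design from `scipy.signal.gammatone`; the bank
is linear up to IIR rounding noise (the narrow 100 Hz channels dominate
the error at ~10⁻⁵ relative).

The hair cell integrates the three-reservoir transmitter dynamics (free
pool q, cleft c, reprocessing w) with the canonical constants A=5, B=300,
g=2000, y=5.05, l=2500, r=6580, x=66.31, M=1, h=50000 at the sample rate,
initialized at the zero-input fixed point
c₀ = M·y·k₀ / (l·k₀ + y·(l+r)), k₀ = g·A/(A+B), so silence yields the
spontaneous output h·c₀ ≈ 64.77 exactly (an analytic test oracle);
onset transients overshoot the adapted level, the model's defining
behavior. A linear input gain (default 30) maps the peak-0.9 rendered
waveform into the model's adaptive operating range (the transduction is
compressive; stimulus-frequency peaks are present at any gain, stronger
in the adaptive range). The inner loop is numba-compiled.

## Frequency tagging

Epochs are 30 s (15 000 samples at 500 Hz), giving 1/30 Hz resolution
with 1/3 and 4/3 Hz exactly bin-centered — an exact multiple of the 3 s
measure, so a rectangular window needs no leakage correction. Amplitude
spectra are scaled so a unit sinusoid at a bin yields amplitude 1.
Baseline correction subtracts the mean of bins at ±2..±4 offsets
(0.0667–0.1333 Hz); edge bins use the neighbors that exist and bins with
fewer than two usable neighbors become NaN. The harmonic normalization
set is {k/3 Hz, k = 1..30} (top 10 Hz), the target bins included, with an
n−1 standard deviation; a zero-spread harmonic set raises unless the
target deviation is also zero (z = 0 by continuity). Epoch counts are
matched across conditions by seeded subsampling to the minimum. ROI
aggregation averages channel spectra before z-scoring (z of the ROI mean);
mean-of-z is exposed as an option.

One property worth knowing: on a 1/f background the surrounding-bin
correction sits on a convex spectral slope, so at 1/3 Hz the no-signal z
is biased slightly negative — a property of the method itself, shared by
any real EEG background, not an implementation artifact. The null
(no-injected-signal) unbiasedness test therefore uses a spectrally flat
background, and a companion test characterizes the sign and bound of the
1/f bias.

## ERP analysis

Filtering is zero-phase FIR (MNE's `filter_data`, 0.1 Hz high-pass, 30 Hz
low-pass) followed by average re-referencing. Epochs are half-open
[−200, 500) ms on the 2 ms sample grid, baseline-corrected over
[−200, 0) ms. Rejection combines a ±100 µV amplitude threshold with a
joint-probability rule: per channel, the empirical density (100-bin
histogram over all epochs' samples) assigns each epoch a mean log-density
score, summed over channels; epochs deviating more than 3 s.d. from the
mean score are dropped. The density estimator is a documented choice, not
claimed identical to any toolbox internals. Control epochs are cut at the
target's own within-measure latency in randomly chosen (seeded, without
replacement) nontarget measures, so control counts follow the relative
frequencies of the target positions. Component windows are closed
intervals (a 250–400 ms window includes both endpoint samples). Analyses
warn when fewer than 10 epochs remain in a cell.

Independent-component ocular-artifact removal and current-source-density
transformation are deliberately outside this pipeline: synthetic
recordings are generated artifact-typed but ocular-free and treated as
reference-free. `PreprocessConfig.real_data_parity` records that real
recordings would need those steps.

## Behavioral statistics

d′ uses the log-linear correction ((hits+0.5)/(targets+1)) by default;
raw rates are available and raise on 0/1. The repeated-measures ANOVA is
implemented directly for fully within-subject designs of 1–3 factors via
recursive marginal-mean decomposition; each effect is tested against its
interaction with subjects, and η_G² divides the effect SS by itself plus
all subject-containing SS. The implementation is cross-checked against
`pingouin.rm_anova(effsize="ng2")` and against the F = t² identity in the
two-level case; its type-I error rate is verified at 5% ± 1.5% over 2000
null replicates. False-alarm opportunities are counted per nontarget
measure (configurable upstream of `sdt_counts`). RT is analyzed on hit
trials only. Zero-variance cells are flagged (warning + NaN F), not
silently propagated.

## Problem sizes

Defaults match the study conditions: 180-measure (9 min) sound phases,
30/30/30 targets, 500 Hz EEG, 128 cochlear channels, 16 tapping and 64
main-task participants. Long-running verification uses smaller sizes as a
package choice, stated where used: the cochlear acceptance run processes
a 96 s stimulus excerpt through the full 128-channel bank; tagging
detection uses 12–16 simulated participants (the null bias check uses the
full 64); ERP sign-recovery uses 12 participants × 48-measure blocks.
Every reduction keeps the per-unit structure (epoch length, channel
counts, trial ratios) identical to the full design.

## Known limitations

- Compositions are constraint-satisfying exemplars; the original scores
  are not reproducible from the printed material.
- The counterbalance enumeration yields 16 assignments; published designs
  citing 32 groups presumably double this with a factor (e.g. measure
  assignment) not derivable from the available description.
- The cochlear model is linear-filterbank + Meddis only: no middle-ear
  filter, no basilar-membrane compression beyond the hair cell, monaural.
- The tagging z-score inherits the 1/f curvature bias described above;
  comparisons between conditions (which share a background) are
  unaffected, absolute single-condition z values are conservative at low
  frequencies.
- Statistical machinery targets balanced within-subject cell-mean
  designs; there is no mixed-effects or trial-level modelling.
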