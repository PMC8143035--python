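# Methods

This note documents the models, parameters, and numerical choices behind
each stage of the pipeline, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Study setting

The pipeline targets supine multi-frequency whole-body vibration: axial
sinusoidal excitation applied simultaneously at the feet (25 Hz, 4.2 g_rms)
and shoulders (15 Hz, 0.7 g_rms) for a 10-minute bout after a 5-minute
baseline. Physiological outcomes are measured as paired
baseline-vs-vibration contrasts per subject: EMG activation of eight
muscles (SO, TA, GL, VM, VL, RF, ST, DM), five breath-metabolic variables
(VO2, VCO2, EE, VE, VT) at 0.1 Hz, and rSO2 at three sites (GL, RF, BB) at
0.25 Hz.

## Accelerometry

Channels (512 Hz) are linearly detrended — "detrending" is read as
removing slow drift, not just the mean — and low-pass filtered with a
6th-order Butterworth at 35 Hz applied forward-backward. Zero-phase
filtering doubles the effective order, so the magnitude response is that
of a 12th-order filter; the passband loss at 25 Hz is |H|² = 0.984 and is
accepted rather than compensated.

Vibration intensity is the mean RMS of consecutive non-overlapping 4-s
windows (partial trailing windows discarded), averaged within and then
across subjects.

Transmissibility uses the H1 estimator H(f) = G_io/G_ii with coherence
γ² = |G_io|²/(G_ii G_oo), assuming a linear elastic input-output relation.
Spectra are Welch estimates at 0.25 Hz resolution (segment length =
rate/resolution samples). The window and overlap are not dictated by the
method, so the field defaults — Hann, 50% overlap, per-segment mean
removal — are used and configurable. Bins where the input auto-spectrum
falls below 1e-12 × max(G_ii) are flagged undefined rather than reported;
coherence is clipped to [0, 1] only against floating-point excursions
(Cauchy–Schwarz guarantees ≤ 1 analytically). Transmissibility is read on
the axis aligned with each excitation chain (y on the foot chain, z on the
shoulder chain).

## EMG activation

Sampling rate defaults to 1000 Hz (no rate is dictated by the method; any
rate > 800 Hz satisfies the 10–400 Hz analysis band). The analysis
segments are: the 1 s immediately preceding vibration onset (baseline),
the 10 s starting exactly 60 s after onset (vibration), and two 5-s MVIC
trials. Segments are band-passed with one 8th-order Butterworth 10–400 Hz
design applied forward-backward (the alternative reading — two cascaded
4th-order passes — was considered and rejected for simplicity).

Welch resolution for EMG defaults to 1 Hz: the 10-s vibration segment then
averages 19 half-overlapped windows, while the 1-s baseline segment yields
a single-window periodogram — a documented limitation that makes the bias
factor noisier than the vibration RMS.

Artifact removal is PSD-domain spike interpolation: for base frequencies
15, 25, 60 Hz, every harmonic k·f0 ≤ 400 Hz contributes an interval
±2 Hz wide (inclusive endpoints; ±2 bins at 1 Hz resolution). Overlapping
or touching intervals merge. Bins inside an interval are replaced by the
straight line joining the nearest bins retained by *all* intervals — using
globally retained anchors matters because two intervals separated by less
than one bin spacing would otherwise anchor on each other's spikes. An
interval abutting the spectrum edge falls back to constant extension from
the available side, with a logged warning.

RMS is computed as √(Σ psd·Δf) over 10–400 Hz (one-sided density). The
bias factor — filtered/unfiltered baseline RMS — compensates for genuine
broadband power removed along with the spikes; the vibration RMS is
divided by it before normalization to MVIC. The baseline %MVIC uses the
spike-filtered baseline RMS directly (bias-correcting the baseline would
be the identity by construction). MVIC reduces across the two trials by
the maximum (standard MVIC practice; the mean is available via
`mvic_reduce="mean"`). Bias is computed per muscle per record, never
pooled.

## Metabolic and rSO2 summarization

Baseline is the arithmetic mean of the final pre-onset window: 180 s (18
samples at 0.1 Hz) for metabolic variables, 60 s (15 samples at 0.25 Hz)
for rSO2. The vibration epoch is summarized by a moving-average peak: the
maximum over all full windows (180 s / 60 s respectively) at
single-sample stride within the first 600 s of vibration; ties resolve to
the earliest window. Window means are computed per-window (not by running
cumsum) so exact ties stay exact. The instrument's display-side 30-s
moving average is treated as already present in delivered data and is not
re-applied.

Note that the max-of-window-means statistic is positively biased under
noise even with no true change; the type-I-error calibration of the
inference layer is therefore performed on paired tables where the null
actually holds (both conditions drawn from the same distribution), not
through the peak summarizer.

rSO2 change is reported both as absolute percentage points and as percent
of baseline, because "increased by x%" is ambiguous for a percent-valued
quantity; outputs label each explicitly.

## Inference

With two conditions, the one-way repeated-measures multivariate condition
test is the one-sample Hotelling T² on per-subject difference vectors
d = vibration − baseline:

    T² = n·d̄ᵀS⁻¹d̄,  Λ = 1/(1 + T²/(n−1)),
    F = T²(n−p)/(p(n−1)) on (p, n−p) df,  partial η² = 1 − Λ.

This reading exactly reproduces the characteristic df patterns (p, n−p)
and the η² = 1 − Λ identity of two-condition repeated-measures output from
standard statistical packages. Subjects enter a family's test only if
complete on all of that family's variables (listwise deletion, logged with
the per-family complete-case count). The difference covariance must be
nonsingular (condition number below 1e10); violations are rejected naming
the most collinear variable pair. Post-hocs are two-sided paired t-tests
with Bonferroni multiplier equal to the family size; zero-variance
differences report p = 1.

Power for the within-factor design uses the noncentral F distribution with
df1 = ε(m−1), df2 = ε(n−1)(m−1) and noncentrality λ = f²·n (the SPSS
effect-size convention; λ = f²·n·m is available via
`noncentrality="times_m"`), where f = √(η²/(1−η²)). With f = 0.734,
n = 19, m = 2, α = 0.05, ε = 1 this gives power ≈ 0.857.

## Synthetic-data generator

The generator emulates the study conditions with recorded ground truth:

- **Accelerometry**: pure sinusoids at 25 Hz (RMS 4.2 g) and 15 Hz
  (RMS 0.7 g) as source channels; tissue channels are the sources scaled
  by per-site gain pairs (defaults decay with distance from each actuator:
  TA (0.10, 0.60), RF (0.15, 0.30), BC (0.40, 0.08) as (gain15, gain25)),
  plus harmonic distortion (5% / 2% of the at-site fundamental for the
  2nd / 3rd harmonics) and white noise of RMS 0.01 g. Per-subject gains
  get 10% lognormal jitter; the realized values are stored in the ground
  truth.
- **EMG**: the physiological component is Gaussian noise shaped by a
  raised-cosine amplitude envelope — flat 20–150 Hz, half-cosine
  shoulders to 10 and 400 Hz, zero outside — normalized to the exact
  requested RMS per condition. This is a deliberate simplification with a
  fully characterizable RMS, not a physiological spectrum model.
  Vibration epochs add pure sinusoid artifact lines at 15/25/60 Hz
  harmonics (1/k amplitude decay, random phase per line per record;
  coincident harmonics merge with combined power), with total artifact
  RMS defaulting to 1.5× the physiological vibration RMS. Resting
  activation defaults to 2–3% MVIC with vibration multipliers
  SO 1.04, TA 1.15, GL 1.30, VM 1.45, VL 1.62, DM 1.25 — spanning the
  4–62% increase range — and RF, ST at exactly 1.0 (planted null
  effects). Between-subject variation is a 20% lognormal factor applied
  to all of a subject's conditions; independent 3% lognormal jitter per
  condition models same-session repeatability. EMG units are arbitrary
  (no absolute µV scale is asserted anywhere downstream).
- **Metabolic/rSO2**: baseline mean plus a saturating-exponential rise to
  a plateau after onset, with additive Gaussian noise. Defaults plant a
  22.3% VO2 increase (τ = 45 s), ~20% increases for VCO2/EE/VE, a 3% VT
  increase, and rSO2 deltas of +4.5/+1.4/+2.5 points at GL/RF/BB
  (τ = 60 s, noise SD 0.8 points, values clipped to [0, 100]% with a
  logged warning). Between-subject variation is lognormal on baselines
  (15% metabolic, 5% rSO2) and on effects (20%).
- **Records**: EMG sessions are generated as trigger-aligned segments — a
  continuous record spanning a configurable pre-onset span (default 5 s)
  and post-onset span (default 75 s, containing the 60–70 s analysis
  window with margin) plus two 5-s MVIC trials — rather than the full
  15-minute protocol timeline, which no analysis step reads.
- **Reproducibility**: one global seed spawns per-subject, per-modality
  substreams via `SeedSequence` spawn keys, so adding a subject never
  changes existing subjects' records, and identical configurations are
  bit-reproducible.

What the generator does **not** emulate: no biomechanical body model
(attenuation is prescribed, not emergent), no sensor dropout, no
nonstationary EMG (tonic vibration reflex onset dynamics), no breath-by-
breath variability structure, no oximeter quantization. Passing tests
therefore certify the *pipeline's* recovery of known signal parameters
under realistic noise — not the physiological claims themselves, which
would require human data.

## Problem sizes used in tests

Test cohorts use 2–19 subjects with 16-s accelerometry records, 2 s + 72 s
EMG records and the full 15-minute slow-series timeline; these sizes give
every estimator at least the minimum averaging the method requires while
keeping the suite fast. The end-to-end statistical-pattern check runs 200
replicates of a 19-subject cohort; type-I-error calibration uses 2,000
null tables; null-bias and coherence-bias oracles use 10,000 and 1,000
Monte-Carlo draws respectively.

## Known limitations

- The baseline bias factor rests on a single-window periodogram (1-s
  segment at 1 Hz resolution) and carries ~4% relative noise; bias values
  are comparable only within this implementation's estimator settings.
- Welch window/overlap conventions affect third-decimal details of
  transmissibility curves; published spectra estimated under unknown
  settings can only be compared qualitatively.
- MVIC max-of-trials reduction is upward-biased by estimation noise
  (~1–2% at two 5-s trials), slightly deflating %MVIC values.
- The moving-average peak summarizer is positively biased under noise;
  between-condition contrasts inherit a small positive shift for
  variables with no true change.
- EE units (kcal/min vs kcal/day) are pass-through metadata; no unit
  conversion is attempted.
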