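# Methods

This note documents the models, numerical choices and limitations of the
`oxiscreen` pipeline in enough detail to reproduce or audit it.

## Signal model and pre-processing

The input is an overnight SpO₂ series sampled at 1 Hz by a portable finger
oximeter (percent saturation, 0–100). Recording validity is assessed before
any cleaning: a portable recording with total recording time below 4 h is
rejected (battery depletion, probe loss or early termination make shorter
nights unscorable); exactly 4 h counts as valid because the exclusion rule
is a strict "<". TRT is (n−1)/fs on the raw series.

Three artifact rules then apply: (i) zero samples (probe disconnection),
(ii) saturations below 20 % (not survivable, hence sensor error), and
(iii) sample-to-sample changes of ≥ 4 %/s (faster than oxygen physiology
allows). Missing samples (empty CSV cells, non-numeric quality flags) are
treated like zeros. Rule (iii) does not by itself say *which* side of a
≥ 4 %/s step is artifactual. We split the series at every such step into
internally consistent runs and drop the shorter run at each step, unless
both sides persist for at least `min_consistent_s` (default 30 s), in which
case the step is treated as a genuine level shift — deep desaturations in
COPD are large but never instantaneous — and both runs are kept.

Surviving segments are concatenated. A junction whose own step would be
≥ 4 %/s gets the *minimal linear ramp*: the smallest number k of equally
spaced samples such that every sub-step is strictly below 4 %/s (k is the
least integer with |Δ|/(k+1) < 4; a seam of 16 % gets 4 intermediate
samples with steps of 3.2 %). After the full pipeline the output provably
contains no missing value, no zero, no sample < 20 %, and no step ≥ 4 %/s,
and cleaning an already-clean signal is the identity. The report counts
each rule's removals and satisfies n_in = n_out − n_interpolated + n_removed.

## The 16 oximetric features

Time-domain and nonlinear measures operate on non-overlapping 512-sample
segments (8.5 min at 1 Hz) and are averaged across segments; spectral
measures come from one whole-recording Welch estimate.

* **M1t–M4t** — population moments of each segment (mean %, variance %²,
  skewness, kurtosis). Kurtosis is the standardized fourth moment (Gaussian
  → 3), not excess: the "fourth-order moment" read literally. A constant
  segment gets skewness/kurtosis 0.
* **Welch periodogram** — 512-sample Hann windows, 50 % overlap, 1024-point
  FFT, per-window mean detrending, one-sided density scaling; 513 bins at
  ~0.001 Hz resolution. Detrending makes the Parseval check (∑PSD·Δf ≈
  signal variance) meaningful; the test suite asserts it within 5 %.
* **M1f–M4f** — moments of the *distribution of normalized PSD amplitudes*
  (the PSD scaled to unit sum, moments over bin values). An alternative
  reading — power-weighted spectral moments of frequency — is implemented
  behind `freq_moment_basis="frequency"`; the amplitude-histogram reading is
  the default because a flat spectrum then gives the natural (1/N, 0, 0, 0).
* **MF** — smallest frequency whose cumulative normalized power reaches ½.
* **SE** — Shannon entropy of the unit-sum PSD divided by log(N_bins) ∈ [0,1].
* **P_T, PA, P_R** — total integrated power; maximum PSD value with
  frequency in the closed band [0.014, 0.033] Hz; band power over total
  power. The band brackets the 30–70 s periodicity of recurrent apneas.
* **SampEn(m=1, r=0.25·SD)** — −ln(A/B) with B and A the counts of m- and
  (m+1)-length template pairs within Chebyshev tolerance r·SD, self-matches
  excluded. The SD is the whole-recording SD, applied to every segment, so
  the tolerance does not shrink in quiet segments. If A or B is zero
  (over-regular signal) SampEn is defined as 0 with a warning. m and r are
  unstated in the source description; these defaults follow common practice
  in oximetry work and are exposed in the configuration.
* **CTM(ρ=0.25)** — fraction of second-order difference points
  (x[t+1]−x[t], x[t+2]−x[t+1]) strictly inside the radius-ρ circle. ρ is in
  % saturation; 0.25 discriminates quiet breathing from event-driven swings
  on integer-quantized oximeters.
* **LZC** — binarize each segment at its median, parse with LZ76
  (exhaustive history: a phrase grows while it can be copied from the text
  before its last character), normalize the phrase count by n/log₂(n).
  Random sequences approach 1; constants give 2·log₂(n)/n.

All 16 features are finite for any valid preprocessed recording of
≥ 1024 samples; adding a constant to the signal changes only M1t (asserted
by a test).

## FCBF feature selection

Entropies require discrete variables; features and the continuous AHI
target are discretized into 4 equal-frequency bins (stable rank-based
assignment, so the result is invariant under strictly monotone transforms
and under subject permutation; a constant vector degrades to one label).
Relevance is SU with the binned AHI; ranking ties break by original column
order. The redundancy pass scans survivors from the most relevant down and
removes any lower-ranked j with SU(i,j) ≥ SU(j, target). No relevance
threshold is applied (δ = 0): the published procedure describes ranking
plus redundancy only.

A caveat documented here because it shapes the tests: for a feature truly
independent of everything, the redundancy comparison pits two near-zero
*empirical* SU values against each other, so whether the noise feature
survives is sample-dependent. The test instances for "independent features
are retained" are therefore fixed-seed constructions whose brute-force SU
table implies retention; the tests verify that precondition explicitly.

## Regression MLP

A single hidden layer of N_H tanh units and a linear output floored at 0
(an AHI cannot be negative; the floor applies at prediction, training uses
the raw linear output). Features are z-scored with training-set statistics
stored in the model. Training minimizes SSE + ν‖w‖² over the connection
weights (biases unpenalized) by full-batch L-BFGS (ftol 1e−6, gtol 1e−8,
max 500 iterations) from a seeded uniform ±0.5/√fan-in initialization; the
analytic gradient is verified against finite differences in the tests, and
identical (data, seed) pairs give identical weights.

Model selection runs leave-one-out cross-validation for every (N_H, ν) grid
cell, repeated `reps` times over fresh initializations, scored by the mean
ICC between held-out predictions and the reference AHI; ties prefer the
smaller N_H, then the larger ν. Default grids are N_H ∈ {2,4,…,20} and
ν ∈ {0.1,0.5,1,2,4,8} (the published report does not enumerate its grids;
these are ours). The published per-setting optima ship as presets: in-lab
9 features (M1t,M2t,M3t,M4t,MF,P_R,SampEn,CTM,LZC) with N_H=12, ν=1; at-home
8 features (M1t,M3t,M4t,SE,P_R,SampEn,CTM,LZC) with N_H=12, ν=4. The
trained weights of the original clinical model cannot be reproduced — its
training cohort was never released — so presets fix the architecture, not
the weights.

## Desaturation indices

No universal algorithm defines the ODI; devices differ. Ours: the signal is
median-filtered over 5 samples (suppresses measurement noise that would
otherwise inflate the index ~10 %), the baseline is a trailing 120-s moving
maximum, and an event triggers when the deficit (baseline − SpO₂) reaches
the threshold (3 % for ODI3, 4 % for ODI4), ending when the deficit
recovers to ≤ 1 % or after 5 min. Because trigger and release are
asymmetric and the release rule is shared by both thresholds, every
4 %-event nests inside a 3 %-event, which guarantees ODI4 ≤ ODI3 for every
input — a property the test suite checks on 1000 random simulated
recordings. An earlier design with a 10-s event-merge rule and a
nadir-latency filter was abandoned precisely because it broke that
guarantee (threshold-3 events start earlier, so they merge across gaps that
threshold-4 events do not). The index is count / recording hours; it is
invariant to adding a constant to the whole signal. CT90 is the percentage
of samples below 90 %; basal SpO₂ is the modal integer saturation (common
oximetry-report convention; a median alternative would be one line).

## Agreement and diagnostic evaluation

* **ICC** — two-way random effects, absolute agreement, single measures
  (ICC(2,1)) by default, computed from the two-way ANOVA mean squares; the
  consistency variant ICC(3,1) is selectable. CIs use the McGraw & Wong
  F-distribution method. The implementation is direct (model selection
  evaluates it thousands of times); `pingouin.intraclass_corr` serves as
  the independent oracle in the tests.
* **Bland–Altman** — bias = mean(b−a), limits of agreement bias ± 1.96·SD
  of the differences (SD with ddof=1), width = 2·1.96·SD. The "confidence
  interval" figure quoted alongside published Bland–Altman plots is read as
  this LoA width.
* **Mountain plot** — folded empirical CDF of the differences with
  mid-rank percentiles (i−½)/n, folded at 50 %.
* **Contingency metrics** — a subject is positive iff AHI ≥ cutoff on each
  side (cutoffs 15 and 30 events/h). LR+ = Se/(1−Sp) is flagged undefined
  when Sp = 100 %. Proportion CIs are Wald, switching to Wilson when any
  cell is below 5; likelihood-ratio CIs use the log method. The CI method
  behind the original report's intervals is unstated, so point estimates,
  not intervals, are the comparable quantities.
* **ROC/AUC** — trapezoidal empirical AUC over all thresholds (equals the
  tie-corrected Mann–Whitney statistic; asserted against a pairwise-count
  oracle), CI by Hanley–McNeil.

## Synthetic data generator

The generator emulates the oximetric phenotype of the validation cohorts,
not gas-exchange physiology. A recording is baseline + events + noise,
clipped to [50, 100] %:

* baseline 94 % (non-COPD default) or 91 % with slow sinusoidal drift
  (±1.5 %, ~90 min period) and 10–40-min epochs lowered a further 2–4 %
  (COPD mode) — this reproduces the CT90 contrast between groups (< 15 %
  non-COPD vs > 30 % COPD) without modelling its mechanism;
* trapezoidal desaturation events: linear fall over 15–35 s, 5-s nadir hold
  at a depth drawn from N(5, 1.5²) % truncated at 3.5, linear resaturation
  over 15 s. The event count is Poisson(rate × duration), thinned if the
  draw cannot fit without overlap, and events are placed with
  exponentially distributed gaps rescaled to the free time — Poisson-like
  irregular spacing with an exactly known implanted count. The *achieved*
  rate is the ground-truth AHI;
* Gaussian measurement noise (SD 0.5 %);
* separately injectable artifacts (zero runs, sub-20 % dips, ≥ 4 %/s
  spikes) at a configurable rate, so preprocessing can be tested round-trip
  against the clean truth.

Cohorts draw nominal rates uniformly (default 0–60 events/h); a paired
"home" night re-simulates each subject with the rate multiplied by a
lognormal(0, 0.4) factor — night-to-night variability — and fresh noise.

**What passing tests do and do not show.** The generator's events are
cleaner, more stereotyped and more exactly counted than real respiratory
events: no hypopneas without desaturation, no positional clustering, no
quantization to integer percent, no sleep/wake distinction (the reference
AHI divides by total sleep time, oximetry by recording time). End-to-end
recovery ICCs near 1.0 on synthetic cohorts therefore demonstrate that the
pipeline is implemented correctly and can track event density; they do not
predict clinical accuracy, which in the original validation was ICC ≈ 0.94
in-lab and ≈ 0.73–0.79 at-home. The home-night degradation our acceptance
script shows (ICC ~0.84 vs ~1.0 in-lab) mirrors the direction, not the
magnitude, of that drop.

## Problem sizes and runtime

Defaults were chosen so the whole validation runs on one CPU in minutes:
8-h recordings (28 800 samples, 56 feature segments), 200-subject cohorts
for the end-to-end recovery experiment (~2.5 min), 1000 short recordings
for the ODI-nesting property (~1.5 min), and single-pass loo-cv where the
published model selection repeated it 100 times (the repetition knob is
`reps`, default 100 in `select_model`, reduced in tests only to bound
runtime, not to change the procedure).

## Known limitations

* EDF support reads the first SpO₂-labelled channel only and requires an
  integer sample rate; the bundled EDF writer is a minimal synthetic-data
  writer, not a general exporter.
* The desaturation detector is a documented stand-in for whichever
  proprietary algorithm produced published ODI columns; agreement with
  device ODIs is not claimed.
* ICC confidence intervals assume the two-way normal ANOVA model; with
  n < ~15 they are wide and approximate.
* The FCBF redundancy decision between two weakly relevant features is
  finite-sample noisy (see above); with 16 features and ~200 subjects the
  selected subset should be read as "a" sufficient subset, not "the" one.
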