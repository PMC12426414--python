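# Methods

This note documents the models, estimators and numerical choices behind
`tmsreact`, and what the synthetic-data generators do and do not emulate.

## Resting spectra

Power spectral density is estimated per channel with Welch's method:
2-second segments (0.5 Hz grid at the 1000 Hz sampling rate the pipeline
assumes), Hann window, 50 % overlap, per-segment mean detrending (which
keeps DC leakage out of the δ band). The density is one-sided and
normalised so its integral over frequency approximates signal variance;
the estimator is verified in the tests against a hand-rolled
periodogram-averaging oracle to 1e-8.

Band powers are Riemann sums of PSD·Δf over **half-open** frequency bins
`low ≤ f < high`. Shared band edges therefore belong to exactly one band,
which makes two identities exact rather than approximate: relative powers
over the δ/θ/α/β/γ partition sum to 1, and δ1 + δ2 = δ. The total-power
denominator for relative power is restricted to 1–45 Hz, the union of the
defined bands. A separate closed-interval integral (`integrate_psd` with
`closed=True`) is provided for free-standing band integrals such as
checking that a 2 μV sinusoid carries A²/2 = 2 μV²; with the Hann window
the energy of an on-grid sinusoid occupies the peak bin and its two
neighbours, so the closed ±0.5 Hz interval captures it completely.

The slowing index `ratio1 = (δ + θ)/(α + β)` is computed per channel from
absolute band powers (the denominator of relative power cancels) and
region-averaged for reporting. Region averages are unweighted means over
named montage clusters; the defaults are the nine-electrode M1 clusters
around C3/C4 and an eight-electrode frontal cluster.

## Phase-lag index

Channels are band-passed with a zero-phase (forward–backward)
Hamming-windowed FIR filter whose order spans at least three cycles of
the band's low edge; instantaneous phase comes from the analytic signal,
and one filter length at each record edge is masked out. PLI is the Stam
sign-of-sine estimator

    PLI(a, b) = | ⟨ sign( sin(φ_a(t) − φ_b(t)) ) ⟩ |

with `sign(0) = 0`, so zero-lag (volume-conducted) coupling dilutes
rather than inflates connectivity. The masked record is split into 2-s
epochs matching the PSD segmentation; the *signed* mean of
`sign(sin Δφ)` is computed per epoch, averaged across epochs, and the
absolute value is taken last. Taking |·| per epoch instead would add a
small-sample bias of order `√(2/(π·n_eff))` per epoch (n_eff is the
number of independent phase-difference samples, only a handful in 2 s of
a low-frequency band); the signed-mean ordering is exactly equivalent to
the whole-record estimator while keeping per-epoch bookkeeping.

The null level of PLI between independent channels is set by n_eff over
the whole record, not the raw sample count: at 60 s the 100-seed maximum
null PLI is ≈ 0.15 for δ and α even though the mean is ≈ 0.045. At the
7-minute resting duration the pipeline is designed around (the
generator's default), the 100-seed maximum is ≈ 0.06. Null-level checks
in the tests and acceptance script therefore use 420-s records.

## TMS-evoked potentials

Epochs span −1000..1000 ms around each pulse (the pulse sample at t = 0);
events without full window support are dropped with a warning. The
residual pulse artifact is removed by replacing samples strictly inside
−5..15 ms with a cubic interpolant anchored on five samples on each side
of the window — all other samples are bit-identical to the input. Trials
whose post-interpolation absolute amplitude exceeds 100 μV on any channel
outside the interpolated window are rejected (a deliberately simple
amplitude criterion standing in for manual/ICA-based cleaning of recorded
data; an external cleaning step can be slotted in before the pipeline).
The evoked response is the trial mean with the −500..−50 ms pre-pulse
baseline subtracted; the baseline stops at −50 ms to stay clear of
pre-pulse ringing near t = 0.

GMFA is the across-channel population standard deviation at each time
point, `√(Σᵢ (Vᵢ − V̄)² / K)` with K the electrode count. Because the
spatial mean is subtracted inside the formula, GMFA is reference-free
(invariant to any common offset) and scales with |c| under global
scaling; re-referencing to the average is therefore a no-op for GMFA and
is not separately applied. Local TEPs are unweighted means over the
nine-electrode cluster surrounding the stimulated M1.

Component peaks are sign-appropriate local extrema inside configurable
search windows (defaults: P30 20–40, N45 40–55, P60 55–80, N100 85–140,
P180 150–250 ms — standard literature windows; configurability absorbs
the variance across reports). On local/channel traces, P-components are
maxima and N-components minima; on the non-negative GMFA trace every
component is a maximum. When several extrema compete, the
largest-magnitude one wins and exact ties go to the earliest latency. A
component with no interior extremum of the right polarity in its window
is reported as not found rather than clamped to a window edge.

M1(+)/M1(−): the hemisphere contralateral to the more affected upper
limb is M1(+). Both the GMFA peak and the local-cluster peak are emitted
for every component, so analyses phrased in terms of either quantity can
be reproduced. Stimulation intensity (e.g. 90 % RMT) is carried as
metadata only; no computation depends on it.

## Responder rule and classifier

A subject is a responder when `(t0 − t10)/t0 ≥ 0.30` **or**
`t0 − t10 > 5` on the UPDRS-III total (inclusive rate clause, strict
absolute clause; improvement is a decrease). A baseline of 0 leaves the
rate undefined and the subject unlabeled; a missing T10 leaves the label
missing. UPDRS-III subscores are computed from the standard item
mapping (tremor = items 20+21, rigidity = 22, axial = 27–30, etc.);
disagreements between a supplied total and the item sum are the caller's
to resolve — the package never silently repairs them.

The classifier is a linear SVM on two baseline features: frontal δ
relative power (region average) and F2–F7 δ PLI. Evaluation is
stratified 5-fold nested cross-validation: the inner 5-fold loop selects
the margin penalty C from a 7-point log grid 1e-3..1e3 by balanced
accuracy, the outer loop produces held-out decision scores, and the
whole partition is re-drawn for each repetition (the repetition count is
read as the number of random outer-partition draws whose metrics are
averaged). Feature z-scoring uses training-fold statistics only, at both
CV levels, so no test information leaks into scaling or model selection;
a constant feature column z-scores to zeros with a warning. AUC is
computed per repetition from pooled outer-fold scores (midrank tie
handling); the reported sensitivity/specificity pair is the
Youden-maximal point of the ROC built on scores averaged across
repetitions. Folds with a single training class are re-drawn (up to 100
attempts) before failing.

Because a *single* random label permutation has a null-AUC standard
deviation of ≈ 0.075 at n = 30/30, chance-level checks average over 10
independent permutations × 20 fold-draw repetitions rather than trusting
one permutation.

## Cohort statistics

All two-sample and paired tests are normality-gated: Shapiro–Wilk at
α = 0.05 (per group, or on paired differences) routes to the parametric
test (independent/paired t, Pearson) or its rank analogue (Mann–Whitney
U, Wilcoxon signed-rank, Spearman). Within-group families use Bonferroni
adjustment `min(1, p·m)`; PLI pairwise families use Benjamini–Hochberg
FDR. Degenerate inputs (all differences zero, zero variance in both
groups) short-circuit to p = 1 with a note instead of erroring mid-
pipeline. Repeated-measures modeling across three timepoints (e.g.
generalized estimating equations) is deliberately out of scope; the
package reports per-timepoint within/between tests on the change table
instead.

## Synthetic-data generators

All generators are pure functions of (spec, seed) and bit-reproducible.

**Resting EEG.** Each channel is a sum of independent band-limited
components plus an optional 1/f^γ background and white sensor noise.
Band components are white noise masked in the Fourier domain to
`[low, high)` with a raised-cosine roll-off *inside* the band edges
(width `min(0.5 Hz, bandwidth/4)`), then rescaled to exactly
`fraction × total_power` variance. Spectral masking rather than FIR
filtering keeps band confinement exact — a realizable FIR leaks several
percent of component power through its transition bands, which would
break the generator's own power bookkeeping; the in-band taper exists
because a brick-wall edge smears across the 0.5 Hz bins of the 2-s Welch
estimate. The residual fraction `1 − Σ fractions` goes to the pink
background, so the total oscillatory variance is always `total_power`
(default 100 μV², i.e. a 10 μV RMS signal). Coupled pairs share one band
component, with the second channel's copy rotated by a constant phase at
all band frequencies via the analytic signal — the exact-lag construction
that makes PLI → 1 at high SNR. Default duration is 420 s, the 7-minute
resting recording the pipeline targets.

**TEP epochs.** Components are Gaussian bumps (width given as FWHM)
scaled by a per-channel topography, identical across trials; white noise
and a decaying artifact burst of random per-trial polarity confined to
−5..15 ms are drawn per trial. Gaussian bumps give analytic ground truth
for recovery tests; they are not dipolar field patterns.

**Protocols.** iTBS trains are fixed at 10 triplet bursts (50 Hz within
burst) at 5 Hz over 2 s, 20 trains per side with 8-s gaps — the standard
600-pulse-per-side structure and the only one consistent with a
1200-pulse bilateral total; 10-Hz rTMS delivers 20 × 30-pulse trains per
side with 40-s gaps. Totals are always derived from the structure. The
scheduler reports per-side durations (192 s iTBS, ~818 s rTMS) but the
package does not assert session wall-clock times, which depend on
operator pauses.

**Cohorts.** Responder fraction 0.5 by default; responders draw frontal
δ relative power from N(0.355, 0.111²) and non-responders from
N(0.442, 0.088²) (the planted phenotype the classifier is designed to
detect), F2–F7 δ PLI from N(0.15, 0.06²) vs N(0.25, 0.06²), baseline
UPDRS-III from N(21, 8²) (clipped at 5, rounded), and improvement rates
from N(0.45, 0.10²) vs N(0.05, 0.10²). The generator stores its
ground-truth class separately from the rule-derived label, which can
disagree near the rule boundary — exactly the ambiguity a real cohort
has.

**What the generators do not emulate:** volume conduction and realistic
field spread (channels are independent unless explicitly coupled),
non-stationarity and drowsiness drift, muscle/ocular artifacts beyond
the amplitude-threshold regime, medication state, and any head-model
forward physics. Passing tests demonstrate that the estimators recover
planted structure under these idealised conditions; they do not certify
performance on recorded patient data.

## Problem sizes and tolerances

Tests and the acceptance script use: 60–120 s single- or two-channel
records for spectral identities; 420-s records for PLI null levels (100
seeds); 50 seeds × 100 trials × 59 channels for TEP recovery (planted
P30 = 4 μV, P60 = 5 μV, noise 2 μV — recovery bias is well under the 5 %
acceptance bound, and latency error ≤ 1 ms against a 3 ms bound);
n = 30/30 cohorts with a 4-SD class gap for the separable-classifier
check and 10 × 20 repetitions for the permutation null; 500 Monte-Carlo
draws for test calibration (type-I error within [0.03, 0.07] at α = 0.05,
paired-t power at a 1-SD shift with n = 26 ≥ 0.99). GMFA agrees with the
brute-force population-SD oracle to 1e-12; interpolation leaves
out-of-window samples bit-identical; PLI is amplitude-invariant to
1e-12.

## File formats

Recordings and epochs travel as delimited numeric matrices with a JSON
sidecar (sampling rate, montage, clusters, events); EDF is supported for
reading via MNE. Writing uses 10 significant digits, so text round trips
are exact to ~1e-9 relative. Cohort tables are CSV; derived metrics are
long-format CSV (subject, timepoint, metric, value); every pipeline run
writes a manifest with the config hash, seed, inputs consumed and
per-stage counts.
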