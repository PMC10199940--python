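# Methods

This note documents the models and numerical choices behind
`eegmarkers`: the six measures, the wavelet band machinery, the
screening and classification protocol, the synthetic cohort generator,
and the design decisions taken where the underlying definitions are
ambiguous or open.

## Signals and study design

The unit of analysis is an 8-s EEG segment sampled at 128 Hz
(T = 1,024 samples) on the 19 electrodes of the 10–20 montage, assumed
band-limited to 0.5–30 Hz. Subjects fall into four groups — A/B healthy
elderly, C/D probable AD, with eyes open (A, C) or closed (B, D) — and
every group comparison stays within one eye condition (A vs. C,
B vs. D); mixed-condition pairs are rejected at validation time because
eye closure alone changes the alpha rhythm enough to confound any
AD contrast.

## Band decomposition

Channels are decomposed with the orthogonal Daubechies-4 wavelet
(`db4`, four vanishing moments) at J = 4 levels using **periodized**
boundaries, which makes the transform exactly orthogonal on lengths
divisible by 2⁴: coefficient counts are 512/256/128/64/64 at T = 1,024
and Σc² equals Σx² to machine precision. At 128 Hz the dyadic sub-bands
map onto the rhythms as d2 → beta (16–32 Hz), d3 → alpha (8–16 Hz),
d4 → theta (4–8 Hz), a4 → delta (0–4 Hz); the dyadic edges differ
slightly from the conventional printed ranges (15–30, 8–15 Hz) but are
the only edges a dyadic transform can realise. The 32–64 Hz detail d1
is reconstructed but never used as a feature band, since the signals
carry no content above 30 Hz. Band signals are reconstructed by zeroing
all other coefficient sets and inverting; the four band signals plus
the d1 reconstruction therefore sum to the original signal exactly, and
band extraction is idempotent up to the filter's spectral overlap.

The level count and boundary mode are our choices (neither is forced by
the band definitions); periodization was chosen precisely so that the
energy bookkeeping behind the relative-energy measure is exact.

## The six measures

**Wavelet coherence (`wc`).** The continuous transform is the discrete
correlation C(a,b) = a^{-1/2} Σ_t x(t) Ψ*((t−b)/a) with the analytic
Morlet wavelet (ω₀ = 6), kernel truncated at |u| = 6, over log-spaced
scales covering 0.5–30 Hz (6 per octave). The raw normalised
cross-spectrum has unit modulus pointwise, so cross- and auto-spectra
are smoothed before the ratio — a Gaussian time kernel of width 0.6·a
(scale-matched, following standard practice for Morlet decorrelation
lengths) and a 5-point moving average across scales. The coherence map
then lies in [0,1] by Cauchy–Schwarz and equals 1 identically for
y = ±x. One scalar per electrode pair is the plane mean over the full
time–scale region; a per-electrode value, when needed, is the mean over
the 18 pairs containing that electrode. The smoothing windows and the
scalar reduction are design choices; the qualitative results (self
coherence 1, independent-noise floor well below 1) are insensitive to
them, but absolute coherence values should only be compared within one
configuration.

**Katz fractal dimension (`fd`).** 𝓕 = ln(T−1)/ln(d(T−1)/D) with D the
summed adjacent-point distance under unit abscissa steps and d the
maximal distance from the first sample. Any straight line (including a
constant) gives exactly 1. The degenerate case d(T−1) = D raises an
error rather than returning ±∞.

**Quadratic entropy (`qe`).** Sample-entropy template matching with
Chebyshev distance, self-matches excluded, both match counts taken over
the T−m templates whose (m+1)-extension exists (the printed summation
limits of the common formulation index past the series end; this
in-bounds convention preserves E = −ln(A/B) exactly). The tolerance r
is expressed in standard-deviation units — the series is z-scored
before matching — so 𝒬 = E + ln(2r) is shift- and scale-invariant and
the study grid r = 0.05…1.00 is anchored to a meaningful scale. A
constant series gives E = 0, 𝒬 = ln(2r). When no template pair matches
(B = 0, or A = 0), the entropy is undefined and signalled by an
exception; grid scans simply drop such points.

**Relative wavelet energy (`we`).** The fraction of total squared
coefficient energy in one band's coefficient set. Orthogonality makes
the J+1 fractions sum to 1, and the "original" band — numerator over
the whole decomposition — is identically 1: the measure carries no
information on unfiltered signals, which is why the pipeline refuses to
screen `we` on band `original`. Note the measure consumes the *raw*
series; the band argument selects the numerator set, not an input
filter.

**Quantile graph (`qg`).** The series is coarse-grained into Q
empirical quantile bins (boundaries at i/Q sample quantiles,
left-closed/right-open, a value equal to an internal boundary belongs
to the upper bin; heavily tied series collapse deterministically onto
fewer bins, a constant series onto one). The lag-k transition counts
A_k (Σ entries = T−k) are row-normalised into the Markov matrix W_k and
summarised by the mean jump length Δ_k = (1/Q)·Σ_{ij} W_k[i,j]·|i−j|.
Two conventions in the common formulation are ambiguous (the matrix
inside the trace and the 1/N prefactor); we use W_k and 1/Q, verified
against hand-computable cases: a strictly alternating two-quantile
series gives Δ₁ = 1 and Δ₂ = 0, the strictly increasing series 1…5
with Q = 5 gives Δ₁ = 4/5. The default node count follows the
Q = 2·T^(1/3) rule (20 at T = 1,024).

**Visibility graph (`vg`).** Natural visibility with the *strict*
inequality: samples i < j are joined when every intermediate sample
lies strictly below their chord ("any existing point" must be read as
"every" for the relation to be geometric visibility; the non-strict
variant would join through touching points). Adjacent samples are
always joined, so the path graph is a subgraph; a strictly convex
series yields the complete graph. The builder is an O(T²) running
slope-maximum sweep, verified exactly against an O(T³) brute force.
The complexity index normalises the largest adjacency eigenvalue
between its path-graph minimum 2cos(π/(N+1)) and complete-graph
maximum N−1: c ∈ [0,1], 𝓘 = 4c(1−c) ∈ [0,1], vanishing at both
extremes. λ_max is computed densely (exact symmetric eigensolver) for
N ≤ 300 and by a Lanczos iteration with a fixed all-ones start vector
and tolerance 1e-10 above, so results are deterministic.

## Screening and classification

Each measure × electrode (or electrode pair) × band × group pair is
scored by the one-way fixed-effects ANOVA p value (for two groups,
identical to a two-sided pooled t-test) and by the rank-based
(Mann–Whitney) AUC with midrank ties, oriented to max(AUC, 1−AUC).
Parameterised measures are scanned over the study grids (`qe`:
r = 0.05…1.00 step 0.05 × m ∈ {1,2}; `qg`: Q = 20, k = 1…25) and the
arg-min-p point is selected, ties broken toward the lexically smallest
parameter label. p values are reported raw — the protocol is a
screening, not a confirmatory analysis, and no multiple-testing
correction is applied; the output header says so.

Classification uses a support vector machine on the single selected
feature: RBF kernel, C = 1, features standardised with statistics fit
on the training folds only, stratified K-fold splits (default K = 10)
so the small control group reaches every fold, seeded shuffling for
reproducibility. The kernel and regularisation are our defaults — a
robust choice for one-dimensional features — not values taken from any
reference protocol. Out-of-fold predictions are pooled into one
confusion matrix with AD as the positive class:
Acc = (TP+TN)/total, Sen = TP/(TP+FN), Spe = TN/(TN+FP), in percent.
Sen and Spe swap exactly if the positive-class convention is swapped.

## Synthetic cohorts

The generator provides the study conditions for every statistical test
in the package. Each channel is an independent Gaussian process
synthesised in the frequency domain: flat narrowband components for the
four rhythms plus a 1/f background, all confined to 0.5–30 Hz, summed
in one variance profile, given random phases, inverted, and
renormalised to unit channel variance (only the relative spectral
profile is informative; amplitude-dependent comparisons are not the
generator's business). Baseline band energies are
delta 1.0 / theta 0.7 / alpha 1.2 (2.2 with eyes closed) / beta 0.6 /
background 1.0; each is multiplied per subject by a log-normal factor
(σ = 0.25) to create between-subject variability.

The AD phenotype has two dials, both zero in healthy groups:

* `delta_shift` (s) — spectral slowing: delta energy ×(1+0.8s), theta
  ×(1+0.5s), alpha and beta ×(1−0.4s) (after unit-variance
  renormalisation this is a pure weight shift from fast to slow
  rhythms), plus an *in-band* slowing of delta itself: the delta
  component's upper edge drops by 3.0·s Hz, so AD delta activity is
  concentrated at lower frequencies even inside the band. The in-band
  slowing is what gives the band-filtered complexity measures (fd, qe,
  qg, vg on the delta band) a systematic signal; the weight shift is
  what the relative-energy measure and raw-signal measures see.
* `autocorr_boost` — a Gaussian smoothing of std `autocorr_boost`
  samples applied (as its transfer function) to AD spectra only,
  lowering every complexity measure. Kept deliberately small
  (effect-grid coupling: 0.25 × delta_shift; default 0.125 samples) —
  strong smoothing creates an artefactual beta-band signature that
  would dominate the band ranking.

With both dials at zero the AD and healthy generators are *identical*,
giving an exact null: ANOVA p is uniform and raw AUC centres on 0.5,
which the test suite verifies over 100 replicate cohorts. The helper
`effect_spec(effect)` scales both dials along a fixed ray
(delta_shift = effect, autocorr_boost = 0.25·effect), which is the
3-point effect grid (0, 0.4, 0.8) used in the monotonicity and
classification-recovery tests. Effect-size values are package design
choices calibrated so that the qualitative structure the analysis
expects — discrimination monotone in the effect; delta the
best-discriminating rhythm band for most measures; near-perfect
quantile-graph classification of a 12-control/80-patient cohort at
effect 0.8 — holds under the study sample sizes.

What the generator does **not** emulate: volume conduction or any
cross-channel correlation (channels are independent, so the coherence
measure has no group signal on synthetic data and its band ranking is
uninformative there), artifacts, nonstationarity within a segment,
non-Gaussian waveform shape, and real inter-subject spectral diversity
beyond the log-normal band weights. Passing tests therefore certify the
measures, the screening machinery and the protocol's statistical
honesty — not clinical performance on real recordings.

All randomness derives from one integer seed through per
(group, subject, channel) counter-based `SeedSequence` spawning, so any
record can be regenerated in isolation and generation order never
matters.

## Cost benchmark

Each measure is timed on freshly drawn white noise over
T = 500…10,000 in steps of 100 (96 points; tests use sparser grids to
stay fast), median over ≥3 repeats, with a warm-up call outside the
timed region; parameters fixed at m = 2, r = 0.2, Q = 2·T^(1/3), k = 1;
coherence gets two independent series. Curves are normalised by the
T = 500 point and summarised by a log–log slope. Only orderings are
meaningful — absolute wall-times are hardware-bound. The visibility
graph, whose adjacency grows as T², is the most expensive measure at
large T; the quadratic entropy shares the T² pair count but with a far
smaller constant.

## Numerical and degenerate-input policy

Errors are raised (never NaN returned) for: constant inputs to the
coherence (zero auto-spectrum), zero-energy signals in the relative
energy, series too short for a measure, Katz's d(T−1) = D degeneracy,
undefined entropy (no matches), single-class labels or K < 2 in the
classifier, and mixed-eye-condition group pairs anywhere. I/O
roundtrips preserve samples to 6 significant digits (`%.6g`) and all
metadata exactly; cohort loading assigns groups by directory and
reports the offending file on any parse error. The pipeline is a pure
function of (cohort, configuration): output tables carry the seed, the
package version and a hash of the scientific configuration (output
paths excluded), and reruns are byte-identical.

## Known limitations

* Coherence is the only pairwise measure and the synthetic generator
  gives it no signal; its screening path is exercised for mechanics,
  not for effect recovery.
* Katz's dimension is not scale-invariant (the unit-abscissa
  convention fixes the time scale); values are comparable only across
  series with the same sampling.
* The quantile binning collapses under heavy ties by design; series
  with fewer distinct values than Q occupy fewer than Q nodes.
* The SVM stage clamps K to the smaller class when a tiny cohort
  cannot fill K stratified folds.
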