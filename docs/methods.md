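# Methods

## Signal model and preprocessing

The analysis treats interictal SEEG as a set of `n` simultaneous traces
`V_i(t)` sampled at 200–1000 Hz, each labelled with one of nine standardized
temporal-lobe regions (hippocampus head/tail, amygdala,
superior/middle/inferior temporal gyrus, fusiform gyrus, parahippocampal
gyrus, temporal pole). Recordings are assumed already referenced; no
re-referencing is performed. Vigilance state and medication are ignored.

**Band-pass filter.** Filtering is done in the frequency domain: the whole
segment is Fourier transformed, multiplied by a purely real amplitude
response, and inverted. The response is 0 at DC and below 5 Hz, 1 on
[5, 50] Hz, a raised cosine from 1 to 0 on (50, 60) Hz, and 0 at and above
60 Hz. A real response is zero-phase (filtering commutes with time
reversal), a zeroed DC bin makes the output exactly zero-mean, and the
sharp 5 Hz edge together with a tapered upper edge balances fidelity to the
stated band against ringing near the mains frequency. The transition-band
shape is a design choice; the exact taper is not critical because nothing
in the analysis depends on content above 50 Hz. Segments must be at least
2 s long so the 5 Hz edge is resolvable, and the sampling rate must exceed
120 Hz so that 60 Hz is below Nyquist.

**Amplitude normalisation and spike clipping.** Each channel is z-scored
(mean 0, SD 1); residual interictal spikes are then "clipped" by hard
amplitude limiting at ±k SD (default k = 5), the most literal reading of
clipping, and the channel is re-z-scored so limiting cannot leave SD < 1.
Clipping is idempotent and order-preserving. A zero-variance channel is a
hard error naming the contact.

**Segment selection.** Three non-overlapping segments of nominally 90 s are
taken before the first seizure, excluding the 30 minutes immediately
preceding it (pre-ictal changes); without a seizure annotation the whole
recording is eligible. The eligible span is divided into equal slots, one
window per slot, placed as centrally as possible; placement and, if
necessary, length (down to 80 % of nominal — the "approximately 90 s" is
encoded as a ±20 % tolerance) are adjusted to minimise spike density, the
fraction of samples exceeding k SD on any channel. An eligible span shorter
than `n_segments × 0.8 × duration` is an error reporting the available
span.

## Connectivity and features

Connectivity is the Pearson correlation of preprocessed traces, one matrix
per segment, averaged elementwise across segments on the raw (signed)
coefficients — no Fisher z-transform, and negative correlations are kept.
Contact-level matrices are reduced to region level before feature
extraction: each distinct region pair receives the mean of all cross-region
contact-pair coefficients (within-region pairs are discarded; the region
diagonal is 1). Whether correlation should be computed at contact level and
then reduced, or on region-averaged signals, is genuinely open; reduction
by averaging coefficients was chosen because it is linear in the quantities
displayed and keeps the matrix granularity of the per-patient figures.

The per-patient features are the mean and the sample SD (n−1 denominator)
of the upper-triangle entries; the upper triangle counts each unordered
pair once, which by symmetry is equivalent to "the off-diagonal elements"
without double-counting. A 2×2 matrix has SD 0 by convention.

Group-level region-pair summaries average each pair only over patients in
whom both regions were sampled — electrode coverage differs between
patients — and mark pairs sampled in no patient as absent (NaN plus a
presence mask) rather than zero.

## Classification and inference

Patients are points `(mean, SD)` with label positive = seizure-free.

**Separating line.** The default fitter is a soft-margin linear
support-vector classifier minimising `½‖w‖² + C Σ hinge` on the raw,
unstandardised features (the feature plane is displayed raw, so the line's
coefficients stay interpretable in those units). Because the SVC is not
scale-invariant, the default `C = 1000` is the unit-variance convention
`C ≈ 1` rescaled to features that live on a ~0.1 scale; with `C = 1` at
this scale the margin term dominates and the fit degenerates into majority
voting. `C` is configurable throughout. The solver is scikit-learn's
bundled libsvm, driven through its low-level entry point because the
permutation test performs thousands of sub-millisecond fits where the
public estimator's per-call validation dominates; coefficient-level
equality with `sklearn.svm.SVC` is asserted in the test suite. A point
exactly on the line is classified positive. A pooled-covariance linear
discriminant with equal priors (`w = Σ⁻¹(μ₊ − μ₋)`, boundary through the
midpoint of the class means) is provided as an alternative fitter; the
two are not equivalent in general and no equivalence is assumed.

**Leave-one-out.** Each patient is classified by a line fitted to the
others; TP/FN count positive patients predicted positive/negative, TN/FP
negative patients predicted negative/positive; sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP), accuracy = (TP+TN)/n. A training fold reduced to
a single class (possible under permuted labels in small cohorts) falls back
to predicting the training majority label rather than aborting.

**Permutation test.** The observed label multiset is uniformly rearranged
(counts preserved, not resampled), the full leave-one-out evaluation is
recomputed per permutation, and each p-value is the fraction of
permutations whose metric is equal to or higher than the observed one
(plain count/n; an add-one variant is available but not default, since the
definition is literally an exceedance probability). Default 10,000
permutations. Group differences in each coordinate use the two-sided
Wilcoxon rank-sum test: exact null enumeration when both groups have ≤ 12
tie-free observations, otherwise the normal approximation with continuity
and tie corrections.

## Synthetic cohorts

The generator exists because the study's recordings are not deposited; it
emulates the statistical structure the analysis consumes, not the
biophysics of SEEG.

**Correlation targets.** A population correlation matrix with prescribed
off-diagonal mean and SD is drawn by sampling off-diagonals from a normal
truncated to (−0.99, 0.99), symmetrising, and projecting to the nearest
correlation matrix (Higham alternating projections with Dykstra
correction). Projection can bias the realised statistics, so up to five
recentering rounds shift/rescale the off-diagonals toward the targets and
re-project; a draw is accepted when the realised mean is within 0.02 and
the realised SD within 0.03 of target (in practice recentering lands within
~0.005), and infeasible targets (e.g. strongly negative means that no PSD
matrix of that size admits) raise an explicit error after a retry limit.

**Recordings.** Independent white Gaussian channels are coloured with the
symmetric PSD square root of the target (eigenvalues floored at 0) and
band-limited to 5–50 Hz with the same filter used in preprocessing — an
identical linear filter on every channel leaves pairwise correlations of
stationary signals unchanged, so the analysis filter cannot distort the
quantity being recovered. Artifacts are added afterwards, scaled by each
channel's clean-signal SD: a common-phase 60 Hz sinusoid (default 2× SD),
per-channel slow drift (sum of sub-0.5 Hz sinusoids, 1× SD, synthesised on
a coarse 8 Hz grid and interpolated), and Poisson-timed biexponential spike
transients (default rate 0.05/s, 8× SD, 70 ms) hitting random channel
subsets with random polarity.

**Cohorts.** Two groups with per-patient `(mean, SD)` targets drawn
uniformly from configurable ranges — defaults: positive 0.05–0.25 mean ×
0.02–0.10 SD, negative 0.25–0.55 × 0.10–0.25. These ranges are plausible
qualitative stand-ins for the reported group separation (weak/homogeneous
vs. strong/heterogeneous), not estimates of any real cohort's coordinates.
Each patient samples 4–8 of the 9 regions with one contact per region (the
multi-contact reduction path is exercised separately in tests; one contact
per region keeps default cohorts at realistic channel counts without
paying for redundant contacts). Default cohorts are 12 + 11 patients at
200 Hz — the lowest of the supported rates, so the defaults are also the
cheapest — with three 90 s segments in an eligible span with 20 % slack,
followed by 30 minutes of unused pre-ictal data and a terminal annotated
seizure. Per-patient seeds come from `numpy.random.SeedSequence.spawn`, so
an identical spec yields a bit-identical cohort.

**What passing tests do and do not show.** The synthetic signals are
stationary correlated Gaussians; real SEEG is nonstationary, has 1/f
spectra, state-dependent synchrony, volume conduction and reference
effects, and its group structure is not two clean rectangles in feature
space. Tests passing on these cohorts demonstrate that the estimator
recovers known correlation structure through the full preprocessing chain,
that the classifier and permutation machinery behave correctly and are
calibrated under the null — not that comparable classification accuracy
would be achieved on patients.

## Numerical choices and problem sizes

- Frequency-domain filtering is circular; segments are long (≥ 18,000
  samples) relative to the filter's effective impulse response, so edge
  effects are negligible at the tolerances tested.
- `nearest_correlation` stops when the smallest eigenvalue is ≥ −1e−8
  (configurable) and errors with the residual after an iteration cap.
- Feature recovery tolerances follow the effective-sample-size bound
  SE ≈ (1 − ρ²)/√(2·B·T) with B = 45 Hz and T = 270 s.
- The test suite and the acceptance script run permutation tests at 200
  draws and classification-recovery checks over 50 seeded replicates of the
  default 12 + 11 cohort; null calibration uses 100 cohorts whose feature
  points are drawn from one distribution for both groups, since calibration
  of the permutation test is a property of the machinery downstream of
  feature extraction. The library default for a single analysis remains
  10,000 permutations.
- Reports serialise with sorted keys and no timestamps; identical config +
  seed reproduces byte-identical artifacts.

## Known limitations

- EDF ingestion requires uniform per-channel sampling rates and a complete
  channel→region map; annotations inside EDF files are not parsed.
- The spike-density heuristic in segment selection is amplitude-based only;
  it is not a spike detector.
- `group_region_pair_means` weights every patient equally regardless of how
  many contact pairs contributed to a region-pair entry.
- The permutation p-value is a Monte-Carlo estimate; with the plain
  count/n estimator, 0 means "below 1/n", not literally zero.
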