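# Methods

This note records the models, parameter choices and numerical decisions
behind `aidlog`, and what the synthetic-data tests do and do not show about
real manufacturer datalogs.

## Data model

A snapshot is one device at one fitting visit.  The canonical schema fixes
the audiogram panel at {250, 500, 1000, 2000, 3000, 4000, 6000, 8000} Hz —
the standard 8-frequency clinical panel — with thresholds in [−10, 120]
dB HL and missing values allowed; the input-SPL histogram at 12 ordered
bins ("<40", then 5-dB ranges, ">90" dB SPL); and the acoustic classes at
{quiet, noise, speech} (other class sets are rejected rather than merged).
Proportions are stored as read; only the simulator quantizes.  On disk a
dataset is UTF-8 CSV with a header row and empty cells for missing values;
`(device_id, session_seq)` is unique and `session_seq` is a global
chronology.  Proportion sums may exceed 1 by at most half an ULP at two
significant figures per bin (0.06 for the 12-bin histogram, 0.015 for the
three acoustic classes).

Mean input SPL, where needed and not logged, is the proportion-weighted
mean of bin representatives 37.5, 42.5, …, 87.5, 92.5 dB, renormalized by
the proportion sum.  The open-ended bins use representatives 2.5 dB beyond
their edge, mirroring the closed bins' midpoints; this is a declared
convention, since a histogram cannot identify the mean level within an
unbounded bin.

## Cleaning

Primary rules: drop snapshots with ≤ 7 days since the last visit, and drop
snapshots whose stored proportion sum in *either* the SPL histogram *or*
the acoustic classes is below 0.9 (OR semantics — both modalities must look
like adequate usage).  Removals are attributed to the first rule that
fires, so report counts always balance.  A tolerance of 1e-9 guards the
0.9 boundary against float summation noise: a stored sum of exactly 0.90 is
retained.  Missing `days_since_last_visit` is *not* treated as short usage
(absence of the field is not evidence).  Secondary rules — complete
audiogram, per-analysis predicates such as "style == BTEa", latest snapshot
per device — are separate composable operations; all cleaning ops are pure
row subsets, hence idempotent and order-commutative.

No imputation is attempted: the pipeline follows an aggressive-preselection
philosophy, trading size for reliability.

## Loan-device detection

Only consecutive snapshot pairs (by session order within a device) are
compared; the rule is improvement (previous − current threshold) ≥ 15 dB at
≥ 3 of the 8 frequencies with the later visit's days-since-last-visit
strictly inside (7, 60).  Both window edges are strict.  Style rates are
compared pairwise with two-sided Fisher exact tests, deliberately
unadjusted for the small number of style pairs — a caveat, not an
oversight: with 15 pairwise tests, one nominal rejection at α = 0.05 is
expected under the global null.

## Audiogram-shape clustering

Calibration subtracts the 250-Hz threshold, making the 250-Hz coordinate
exactly 0 and the others "dB (calibrated)" — possibly negative where high
frequencies are better than 250 Hz.  K-means uses plain Euclidean distance
on the calibrated 8-vectors with no per-dimension weighting (no weighting
scheme is better motivated), k-means++ seeding, and the best of 20 restarts
by within-cluster sum of squares; clustering is stochastic, so the restart
count and seed are part of the model object.

The low-frequency screen keeps PTA(250, 500) strictly below 20 dB HL.  The
boundary is exposed (`strict=False` gives ≤) because "below 20" and "not
exceeding 20" are both defensible readings of the screening idea; the
strict form is the default.

A *notch* in a cluster center is scored as
`depth = max(center[3k, 4k, 6k]) − max(center[2k], center[8k])`, i.e. the
excess of the worst mid-high-frequency loss over the better flank, with a
10 dB default criterion.  The threshold is a package choice (no canonical
definition exists) and is a parameter.

## Sparse-GP fitting-anomaly detection

The regression direction is y = mean input SPL on x = fraction of time
directional, restricted (as a rule-(iv) predicate) to the BTEa style, the
only modeled style with directional microphones in the synthetic
population.  Zero-directionality snapshots are retained by default;
excluding them is a flag.

The model is a sparse variational GP regression with the collapsed
(Titsias) bound: 100 inducing inputs fixed at equally spaced quantiles of
x (deduplicated, always inside the observed range), kernel
`lin_var·x·x′ + rbf_var·exp(−(x−x′)²/2ℓ²) + bias_var`, Gaussian noise.
The five hyperparameters are optimized in log space by L-BFGS-B with
finite-difference gradients (bounds e^±15, lengthscale in [0.01, 10];
initialization splits the centered-y variance between the linear and RBF
terms, ℓ = 0.2).  Inducing locations are *not* optimized: with 1-D inputs,
100 quantile-placed points already saturate the bound, and tests verify
sparse predictions match a dense GP with the same kernel to well under the
0.5 dB tolerance.  y is centered internally (the offset is restored at
prediction); a y with zero variance is rejected as degenerate.  Cholesky
factorizations carry a relative jitter of 1e-8 on the inducing Gram matrix.

z-scores use the *predictive* standard deviation (latent variance plus
observation noise), since observed values are being scored.  The outlier
band is |z| > Φ⁻¹(0.999) ≈ 3.0902, i.e. the central 0.1 %–99.9 % interval;
under a correctly calibrated model 0.2 % of draws are flagged, and the
package verifies this on data simulated from its own fitted predictive
distribution.  The z histogram clips at ±10 with end bins absorbing
overflow.

## Subgroup discovery

Dimension subsets are enumerated exhaustively (2^d − 1 per ordinal
modality, 1 for categorical), ordered by size then position.  Each ordinal
subset is re-clustered by K-means with k = 5 (best of `n_starts`, default 2
— the 5-cluster quantization is deliberately coarse, so extra restarts buy
little); categorical modalities use their categories as clusters.
Re-clustering per subset (rather than fixing one clustering per modality)
matches the subset-specific centers the results report.  Clusterings are
cached per modality since they do not depend on the partner modality.

The cell test is a one-sided binomial tail: cell count under independence
is Binomial(N, rowTotal·colTotal/N²), p = P(X ≥ observed).  Testing single
cells rather than whole tables is what makes the Bonferroni accounting
multiply by kA·kB.  The effect size is the lift observed/expected, exposed
as a pluggable scorer.  A subgroup is reported iff p < α/total_tests and
lift ≥ 1.1; share flags mark subgroups below (`*`) or above (`#`) 0.1 of
the population, and `+` marks lift > 1.1.

Full enumeration is refused beyond 2²⁰ cells (the audiogram × SPL pairing
at 26 105 625 tests needs ~10⁶ K-means fits and is out of desk-scale
reach); a uniform subset-sampling mode exists but is off by default, and
the Bonferroni denominator always counts the full search.

A caution on reading the output: the *maximum* reported lift over a
122 850-cell search is upward-biased by selection (winner's curse), so the
package reports all surviving subgroups ranked by lift rather than only the
champion, and recovery of a planted association is assessed at the
truth-matched cell, not at the maximum.

## Style prediction

Stratified 10-fold CV (the stratification is a package choice; plain
k-fold would starve rare styles) of a Random Forest with 50 trees, Gini
impurity, and either unbounded depth or the depth-4 variant.  Features are
the 12 stored SPL proportions; the confusion matrix pools out-of-fold
predictions.  The region heatmap walks every tree; every leaf whose
majority class is the target style contributes its training-sample count as
weight to the grid cells (12 dimensions × 50 equal-width bins on [0, 1])
overlapped by its root-to-leaf interval per dimension; unsplit dimensions
span [0, 1].  The accumulation rule (leaf sample count) is a package
definition; the map is normalized to max 1 and is invariant to tree and
fold order.

## Synthetic datalog generator

The generator is the package's study population; its defaults are the
declared conditions under which all recovery properties are tested.

* **Population**: style probabilities (BTEa 0.55, BTEb 0.12, CIC 0.10,
  ITE 0.08, ITC 0.08, HalfShell 0.07) reflect a BTE-dominated fitted
  population with a custom-style minority; visits per device default to
  uniform 1–6 (the real visit distribution is unknown; this is a declared
  assumption).
* **Audiograms**: three archetypes — presbyacusis-like slope
  (20→65 dB HL, weight 0.55), flat moderate loss (~30–40 dB, 0.30), and an
  NIHL notch (good low frequencies, 45–50 dB at 3–4 kHz, recovery at 8 kHz,
  0.15) — with diagonal Gaussian spread (5–6 dB), clipped to [−10, 120] and
  rounded to 5-dB steps; per-visit test–retest noise of 2.5 dB.  The notch
  archetype has low PTA(250, 500), so PTA screening enriches it: that is
  the mechanism behind the screening-reveals-notch property.
* **Acoustic demand**: three latent profiles (quiet/moderate/loud) with
  Dirichlet concentration 60×mean; a planted association raises
  P(profile | style) so its lift over the realized population marginal hits
  the configured value (default CIC×loud at 1.5), solved by fixed-point
  iteration because the boost moves the marginal it is measured against.
  Because histograms depend on style only through the latent profile, any
  histogram-derived clustering has cell lift bounded by the planted lift,
  which is what makes ±0.15 recovery well-posed.
* **Directionality link**: for BTE styles,
  x = 0.5 + 0.015·(mean SPL − 65) + N(0, 0.05), clipped to [0, 1]
  (directionality responds to the environment; in-ear styles log 0).
  Planted outliers (1 % of BTEa snapshots) get a decoupled x resampled from
  other snapshots' link values, rejection-sampled until the pair deviates
  from the link-implied conditional mean of y given x by ≥ 5 link noise-sd
  in dB (noise-sd_y = 0.05/0.015 ≈ 3.3 dB).  Outliers are planted inside
  the observed x support; a deviation planted where the model has no other
  data would simply be fitted, making sensitivity meaningless.
* **Loans**: 8 % of BTE devices with ≥ 2 visits switch wearer once; the new
  wearer's audiogram is rejection-sampled until the *measured* switch pair
  satisfies the detection rule, and the switch visit's day gap is drawn
  strictly inside (7, 60).  Loan devices are exempt from audiogram
  missingness so the planted signal is always observable after the
  complete-audiogram cleaning step.
* **Dirt**: 6 % of visits are short-usage (≤ 7 days); 2 % of records are
  scaled by U(0.40, 0.85) before storage so their proportion sums fall
  strictly below 0.9; all stored proportions are rounded to two significant
  figures, half to even.  Gain reductions couple to low-/high-SPL occupancy
  with Gaussian noise; the logged mean-SPL field is the histogram mean plus
  0.3 dB noise.
* All randomness flows from a single seeded `numpy` generator; default seed
  20180531.

**What the generator does not emulate**: real datalogs have calibration
drift, pinna-diffraction differences between styles, classifier errors,
left/right ear correlation, demographic covariates, and loan practices far
messier than a single clean wearer switch.  Passing recovery tests shows
the *methods* are correctly implemented and statistically calibrated under
a known mechanism — not that real data would yield the same rates, shapes
or subgroups.

## Problem sizes

Recovery properties are exercised at sizes chosen to make their error
bands meaningful on a single CPU: ~2000 BTE devices for loan rates (3
binomial sd ≈ 1.8 percentage points), ~10 000 BTEa snapshots for GP
sensitivity with ~100 planted outliers, 50 000 self-simulated draws for
band calibration, ~20 000 devices for the full 122 850-test subgroup
search, 200 permutation replicates at n = 5000 for family-wise error, and
~7000 audiograms for the k = 11 clustering contrast.

## Known limitations

* The binomial cell test treats margins as fixed; for very small cells a
  hypergeometric test would be slightly more exact.
* Inducing inputs are not optimized (see above); with multi-modal 1-D
  inputs this is saturating, but the choice would matter in higher
  dimensions.
* The subgroup engine's lift is the only built-in effect size; the scorer
  hook exists for alternatives.
* Fisher style comparisons are unadjusted; interpret marginal p-values
  near α accordingly.
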