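# Methods

This note documents the models, estimators and numerical choices behind
`plastox`, and what the synthetic-data generators do and do not emulate.

## Rank-based differential expression

Expression values are rank-normalized per sample: the highest expressed
gene receives rank N (the number of genes), the lowest rank 1, and all
ranks are divided by N, giving values in (0, 1].  Ties receive the
average of the tied integer ranks, which keeps the per-sample mean rank
at (N+1)/2N regardless of ties.  The per-gene differential value
(SubDiff) is the difference of mean normalized ranks between case and
control samples, bounded by [−1+1/N, 1−1/N]; with one sample per group
it reduces to a plain rank difference.  DE genes are called by
standardizing the SubDiff vector across the genes of the profile
(subtract the mean, divide by the n−1 sample SD) and thresholding at
|Z| > 1.5 (configurable).  Standardizing within the profile is the only
self-contained choice of reference population; near-degenerate profiles
(SD at float-roundoff scale) are rejected.

Probe-to-gene collapsing keeps, per gene, the probe maximizing either
mean intensity or mean normalized rank (two conventions used for
transcriptome backgrounds and rank profiles respectively); criterion
ties keep the first probe in input order for determinism.  Unmapped
probes are dropped and counted.  An optional two-column ortholog table
maps identifiers before set operations; the default is identity.

## Enrichment screens

Chemical gene-set libraries are built from deduplicated
(chemical, gene, direction) records: the *composite* library takes the
union of a chemical's increased and decreased genes; the directional
libraries split them.  Both apply a 3–2500 gene size filter, the
directional ones after splitting, so a chemical can survive in one
direction only (or neither).

All overlap tests are upper-tail hypergeometric probabilities
P(X ≥ k) with population N = |universe|, successes |A| and draws |B|.
The universe is the intersection of the assay transcriptome and the
genes annotated to any chemical; set members outside the universe are
dropped before testing because the hypergeometric model requires
set ⊆ population.  The odds ratio is the sample OR of the 2×2 table,
(k·d)/(b·c) — not the conditional MLE; at printed precision the two
are indistinguishable, and the sample OR is reproducible without an
iterative solver.  The Pb/LPS-style shared-gene association uses the
two-sided Fisher exact test on the same table.

The directional reversal screen pools its two families (chemical-down ×
signature-up, chemical-up × signature-down) into a single
Benjamini–Hochberg family: pooling is symmetric and, if anything,
conservative for either family alone.  Rows are ranked by adjusted p
with alphabetical tie-breaks, significant at p_adj < 0.05.  BH and Holm
adjustments are delegated to statsmodels.

Because the hypergeometric p is discrete it is super-uniform under the
null; the test suite checks exact uniformity of its randomized
counterpart P(X > k) + U·P(X = k), the statistically correct version of
"null p-values are uniform".

## Molecular matching

The match score of a differential profile against a gene set is
M = Σ SubDiff(g) over the profile's genes inside the set; M < 0 means
the profile decreases the set's genes.  The permutation null shuffles
gene labels, equivalently sums a uniform random subset of profile
values of the observed overlap size (O(n·k), n = 10,000 permutations by
default, RNG fully determined by the seed).  The normalized score
divides the centered M by the n−1 permutation SD.  Z is invariant under
affine rescaling of the profile, since the null is built on the same
profile.

Tail p-values: when at least 10 permutation scores are as extreme as M,
the empirical estimator (k+1)/(n+1) is used.  Otherwise the 250 most
extreme permutation scores beyond a midpoint threshold are fit by
maximum likelihood to a Generalized Pareto Distribution and
p = (N_exc/n)·GPD_tail(M); the goodness of fit is checked by a
parametric-bootstrap Anderson–Darling test (B = 249, α = 0.05) — a
bootstrap rather than tabulated critical values, trading a little CPU
for not depending on a transcription of published tables — and the
exceedance count is halved on failure, down to 30, before falling back
to the empirical estimator.  The returned p is clamped to (0, 1].

Sidedness: the p is one-sided.  With `alternative="auto"` the tail is
chosen by the observed deviation, the natural report for a single
observed score.  A screen with an a-priori direction (e.g. "does this
exposure suppress the plasticity-elevated genes") should fix
`alternative="less"` or `"greater"`; only then is the p uniform under
the null and the type-I error equal to α.  A collection of normalized
scores (e.g. one exposure across many tissues) is compared to N(0, 1)
by a one-sample two-sided KS test to detect a shared skew.

## Ocular dominance electrophysiology

Peristimulus histograms use configurable windows, defaulting to a
[−500, 0) ms baseline, a [0, 500) ms response window and 25 ms bins
(these are not universal constants; they are explicit so summaries are
reproducible).  Baseline is the mean pre-stimulus rate; peak is the
maximum trial-averaged binned rate, which is upward-biased by max
selection — the simulation tests account for that.

ODI = (E_ipsi − E_contra)/(E_ipsi + E_contra) on baseline-subtracted
peaks, clamped to [−1, 1] only when a single-eye evoked rate is
negative; neurons with nonpositive summed evoked response are excluded
as unresponsive and counted in a QC report.  Animal-level QC (minimum
cells per animal) is a configurable filter.  The ODS bins are
[−1,−0.5)→1, [−0.5,−0.3)→2, [−0.3,−0.1)→3, [−0.1,0.1]→4, (0.1,0.3]→5,
(0.3,0.5]→6, (0.5,1]→7 (closed center bin), and
CBI = [(n1−n7) + ⅔(n2−n6) + ⅓(n3−n5) + N]/2N ∈ [0, 1], which satisfies
CBI(counts) + CBI(reversed) = 1 exactly.  The spontaneous-to-evoked
ratio is operationalized as the dominant eye's baseline over its peak
(the dominant eye being the one with the larger evoked response).

Group comparisons: animal-level t test on CBI (one-sided when the
direction is hypothesized a priori), neuron-level χ² on the 2×7 ODS
count table (all-zero columns are dropped, which is numerically
identical to merging a zero bin into its neighbor), and a neuron-level
two-sample KS test on ODI.  The hierarchical model is a linear mixed
model of neuron-level ODI with the four group × experience cell means
as fixed effects and a random intercept per animal (no random slopes —
nothing in the design identifies them), fit by REML via statsmodels
MixedLM; this module's contract is the model specification, the
pairwise cell contrasts on the fixed-effect (least-squares) means with
Wald z tests, and Holm adjustment.  Boundary fits with a non-PSD
covariance yield flagged NaN contrasts rather than a crash; a singular
fit suppresses contrasts entirely.  Wald-normal intervals on few
animals are mildly anticonservative; the parameter-recovery tests
measure the realized coverage (≈92% nominal 95% at 6+3 animals).

## qPCR

Technical replicates are averaged per (sample, gene); ΔCT subtracts the
geometric mean of the two reference genes' mean CTs, taken on the CT
scale as is conventional in the two-reference formulation (an
arithmetic-mean switch exists; at realistic CTs near 20 the two differ
by far less than replicate noise).  Samples missing a reference are
dropped with a warning; targets flagged for poor amplification are
discarded.  Per gene, ΔCT is regressed on group, recording status and
their interaction (treatment coding, control/not-recorded reference);
when recording status does not vary the covariate is omitted and the
estimator reduces exactly to the difference of group mean ΔCTs.  The
negated group coefficient is the −ΔΔCT ≡ log2 fold change, with t-based
confidence intervals and BH adjustment across the panel.  A
rank-deficient design (e.g. recording status confounded with group)
raises an error naming the aliased terms.

## Synthetic data

The generators emulate the statistical structure of the study
conditions; one seed makes every output byte-identical, with
independent streams per generator.

* **Expression**: log-normal intensities (log2 base N(8, 2²), replicate
  noise SD 0.5), 3 case vs 3 control samples, 50 planted DE genes with
  an additive ±4 log2 shift.  Planted genes are drawn from the central
  90% of baseline intensity: a rank-based caller cannot register an
  upward shift of a gene already at the top rank, so tail planting
  would put unrecoverable entries in the truth table.  Even so, rank
  saturation near the band edges caps recovery at ~44–48 of 50.
* **Chemical table**: per-direction set sizes log-uniform in [10, 300]
  for 100 decoys; each planted reverser has 60 down-genes of which a
  stated fraction (0.5 by default) comes from the 80-gene up-signature,
  inside a 10,000-gene pool.  The realized screening universe is the
  chemically-annotated subset of that pool (~8,000 genes), by the
  method's own background rule.
* **Cohort**: 3/6/5/5 animals (control-noMD / control-MD / Pb-noMD /
  Pb-MD) with Poisson(28.8) neurons each (min 10), mirroring the
  validation cohort sizes.  Neuron ODI is truncated-normal with cell
  mean = −0.2 baseline, +0.28 under deprivation, of which exposed
  animals retain 57% (matching the deprivation and residual-plasticity
  contrasts the model targets), animal SD 0.05, neuron SD 0.25.
  Evoked rates are back-computed from the planted ODI (fixed summed
  evoked rate, gamma-distributed spontaneous rate with a higher mean
  under exposure), so `compute_odi` round-trips the planted ODI exactly
  in the noise-free limit.  Optional Poisson spike trains feed the PSTH
  path.
* **qPCR**: reference CTs ~ N(20, 0.2²); target CT = reference
  geometric mean + per-gene baseline ΔCT + group·ΔΔCT + N(0, 0.2²)
  noise, three technical replicates (SD 0.05); planted ΔΔCT +0.6, +0.51
  and −0.92 on three of five panel genes; 8 exposed vs 6 control
  samples with recording status varying within both groups so the
  covariate is estimable.

What the generators do **not** emulate: probe-level microarray noise
models and background correction, chemical synonym structure and the
real database's heavy-tailed set sizes beyond the log-uniform range,
correlated gene modules, electrode drift or spike-sorting artifacts,
and qPCR efficiency differences.  Passing tests therefore demonstrate
the estimators' correctness and calibration under the assumed
statistical structure, not robustness to those real-data artifacts.

## Numerical and design notes

* Chemical-name filters match case-insensitively and exactly; synonym
  resolution is out of scope.
* Hypergeometric/Fisher/KS/χ²/t machinery comes from scipy; BH/Holm
  from statsmodels; the GPD fit from scipy's `genpareto` MLE.
* p-values are clamped into (0, 1] where extrapolation could underflow.
* All screen tables carry (k, |A|, |B|, N, OR, p, p_adj, rank) so any
  row can be re-derived by hand.
* Simulation problem sizes in the tests and the acceptance script
  (2,000-permutation nulls, 25–200 replicate recovery loops) are scaled
  to give stable calibration estimates while keeping a full run in the
  order of minutes on one CPU.

## Known limitations

* The GPD branch's bootstrap goodness-of-fit check costs a few seconds
  per extreme score; batch screens over thousands of profiles would
  want the tabulated-critical-value variant.
* Mixed-model inference uses Wald z on the fixed effects; no
  Satterthwaite/Kenward–Roger small-sample correction is applied.
* The hierarchical model fits a random intercept only; designs with
  within-animal stimulus structure would need richer random effects.
* Empirical p-values are bounded below by 1/(n+1); only the GPD branch
  extrapolates beyond the permutation resolution.
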