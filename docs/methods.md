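# Methods

This note documents the statistical model behind each pipeline stage, the
design choices made where more than one reasonable option existed, and what
the synthetic cohorts do and do not establish about behaviour on real
array data.

## Data model and transforms

All stages operate on the methylation fraction β ∈ [0, 1] per probe and
sample. Linear modeling uses M = log2(β/(1−β)), which is approximately
homoscedastic across the methylation range; β is clipped to
[ε, 1−ε] with ε = 10⁻⁶ before the logit so boundary values stay finite
without materially moving interior values. Effect sizes are always
reported on the β scale (a Δβ of 0.10 is a 10 % methylation difference);
p-values always come from the M-scale model. Missing β propagates as
missing; probes with missing values are not removed automatically.

Probe filtering removes, in order: sex-chromosome probes (their
methylation reflects sex and X-inactivation, not disease), probes with
detection p > 0.01 in **any** sample (the strictest reading; common
practice and deterministic), SNP-overlapping probes and cross-reactive
probes. The filter report attributes each removed probe to the first
criterion it fails, so counts always sum to the input probe count, and the
filter is idempotent.

## Matched-control selection and outlier iteration

Controls are selected greedily, one case at a time in lexicographic id
order, without replacement: candidates must match the case exactly on sex
and array type, and the `ratio` (default 2) candidates nearest in z-scored
age are taken, ties broken by control id. Greedy nearest-neighbour
matching is the default behaviour class of the standard matching tools and
is fully reproducible; optimal (network-flow) matching is out of scope. A
case with missing age matches on the exact covariates only, with a logged
warning.

After each matching round the combined case+control M matrix is embedded
with PCA (probes centered; deterministic sign convention: the
largest-magnitude loading of each component is made positive). Samples
deviating more than k = 3 robust SDs on PC1 or PC2 are flagged, flagged
controls are removed from the pool, and matching repeats until clean. The
loop terminates because the pool strictly shrinks.

Two refinements to the flagging rule matter in practice:

- **Within-group deviations.** A genuine episignature is a coherent
  direction in probe space, so cases and controls occupy different regions
  of the top components whenever the signature variance is comparable to
  the global structure. Deviations are therefore taken from each sample's
  *own group median*; otherwise the minority group itself would be flagged
  wholesale. The scale (MAD, and see next point) is pooled over all
  within-group residuals so a small case group does not produce a noisy
  scale estimate.
- **Scale = max(robust SD, plain SD).** 1.4826·MAD is immune to gross
  outliers but underestimates the spread of mildly heavy-tailed or mixed
  distributions, which produced sporadic ≈3.0-SD false flags. The plain SD
  of the within-group residuals covers that case, while a genuinely
  aberrant sample (a 10-SD global shift) still lands far beyond k on its
  own principal axis, since one such sample inflates the SD of n samples
  only by ≈√(1+z²/n).

Cases are never removed automatically — they are a curated clinical set —
but a case flagged in an embedding with no removable control aborts with
an error for the operator. When both cases and controls are flagged in the
same round, the controls are removed first and the cases re-examined in
the next, cleaner embedding.

## Moderated differential methylation

Per probe, ordinary least squares of M on an intercept and a case
indicator gives the group contrast (equal to the difference of group
means) and a residual variance s² on d = n−2 degrees of freedom. The
variances are shrunk toward a scaled-inverse-χ² prior with df d₀ and scale
s₀², estimated by method of moments on z = log s²: with
e = z − ψ(d/2) + log(d/2), the excess of Var(e) over ψ′(d/2) identifies
ψ′(d₀/2) (inverted by Newton iteration), and the mean of e identifies s₀².
If the empirical variance does not exceed the theoretical sampling
variance the prior is degenerate (d₀ = ∞) and all probes share s₀². The
moderated statistic is t = Δ/√(s̃²(1/n₁+1/n₀)) with
s̃² = (d₀s₀² + d s²)/(d₀+d), referred to a t distribution on d+d₀ df
(normal when d₀ = ∞). Zero-variance probes are excluded from the moment
fit but still receive a finite moderated variance. With d₀ = 0 the
ordinary pooled two-sample t is recovered exactly, which the tests assert
to machine precision. The implementation agrees with the reference
empirical-Bayes implementation in the Bioconductor ecosystem to ~10⁻¹⁵ on
toy fixtures.

## Three-step probe selection

1. Keep the `n_top_product` (default 500) probes with the largest
   |Δβ| · (−log₁₀ p_BH). The absolute value is required: with a
   hypomethylation-dominant signature a signed product would rank hypo
   probes last. The log base is irrelevant to the ranking (positive scalar
   multiple), base 10 is used by convention; p_BH is floored at the
   smallest positive double before the log.
2. Keep the `n_top_auroc` (default 250) of those with the highest AUROC,
   computed by the rank-sum identity with half-credit ties and reflected
   to max(a, 1−a) so hypo- and hypermethylated probes compete equally.
3. Greedy correlation pruning in step-2 rank order: a probe is dropped if
   its Pearson r with any already-retained probe strictly exceeds `r_max`
   (default 0.85) within the case samples **or** within the control
   samples. Keeping the earlier-ranked member of a correlated pair is the
   deterministic choice.

Ties at every cutoff break by probe id, making selection reproducible and
invariant to input row order. The signature stores per-probe statistics
and the case/control reference mean β profiles used later for projection
and imputation; provenance records parameters, an input hash and the seed
(no timestamp — artifacts are byte-identical across reruns by design).

## Unsupervised validation

Ward-linkage clustering on Euclidean distances over signature-probe β is
cut at two clusters and scored against the labels by majority mapping.
MDS is classical (Torgerson) scaling — eigendecomposition of the doubly
centered squared-distance matrix — because that is what "scaling of the
pairwise Euclidean distances" means; it reproduces any configuration that
is exactly 2-D up to rotation/reflection, which the tests assert at 10⁻⁸.

Leave-one-out validation re-derives the signature from scratch in every
round (selection on the remaining cases vs the fixed controls); reusing
the full-data signature would leak the held-out sample into probe
selection. The held-out case is assigned to the nearer group centroid in
the round's signature-probe β space — a deterministic surrogate for the
visual "clustered with the training samples" judgement.

One calibration subtlety: under a **null** signal the centroid rule is not
unbiased when group sizes differ. Probes are selected to maximize apparent
separation of the training groups, and the smaller group's centroid
carries the larger chance offset (variance σ²/n_case vs σ²/n_control), so
with 1:2 controls the held-out case is systematically assigned "control"
and null accuracy falls below 0.5. Null calibration is therefore checked
at equal group sizes, where accuracy is binomially consistent with chance
(50/104 rounds, p = 0.77). On strong-signal data the bias is irrelevant —
all rounds are correct.

## MVP classifier

A linear SVM on β at the signature probes, cases vs negatives. Cost is
selected from {10⁻³, 10⁻², 10⁻¹, 1, 10} by stratified k-fold CV accuracy
(k = 10, reduced to the minority class size when necessary), ties going to
the smallest cost (strongest regularization). Classes are weighted
inversely to size because the specificity design (dozens of cases vs a
thousand-plus negatives) collapses an unweighted SVM to the majority
class. The 0–1 MVP score is a Platt sigmoid 1/(1+exp(A·d+B)) fit on
**out-of-fold** decision values with the standard smoothed targets, so the
calibration never sees a margin produced by a model trained on the same
sample; A < 0 is enforced so the score increases with the margin. Scoring
a new sample mean-imputes up to 5 % missing signature probes from the
training means and fails beyond that. The specificity variant adds
other-disorder cohorts to the negative class and reports per-cohort score
distributions.

## DMR calling

All testable probes are sorted per chromosome and split wherever the gap
between consecutive probes exceeds 1 kb ("within 1 kb" read as a
consecutive-gap rule, as density-based region growers do; a span-capped
mode is one flag away). Clusters with ≥ 3 CpGs are candidates; each gets a
Fisher-combined p (−2Σln p against χ² with 2k df) over its member probes'
moderated p-values, BH-adjusted **across clusters**; candidates with
|mean Δβ| ≥ 0.10 and adjusted p < 0.01 are reported, sign preserved so
hypo- and hypermethylated regions remain distinguishable. The
combined-then-corrected reading is the simplest faithful interpretation of
a per-region Fisher criterion; kernel-smoothed region statistics are a
non-goal.

## The synthetic cohort generator

The simulator reproduces the features of Infinium-style array data that
the pipeline's statistics actually rely on:

- **Bimodal baseline.** Per-probe mean β from an equal-weight two-component
  Beta mixture with modes near 0.1 and 0.85.
- **Logit-scale noise.** Per-sample jitter of SD 0.25 on the M scale,
  mapped back through the inverse logit so β stays in (0, 1).
- **Global-structure latent factors.** Two shared factors whose projected
  sample-score SDs (40 and 28 M-units) dominate the top principal
  components, the way batch and cell-composition variation do on real
  arrays; without them a spiked signature owns PC1 and the outlier
  iteration cannot be exercised as designed. Factor scores are truncated
  at 2 SD so a clean cohort produces no spurious flags at the 3-robust-SD
  threshold. A small array-type batch shift (0.05) is added on top.
- **Spiked DMPs.** Exactly round(0.87 · n) of the n spiked probes are
  hypomethylated in cases (deterministic allocation, so tests can assert
  exact counts); effect sizes are drawn around Δβ = 0.18 and the baseline
  is re-anchored so the nominal effect is realizable within [0, 1].
- **Planted DMRs.** Regions pack a configurable number of CpGs within
  800 bp on one chromosome; background probes are laid 5 kb apart so only
  planted regions form 1 kb clusters. An explicit per-region
  (n_cpgs, Δβ) plan supports sub-threshold regions for boundary testing.
- **Covariates and failures.** Age uniform on 2–40 years, sex 50/50, array
  type 80/20 EPIC/450k; detection p-values near zero with a 0.2 % failure
  rate hitting one random sample each; optional globally shifted outlier
  samples (magnitude × per-probe SD on the M scale).

One integer seed drives every stage through independently spawned
substreams; identical configuration gives bit-identical cohorts.

Default study conditions mirror the discovery design the package targets:
41 cases, a 200-sample control pool (1:2 matching), 300 spiked DMPs with
the 87/13 direction mix, 20 000 probes. The full ~850 k-probe array is
emulated at reduced width because every statistic involved is per-probe or
rank-based; 20 000 probes preserve the multiple-testing and selection
behaviour at a size where the whole discovery runs in seconds. Unit tests
use 1 500–8 000-probe cohorts.

**What the simulator does not model** — probe-type (Infinium I/II)
chemistry bias, raw intensity channels and background correction,
cell-composition heterogeneity, age- or sex-dependent methylation drift,
and spatial autocorrelation outside planted regions. Passing tests
therefore demonstrate that the pipeline's logic and statistics behave as
specified under a faithful abstraction of array data, not that any
particular clinical signature would be recovered from a given real
cohort; with independent per-probe noise the spike-in recovery rates here
are upper bounds on real-data behaviour.

## Numerical and degenerate-input conventions

- BH adjustment is the standard step-up with capping at 1, in input order.
- p-values of exactly 0 are floored at the smallest positive double before
  logs (product score, Fisher combination) with a warning where relevant.
- NaN correlations from constant probes never trigger pruning.
- PCA/MDS axis signs follow a largest-element-positive convention so
  embeddings are deterministic.
- An all-constant matrix is a zero-variance error for PCA; all-equal
  distances yield all-zero MDS coordinates with a warning.
- The 2-cluster cut, the centroid rule and the SVM all operate on β, where
  the signature's reference means are defined; the choice is recorded in
  the model file and could be flipped to M without changing any interface.
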