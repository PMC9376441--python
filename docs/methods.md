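# Methods

## Study design the package assumes

The analysis targets a four-site maternal cohort (labelled DRC,
Guatemala, India, Pakistan) with stool microbiota profiled at 12 and 34
weeks of gestation under a three-arm nutrition-trial design. Arm 1
starts a lipid-based supplement before the first visit, Arm 2 between
the visits, Arm 3 never. Microbiota sampling begins after arm
assignment, so Arm 3 contributes no 12-week samples anywhere, and the
India-like site has no Arm 3 at all. Because arms cannot be compared
directly at 12 weeks, the design variable used in all models is
*supplement status*: 1 for (Arm 1, week 12), (Arm 1, week 34),
(Arm 2, week 34); 0 for (Arm 2, week 12) and (Arm 3, week 34). Time is
coded 0/1 for 12/34 weeks, so every coefficient is a per-pregnancy
(12→34-week) contrast. Every model additionally adjusts for sequencing
batch and standardized (z-scored) read depth.

## Filtering

Libraries need ≥ 3,700 reads (inclusive: "minimum" is read as the
smallest admissible depth). A genus is analyzed when it is present in
at least ⌈0.05 · n⌉ samples *and* exceeds 0.001 relative abundance
strictly in at least one sample, both evaluated on the full analysis
set rather than per site. The filter is applied at the analyzed (genus)
level by default; both thresholds are arguments. Filtering order and
boundaries are fixed so reruns are reproducible, and each filter emits
an audit report naming every removed sample/taxon and the rule that
removed it.

## Diversity

Alpha metrics are computed on unrarefied counts — depth is handled as a
model covariate, not by subsampling. Shannon H uses log base 2 (the
convention of the Explicet-style toolchain this mirrors); evenness
H/log₂(Sobs) is base-invariant and defined as 1 for ≤ 1 taxon. Chao1
uses the bias-corrected form S + F₁(F₁−1)/(2(F₂+1)) so it stays finite
without doubletons; the classic form is available by flag. Bray-Curtis
dissimilarity is computed on relative abundances (library depth in the
emulated study spans 3,983–406,259 reads); a raw-count mode exists for
comparison. PCoA is classical scaling of the Gower-centered −½D²
matrix; negative eigenvalues (the non-Euclidean part of Bray-Curtis)
are dropped and excluded from the variance-explained denominator, so
reported fractions refer to the representable (Euclidean) part.

## Per-site models

**Alpha diversity.** Gaussian GEE per site and measure with an
exchangeable working correlation over subjects and robust sandwich
standard errors; inference is Wald-z per term. Non-convergence is
flagged on the result and the fit is excluded from pooling — never
silently downgraded to OLS.

**Beta diversity.** The McArdle–Anderson pseudo-F is computed from the
Gower-centered matrix with sequential sums of squares, the tested term
entered last. "Adjustment for repeated measures" is implemented as
restricted permutations: testing *time* swaps the two visits within
each complete subject (subjects with one visit stay fixed — they carry
no within-subject contrast); testing between-subject terms permutes
whole subjects among subjects with the same visit pattern. Cross-
sectional screens use free permutations. p = (1 + #{F* ≥ F})/(1 + B).
When the design saturates the distance matrix (zero residual SS) the
statistic is treated as +∞ so maximal separation yields the smallest
attainable p rather than a 0/0. A Freedman–Lane-style residual scheme
was considered and rejected: restricted label permutation preserves
exactly the exchangeability that the repeated-measures adjustment
implies, at the cost of mild conservatism when nuisance covariates
carry real signal.

**Individual taxa.** Counts are modeled per genus with an NB2
negative-binomial GLM (log link, ML dispersion). Read depth enters as
the standardized covariate, matching the alpha models, rather than as
an offset (an offset mode can be had by dropping the depth term and
supplying an exposure). Significance comes from a cluster bootstrap:
subjects are resampled with replacement keeping both their samples, the
GLM is refit per replicate (warm-started at the full-data MLE), and
p = 2(1 − Φ(|mean*/sd*|)) on the replicate distribution of the
coefficient — the "mean equal to zero" test on the bootstrap
distribution. A percentile-tail alternative is available
(`pvalue_method="percentile"`). Failed refits are dropped and counted;
more than 20% flags the test unreliable. The resampling unit is the
subject, not the sample, because the GLM itself ignores the repeated
measures.

**Phyla.** Relative abundance of each major phylum is fit across all
sites with a linear mixed model (subject random intercept, batch fixed):
first the time × site interaction model, tested by Wald ANOVA; if the
interaction p ≥ 0.05 the additive model is refit and only significant
main effects are followed up. Pairwise follow-ups use Tukey
(studentized-range) adjustment on treatment-coded contrasts. A singular
random-effects fit falls back to fixed effects with cluster-robust
errors and is flagged.

**Outlier sensitivity.** Residuals from a converged alpha GEE define
fences Q₁ − 3·IQR / Q₃ + 3·IQR with quartiles by linear interpolation
(the numpy default; documented because the mask is boundary-sensitive
at small n). The model is refit once without flagged samples and both
fits are reported; a refit that loses a design level or too many
clusters is flagged degenerate instead.

**Cohort comparisons.** Baseline continuous characteristics use the
Welch unequal-variance t-test; ordered categorical distributions use
the Cochran–Armitage trend test with equally spaced scores by default.

**Biomarkers.** Inflammatory markers (AGP, CRP, MPO, calprotectin) are
log-transformed and modeled by GEE on time + supplement + site;
associations with each alpha measure add the biomarker to the standard
alpha model. Sites without measurements (the DRC-like site has no blood
collection) are skipped with a log entry. The exact test behind the
emulated study's biomarker time-trend is not specified upstream; the
GEE here is this package's choice and is validated only against its own
simulator.

## Covariate screening

Each candidate covariate is screened per (site, timepoint) with a
cross-sectional PERMANOVA of Bray-Curtis distances on the covariate,
adjusted for batch, regional cluster (when present), and supplement
status. A covariate survives for a site when any timepoint p is
strictly below 0.1. Survivors are pruned within site: pairwise Pearson
correlation on integer-coded values (level order for categoricals — a
documented simplification, since the upstream procedure does not say
how categorical pairs were correlated); |r| > 0.7 pairs are processed
in descending |r|, keeping the member associated in more sites, ties
broken by a configurable generality ranking whose shipped default puts
the composite SES indicator above its components. Batch and read depth
are always carried regardless of screening. The full decision sequence
is logged so a rerun is byte-identical.

## Meta-analysis

Per-term site estimates are pooled by DerSimonian–Laird: fixed weights
1/se², Q, τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)), random weights
1/(se²+τ²); REML is available by flag. The supplement-term meta
excludes any site with no supplement contrast at some timepoint — the
generalization of the India rule (all women supplemented at 34 weeks).
Beta-diversity p-values are combined by Fisher's method (−2Σln p,
χ²₂ₖ), treating sites as independent cohorts. FDR control is
Benjamini–Hochberg step-up at q = 0.05 (inclusive rejection), applied
independently within each (site, analysis-type) group, and within its
own group for meta-analytic p-values.

## The synthetic cohort

Two simulators share one design generator (site sizes, arm
assignment, visit schedule with the Arm-3 missingness, iid batch
labels, log-normal read depth with desk-scale median 10,000 — a
study-scale flag raises it to 96,064 — and subject-level covariates
including an SES composite with two deliberately collinear components).

*Direct-outcome path*: each alpha measure is drawn from the Gaussian
design model y = β₀(site) + β_t·t + β_s·s + batch + depth·z + subject
intercept + noise. Planted Shannon-H time effects are DRC −0.20,
Guatemala −0.25, India −0.20, Pakistan −0.21 — the three
meta-eligible sites average −0.22 — with a supplement effect of −0.08
everywhere; Guatemala additionally carries the stratified richness
(−2.13 Chao1) and evenness (−0.04) declines. Subject/residual noise
(0.40/0.25 for Shannon H, scaled analogues elsewhere) is a simulator
assumption, not an upstream value: it is sized so a 250-subject site
estimates its time contrast with SE ≈ 0.03, keeping the recovery
tolerances the test suite asserts at roughly three Monte-Carlo
standard deviations. These components are recorded in the truth
record.

*Count path*: a 30-genus panel is assigned to phyla and weighted so
each site's baseline composition matches the emulated phylum table
(e.g. Firmicutes 56%, Bacteroidetes 27% for the DRC-like site at 12
weeks) with Prevotella the most abundant genus. For each (site, time,
supplement) cell, targeted genera are *pinned*: their relative
abundance changes by exactly the planted log-fold effect (Prevotella
+0.326 in Guatemala; unclassified Ruminococcaceae −0.442 in DRC and
−0.389 in Guatemala; unclassified Lachnospiraceae −0.236 and Blautia
−0.2 in Guatemala; Christensenellaceae −0.7 at every site — the
Blautia value is a package choice for a decline reported without a
printed coefficient). The untargeted remainder is then
temperature-scaled (a monotone softmax root-search, solved to 1e-6
bits) so each cell's expected Shannon H reproduces the planted
diversity contrasts. Per sample, the cell composition is perturbed by
subject-level (sd 0.30) and batch-level (sd 0.10) per-genus log
effects — and by a planted SES composition confounder at the DRC-like
site only, used to validate covariate screening — then drawn through a
Dirichlet layer (concentration 300) and a multinomial at the sample's
depth. Biomarkers are log-normal with the emulated per-site means/SDs
(AGP declining ≈ 35% over pregnancy) and absent at the DRC-like site.

What the simulator does *not* emulate: dropout between visits,
phylogenetic correlation between genera, zero-inflation beyond what the
Dirichlet-multinomial produces, true rank-abundance tails (30 genera
vs. hundreds of OTUs), or covariates that genuinely confound the time
effect. Passing recovery tests therefore demonstrate correctness of the
estimators under the assumed data-generating process, not robustness to
every feature of real cohorts.

## Problem sizes and numerical choices

The shipped validation runs at desk scale — chosen as this package's
standard verification configuration: 250 subjects/site for the
direct-outcome recoveries (10 seeds), 300 subjects/site for count-level
recoveries, B = 1,000 bootstrap for significance claims, and
null-scenario calibrations of 200 simulations with B = 200 and 200
permutations at 100–250 subjects. Child seeds always derive from one
base seed through `numpy.random.SeedSequence`, which keeps streams
independent and every run reproducible; fixed small-integer seed blocks
are avoided for recovery checks because adjacent low seeds showed a
correlated ~2σ fluctuation worth knowing about when debugging.
Degenerate cases are handled explicitly: saturated PERMANOVA designs
(F = +∞), all-zero count vectors (errors), constant depths (errors),
singular mixed models (flagged fixed-effects fallback), bootstrap
refit failures (dropped, counted, unreliability flag past 20%).

## Known limitations

* The GEE sandwich covariance is anticonservative below ~100 clusters
  (empirically ~10% type-I at 40 subjects/site, nominal by ~100); site
  strata far smaller than the emulated cohort should use small-sample
  corrections this package does not implement.
* Restricted-permutation PERMANOVA conditions on batch/depth
  covariates whose misalignment under permutation makes the test
  mildly conservative when those nuisance effects are strong.
* Pearson correlation on integer-coded categoricals is a crude
  collinearity screen; an association measure for mixed types would be
  preferable.
* Compositional closure means planting a log-fold effect on one genus
  necessarily shifts all others; the pinning construction makes the
  targeted contrasts exact but spreads a small compensating change over
  filler genera.
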