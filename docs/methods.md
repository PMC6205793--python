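# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of placmeth. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Differential methylation model

Methylation at CpG *c* in sample *i* is summarised by the beta value
β ∈ [0, 1]; modelling is done on the M scale, M = log2(β/(1−β)), which is
approximately variance-stabilised and unbounded. The per-CpG model is
ordinary least squares:

    M_ic = b0 + b1·case_i + b2·GA_i + b3·male_i + Σ_k b_{3+k}·MDS_ik + e_ic

with case status the primary term (indicator coded, positive coefficients
meaning higher methylation in cases), gestational age in weeks, fetal sex,
and k genetic-ancestry MDS coordinates (default k = 2) as additive
covariates. CpGs with missing values are fitted on row-wise complete cases
with the residual degrees of freedom reduced accordingly; CpGs that become
unestimable stay NaN rather than being imputed.

With `moderation="empirical_bayes"` (the default) residual variances are
shrunk toward a common prior, s²_post = (d0·s0² + d·s²)/(d0 + d), with
(d0, s0²) estimated by the method of moments on log residual variances
(matching the limma approach; the test suite pins coefficients, moderated t
and p against `limma::eBayes` to ~1e-8 on a shared fixture). The prior
degrees of freedom d0 may be infinite when variances are effectively
constant, in which case the t reference collapses to a normal.

Effect sizes are reported on the beta scale as Δβ = mean β(case) − mean
β(control) (positive = hypermethylated in cases), deliberately unadjusted:
the covariate-adjusted coefficient lives on the M scale in `estimate`. A
site is called DM when the Benjamini–Hochberg q-value is below `fdr_max`
and |Δβ| exceeds `delta_beta_min`; both hyper- and hypomethylated
directions count. Discovery-style runs default to (0.15, 0.05);
tissue-pair contrasts to the stricter (0.01, 0.20). Candidate-gene runs
restrict the matrix to the candidate CpG set *before* fitting, so BH
adjustment happens within the subset.

## Preprocessing

Order: probe filtering → (optional) quantile normalization → ComBat on M
values. Filtering applies criteria in a fixed order (blocklist,
cross-reactive, polymorphic, sex chromosomes, missingness, detection
failure) and reports counts per criterion at first hit; it is idempotent.
Missing betas are carried as a mask and never silently imputed.

ComBat is the parametric empirical-Bayes algorithm: per-feature OLS of the
protected design plus batch indicators under the weighted sum-to-zero
constraint on batch effects; residual-scale standardisation; normal prior
on batch locations γ and inverse-gamma prior on batch scales δ², with
method-of-moments hyperparameters across features; fixed-point iteration
(relative tolerance 1e-4) to the posterior (γ*, δ*); back-transformation
with batch effects removed and protected effects (case status, GA, sex,
ancestry by default) restored. Two sequential passes — chip row, then chip
id — handle the two technical variables recorded on arrays; the order is
configurable since neither variable is naturally "first". The
implementation agrees with `sva::ComBat` to ~1e-14.

Two properties of ComBat worth knowing:

* It is **not idempotent to machine precision**. EB shrinkage leaves
  γ̂ − γ* residue (sampling noise of batch means), so a second pass makes a
  further, smaller adjustment. The reference R implementation behaves
  identically. The suite therefore asserts the second pass removes no
  *systematic* structure (re-estimated batch locations average ~0 across
  features) and is much smaller than the first.
* With **small batches** (here 8 samples per chip, ~5 per row level) the
  per-batch scale standardisation induces cross-sample dependence that can
  make downstream per-CpG tests anti-conservative. For this reason the
  null-calibration checks run on cohorts simulated without batch structure;
  on real data, inspecting genomic inflation after batch adjustment is
  advisable.

## Ancestry and demographics

Ancestry is inferred by classical (Torgerson) MDS of a pairwise distance
matrix from an AIM-SNP genotype panel: square the distances, double-center,
eigendecompose, scale the top-k eigenvectors by √eigenvalue. The default
distance is allele sharing (mean absolute genotype difference / 2);
Euclidean is available. Missing genotypes are mean-imputed per SNP. The
embedding is deterministic up to axis sign; k = 2 coordinates are carried
into the EWAS design by default.

Demographic tables compare groups with the two-sided Wilcoxon–Mann–Whitney
test for continuous covariates (exact distribution for combined n ≤ 30
without ties, normal approximation with tie correction otherwise), the
two-sided Fisher exact test for binary covariates, and the two-sample
Kolmogorov–Smirnov test for ancestry coordinates.

## Cross-tissue analyses

Matched-tissue correlation computes per-CpG Spearman r across individuals
sampled in both tissues (M values; CpGs with fewer than 3 complete pairs
or zero variance are excluded and counted). The null pools per-CpG r over
`n_shuffles` random permutations of the matching; the report counts CpGs
above the pooled null's 95th percentile and tests that count against the
nominal 5% with a one-sided binomial test.

The overlap test draws `n_draws` (default 10,000) random CpG sets of the
query's size from the tested background without replacement and reports
the empirical tail probability with the +1 correction,
p = (1 + #{overlap ≥ observed})/(n_draws + 1), so p is never exactly zero.
The exact hypergeometric tail is always reported alongside; the suite
checks agreement within Monte-Carlo error at 100,000 draws.

## Cell-type signatures and clustering

A cell type's signature is the intersection of DM sets from moderated
two-group contrasts of that type against chorionic villi and against each
other immune class (thresholds default to q < 0.05, |Δβ| > 0.20; the
thresholds used are recorded in every output manifest since reasonable
choices differ). Tightening thresholds can only shrink the signature.

Trend concordance compares, per DM site, the sign of (case − control) villi
methylation with the sign of (cell reference − control villi); sites with
either sign exactly zero are excluded from the denominator, and sites
absent from the reference platform are dropped and counted. Both a
binomial(0.5) tail p and an empirical p from random same-size CpG sets
drawn from the shared-platform background are always reported, because a
"chance" baseline can be defined either way.

Clustering is deterministic agglomerative clustering of samples on
signature CpGs — Euclidean distance on beta values with average linkage by
default (M-scale and other linkages configurable); scipy's tie-breaking by
lowest pair index makes results reproducible. Cluster support follows the
pvclust multiscale-bootstrap scheme: at each scale r (default 10 values in
[0.5, 1.4]) the CpGs are resampled with replacement to round(r·p), samples
reclustered, and BP_r recorded as the fraction of bootstrap trees
containing the node's exact leaf set; z_r = Φ⁻¹(1 − BP_r) is regressed on
(√r, 1/√r) by weighted least squares with binomial-variance weights, and
AU = 1 − Φ(v − c). BP is reported at r = 1 (clamped to (0.5/n_boot,
1 − 0.5/n_boot) before the probit). A node recovered in essentially every
tree at every scale gets AU 1 directly; a node never recovered at any scale
gets AU 0 with a flag. The default n_boot is 1,000 per scale; the test and
acceptance runs use 300–600 per scale, which the AU-calibration checks show
is sufficient for stable support values at these problem sizes.

Split significance is a Monte-Carlo cluster-index test: the observed
statistic is CI = within-split sum of squares / total sum of squares for
the two-way split; null datasets are drawn from a single Gaussian with
diagonal covariance equal to the per-CpG sample variances, clustered with
the same procedure, and the best two-split CI recorded;
p = (1 + #{null CI ≤ observed})/(n_sim + 1). The diagonal-covariance null
is a simplification of the original eigenvalue-model covariance of
sigclust; with many more CpGs than samples it is the practical choice, but
it ignores CpG-CpG correlation and will be anti-conservative when strong
correlated blocks exist under the null. Cluster–phenotype enrichment is a
two-sided Fisher exact test on the 2×2 cluster-by-phenotype table, plus
Wilcoxon/Fisher comparisons of the remaining clinical covariates across
clusters.

An "AU-stable two-cluster structure" means both children of the dendrogram
root are internal nodes with AU ≥ 0.95; a singleton child (one-sample
split) never counts as a stable cluster.

## Synthetic-data generator

The generator emulates the study design so that every stage has ground
truth:

* **Cohort layout.** Default 22 aCA + 22 non-aCA chorionic villi, 9 + 7
  chorion, 8 + 7 amnion; membrane samples reuse villi individuals
  (shared `individual_id`), giving matched-tissue structure. Reference
  panels provide 6 samples per immune class (neutrophil, eosinophil,
  monocyte, pooled lymphoid), whole blood, and villi controls.
* **Archetypes.** Per-CpG base beta drawn from a bimodal mixture: low
  U(0.01, 0.15), intermediate U(0.25, 0.75), high U(0.85, 0.99), with
  default proportions (0.4, 0.2, 0.4).
* **Planted sets.** Disjoint CpG blocks per tissue and immune class shift
  the owning type toward the far side of the scale by `effect_delta` times
  a U(1, 1.5) margin, so the planted separation is at least `effect_delta`
  and detectable above threshold noise. Case, GA and sex effect sets are
  planted as the logit shift that moves the archetype beta by exactly
  ±`effect_delta` (per GA standard deviation of 2 weeks for the GA slope;
  per male indicator for sex), so planted effect sizes are interpretable on
  the beta scale regardless of where the CpG sits.
* **Noise model.** All effects act additively on the logit scale; residual
  noise is logit-Gaussian (default SD 0.3), chip and row batch effects are
  independent per-batch-per-CpG Gaussians (default SD 0.1), optional
  individual-level offsets (default 0) generate cross-tissue correlation.
  Inverse-logit then clipping to (1e-6, 1 − 1e-6) keeps betas strictly
  inside the unit interval and logits finite.
* **Mixture cases.** aCA villi are mixed with the noise-free neutrophil
  archetype: β ← (1 − f)·β + f·β_neutrophil, f ~ U(0.1, 0.4) per case by
  default, 0 elsewhere. Direct (non-mixture) case effects are available
  (`n_aca_effect`) but default to zero — the admixture hypothesis is the
  default generative story, and the direct-effect knob exists to test the
  EWAS machinery itself.
* **Covariates.** GA is drawn so the realised case-group mean is below the
  control mean (~30.7 vs ~32.3 weeks, clipped to [28, 36.7]); sex is
  Bernoulli(0.5); ancestry coordinates come from two latent populations.
  Genotype panels are two-population binomials with a configurable
  allele-frequency gap.
* **Reproducibility.** One integer seed drives three separated substreams
  (profiles/sets, cohort, references); identical configuration and seed
  give bit-identical outputs.

What the generator does **not** emulate: probe-type chemistry differences
and raw intensities (no IDAT-level effects), spatially structured batch
effects, CpG-CpG correlation blocks (co-methylation), cell types beyond the
five reference classes, and platform-specific probe sets (cross-platform
intersection is modelled simply by subsetting CpG ids). Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated generative model, not robustness to every artefact of real arrays.

## Problem sizes and numerical choices

The acceptance battery runs at: 20,000 CpGs × 44 samples for null
calibration and DM recovery (10 seeds); 2,000 features × 20 samples for
batch-shift recovery; 100,000 draws for the overlap null; 8,000 CpGs for
the signature-clustering mirror (10 seeds for the enrichment check, 2 × 3
cell types for stability, n_boot 400/scale); 500 × 30 for AU calibration
(n_boot 300–400/scale, 5 replicate null clouds). These sizes give stable
Monte-Carlo estimates while keeping a full run to a few minutes.

Other numerics: logit clipping ε = 1e-6; ComBat fixed-point tolerance
1e-4; trigamma inversion by Newton iteration; BH implemented by the
statsmodels step-up with NaN propagation (cross-checked against a
brute-force implementation); Fisher exact p by hypergeometric enumeration
(scipy, cross-checked against a direct enumeration oracle); dendrogram
ties broken by lowest pair index.

## Known limitations

* Δβ is a raw group-mean difference; when covariates are imbalanced it can
  disagree in magnitude with the adjusted M-scale coefficient.
* The concordance empirical null draws CpG sets uniformly; if DM sites are
  enriched for intermediate-methylation CpGs, the uniform background is
  only an approximation to a matched null.
* AU values are extrapolations; with very low BP at every scale the fit is
  noisy, which is why the stability criterion requires both split children
  to clear the threshold rather than any single node.
* ComBat with few samples per batch can make downstream tests
  anti-conservative (see Preprocessing); the package intentionally leaves
  the decision of whether to batch-adjust to the analyst.
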