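# Methods

This note documents the models, conventions, and numerical choices behind
`cotwin`, and what the synthetic cohorts do and do not establish.

## Synthetic twin cohorts

**Phenotype.** Each pair draws a bivariate standard-normal liability with
correlation `liability_corr_mz` (MZ) or `liability_corr_dz` (DZ); an
individual is MD-affected when liability exceeds Φ⁻¹(1 − prevalence).
The liability-threshold model is the simplest generative mechanism that
produces the MZ > DZ concordance ordering from a single prevalence.
Defaults: prevalence 0.329 (144 affected among 438), correlations
0.63 / 0.08, calibrated once by bivariate-normal quadrature so the
expected proband-wise concordances match the 61% / 36% of the example
cohort. The DZ value is barely above the prevalence, hence the small DZ
correlation. Default cohort geometry is 97 MZ + 122 DZ same-sex pairs.

**Counts.** Genus counts follow a log-normal–multinomial model. The
latent log-abundance of genus *g* in individual *i* is

    z_ig = b_g + a_{j[i],g} + δ_g · MD_i + e_ig

with genus baselines `b_g ~ N(0, 1.5²)`, a pair-shared effect
`a_{j,g} ~ N(0, pair_var_z)` and individual noise `e_ig`. The total
latent variance is equalized across zygosities at
`max(pair_var_mz, pair_var_dz) + residual_var`; the individual component
absorbs the remainder. This equal-total-variance form matters: with a
*common* residual variance the shared effect cancels in within-pair
differences and MZ and DZ pairs would be equally dissimilar. Equal totals
with a zygosity-specific shared fraction — the classical twin-model
assumption — makes MZ pairs genuinely more similar whenever
`pair_var_mz > pair_var_dz`. Defaults 0.5 / 0.3 / 0.5 give a clear
within-pair < outside-pair and MZ < DZ dissimilarity ordering.
Compositions are the softmax of the latent scores; counts are multinomial
at a common `seq_depth` (20 000, above the 10 000 depth filter; depth
variation is deliberately not modeled). Spiked effects `δ_g` (signed,
alternating) act on `n_affected_genera` randomly chosen genera. Because
compositions are closed, spiking some genera slightly perturbs the CLR
values of all others; "null" genera in a spiked cohort are therefore only
approximately null (see Error control below).

**Metabolites.** A pair-correlated Gaussian panel with the same variance
structure sits on the log scale; the emitted concentration is
`exp(μ_m + latent) − 1` (floored at 0) so that the downstream log(1+x)
transform recovers the Gaussian panel exactly. Missingness is
missing-at-random per cell at `missing_rate_metabolite`; missing cells
are NaN (empty TSV cells), never zeros.

**Pathways.** Predicted-pathway abundances are noisy linear combinations
of genus CLR profiles, `pathway_j = Σ_g loading(j,g)·CLR(g) + noise`.
Each spiked genus is guaranteed one dedicated pathway with loading 1.0,
so the network stage has a known recoverable edge; remaining pathways
load on two random genera with weights ±U(0.5, 1.5).

**Confounders.** Age and sex are pair-shared (twins are born together;
the cohort is 96.8% female and all pairs same-sex); BMI and dietary
intake mix shared and individual components (BMI within-pair correlation
0.5); antibiotics use is individual (8%). Two switches exist purely for
testing covariate adjustment: `confounder_leakage` adds a BMI effect to
the first genus's latent score, and `bmi_md_shift` makes BMI differ by MD
status.

**What the generator does not emulate:** sequencing-depth variation,
overdispersion beyond the log-normal latent scale, taxonomic structure
(chimeras, ASV-level noise, phylogeny), longitudinal sampling, realistic
metabolite covariance blocks, or informative missingness. Tests passing
on these cohorts demonstrate the *procedures* are correct and calibrated
under the assumed structure, not that real cohorts satisfy the structure.

## Preprocessing

Counts: samples with depth strictly below 10 000 are removed; rare-taxon
rules run in order (total-count-1 taxa, taxa in ≤ 1 sample, zero taxa,
empty samples) with a per-rule removal log — the first two rules overlap
and an all-zero taxon is consumed by the second. CLR replaces zeros by
0.5 (half a count, the standard multiplicative replacement; exposed as a
parameter) and subtracts the per-sample mean log. CLR rows sum to zero to
1e−9 and the transform is invariant to per-sample rescaling of positive
counts (the absolute pseudo-count breaks exact invariance for samples
containing zeros).

Metabolites: the four steps run in the only order in which each is
well defined — (1) drop features missing in > 25% of samples, (2) impute
remaining missing cells with the feature median, (3) log(1+x),
(4) center/scale per feature. Scaling uses the population SD (divisor n)
by default; `population_sd=False` switches to the sample SD. Zero
variance after the log makes scaling undefined; such features are
dropped with a warning. Covariates are median-imputed; binary covariates
are mode-imputed with ties broken toward 0 (no exposure), since the
median of a 50/50 binary split is ambiguous.

## Dissimilarity comparisons

Bray–Curtis runs on relative abundances from filtered genus counts (CLR
values can be negative, which is invalid for Bray–Curtis); metabolome
distances are Euclidean on the processed log-z panel. Within-pair
distances are one per complete pair; outside-pair distances pair each
individual with everyone except the own co-twin, and the MZ/DZ-restricted
comparison uses only same-zygosity pairs of individuals. Group
comparisons gate on Shapiro–Wilk (both groups p > 0.05 → Student's t,
otherwise Wilcoxon rank-sum). Two caveats are inherent to the procedure
and flagged rather than "fixed": outside-pair distances are not
independent observations (each sample contributes ~n of them), so these
p-values are descriptive; and Shapiro–Wilk p-values are approximate for
the very large outside-pair sets. An O(n²)-avoiding subsampling cap
(fixed seed) is available and off by default.

## Pairwise layers and the exact signed-rank test

Layers a–c test within-pair differences (MD minus healthy co-twin) per
feature with a two-sided Wilcoxon signed-rank test at raw α = 0.05
(α = 0.1 for pathways in the MZ layer). No multiple-testing correction
is applied in these layers by design; correction happens in the
mixed-model layers. Zero differences are discarded before ranking; tied
absolute differences get mid-ranks. For ≤ 25 nonzero differences the
p-value is exact: the null distribution of the positive-rank sum over all
2ⁿ sign assignments is built by dynamic programming on doubled ranks
(mid-ranks are half-integers), and the two-sided p doubles the smaller
tail. This exactness under ties is why the test is implemented in-package
— the common library routine's exact mode assumes untied ranks, and ties
are routine in count-derived data. Above 25, a normal approximation with
tie correction and continuity correction is used. The exact path is
verified against brute-force enumeration, and the tie-free path against
the standard library implementation. The exact test is
discrete-conservative: its realized level sits slightly below α
(measured 0.046–0.049 at α = 0.05 across layers).

## The zygosity-stratified mixed model

Marginal covariance is block diagonal with 2×2 pair blocks
σ²_z·𝟙𝟙ᵀ + σ²·I. Each block is rotated onto its eigenbasis: the
within-pair sum carries variance σ² + 2σ²_z and the within-pair
difference carries σ² (singleton pairs contribute σ² + σ²_z), which
diagonalizes the model exactly. β is profiled out by weighted least
squares at every variance evaluation, and σ² is profiled analytically,
leaving one or two log variance-*ratio* parameters. These are optimized
by a coarse 9-point-per-axis grid scan (covering ratios e⁻⁸ to e⁴,
i.e. boundary to strongly pair-dominated) followed by one Nelder–Mead
polish; the grid scan is the guard against local optima. Variance
components are nonnegative by construction (log parameterization); ratios
driven to the boundary reproduce OLS exactly. The likelihood is validated
against a dense multivariate-normal density (≤ 1e−8 on 40-individual
cohorts) and, in the shared-variance configuration, against a generic
mixed-model fitter (ML log-likelihood to 1e−6, REML variance components
to 0.1%).

`TwinLMM` defaults to ML, which makes likelihood comparisons and
likelihood-ratio tests exact; REML is available. The per-feature screen
(`screen_features`) defaults to REML: at a few hundred pairs, ML variance
estimates are biased low, which makes Wald p-values liberal (measured
null rejection 0.069 at nominal 0.05, vs 0.054 under REML) and inflates
the realized FDR of the downstream BH step. REML is also what the
standard mixed-model software this analysis style is built on uses by
default. The screen's Wald tests use a t reference with between-within
denominator degrees of freedom (observations − pairs −
within-pair-varying fixed effects); `TwinLMM` itself reports large-sample
normal Wald p-values. A likelihood-ratio option (`test="lr"`) refits
without the MD column under ML.

Setup d restricts the sample to healthy co-twins of discordant pairs plus
all MD twins (74 + 144 = 218 on the example cohort); setup e uses
everyone (294 + 144). BH adjustment runs within each feature family
(genera, metabolites, pathways separately) at FDR 0.2 (0.25 for
pathways). Every pair receives a random intercept, including concordant
pairs whose members share the MD value. Constant features, and constant
covariates within the selected subsample, are dropped with a log entry.
BMI is a covariate by default; the `covariates` tuple reproduces the
reduced set without it.

## Consistency ledger

The ledger ticks a feature per layer. Pairwise layers tick at their own
α. Mixed-model layers tick at raw Wald p < 0.05, with the FDR-adjusted
flags carried alongside in `layer_{d,e}_fdr` columns — this mirrors how
layered twin analyses annotate their summary figures (asterisked ticks
significant before but not after correction). A feature is *consistent*
when ticked in every layer where it was tested; only features ticked
somewhere appear.

## Correlation network

All genus × pathway pairs among the differential features are Spearman
rank correlations — Pearson on mid-ranks, tie-corrected by construction —
computed on the setup-d population; genus values on the CLR scale and
pathways on their abundance scale (rank-based, so monotone rescaling is
inert). p-values use the t approximation, with an exact permutation
distribution below n = 10. BH runs across *all* tested pairs; an edge
needs |ρ| > 0.2 and q < 0.05. In the full pipeline the differential sets
are the layer-d FDR-significant features, falling back to the raw
p < 0.05 sets (logged) when correction retains nothing.

## Error control and power: what the replicate experiments show

Under the null generator the per-layer flag rate over 200 cohorts × 200
genera is 4.6–4.9% at α = 0.05 (the exact test's discreteness keeps it
just below nominal). The layer-d BH step is checked on the metabolite
family: spiking 6 of 60 metabolites at effect 0.6 yields an observed FDR
of ~0.15 at nominal 0.2 with well-calibrated null p-values. The genus
family is unsuitable for a literal FDP measurement because compositional
closure converts spiked effects into small real shifts on every other
genus, inflating the apparent false-discovery count.

The MD fixed effect is recovered on 400-pair cohorts with |bias| < 0.01
on a unit-SD response, and 95% Wald intervals cover the truth at ~95%
(300 replicates).

End-to-end recovery uses a power-calibration oracle
(`cotwin.power.calibrate_genus_effect`): layer-d detection power is
estimated by replicate simulation at three candidate effects and probit
interpolation locates the effect with 90% power. At that effect
(≈ 0.53–0.57 on the latent log scale) the per-layer tick rates are
roughly a 0.76, b 0.92, c 0.98, d 1.0, e 1.0 — the 28-pair MZ layer is
the binding constraint — so a spiked genus is consistent across *all*
five layers in ~55–72% of runs. Joint all-layer recovery above 80% would
require calibrating the weakest layer, not layer d; this ceiling is a
property of the design (the pairwise MZ layer simply has 28 pairs), not
of the implementation. The dedicated identity-loading pathway edge is
recovered with ρ = 1.0 at zero noise.

Problem sizes used by the test suite and `scripts/acceptance.py` —
200 replicates for null calibration, 100–300 for FDR/coverage, 50 runs
for end-to-end recovery, 40 per calibration point — were chosen to keep
Monte-Carlo standard errors at or below the one-point level on the
quantities asserted.

## Known limitations

* Wald inference in the screen relies on a heuristic between-within df;
  no Satterthwaite/Kenward–Roger correction is implemented.
* The dissimilarity tests inherit the independence violation of treating
  pairwise distances as observations; they are reported as descriptive.
* The generator's compositional closure makes strict per-genus FDR
  statements ill-posed under spiked alternatives (see above).
* REML log-likelihoods are comparable only across fits with the same
  fixed-effect design.
* The exact signed-rank path is O(n · Σranks) per feature; above 25
  nonzero differences the normal approximation takes over.
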