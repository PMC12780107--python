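# Methods

`lowbiome` implements the statistical core of a low-biomass tissue
microbiome study: decontamination of taxonomic read counts, rarefied
diversity, compositional differential abundance, per-taxon survival scans,
cross-platform meta-analysis, and the power machinery needed to interpret
null results. This note records the models, the defaults and why they hold,
the numerical choices, and what the synthetic cohorts do and do not emulate.

## The setting

Lung tissue carries very few bacteria. After removing host reads, a sample
typically retains on the order of 10^2–10^4 bacterial reads depending on
assay (genus-level medians used as generator defaults: ~344 reads for
WGS-like tumor samples, ~730 for 16S-like, ~9080 for RNA-seq-like). At
these depths, reagent and handling contamination can dominate the observed
community, and sampling noise dominates per-taxon abundances. Every design
choice below follows from those two facts.

## Decontamination (`lowbiome.decontam`)

**List removal with a rescue rule.** Genera on a curated
frequent-contaminant list are removed, unless the genus encompasses at
least `rescue_min_species` (default 2) known human-associated species, in
which case it is rescued. Genera in `forced_removals` (default
`{Cutibacterium}`, a near-universal skin/reagent contaminant) are removed
regardless of rescue. The package ships a small illustrative list;
real analyses must supply their own curated files.

**Recursive upward propagation.** Removing a genus leaves its reads inside
every ancestor's clade count, so each ancestor at rank *r* is rescaled:

    adjusted(node) = original(node) × Σ adjusted(next-level descendants)
                                      / Σ original(next-level descendants)

computed per sample, from family rank up to the root. "Next-level
descendants" are the first standard-ranked nodes on each downward path:
`no rank` intermediates are transparent (but their own counts are rescaled
by the same rule so the tree stays internally consistent), and a lineage
that skips a rank (a genus attached directly under an order) still
contributes to its ancestor's retained fraction rather than being silently
lost. Adjusted counts are real-valued; rounding happens only on explicit
export. Direct (node-exclusive) reads are scaled by the node's own retained
fraction, which preserves `clade = direct + Σ children` on trees without
rank skipping.

**Zero-denominator rule.** A node with no reads among its next-level
descendants (a taxon observed only above genus level) keeps its reads by
default (`empty_descendants="keep"`); the strict multiplicative reading
(`"zero"`) is available. The rule operates on clade counts; a table-only
variant (`decontaminate_table`) handles the common case where only a
genus-level matrix exists.

**Per-cell read floors.** Genus cells below `min_genus_reads` are zeroed
(default 2 for Bracken-style-adjusted DNA platforms, 5 for RNA-seq).

## Diversity (`lowbiome.diversity`)

All diversity is computed at a common rarefaction depth (defaults per
platform: 500 reads RNA, 250 reads 16S, 100 reads WGS; 250 for
cross-platform concordance analyses).

* **Expected richness** has the closed hypergeometric form
  `E[S] = Σ_j [1 − C(N−N_j, d)/C(N, d)]`, evaluated with log-gamma.
* **Shannon diversity** (natural log; log-base flag available) is the
  median over 100 subsamples drawn without replacement (multivariate
  hypergeometric).
* **Bray–Curtis** dissimilarity is the arithmetic mean of 50 rarefied
  distance matrices. Equal depths make count-based and proportion-based
  distances identical.
* **Marginal PERMANOVA**: the squared distance matrix is Gower-centered,
  explained sums of squares are hat-matrix traces `tr(HG)`, and a term's
  marginal SS is `SS(full) − SS(full without term)`; pseudo-F uses the
  full-model residual. P-values permute sample identities (999 by default)
  with the observed statistic included: `p = (1 + #{F* ≥ F})/(1 + n_perm)`.
  Freedman–Lane residual permutation was considered and not used; raw
  identity permutation is the simplest scheme consistent with marginal SS.

Per-sample rarefaction seeds derive from the master seed plus the sample's
column position, so one sample's value does not depend on which other
samples are present.

## Compositional statistics (`lowbiome.compositions`)

Counts are mapped to the centered log-ratio scale,
`y = ln(x + c) − mean ln(x + c)` per sample, with pseudo-count `c = 0.05`.
Tumor–normal differential abundance is a paired t-test on per-subject CLR
differences (the package's DA primitive, aligned with the power model
below; bias-corrected compositional methods like ANCOM-BC are out of
scope). Zero-variance differences are reported degenerate with p = 1.
Multiple testing uses Benjamini–Hochberg by default (Holm available).
Platform subsets pool by inverse-variance fixed-effect meta-analysis;
combined p-values use Fisher's method (−2Σ ln p on 2k df); beta-diversity
meta-analysis averages R² and Fisher-combines the p-values. Cell-type
scores are medians of log2(CPM+1) over marker gene sets (log base affects
only a monotone rescaling).

**A calibration warning worth knowing.** The CLR zero-bias depends on
sequencing depth: a taxon absent at depth 700 and absent at depth 9000
contributes the same `ln c`, but the sample mean-log it is centered by does
not move the same way. If tumor and normal samples have systematically
different depths, this alone shifts paired CLR differences away from zero
and inflates type-I error (we measure ~0.06 at nominal 0.01 under the
generator's default unequal medians). The paired-test calibration results
below therefore hold for depth-matched designs; with unequal depths,
depth must be treated as part of the effect being tested, which is one
reason rarefaction and depth filters matter in this setting.

## Survival (`lowbiome.survival`)

Records are prepared with a ten-year horizon (times truncated, events
censored at truncation), stages II–IV merged, age dichotomized at 65 for
stratification and binned in ten-year categories for adjustment; records
with unknown stage or missing survival fields are dropped (listwise).

The Cox partial-likelihood solver is implemented in the package
(Newton–Raphson with step halving; Breslow ties by default, Efron by flag)
because the per-taxon scan needs stratified baselines together with a
choice of tie convention. A vectorized single-covariate Breslow path
serves the power simulation. Convergence requires gradient norm < 1e-9;
coefficients wandering past |β| > 50 flag monotone likelihood (separation).
Standard errors come from the inverse observed information; Wald p-values
are two-sided normal.

The scan fits one model per taxon: the taxon's CLR abundance plus
dummy-coded adjustment covariates (histology, age decade), stratified by
study site × stage group × age group. Strata with no events contribute
nothing; constant-abundance taxa are flagged aliased and excluded; BH
adjustment runs across the tested taxa. Taxa enter the scan only if they
reach 50 reads in ≥10% of samples (RNA) or 10 reads (16S/WGS).

## Power (`lowbiome.power`)

**Paired contrasts (closed form).** For standardized effect
β = E(δ)/σ and n pairs, the test statistic is approximately normal with
noncentrality ξ = β√n, giving two-sided power
`Φ(ξ − C_α) + Φ(−ξ − C_α)` with `C_α = Φ⁻¹(1 − α/2)`. Both terms are
retained, so β = 0 recovers exactly α. The minimum detectable effect
inverts this by bisection (tolerance 1e-6) from the one-term closed form.
At the published settings this machinery reproduces the printed minimums:
n = 385, α = 2.8e-4 → 0.23; α = 0.01 → 0.17; n = 1279, α = 3.9e-5 → 0.14;
α = 0.01 → 0.096.

**Survival scans (simulation).** A log-normal baseline
(`log S ~ N(μ, σ²)`) is fit to observed times by censoring-aware maximum
likelihood (density terms for events, survival terms for censored;
uncensored-only fitting by flag). Each replicate draws a standard-normal
covariate, generates event times by the inverse-probability method
`T = S₀⁻¹(U^{exp(−βz)})` with `S₀⁻¹(s) = exp(μ + σΦ⁻¹(1−s))`, censors a
random fraction of subjects at a time uniform on (0, T) (administrative
censoring by flag), fits a Cox model, and records the Wald p. Power is the
rejection fraction over 1000 replicates by default, with binomial
Monte-Carlo standard error. The minimum detectable hazard ratio bisects on
β ≥ 0 with common random numbers, which makes the empirical power curve
monotone within a run; by covariate symmetry the protective-side minimum
is the reciprocal. Without censoring the simulation agrees with the
Schoenfeld approximation `Φ(|β|√D − z_{1−α/2})` within Monte-Carlo error.
The transformed uniform is clipped to [1e-15, 1−1e-15] so extreme linear
predictors cannot produce zero or infinite times.

## Synthetic cohorts (`lowbiome.simulate`)

Each cohort draws a base abundance profile (softmax of N(0, 1.5²) logits —
a log-normal-like rank-abundance curve), per-subject compositions from a
Dirichlet around it (concentration 50: visible inter-subject variation),
and counts from a multinomial at a log-normal depth parameterized by its
median (σ = 0.7 on the log scale). Tumor samples shift planted taxa on the
CLR scale; because CLR shifts must sum to zero across taxa, planting t_j on
k of D taxa gives the remaining taxa −Σt/(D−k) each, and the planted taxa
realize exactly t_j in the latent composition. Contaminant reads are
Poisson spikes restricted to configured batches (other batches stay clean).
Survival times follow the same inverse-probability generator with the
linear predictor built from planted log hazard ratios times standardized
true CLR abundances, so hazard ratios read "per SD of abundance".

All randomness flows from one master seed through named `SeedSequence`
streams (cohort, contamination, survival), so stages are independently
reproducible. `base_seed` optionally pins the cohort *design* (the base
profile) while resampling subjects and counts — replicate cohorts then
share a fixed per-taxon truth, which is what per-taxon power estimation
across replicates requires.

**What the generator does not emulate:** read-level artifacts (errors,
adapters, mapping), taxonomic misassignment, batch effects other than
contaminant spiking (no ComBat-style location/scale shifts), overdispersion
beyond Dirichlet-multinomial, within-subject spatial heterogeneity, and
informative censoring. Passing tests demonstrate that the pipeline recovers
truth under these idealized conditions; they do not certify behavior under
misassignment or structured batch effects in real data.

## Problem sizes used in the test suite

Calibration and recovery checks run at sizes chosen to keep Monte-Carlo
error well inside the tested tolerances: 2000 null paired tests (20 cohorts
× 100 taxa), 1000 survival-power replicates at n = 150, 400 replicates for
the Schoenfeld comparison, 100 replicate cohorts of 400 pairs for the
planted-effect power check, and 20 cohorts of 600 subjects for the hazard
scan. The brute-force oracles (tree propagation, Cox grid search,
subsampled richness) run on instances small enough to enumerate.

## Known limitations

* The paired DA primitive is a CLR t-test; it matches the power model but
  does not correct compositional bias the way ANCOM-BC/ALDEx2 do.
* PERMANOVA permutes raw identities; under strong covariate imbalance a
  restricted or residual permutation scheme would be preferable.
* The propagation rule destroys direct reads of a node whose next-level
  descendants are all removed (fraction 0) — by construction of the
  multiplicative rule; the `keep` default only protects nodes with *no*
  lower-rank descendants.
* Cox separation is flagged, not penalized (no Firth correction).
* Minimum-HR estimates inherit Monte-Carlo noise from the simulated power
  curve; common random numbers control but do not eliminate it.
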