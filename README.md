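# lowbiome

Analysis toolkit for **low-biomass tissue microbiomes** — settings like lung
tumor and adjacent-normal tissue where a sample yields only hundreds to a
few thousand bacterial reads and reagent contamination can dominate the
observed community. It is written for microbiome analysts who need their
*null results* to be interpretable: every filtering rule, test, and power
calculation is reproducible end to end on synthetic cohorts with known
ground truth.

The package provides:

* **Taxonomic I/O and filters** — Kraken-style report parsing into a
  rank-coded tree with clade/direct counts, taxa × samples count tables,
  per-sample depth cutoffs (500/250/100 reads for RNA-seq/16S/WGS),
  prevalence filters (strict "less than" 5% / 1%), and the survival
  abundance rule (≥50 reads in ≥10% of samples for RNA, relaxed to 10 for
  DNA platforms).
* **Hierarchical decontamination** — curated-list removal of contaminant
  genera with a rescue rule (genera encompassing ≥2 human-associated
  species are kept; *Cutibacterium* is removed regardless), then recursive
  upward propagation: each ancestor's clade count is multiplied by the
  retained fraction of its next-lower-rank descendants, up to the root.
* **Rarefied diversity** — expected genus richness (closed hypergeometric
  form), median Shannon diversity over 100 rarefaction draws, mean
  Bray–Curtis over 50 draws, and marginal-variance PERMANOVA
  (999 permutations).
* **Compositional statistics** — CLR transform (pseudo-count 0.05), paired
  tumor–normal t-tests on CLR differences, BH/Holm adjustment,
  inverse-variance fixed-effect meta-analysis, Fisher's combined test, and
  marker-set cell-type scores (median log2 CPM).
* **Survival scans** — ten-year overall survival, one stratified Cox model
  per taxon (strata: study site × stage I vs II–IV × age ≤65 vs >65;
  adjusted for histology and age decade), with a built-in
  partial-likelihood solver (Breslow/Efron ties).
* **Power** — the closed-form paired-test framework
  `power = Φ(β√n − C_α) + Φ(−β√n − C_α)` with minimum-detectable-effect
  solving, and a simulation framework for Cox scans: log-normal baseline
  fit by censoring-aware ML, inverse-probability event-time generation
  `T = S₀⁻¹(U^{exp(−βz)})`, and minimum-detectable-hazard-ratio bisection.
* **Synthetic cohorts** — paired tumor/normal counts at realistic
  low-biomass depths, batch-specific contaminant spiking, planted CLR-scale
  tumor effects and proportional-hazards taxon effects, all with a
  serialized ground-truth manifest.

## Worked example

Simulate a contaminated cohort, decontaminate it with the true list, and
watch the batch signal collapse:

```python
import lowbiome as lb

cfg = lb.CohortConfig(
    n_subjects=120, n_genera=40, platform="16S", seed=7,
    contaminants={"Ralstonia": 80.0, "Delftia": 50.0},
    contaminated_batches=("b2",),
)
table, metadata, truth = lb.generate_cohort(cfg)
table, truth = lb.spike_contamination(table, metadata, truth, cfg)

policy = lb.ContaminantPolicy(contaminant_genera={"Ralstonia", "Delftia"})
cleaned, report = lb.decontaminate_table(table, policy)
print("removed genera:", sorted(report.removed_genera))

protocol = lb.RarefactionProtocol(depth=250, n_beta_draws=50, seed=7)
for label, tab in [("before", table), ("after", cleaned)]:
    deep = lb.filter_min_depth(tab, 250)
    dm = lb.braycurtis_rarefied(deep, protocol)
    res = lb.permanova_marginal(dm, metadata, ["batch"], n_perm=999, seed=7)
    row = res.summary.loc["batch"]
    print(f"batch PERMANOVA {label}: R2 = {row.R2:.3f}, p = {row.p:.3f}")

beta = lb.min_detectable_effect(n=385, alpha=2.8e-4)
print(f"minimum detectable paired effect (n=385, alpha=2.8e-4): {beta:.3f}")
```

Output:

```
removed genera: ['Delftia', 'Ralstonia']
batch PERMANOVA before: R2 = 0.130, p = 0.001
batch PERMANOVA after: R2 = 0.020, p = 0.012
minimum detectable paired effect (n=385, alpha=2.8e-4): 0.228
```

The spiked contaminants create real batch structure (13% of
community variance, p = 0.001); list-based removal eliminates the planted
genera and drops the batch R² by ~85%. The last line is the smallest
standardized paired effect `E(δ)/σ` detectable at 80% power with 385
tumor–normal pairs at a Bonferroni-corrected two-sided α — i.e., what a
null differential-abundance result at that sample size does and does not
rule out.

A command-line interface mirrors the library
(`lowbiome simulate | decontam | diversity | permanova | da | survival |
power | run`); `lowbiome run --config cohort.yaml --out run1/` executes the
full pipeline into one immutable directory with a hash manifest, and
re-running the same config reproduces byte-identical outputs.

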