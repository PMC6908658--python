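# phyllocom

Occupancy, prevalence, and phylogenetic-diversity analysis of phyllosphere
microbiota from OTU count tables.

Bacteria on leaves and flowers are sampled by 16S amplicon sequencing,
summarised as an OTU table (samples × taxa read counts), and the scientific
questions are about *distribution*: which organs and host species does each
taxon reach (occupancy), how often is it detected in each sub-environment
(prevalence), and does phylogeny constrain which taxa assemble together?
Answering these questions honestly requires dealing with three nuisances
that `phyllocom` treats as first-class citizens: sequencing noise
(calibrated on a mock community), unequal sequencing depth (rarefaction and
depth covariates), and temporal dependence (random effects for collection
time).

## What the package computes

Given a count table, sample metadata (host, organ, time point, series,
control flags), and optionally a phylogeny of the OTUs:

1. **QC / noise filtering** — samples with < 1000 reads are dropped; the
   per-OTU minimum total is set to the read count of the most abundant
   *alien* OTU in the mock-community sample (the level at which false
   positives demonstrably occur); richness outliers are flagged by the
   1.5 · IQR rule; compositional outliers by a nearest-neighbour
   Bray–Curtis distance threshold within host × organ groups.
2. **Rarefaction and alpha diversity** — multivariate-hypergeometric
   subsampling to a common depth; richness *S*, Shannon *H* (natural log),
   Pielou evenness *J = H / ln S*; organ/host contrasts with a Poisson GLMM
   (richness) or linear mixed model (evenness), time of sampling as the
   random term.
3. **Community structure** — Bray–Curtis dissimilarity
   d(i,j) = Σ|xᵢ−xⱼ| / Σ(xᵢ+xⱼ) and a from-scratch sequential (Type I)
   multi-term PERMANOVA: Gower-centred inner-product matrix, per-term
   pseudo-F = (SSₜ/dfₜ)/(SSᵣ/dfᵣ), p-values by free (optionally stratified)
   permutation of sample labels.
4. **Occupancy** — presence/absence at an incremental rarefaction depth
   grid plus the "all-read" layer (unrarefied detection restricted to OTUs
   detected at the reference depth); Venn-region accounting of leaf/flower
   and across-host overlaps, and the depth dependence of those overlaps.
5. **Prevalence** — per-OTU binomial logit GLMMs of detection with host,
   organ, their interaction and standardized sequencing depth as fixed
   effects and a random time-of-collection intercept (three model
   families: joint, per-host, per-organ), Wald tests with Bonferroni
   correction, and aggregation into conserved / prevalent / remaining
   classes.
6. **Phylogenetic diversity** — Faith's PD, a tip-label-swap null model
   (1000 replicates by default) giving per-sample p-values and
   standardized effect sizes SES = (PD_obs − μ_null)/σ_null; negative SES
   with small lower-tail p indicates phylogenetic clustering.

A synthetic-data generator (`phyllocom.synthetic`) emulates the field
design the pipeline targets — 3 host species × 2 organs × 13 time points in
2 series, ~288 samples, 476 OTUs with a tunable generalist fraction, depths
of 1000–40,000 reads, a mock community with planted false positives, and
near-empty negative controls — with full ground truth, so every stage is
testable without sequencing data.

The GLMM machinery (`phyllocom.glmm`) fits random-intercept binomial and
Poisson mixed models by marginal maximum likelihood with Gauss–Hermite
quadrature; it reproduces R `lme4::glmer` coefficients to ~1e-3 on the same
data (checked in the test suite).

## Worked example

```python
import pandas as pd
from phyllocom import (SyntheticDesign, simulate_community, simulate_controls,
                       SampleMeta, PipelineConfig, run_pipeline)

design = SyntheticDesign(n_otus=150, samples_per_cell=2,
                         time_points_per_series=(4, 3), missing_cells=(),
                         depth_range=(2000, 15000), rng_seed=1)
table, meta, truth = simulate_community(design)
table, ctrl_meta, declared = simulate_controls(table, rng_seed=2)
meta = SampleMeta(pd.concat([meta.df, ctrl_meta.df]))

cfg = PipelineConfig(rarefaction_depth=2000, depth_grid=[1000, 2000],
                     permutations=199, pd_replicates=199,
                     glmm_data_per_parameter_floor=5)
report = run_pipeline(cfg, table, meta, tree=truth.tree,
                      declared_mock_members=set(declared))

print("noise threshold:", report.noise_threshold)
print(report.permanova_result.table[["term", "r2", "pvalue"]].round(3))
print("globally shared OTU fraction:", round(report.global_shared, 3))
print("mean PD SES:", round(report.pd_result.mean_ses(), 2))
```

prints

```
noise threshold: 63
         term     r2  pvalue
0  time_point  0.075   0.065
1        host  0.102   0.005
2       organ  0.056   0.005
3    Residual  0.767   NaN
4       Total  1.000   NaN
globally shared OTU fraction: 1.0
mean PD SES: -0.12
```

The threshold is the 63-read alien planted in the simulated mock; host and
organ each explain several percent of Bray–Curtis variance (p at the
permutation floor 1/200) while the time term does not reach significance
in this small design; every OTU is detected in more than one host × organ
cell; and the PD standardized effect size is near zero because habitat
preference was simulated without phylogenetic signal (raise
`conservatism_strength` to push it negative).

The same workflow is available from the shell:

```bash
phyllocom simulate --seed 1 --outdir data/
phyllocom all --counts data/counts.tsv --meta data/meta.tsv \
    --tree data/tree.nwk --outdir run/
```

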