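# Methods

This note records the models, conventions and design choices behind
`phyllocom`, in the order the pipeline applies them.

## Data model

The central object is a samples × OTUs matrix of non-negative integer read
counts (`CountTable`), joined to per-sample factors: host species, organ
(leaf/flower), ordinal time point, collection series, control status
(none/negative/mock) and a `pooled` flag marking samples that pool several
plant individuals. Pooling is a property of samples, not of a species
concept: any host whose samples are pooled is excluded from host-to-host
diversity and prevalence comparisons but participates in occupancy, which
only asks about detection. Control samples carry a sentinel `na`
host/organ. Identifiers are opaque strings; no taxonomy is parsed.

Trees are read from newick via dendropy. An unrooted input is treated as
rooted at its basal polytomy with a zero-length root edge — Faith's PD
needs a defined root, and a zero-length edge makes the choice neutral for
total branch length.

## Noise filtering

Order matters and is fixed: (1) calibrate the per-OTU threshold on the
mock sample while the table is still complete, (2) drop samples with fewer
than 1000 reads (strict inequality: 1000 stays), (3) drop OTUs whose
dataset-wide total is below the threshold, (4) set controls aside,
(5) rarefy, (6) screen outliers. Each step is idempotent and every
exclusion is logged with its rule.

The threshold rule: the mock community has a declared membership, so any
other OTU observed in it is a demonstrated false positive (index hopping,
reagent carry-over, cross-talk). The count of the *most abundant* alien
OTU in the mock is the level at which such artifacts are known to occur,
and becomes the minimum dataset-wide total for every OTU. A clean mock
degenerates to threshold 1 (no filtering) with a warning. OTUs that merely
appear in negative controls are retained — their low-level presence in
controls is explained by the same cross-contamination processes, and
removing them would discard biologically real taxa.

Richness outliers (below Q1 − 1.5·IQR or above Q3 + 1.5·IQR, linear-
interpolation quartiles — the common "type 7" convention, chosen because
no other convention is implied by the procedure) are *flagged only*.
Compositional outliers are formalized as a thresholded nearest-neighbour
rule: a sample whose minimum Bray–Curtis distance to every other sample of
its host × organ group reaches 0.95 (configurable) is flagged, and removed
when the config says so. At threshold 1.0 exactly the samples sharing no
OTUs with their group are caught, which is the fully-disjoint case the
rule is meant to capture.

## Rarefaction

One seeded multivariate-hypergeometric draw per sample per depth —
rarefaction is a single subsampling event, not an average. Per-sample
random substreams are keyed on a CRC of the sample id so results do not
depend on sample order. `draw_mode="nested"` instead shuffles each
sample's reads once and takes prefixes, guaranteeing that the depth-d
subsample is contained in the depth-d′ subsample for d ≤ d′; this makes
depth-monotonicity of detection exact and testable. Note that nesting
makes detected *sets* monotone in depth; a shared-OTU *fraction* can still
dip when newly detected OTUs enter only one side of an overlap.

Shannon entropy uses the natural log (Pielou's original definition; J is
base-invariant anyway). J is reported missing for samples with S ≤ 1.

Richness contrasts use a Poisson GLMM with a random time-point intercept;
evenness uses a linear mixed model that first attempts a random slope of
the fixed factor over time points and falls back to a random intercept on
convergence failure (logged). The Poisson model does not attempt random
slopes: in this data regime slope models fail to converge at high rates,
and a failed slope model is strictly less informative than a converged
intercept model.

## Mixed-model fitter

No installed Python package fits binomial/Poisson GLMMs by maximum
likelihood, so `phyllocom.glmm` implements the single-random-intercept
case directly: the marginal likelihood integrates the group intercept out
with 25-node Gauss–Hermite quadrature (more accurate than one-point
Laplace), maximised by L-BFGS-B with the analytic score; Wald tests use
the numerically differentiated observed information. The fitter matches
`lme4::glmer(..., nAGQ=25)` to ~1e-3 on shared data (asserted in the test
suite). Failures — optimizer breakdown, coefficients at the ±15 boundary
(quasi-separation), singular information — are returned as
`converged=False` with a reason, never raised: in per-OTU screens a failed
fit is a data point.

## PERMANOVA

Implemented from scratch as the distance-based linear model: squared
distances are Gower-centred into an inner-product matrix G with
tr(G) = SS_total = (1/n)·Σ_{i<j} d²ᵢⱼ (asserted on every run); each term's
sequential (Type I) SS is the increase in tr(HG) as its treatment-coded
dummy block joins the cumulative hat matrix. Sequential decomposition in
the order time, host, organ matches the convention of reporting a single
ordered variance split; term order is explicit and changing it changes
per-term SS but never the total. Significance is by free permutation of
sample labels (default 1000), recomputing every term's pseudo-F, with
p = (#{F_perm ≥ F_obs} + 1)/(n_perm + 1); ties count as exceedances, with
a 1e-9 relative tolerance so exact ties are not split by floating-point
noise. A `strata` option restricts permutations within the levels of a
factor (e.g. within time points). Rank-deficient (confounded) designs
raise an error naming the term; interactions are not supported.

## Occupancy

Presence is any count ≥ 1. The profile holds one presence matrix per grid
depth (default 1000, 2000, …, 6000, 6955) and the "all-read" layer:
presence judged on unrarefied counts, restricted to the OTUs detected
anywhere at the reference depth. The restriction matters — an OTU with
positive raw counts that never survives rarefaction is *excluded* from the
all-read layer, which is what makes the layer an extrapolation of the
reference-depth OTU set rather than raw presence. Overlaps are reported as
Venn-region counts (leaf-only/flower-only/both within a host; the full
2^k−1 region partition across hosts within an organ) and as the shared
fraction; the global statistic (fraction of OTUs in >1 host × organ cell)
is computed two independent ways and asserted equal. The depth curve
reports the shared fraction at every grid depth plus all-read, and its
max−min spread — the measure of how depth-sensitive occupancy conclusions
are.

## Prevalence

Detection of an OTU in a sample is Bernoulli; the linear predictor holds
the family's factors plus the centred and rescaled library size
(population-sd convention, ddof=0 — the convention is logged; a
zero-variance depth gives an all-zero covariate with a warning), and a
random intercept for time of collection. The joint family (host + organ +
interaction + depth) is restricted to the first collection series because
the second lacks flowers of one host, which would unbalance the random
effect. Per-host and per-organ families add a series effect when both
series are in scope. Families are only fitted when observations per
parameter reach a configurable floor (default 17).

Classification: per family, the Bonferroni threshold is α/m with m = the
number of converged models in that family (the correction universe is the
family's tests; sensitivity to no correction is always reported
alongside). A significant organ or species main effect labels the OTU
prevalent on the level the coefficient's sign points to; interaction terms
never set the label alone; everything else is conserved; failed fits are
their own reported category, and the per-family class proportions
(including non-converged) sum to one.

Aggregation: an OTU is globally conserved when *any* converged family
finds it comparably prevalent in ≥ 2 host/organ combinations; OTUs with
only significant-effect models are "prevalent-somewhere"; OTUs never
tested or never converged are "remaining". For parameter recovery
(estimating a design's specialist fraction) the right denominator is
converged models only — non-converged fits carry no prevalence information
and would mechanically bias the estimate — so
`family_conserved_among_converged` is reported next to the all-tested
proportions.

## Phylogenetic diversity

Faith's PD is the branch-length sum of the minimal subtree spanning a
community, by default including the path to the root (`include_root=True`,
the prevailing convention in community phylogenetics; configurable). The
production implementation counts, per edge, the community tips below it; a
brute-force oracle recomputes PD from explicit edge bipartitions on small
trees and the two are asserted equal on 1000+ random cases.

The null model permutes tip labels on the fixed topology — a property of
the *tree*, so by default one shared permutation per replicate is applied
to all communities, preserving their co-occurrence structure
(`per_community=True` gives independent permutations, used for the
calibration checks where independence across communities is wanted). The
null pool is all tips of the supplied tree, not just the tips present in
the analysed samples. Richness is preserved exactly by construction. Both
tail p-values include the observed value, so the attainable floor is
1/(n_reps + 1) ≈ 0.001 at the default 1000 replicates; per-sample p and
their maximum are reported rather than a single summary threshold. A
community spanning all tips (or any symmetric case such as a uniform star
tree) has a degenerate null with sd 0: SES is NaN, p_low is 1, and a
warning is emitted.

## Synthetic data

The generator is the package's study stand-in, with defaults fixed to the
emulated design: 3 hosts (one pooled) × 2 organs × 13 time points in two
series (7 + 6) × 4 samples per cell, with first-host flower cells absent
from series 2 — 288 samples; 476 OTUs, 90% generalists; library sizes
uniform on [1000, 40000] (the true depth distribution is unknown; uniform
deliberately stresses the depth-covariate logic); lognormal(0, 1.5) base
abundances; specialist penalties of 3 logits on both the inclusion
probability and the relative abundance (detection in amplicon data is
depth-mediated, so both channels must carry the effect); inclusion base
logit 2; a time-point effect of sd 0.5 exercising the random-intercept
machinery; Brownian habitat preference on a simulated coalescent tree,
scaled by `conservatism_strength` (0 by default = exchangeable tips). The
mock control plants aliens at 63/34/1 reads over 8 declared members;
negative controls total 19 and 20 reads.

What the generator does *not* emulate: compositional correlation between
taxa, PCR/primer bias, chimeras, overdispersed (non-multinomial) counts,
realistic depth distributions, and within-cell spatial structure. Passing
tests therefore demonstrate that the estimators recover the truth under a
clean generative model of the design — not that they are robust to every
artifact of real amplicon data.

## Problem sizes

Validation runs use scaled designs chosen so Monte-Carlo error sits well
inside each asserted band: 1000+ oracle pairs on ≤16-tip trees; 400
random / 100 clade communities × 500 null replicates on a 128-tip tree;
500 null PERMANOVA datasets (n=24, 199 permutations) plus exhaustive
enumeration at n=4; 2000 rarefaction draws against the hypergeometric
closed form; 200-OTU occupancy designs at 20–40k reads; 250 null OTUs, 30
effect-recovery seeds and a 150-OTU 10%-specialist design for the GLMMs.

## Known limitations

* One random-effect grouping per model (time of collection); crossed or
  nested random effects are out of scope.
* PERMANOVA has no interaction terms and no dispersion (betadisper-style)
  diagnostic; a significant term can reflect dispersion differences.
* Wald p-values per coefficient (configurable in principle to LRT at ~4×
  the fit count); GLMM p-values are approximate by nature.
* The tip-swap null is the only null model; independent-swap or
  frequency-weighted nulls are not implemented.
* NMDS ordination and figure rendering are out of scope; outputs are TSV.
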