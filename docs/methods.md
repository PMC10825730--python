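# Methods

This note documents the models, parameter choices and numerical decisions
behind `methylpanel`, and what the synthetic-data experiments do and do not
demonstrate.

## The synthetic cohort generator

The generator is the package's substitute for unreleasable patient arrays;
its defaults define the conditions under which every downstream guarantee
is tested.

**Cohort.** Default class sizes are 74 healthy volunteers, 42
endoscopy-negative subjects, 52 nondysplastic Barrett's, 28 intramucosal
and 60 invasive adenocarcinomas (256 analysis samples) plus 9 high-grade
dysplasia samples that never enter model building, and optionally technical
duplicate arrays (the pipeline default adds 10). Sex is Bernoulli with
male:female odds 2.52. Covariates are truncated normals (age >= 18, the
rest >= 0) with group-specific means and SDs: cancer groups are older
(70.9 +/- 8.8 vs 63.2 +/- 13.4 years), heavier (BMI 28.2 vs 26.8), smoke
more (7.4 vs 3.4 pack-years) and take more PPI (1.72 vs 1.24 pill-years);
the HGD group sits between, slightly younger than cancer with
cancer-like lifestyle exposure. The true epithelial cell fraction is
Beta(4, 6) (mean 0.4), a realistic saliva range; fibroblast content is
fixed at 0.005 and immune content is the complement.

**Methylation.** Gene g in module m has a unit-variance latent signal
z_g = l*f_m + sqrt(1-l^2)*eps over samples (shared factor f_m). Genes in
the disease module additionally gain a constant standardized shift
(default 0.8) in cancer samples; a random subset of background genes
drifts with z-scored age (50 genes, loading 0.3) and smoking pack-years
(30 genes, loading 0.2). Each gene expands to 1-3 probes on the natural
logit scale: probe = base + offset + 0.5*z + noise(SD 0.2), where the
per-gene base is drawn from a bimodal mixture typical of methylation
arrays (55% unmethylated around M = -5, 30% methylated around M = +4, 15%
intermediate); values pass through the logistic function and are clamped
to [1e-6, 1-1e-6], so beta stays in [0, 1]. Batch effects are additive
logit-scale shifts, constant per 50-probe block per (plate, row) unit
(SD 0.4). Sixty marker probes are generated as
f*epithelial + (1-f-0.005)*immune + 0.005*fibroblast mixtures of
reference beta profiles with SD-0.02 noise, and carry no gene annotation
(they drop out at the collapse stage, like unannotated loci). Duplicates
reuse their source sample's latent gene values with fresh pair-specific
logit-scale noise (default SDs 0.1-1.6, emulating the observed spread from
faithful to poor replicates). Simulated bisulfite-control intensities are
N(8000, 1500); QC failures (low intensity, or wholesale replacement of a
sample's betas by a mid-range distribution whose M-density peaks near +1)
are planted only on request.

**Correlation calibration.** `module_cor` (default 0.6) targets the
*observed* probe-scale within-module mean |correlation|. Two attenuations
sit between the latent factor model and the data: probe noise shrinks
pairwise correlation by s^2/(s^2+sigma^2) = 0.862 at the defaults, and the
logit-to-beta squashing by a further ~0.87 (measured once on the default
baseline mixture; it is nearly flat across the mixture's components). The
generator divides the requested target by both factors before setting the
factor loading, and the realized mean |cor| lands within ~0.01 of target
at default scale. An observed within-module correlation of ~0.6 is typical
of cell-composition- and CpG-island-driven co-methylation blocks in
heterogeneous tissues, and is the regime in which a power-6 unsigned
network with a static tree cut detects modules stably; substantially
weaker modules (observed |cor| ~ 0.45) sit at the detection boundary and
drop out of a few percent of resampled networks, which the 200-run
averaging is designed to expose, not hide.

**What the generator does not emulate:** probe type I/II chemistry bias,
raw two-channel intensities, spatially structured (non-additive) batch
effects, genomic autocorrelation between neighbouring CpGs, and
non-Gaussian covariate tails. Passing tests therefore certify the
pipeline's logic and statistics under a clean factor-model world, not its
performance on any real cohort.

## Design stage

The match distance is weighted Euclidean over z-scored covariates; sex is
kept 0/1 (z-scoring a near-balanced binary would rescale the printed
weight into meaninglessness) so two otherwise-identical people of opposite
sex are exactly weight 5 apart. Greedy matching visits cases in seeded
random order, nearest-neighbour ties break on the smaller sample id, and
technical duplicates and HGD samples are excluded from the case-control
pool. The plate-layout objective sums, over every pair of rows (uniquely
numbered across plates) and the pair of plates, Welch |t| statistics for
the six continuous covariates and the 2x2 chi-square statistic for sex; a
proposed swap of two random samples is kept only if the objective strictly
decreases, making the acceptance trace non-increasing by construction.
Group variances in the t denominator get a 1e-12 floor so single-sample or
constant units contribute 0 rather than NaN.

## QC stage

The KS distance is the standard two-sample statistic (sup of the ECDF
difference) between beta-value vectors. Each array's distance is taken to
the leave-one-out average array; of each duplicate pair the closer member
survives, ties keeping the smaller sample id. The 0.6 flag is advisory
only — stringent KS-based discarding removes good arrays along with bad.
M = log2(beta/(1-beta)) with beta clamped to [1e-6, 1-1e-6]; the density
peak uses a Gaussian KDE with Silverman bandwidth on a fixed grid over
[-12, 12], and the acceptance window for the global peak defaults to
[-6.5, -3.5] around the canonical unmethylated mode at -5. The
bisulfite-intensity rule (< 2000) applies regardless of any other measure.
Both filters are idempotent.

## Preprocessing

Cell fractions solve min ||R f - y||^2 subject to f >= 0, sum(f) = 1 per
sample, exactly, by enumerating active sets of the 3-component KKT system
(7 candidate supports; the feasible solution with minimal residual wins).
A rank-deficient reference is rejected. Row-batch residualization is OLS
on batch indicators, which for a purely categorical design is per-batch
mean centering of each probe; because every per-batch residual mean is
then zero to machine precision, *any* linear functional of probes —
including every SVD component — has zero batch-group means, forcing the
one-way ANOVA F to ~0 and p to 1.00. This is an exact algebraic property,
not an empirical one, and it holds for the plate variable too since plates
are unions of rows. Per-probe per-batch means are retained
(`batch_intercepts`) so a deployment baseline could be reconstructed for a
single new array, but the pipeline never re-applies them. SVD diagnostics
test categorical covariates by one-way ANOVA of component scores and
continuous ones by the Pearson correlation t-test; constant covariates
record p = 1.

## Network stage

Collapse keeps, per gene, the probe with the highest across-sample mean
(computed on the residual scale, since collapse follows preprocessing),
ties to the smaller probe id. The network is unsigned: a = |cor|^beta with
beta = 6 (the fallback and default; `pick_soft_threshold` returns the
lowest candidate power whose signed scale-free R^2 over ten equal-count
log-log bins reaches 0.8, and falls back to 6 otherwise). Constant genes
get zero correlation with a warning. The topological overlap uses the
standard unsigned formula; it is verified against a triple-loop oracle to
1e-12 rather than via the (false in general) claim TOM >= adjacency.
Module detection is average-linkage clustering of 1 - TOM with a *static*
cut (default height 0.995, minimum size 20); the dynamic variant is out of
scope, and both parameters are exposed because the original cut is
unknowable — the static choice reproduces the qualitative behaviour
(a handful of modules, occasionally fragmenting under resampling).
Eigengenes are unit-norm first right singular vectors of the z-scored
member genes, sign-aligned with the module mean profile. Module
significance is the Wald p-value of the eigengene in a logistic model with
age, sex and epithelial fraction; fits flagged unstable (non-convergence,
SE > 100, |coef| > 30 — the signatures of separation) fall back to a
ridge-penalized (1e-4, intercept unpenalized) likelihood-ratio test,
because the Wald statistic loses all power under separation (Hauck-Donner)
no matter how the fit is stabilized. Importance scores are not capped at
200; 200 is the default for unassigned genes, comparable to the least
important gene of a non-significant module, not a bound.

## Stability and candidates

Each of the (default) 200 runs removes 5 random samples (~3% of a
discovery cohort) and repeats network construction, module detection,
eigengene testing and scoring at the fixed power 6. Scores average across
runs; a gene never assigned anywhere averages exactly 200. Duplicate
removal sets are collision-checked and logged. Module-label vectors are
k-means-clustered as raw integers — the literal procedure, which works
because co-moving genes share label vectors even though the labels
themselves are arbitrary; its label-permutation sensitivity is a known
limitation, and the candidate stage ranks *clusters* by their best member
score, which is invariant to cluster-id permutation. Candidate lists take
the N-c+1 lowest-mean-score genes from the c-th ranked cluster
(c = 1..N), giving triangular lengths N(N+1)/2; undersized clusters
contribute what they have and flag truncation. When module recovery is so
stable that fewer distinct membership vectors exist than a requested k,
that k is skipped with a warning (k-means over duplicated points is
ill-posed); the k = 2..20, N = 2..k sweep otherwise enumerates exactly
190 candidates.

## Classification

Splits are stratified per diagnosis subclass by largest remainder at
(0.64, 0.16, 0.20); HGD is always and entirely held out; strata under 3
samples go to discovery with a warning. Features are the candidate genes'
residual-scale values plus age, sex (0/1) and estimated epithelial
fraction. The forest defaults to 500 trees with sqrt(p) features per
split; the pipeline's 190-candidate sweep uses 100 trees (the selection is
insensitive to tree count well before 100, consistent with the known
flatness of forest performance in ntree/mtry) and re-evaluates only the
winner with bootstrap confidence intervals (stratified percentile, 2000
resamples of the evaluation sets). Discovery AUC is tenfold stratified
out-of-fold; folds that lose a class are re-folded with a shifted seed and
logged. Rank-sum selection adds the rank of descending mean AUC and the
rank of ascending across-dataset AUC variance; ties break to the higher
mean, then the shorter list, then lexicographic (k, N). The cost wrapper
thresholds the predicted cancer probability at 1/(1+w) — the exact
expected-cost-minimizing rule for two classes — so w = 1 is the base
model and w = 20 gives 1/21; a case-weighted retraining mode is
deliberately not the default since threshold shifting leaves the
underlying probability model (and its ROC) untouched.

## Problem sizes used by the test suite

The acceptance-grade checks run the pipeline at its study-emulating
default scale: 256-sample analysis cohort (+9 HGD, +10 duplicates), 1000
genes in five 30-gene modules with one disease module at standardized
effect 0.8, 200 leave-5-out runs, 100-tree forests for the sweep. Null
calibration of the module test uses 1000 simulated eigengenes at n = 150;
the null-pipeline check (disease effect 0) runs at a reduced scale (300
genes, 50 runs, k up to 8) since its verdict — validation AUC within
0.5 +/- 3 SE — does not depend on the gene count. The paper-scale 2500-run
resampling is available through `PipelineConfig(n_runs=2500)`.

## Known limitations

- The static tree cut stands in for an unspecified dynamic cut; module
  counts depend on it and only the qualitative resampling behaviour is
  reproduced.
- k-means on raw label vectors inherits label-permutation noise; an
  optional co-assignment encoding is a natural extension but is off by
  default to keep the literal procedure.
- The cell-fraction step is a constrained-least-squares method, simpler
  than reference-based robust partial correlation approaches; on the
  synthetic marker model it is exact, on real arrays it would be a
  behavioural approximation.
- Real-cohort performance numbers (AUCs, sensitivities) are not
  reproducible from synthetic data and are not targets of the test suite;
  the suite verifies structure, calibration and recovery, not clinical
  effect sizes.
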