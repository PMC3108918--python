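# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `mdrld`.

## Population model

Haplotype pools evolve forward in time under the simplest model
consistent with the study design: non-overlapping generations, random
union of gametes drawn uniformly with replacement (no sexes, no selfing
prohibition), no mutation, no migration, no selection. Each offspring
haplotype is an independent gamete of two parent haplotypes; crossovers
occur independently per adjacent-locus gap with the template's
recombination fraction (within-block fractions in 1e-7…1e-4, a larger
between-block fraction, default 0.01–0.05). Linkage disequilibrium
therefore arises *only* from drift while the pool is small, which is the
mechanism the growth curve controls.

Population size follows a Richards curve

    N(t) = N0 + (Ninf − N0) · (1 + s·exp(−r (t − t*)))^(−1/s)

rounded to an integer, with shape `s = 1` (logistic) by default, rate
`r` in 0.02–0.04 and generation of maximum growth `t*` as the tuned
parameters. With `s = 1` the discrete growth increment peaks at `t*`
(verified in tests).

**Pool selection.** Several independent simulator runs ("sweeps") vary
`r` over [0.02, 0.04] and the within-block recombination over
[1e-7, 1e-4]; snapshots from all sweeps are pooled, and for each
relative-LD target the closest snapshot within tolerance is selected.
Relative LD is the fraction of polymorphic SNPs (minor-allele frequency
above a 0.01 floor) whose pairwise D′ with at least one other SNP
reaches the 0.90 criterion; the criterion is configurable because no
canonical cutoff exists for "in LD with at least one other SNP".
Snapshots must additionally support the single-locus placement layouts
(a called block with a frequency-qualified edge/interior locus);
two-locus layouts may legitimately be unsatisfiable in low-LD pools and
are recorded as skipped by the full driver, matching the expectation
that same-block scenarios cannot be built where blocks are too small.
If the pooled snapshots cannot satisfy the targets, the sweep is
extended with further runs before giving up.

### Desk-scale study conditions

The package defaults describe the full design (~600 SNPs, 1000
generations, 100 replicates of 1000/1000). All shipped tests and the
acceptance script run `ExperimentConfig.desk_scale()`, sized for one
CPU: 100 loci in ten 10-SNP blocks, founding pool of 500 haplotypes
growing to 4000 with `t* = 900` over 950 generations, three sweeps,
25 replicates of 500 cases / 500 controls.

Two properties of the 100-locus scale shaped the desk configuration,
and both are worth understanding before interpreting results:

* The D′-based relative-LD summary **saturates early**: drift at N=500
  pushes most loci past the 0.90 D′ criterion within ~100 generations,
  long before block members become strongly *correlated* (r²). Pools
  confound MDR only once blocks are internally near-duplicated, so the
  snapshot schedule samples the trajectory densely early (generations
  10–60, candidates for the low-LD pool) and then only late (800 and
  950, mature high-LD pools), and the desk LD targets are 0.55 and 1.0
  — the same low/high contrast as the published 60%-vs-95% comparison.
* Young 100-locus pools at ~40% relative LD almost never contain a
  called 3-SNP block with a frequency-qualified interior locus, so a
  40% target cannot host the middle-of-block layout at this scale; this
  mirrors, one scale down, the fact that same-block scenarios could not
  be built in the published lowest-LD pool.

Passing desk-scale tests shows the mechanism (LD confounds exact but
not indirect detection) reproduces at 1/6 the locus count and 1/4 the
replicates; it does not reproduce the published per-condition counts,
whose source pools are unpublished stochastic artifacts.

## LD statistics and blocks

All LD is computed on phased pool haplotypes — phase is known by
construction, so no EM haplotype-frequency estimation is involved —
with allele 1 as the tracked allele: `D = p11 − pA·pB`;
`Dmax = min(pA(1−pB), (1−pA)pB)` for positive `D` and
`min(pA·pB, (1−pA)(1−pB))` otherwise; `D′ = |D|/Dmax` (0 when `D = 0`);
`r² = D²/(pA qA pB qB)`. Monomorphic loci make these undefined and
raise.

Blocks are maximal runs of consecutive polymorphic loci in which every
adjacent pair has D′ ≥ 0.90 and at least 90% of all within-run pairs
meet the same cutoff; a run failing the all-pairs fraction is shrunk
from its least-connected end. Both thresholds are configuration. This
transparent rule stands in for the (undocumented) block caller of the
original simulation software; it is deliberately simpler than
confidence-interval methods (Gabriel-style calling and four-gamete
tests are out of scope).

## Disease models

**Additive single-locus.** Disease odds at genotype `g` (minor-allele
count) are `odds0 · OR^g`; `odds0` is solved by root-finding so the
Hardy-Weinberg population prevalence equals the requested baseline
(default 0.10). Sensitivity metrics are ratio-based, so the baseline
choice is not load-bearing.

**Purely epistatic two-locus.** Only two constraints are specified for
these models: broad-sense heritability on the penetrance scale,
`H² = Σ_g f_g (p_g − K)²/(K(1−K))`, hits the target, and both
frequency-weighted marginal penetrance vectors are flat (no main
effects). The generator starts from a random 3×3 table and alternates
(i) projection onto the zero-marginal subspace — the frequency-weighted
two-way interaction component, exact in one step — (ii) rescaling of
the deviations to the target variance, and (iii) clipping to [0, 1];
when no clipping is needed both constraints hold exactly, otherwise
iteration continues until residuals fall below 1e-3 (they are always
re-verifiable by direct 9-cell summation).

Feasibility matters here: maximizing the penetrance variance over the
zero-marginal subspace shows that `H² = 0.25` is *unattainable* when
either minor-allele frequency falls much below 0.2 — the rare genotype
cells cannot carry enough variance inside [0, 1]. Two consequences:
functional loci for epistatic models must have MAF in [0.2, 0.5]
(single-locus models use [0.1, 0.5]), and the generator escalates the
prevalence toward 0.5 (where the headroom `K(1−K)` relative to the
bounds is maximal) when the requested prevalence leaves too little
room. Prevalence is otherwise unconstrained for these models.

**Placement.** Blocks are considered in order of decreasing size, so
functional loci land in the most prominent LD structure satisfying the
layout; "edge" is the first or last member of a block, "middle" the
interior member closest to the block centre. The choice among equally
qualifying loci is random (seeded).

**Sampling.** Each individual is two chromosomes drawn uniformly with
replacement; affection is Bernoulli at the penetrance of the
functional genotype; drawing continues until the case and control
quotas fill. Genotype columns are recoded to minor-allele counts using
pool frequencies. Removing functional SNPs happens after penetrance
assignment, which is what makes the dropped-SNP conditions a model of
indirect association.

## MDR implementation

The search is exhaustive over all 1- and 2-locus models. Per
cross-validation fold (10-fold, stratified by status so the per-split
case:control threshold stays stable): cells are labelled high-risk when
`#cases ≥ T · #controls` with `T` the training split's case:control
ratio (the comparison is done in cross-multiplied integer form, so
ratio ties label high exactly); empty cells are *unknown*. Balanced
accuracy is (sensitivity + specificity)/2 of the "high ⇒ case" rule;
individuals in unknown cells are excluded from both numerator and
denominator, and if one status class has no classifiable individuals
the accuracy is the remaining class's rate. Within each fold the model
of each order with the highest training accuracy wins the fold;
CVC(model) = folds won. Best-of-order maximises CVC, then mean testing
accuracy, then lowest locus indices; the overall best maximises CVC,
then testing accuracy, then parsimony (lower order).

Exact training-accuracy ties between models arise routinely in mature
pools, where several SNP columns are identical. When a seeded generator
is supplied, fold wins among exactly tied models are assigned uniformly
at random — equally predictive loci are selected with equal
probability, which is the behaviour the confounding phenomenon
describes; a deterministic lowest-index rule would make duplicated
columns win or lose wholesale. Without a generator the lowest-index
rule applies and the search is fully deterministic (this is the mode
the brute-force oracle equivalence tests exercise).

The implementation is vectorised: per fold, the 9 cell counts of *all*
locus pairs are obtained at once as one-hot matrix products
(`I_a^T I_b` for genotype indicators `a, b ∈ {0,1,2}`), so a 100-locus
dataset (5050 pairs × 10 folds) evaluates in a few hundred
milliseconds. An unoptimised dictionary-and-loops reference
implementation lives in the test suite and must agree with the
vectorised engine on every statistic, to 1e-12.

**Null behaviour.** The cross-validated accuracy of the single overall
best model does not centre on 0.5 under a null dataset: picking the
most consistent of ~5000 models is optimistic by construction, which is
why MDR inference relies on permutation testing. The statistic that is
honest at the null is the held-out accuracy of each fold's
training-selected winner (`SearchResult.cv_prediction_ba`); it centres
on 0.5 (measured 0.4996 ± 0.0032 at 100 loci, 500/500) and is what the
null-calibration test asserts.

## Sensitivity scoring

Exact hit: best-model locus set equals the functional set — a model
with any extra non-functional locus never counts, even if it contains
the functional one. Signal hit: the model order matches the truth and
a one-to-one matching of chosen to functional loci exists with each
pair's pool-level D′ ≥ 0.90 (a functional locus tags itself). The
same-block scenario relaxes both rules to "every chosen locus is
functional / tags some functional locus, at least one chosen", because
two functional SNPs in one block are so correlated that the epistatic
signal presents as a single-locus effect and MDR legitimately returns
one-locus models. D′ for scoring is computed on the source pool, not
the sampled dataset — dropped loci no longer exist in the data, and the
pool is the phase-known ground truth the threshold refers to. A
permissive variant (order match not required outside the same-block
scenario) is available behind `require_order_match=False`.

Sensitivities are reported per 100 replicates; cross-effect-size means
are arithmetic means reported to one decimal. "Within the binomial 95%
margin" for comparing two conditions is implemented as overlapping 95%
Wilson score intervals, which behave correctly when a proportion sits
at 0 or 1 (a naive ±1.96·√(p(1−p)/n) margin collapses to zero width
there).

## Reproducibility and numerics

Every source of randomness flows from one master seed through
`numpy.random.SeedSequence` spawning (per-sweep, per-condition,
per-replicate); identical seeds give bit-identical pools, datasets and
reports. Derived seeds stay below 2³¹. Pool snapshots, datasets and
summaries are plain text with the configuration hash and master seed
embedded; pools selected by the full driver are cached content-addressed
by that hash so the simulation stage is reused across scenarios.

## Limitations

* No mutation, migration, selection or admixture; LD comes from drift
  alone. Real panels carry ascertainment and demographic structure the
  generator does not emulate.
* Desk-scale pools are small (hundreds of haplotypes), so sampled
  datasets resample the same chromosomes many times; this is faithful
  to finite-pool simulation but not to population sampling.
* Genetic heterogeneity, phenocopy, missing data, covariates and
  model orders above 2 are out of scope.
* The block caller is a transparent D′-run rule, not a
  confidence-interval method; block boundaries on real data would
  differ.
* Published per-condition sensitivity counts are not reproducible
  bit-for-bit because the original pools are unpublished; the package
  reproduces the aggregation arithmetic exactly and the confounding
  trends at desk scale.
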