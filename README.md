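# mdrld

Detection sensitivity of Multifactor Dimensionality Reduction (MDR) in
SNP data with linkage disequilibrium (LD).

Genome-wide association analyses rely on LD — the correlation between
nearby variants — to pick up disease signals through tagging SNPs, but
the same correlation confounds the attempt to pinpoint *which* variant
is functional. This package measures that trade-off for MDR, the
exhaustive combinatorial search used to detect gene-gene interactions in
case-control data. It is aimed at statistical geneticists who want to
quantify how often MDR's best model is the embedded functional variant
(*exact sensitivity*) versus a variant merely correlated with it
(*signal sensitivity*), as a function of the LD structure around the
functional locus.

## What it does

The pipeline is simulation-through-analysis, with no external data:

1. **Forward-time simulation** (`mdrld.simulate`) — pools of biallelic
   haplotypes evolve by random mating, genetic drift and block-structured
   recombination while the population grows along a Richards curve
   `N(t) = N₀ + (N∞ − N₀)(1 + s·e^{−r(t−t*)})^{−1/s}`. Drift in the
   small founding phase builds LD inside low-recombination blocks;
   snapshots are selected by **relative LD** — the fraction of
   polymorphic SNPs in LD (pairwise D′ ≥ 0.90) with at least one other
   SNP.
2. **LD statistics** (`mdrld.ld`) — on phased haplotypes:
   `D = p₁₁ − p_A p_B`, `D′ = |D| / D_max`, `r² = D² / (p_A q_A p_B q_B)`,
   plus a D′-based contiguous block caller.
3. **Disease models** (`mdrld.disease`) — single-locus additive tables
   with per-allele odds ratios {1.5, 2.0, 3.0} (baseline odds solved so
   the Hardy-Weinberg prevalence matches a target), and purely epistatic
   two-locus tables at broad-sense heritability
   `H² = Σ_g f_g (p_g − K)² / (K(1−K))` ∈ {5%, 15%, 25%} with *flat*
   marginal penetrances — no main effects. Functional loci are placed
   relative to called blocks in five layouts (edge of a block, middle of
   a block, one in / one out, two separate blocks, two in the same
   block); balanced case-control datasets are drawn by rejection
   sampling through the penetrance table.
4. **MDR** (`mdrld.mdr`) — from scratch: every 1- and 2-locus model's
   genotype cells are labelled high/low risk by the training
   case:control ratio, scored by balanced accuracy under 10-fold
   stratified cross-validation; models are ranked by cross-validation
   consistency (CVC) and the single best model selected.
5. **Sensitivity metrics** (`mdrld.sensitivity`) — over replicate
   datasets: an *exact hit* means the best model equals the functional
   set; a *signal hit* means the best model has the right order and each
   chosen locus tags a functional locus at pool-level D′ ≥ 0.90.
   Dropping the functional SNP before analysis isolates indirect
   association.

## Worked example

```python
from mdrld import ScenarioSpec, relative_ld, run_condition
from mdrld.io import ExperimentConfig, simulate_and_select_pools

config = ExperimentConfig.desk_scale(seed=1)   # 100 loci, single CPU
pools = simulate_and_select_pools(config)      # sweep + select by relative LD
for target, pool in pools.items():
    print(target, pool.generation, relative_ld(pool).relative_ld)

report = run_condition(pools[1.0], ScenarioSpec("middle_of_block", 2.0),
                       n_replicates=25, n_cases=500, n_controls=500, seed=5)
print(report.exact_sensitivity, report.signal_sensitivity)
```

prints (seed 1):

```
0.55 19 0.58
1.0 800 1.0
12.0 100.0
```

Two pools were selected from the simulation sweep: a young low-LD pool
(58% of SNPs have a strong D′ partner) and a mature saturated one. With
an odds-ratio-2.0 functional SNP in the middle of an LD block of the
high-LD pool, MDR finds *a* disease signal in 100% of the 25 replicate
datasets (signal sensitivity 100), but the chosen locus is the actual
functional SNP in only 12% of them (exact sensitivity 12) — the
surrounding block members predict disease as well as the functional
variant itself. Running the same condition in the low-LD pool gives
exact ≈ signal ≈ 90+: with little LD there is nothing to confound the
search.

The same machinery is scriptable from the shell:

```bash
mdrld simulate-pool --desk-scale --seed 1 --out pools/
mdrld sample --pool pools/pool_1.0.txt --layout middle_of_block \
      --effect 2.0 --n-cases 500 --n-controls 500 --seed 5 --out data.txt
mdrld run-mdr --input data.txt --folds 10 --seed 5
mdrld evaluate --pool pools/pool_1.0.txt --scenario middle_of_block \
      --effect 2.0 --replicates 25 --seed 5
mdrld full-run --desk-scale --seed 1
```

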