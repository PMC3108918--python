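"""Penetrance models, functional-locus placement, and case-control sampling.

Disease status is generated from a penetrance table: the probability of
disease given the genotype (minor-allele count) at one functional locus,
or the joint genotype at two.  Two families of models are provided:

* additive single-locus models parameterised by a per-allele odds ratio,
  with the baseline odds solved so the population prevalence matches a
  requested value under Hardy-Weinberg genotype frequencies;
* purely epistatic two-locus models parameterised by broad-sense
  heritability ``H² = Σ_g f_g (p_g - K)² / (K(1-K))`` with *flat*
  single-locus marginal penetrances, so neither functional SNP shows any
  main effect on its own.

Functional loci are placed relative to called LD blocks in one of five
layouts (edge of a block, middle of a block, one in / one out, two
separate blocks, two in the same block), and balanced case-control
datasets are drawn by sampling two chromosomes per individual from the
pool and rejection-sampling affection status until both quotas fill.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .ld import HaplotypePool, LDBlock, allele_frequencies

__all__ = [
    "PenetranceTable",
    "ScenarioSpec",
    "CaseControlDataset",
    "SCENARIO_LAYOUTS",
    "hwe_genotype_frequencies",
    "additive_or_penetrance",
    "broad_sense_heritability",
    "epistatic_penetrance",
    "marginal_penetrances",
    "select_functional_loci",
    "sample_case_control",
    "drop_loci",
]

SCENARIO_LAYOUTS = (
    "edge_of_block",
    "middle_of_block",
    "one_in_one_out",
    "two_separate_blocks",
    "two_same_block",
)

Layout = Literal["edge_of_block", "middle_of_block", "one_in_one_out",
                 "two_separate_blocks", "two_same_block"]


def hwe_genotype_frequencies(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies indexed by minor-allele count."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("minor-allele frequency must lie in (0, 0.5]")
    q = 1.0 - maf
    return np.array([q * q, 2.0 * q * maf, maf * maf])


@dataclass(frozen=True)
class PenetranceTable:
    """Disease probability per genotype, indexed by minor-allele counts.

    ``penetrances`` has shape (3,) for single-locus models and (3, 3)
    for two-locus models; ``maf_context`` holds the minor-allele
    frequency per functional locus and supplies the Hardy-Weinberg
    genotype frequencies for all derived quantities.
    """

    penetrances: np.ndarray
    maf_context: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.penetrances, dtype=float)
        object.__setattr__(self, "penetrances", p)
        if p.shape not in ((3,), (3, 3)):
            raise ValueError("penetrances must have shape (3,) or (3, 3)")
        if len(self.maf_context) != p.ndim:
            raise ValueError("need one MAF per functional locus")
        if p.min() < -1e-12 or p.max() > 1 + 1e-12:
            raise ValueError("penetrances must lie in [0, 1]")

    @property
    def order(self) -> int:
        return self.penetrances.ndim

    def genotype_frequencies(self) -> np.ndarray:
        """Joint Hardy-Weinberg cell frequencies (3 or 3x3)."""
        fs = [hwe_genotype_frequencies(m) for m in self.maf_context]
        return fs[0] if len(fs) == 1 else np.outer(fs[0], fs[1])

    @property
    def prevalence(self) -> float:
        """Population prevalence K = Σ_g f_g p_g."""
        return float((self.genotype_frequencies() * self.penetrances).sum())


def additive_or_penetrance(baseline_prevalence: float, per_allele_or: float,
                           maf: float) -> PenetranceTable:
    """Additive (multiplicative-odds) single-locus penetrance table.

    The disease odds at genotype ``g`` are ``odds(0) * OR**g``; the
    baseline odds are solved numerically so the Hardy-Weinberg population
    prevalence equals ``baseline_prevalence`` at the given MAF.
    """
    if not 0.0 < baseline_prevalence < 1.0:
        raise ValueError("baseline prevalence must lie in (0, 1)")
    if per_allele_or <= 0:
        raise ValueError("odds ratio must be positive")
    f = hwe_genotype_frequencies(maf)
    ors = per_allele_or ** np.arange(3)

    def prevalence_gap(log_odds0: float) -> float:
        odds = np.exp(log_odds0) * ors
        return float((f * odds / (1.0 + odds)).sum()) - baseline_prevalence

    try:
        log_odds0 = brentq(prevalence_gap, -40.0, 40.0, xtol=1e-13)
    except ValueError as exc:  # pragma: no cover - requires pathological input
        raise ValueError("requested prevalence unattainable for this model") from exc
    odds = np.exp(log_odds0) * ors
    return PenetranceTable(odds / (1.0 + odds), (maf,))


def broad_sense_heritability(table: PenetranceTable) -> float:
    """Broad-sense heritability on the penetrance scale.

    ``H² = Σ_g f_g (p_g - K)² / (K(1-K))`` where ``K`` is the prevalence
    — the fraction of total binary-trait variance explained by genotype.
    """
    f = table.genotype_frequencies()
    K = table.prevalence
    if K <= 0.0 or K >= 1.0:
        raise ValueError("heritability undefined at prevalence 0 or 1")
    return float((f * (table.penetrances - K) ** 2).sum() / (K * (1.0 - K)))


def marginal_penetrances(table: PenetranceTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus marginal penetrance vectors of a two-locus table.

    ``m_A(g) = Σ_h f_B(h) p[g, h]`` and symmetrically for B; a purely
    epistatic table has both vectors constant (equal to the prevalence).
    """
    if table.order != 2:
        raise ValueError("marginal penetrances require a two-locus table")
    fa = hwe_genotype_frequencies(table.maf_context[0])
    fb = hwe_genotype_frequencies(table.maf_context[1])
    return table.penetrances @ fb, fa @ table.penetrances


def epistatic_penetrance(target_h2: float, maf_a: float, maf_b: float,
                         tol: float = 1e-3,
                         rng: np.random.Generator | None = None,
                         prevalence: float = 0.25,
                         max_iter: int = 500,
                         n_restarts: int = 50) -> PenetranceTable:
    """Generate a purely epistatic two-locus penetrance table.

    Starting from a random table, the generator alternates between
    projecting onto the subspace of zero frequency-weighted marginal
    deviations (the weighted two-way interaction component), rescaling
    the deviations so the broad-sense heritability hits ``target_h2`` at
    the given prevalence, and clipping to [0, 1].  When no clipping is
    needed the marginal and heritability constraints hold exactly;
    otherwise iteration continues until both residuals drop below
    ``tol``.  The prevalence is a free parameter of these models (only
    the heritability and the flat marginals are constrained); when the
    requested prevalence leaves too little room between the [0, 1]
    penetrance bounds — which happens for skewed MAF pairs, whose rare
    genotype cells need large deviations — the generator retries at
    prevalences stepped toward 0.5, where the variance headroom
    ``K(1-K)`` relative to the bounds is maximal.

    Raises
    ------
    ValueError
        If no table satisfying both constraints is found within the
        restart budget; the message reports the best residuals seen.
    """
    if rng is None:
        rng = np.random.default_rng()
    if target_h2 < 0 or target_h2 > 1:
        raise ValueError("target heritability must lie in [0, 1]")
    fa = hwe_genotype_frequencies(maf_a)
    fb = hwe_genotype_frequencies(maf_b)
    f = np.outer(fa, fb)
    if target_h2 == 0.0:
        return PenetranceTable(np.full((3, 3), prevalence), (maf_a, maf_b))

    best = (np.inf, np.inf, None)

    def interaction_part(d: np.ndarray) -> np.ndarray:
        # frequency-weighted two-way ANOVA decomposition: subtract row and
        # column effects so both weighted marginals vanish exactly
        row = d @ fb
        col = fa @ d
        mu = fa @ d @ fb
        return d - row[:, None] - col[None, :] + mu

    prevalence_ladder = [prevalence]
    for step in (0.35, 0.5):
        if step > prevalence:
            prevalence_ladder.append(step)

    for K in prevalence_ladder:
        target_var = target_h2 * K * (1.0 - K)
        for _ in range(n_restarts):
            d = interaction_part(rng.uniform(-1.0, 1.0, (3, 3)))
            for _ in range(max_iter):
                var = float((f * d * d).sum())
                if var < 1e-14:
                    break
                d *= np.sqrt(target_var / var)
                p = K + d
                if p.min() >= 0.0 and p.max() <= 1.0:
                    return PenetranceTable(p, (maf_a, maf_b))
                d = interaction_part(np.clip(p, 0.0, 1.0) - K)
            else:
                # converged to a clipped fixed point: check residuals
                p = np.clip(K + d, 0.0, 1.0)
                table = PenetranceTable(p, (maf_a, maf_b))
                h2_err = abs(broad_sense_heritability(table) - target_h2)
                ma, mb = marginal_penetrances(table)
                Kt = table.prevalence
                marg_err = max(np.abs(ma - Kt).max(), np.abs(mb - Kt).max())
                if h2_err <= tol and marg_err <= tol:
                    return table
                if h2_err + marg_err < best[0] + best[1]:
                    best = (h2_err, marg_err, table)
    raise ValueError(
        f"could not build a purely epistatic table with H²={target_h2} at "
        f"MAFs ({maf_a}, {maf_b}); best residuals: heritability {best[0]:.2e}, "
        f"marginal flatness {best[1]:.2e}")


@dataclass(frozen=True)
class ScenarioSpec:
    """Where the functional locus or loci sit relative to LD blocks.

    The default MAF window for functional loci is [0.1, 0.5] for
    single-locus models and [0.2, 0.5] for two-locus epistatic models:
    a purely epistatic table with flat marginals cannot reach 25%
    broad-sense heritability when either MAF falls much below 0.2 (the
    rare genotype cells cannot carry enough penetrance variance inside
    [0, 1]), so the allele-frequency requirement is part of the model's
    feasibility, not just a convention.
    """

    layout: Layout
    effect: float
    maf_constraint: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.layout not in SCENARIO_LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.maf_constraint is None:
            window = (0.1, 0.5) if self.order == 1 else (0.2, 0.5)
            object.__setattr__(self, "maf_constraint", window)
        lo, hi = self.maf_constraint
        if not 0.0 <= lo <= hi <= 0.5:
            raise ValueError("MAF constraint must satisfy 0 <= lo <= hi <= 0.5")

    @property
    def order(self) -> int:
        return 1 if self.layout in ("edge_of_block", "middle_of_block") else 2


def _maf_ok(pool: HaplotypePool, spec: ScenarioSpec) -> np.ndarray:
    p = allele_frequencies(pool)
    maf = np.minimum(p, 1.0 - p)
    lo, hi = spec.maf_constraint
    return (maf >= lo) & (maf <= hi)


def select_functional_loci(pool: HaplotypePool, blocks: Sequence[LDBlock],
                           spec: ScenarioSpec,
                           rng: np.random.Generator) -> tuple[int, ...]:
    """Choose functional locus indices satisfying the layout and MAF window.

    Layout meanings: ``edge_of_block`` = first or last member of a block;
    ``middle_of_block`` = the interior member closest to the block
    centre; ``one_in_one_out`` = one block member plus one locus outside
    every called block; ``two_separate_blocks`` = one member from each of
    two distinct blocks; ``two_same_block`` = two members of one block.
    Blocks are considered in order of decreasing size, so the functional
    loci land in the most prominent LD structure that satisfies the
    layout; the choice among equally qualifying loci within a block is
    random.

    Raises
    ------
    ValueError
        If the layout cannot be satisfied in this pool — e.g. two loci in
        the same block when no called block holds two qualifying SNPs (the
        situation of the lowest-LD pool, where block structure is scarce).
    """
    ok = _maf_ok(pool, spec)
    blocks = sorted(blocks, key=lambda b: (-b.size, b.start_locus))

    def fail() -> ValueError:
        return ValueError(
            f"layout {spec.layout!r} unsatisfiable in this pool "
            f"({len(blocks)} blocks, MAF window {spec.maf_constraint})")

    if spec.layout == "edge_of_block":
        for b in blocks:
            edges = [e for e in (b.start_locus, b.end_locus) if ok[e]]
            if edges:
                return (int(edges[rng.integers(len(edges))]),)
        raise fail()

    if spec.layout == "middle_of_block":
        for b in blocks:
            interior = [i for i in range(b.start_locus + 1, b.end_locus) if ok[i]]
            if interior:
                centre = (b.start_locus + b.end_locus) / 2.0
                return (int(min(interior, key=lambda i: (abs(i - centre), i))),)
        raise fail()

    if spec.layout == "one_in_one_out":
        in_any = np.zeros(pool.n_loci, dtype=bool)
        for b in blocks:
            in_any[b.start_locus:b.end_locus + 1] = True
        outside = np.flatnonzero(ok & ~in_any)
        for b in blocks:
            members = [i for i in b.member_loci if ok[i]]
            if members and outside.size:
                mem = int(members[rng.integers(len(members))])
                out = int(outside[rng.integers(outside.size)])
                return (mem, out)
        raise fail()

    if spec.layout == "two_separate_blocks":
        eligible = [[i for i in b.member_loci if ok[i]] for b in blocks]
        eligible = [m for m in eligible if m]
        if len(eligible) >= 2:
            first, second = eligible[0], eligible[1]
            return (int(first[rng.integers(len(first))]),
                    int(second[rng.integers(len(second))]))
        raise fail()

    # two_same_block
    for b in blocks:
        members = [i for i in b.member_loci if ok[i]]
        if len(members) >= 2:
            pick = rng.choice(len(members), size=2, replace=False)
            return tuple(sorted(int(members[k]) for k in pick))
    raise fail()


def layout_feasible(pool: HaplotypePool, blocks: Sequence[LDBlock],
                    spec: ScenarioSpec) -> bool:
    """Whether :func:`select_functional_loci` can satisfy ``spec`` in this pool.

    Satisfiability depends only on the pool, the called blocks and the
    MAF window, not on the random choice among qualifying loci.
    """
    try:
        select_functional_loci(pool, blocks, spec, np.random.default_rng(0))
    except ValueError:
        return False
    return True


@dataclass
class CaseControlDataset:
    """Balanced case-control genotype data drawn from a haplotype pool.

    ``genotypes`` holds minor-allele counts (0/1/2); ``status`` is 1 for
    cases and 0 for controls.  ``functional_loci`` lists the embedded
    disease loci still present in the data, while
    ``embedded_functional_loci`` records the original (pre-drop)
    identities so sensitivity scoring can refer to them after removal.
    """

    genotypes: np.ndarray
    status: np.ndarray
    locus_ids: list[str]
    functional_loci: list[str] = field(default_factory=list)
    embedded_functional_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D")
        if self.genotypes.shape[0] != self.status.shape[0]:
            raise ValueError("one status per individual required")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotypes must be minor-allele counts in {0, 1, 2}")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0 (control) or 1 (case)")
        if len(self.locus_ids) != self.genotypes.shape[1]:
            raise ValueError("locus_ids length must equal the number of columns")
        if not self.embedded_functional_loci:
            self.embedded_functional_loci = list(self.functional_loci)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())


def sample_case_control(pool: HaplotypePool, loci: Sequence[int],
                        table: PenetranceTable, n_cases: int, n_controls: int,
                        rng: np.random.Generator,
                        max_draws: int = 5_000_000) -> CaseControlDataset:
    """Draw a balanced case-control dataset through the penetrance table.

    Each individual is formed from two chromosomes drawn uniformly with
    replacement; affection status is Bernoulli with the penetrance at the
    individual's functional genotype, and drawing continues until both
    the case and control quotas are filled (rejection sampling).
    Genotypes are stored as minor-allele counts: columns where allele 1
    is the major allele in the pool are flipped ``g -> 2 - g``.
    """
    loci = tuple(int(i) for i in loci)
    if table.order != len(loci):
        raise ValueError("penetrance-table order must match the functional loci")
    pen = table.penetrances
    if n_cases > 0 and pen.max() <= 0.0:
        raise ValueError("penetrance is identically 0: case quota unreachable")
    if n_controls > 0 and pen.min() >= 1.0:
        raise ValueError("penetrance is identically 1: control quota unreachable")

    flip = allele_frequencies(pool) > 0.5
    haps = pool.haplotypes
    n_haps = pool.n_haplotypes
    kept_a: list[np.ndarray] = []
    kept_b: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    need_cases, need_controls = n_cases, n_controls
    drawn = 0
    batch = max(2 * (n_cases + n_controls), 1000)
    while need_cases > 0 or need_controls > 0:
        if drawn > max_draws:
            raise ValueError("case/control quota unreachable within draw budget")
        ia = rng.integers(0, n_haps, size=batch)
        ib = rng.integers(0, n_haps, size=batch)
        drawn += batch
        g_fun = haps[ia][:, loci].astype(np.int8) + haps[ib][:, loci].astype(np.int8)
        for k, loc in enumerate(loci):
            if flip[loc]:
                g_fun[:, k] = 2 - g_fun[:, k]
        if table.order == 1:
            probs = pen[g_fun[:, 0]]
        else:
            probs = pen[g_fun[:, 0], g_fun[:, 1]]
        is_case = rng.random(batch) < probs
        take_case = np.flatnonzero(is_case)[:need_cases]
        take_ctrl = np.flatnonzero(~is_case)[:need_controls]
        take = np.concatenate([take_case, take_ctrl])
        kept_a.append(ia[take])
        kept_b.append(ib[take])
        kept_status.append(is_case[take].astype(np.int8))
        need_cases -= take_case.size
        need_controls -= take_ctrl.size

    ia = np.concatenate(kept_a)
    ib = np.concatenate(kept_b)
    status = np.concatenate(kept_status)
    genotypes = haps[ia].astype(np.int8) + haps[ib].astype(np.int8)
    genotypes[:, flip] = 2 - genotypes[:, flip]
    functional_ids = [pool.locus_ids[i] for i in loci]
    return CaseControlDataset(genotypes, status, list(pool.locus_ids),
                              functional_loci=functional_ids,
                              embedded_functional_loci=functional_ids)


def drop_loci(dataset: CaseControlDataset,
              loci: Sequence[int | str]) -> CaseControlDataset:
    """Remove named loci from a dataset, leaving statuses untouched.

    Removal happens after the penetrance function was applied, so
    dropping a functional SNP simulates an indirect association: the
    disease signal remains in the data only through loci correlated with
    the removed one.
    """
    drop_ids = set()
    for loc in loci:
        lid = dataset.locus_ids[loc] if isinstance(loc, int) else loc
        if lid not in dataset.locus_ids:
            raise KeyError(f"unknown locus id {lid!r}")
        drop_ids.add(lid)
    keep = [k for k, lid in enumerate(dataset.locus_ids) if lid not in drop_ids]
    return CaseControlDataset(
        dataset.genotypes[:, keep],
        dataset.status.copy(),
        [dataset.locus_ids[k] for k in keep],
        functional_loci=[lid for lid in dataset.functional_loci if lid not in drop_ids],
        embedded_functional_loci=list(dataset.embedded_functional_loci),
    )
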