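"""Replicate experiments and the exact / signal detection-sensitivity metrics.

For each condition (pool LD level x scenario layout x effect size x
drop plan) many balanced case-control replicates are drawn, each is
analysed with the exhaustive MDR search, and the chosen best model is
scored two ways:

* **exact hit** — the best model's locus set equals the embedded
  functional set (a model with any extra, non-functional locus never
  counts, even if it contains the functional one);
* **signal hit** — the best model has the right order and each chosen
  locus tags a functional locus at pool-level ``D' >= 0.90`` (a
  functional locus tags itself with ``D' = 1``), so indirect association
  through LD counts.

The same-block scenario relaxes both rules: because two functional SNPs
in one LD block are highly correlated, the epistatic signal collapses to
a single-locus effect and MDR legitimately returns one-locus models, so
a best model counts as exact when every chosen locus is functional (at
least one), and as a signal when every chosen locus tags some functional
locus.

``D'`` for signal scoring is computed on the source haplotype pool, not
on the sampled dataset: dropped loci no longer exist in the data, and
the pool is the phase-known ground truth the threshold refers to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import ld as _ld
from .disease import (CaseControlDataset, PenetranceTable, ScenarioSpec,
                      additive_or_penetrance, drop_loci, epistatic_penetrance,
                      sample_case_control, select_functional_loci)
from .ld import HaplotypePool, LDBlock, allele_frequencies, call_ld_blocks
from .mdr import exhaustive_search, make_cv_plan

__all__ = [
    "ReplicateResult",
    "SensitivityReport",
    "DprimeLookup",
    "exact_hit",
    "signal_hit",
    "run_condition",
    "mean_over_effect_sizes",
    "tagging_ld_report",
]

SIGNAL_DPRIME_THRESHOLD = 0.90


class DprimeLookup:
    """Pool-level pairwise ``D'`` lookup keyed by locus id.

    A locus always has ``D' = 1`` with itself.  Asking about a locus id
    absent from the pool, or a monomorphic locus, raises ``KeyError`` /
    ``ValueError`` rather than silently returning 0.
    """

    def __init__(self, pool: HaplotypePool):
        self._pool = pool
        self._index = {lid: i for i, lid in enumerate(pool.locus_ids)}
        self._dp = _ld.dprime_matrix(pool)

    def __call__(self, locus_a: str, locus_b: str) -> float:
        try:
            i, j = self._index[locus_a], self._index[locus_b]
        except KeyError as exc:
            raise KeyError(f"locus {exc.args[0]!r} not present in the pool") from None
        if locus_a == locus_b:
            return 1.0
        value = self._dp[i, j]
        if np.isnan(value):
            raise ValueError(
                f"D' between {locus_a!r} and {locus_b!r} is undefined "
                "(monomorphic locus)")
        return float(value)


@dataclass(frozen=True)
class ReplicateResult:
    """Best model and hit flags for one replicate dataset."""

    replicate_id: int
    best_loci: tuple[str, ...]
    best_order: int
    exact: bool
    signal: bool
    dropped_loci: tuple[str, ...] = ()
    scenario_layout: str = ""


@dataclass(frozen=True)
class SensitivityReport:
    """Exact / signal hit counts over the replicates of one condition.

    Sensitivities are reported on the per-100 scale the counts-of-100
    convention implies: 87 means 87% of replicates were hits.
    """

    n_replicates: int
    exact_count: int
    signal_count: int
    ld_level: Optional[float] = None
    scenario_layout: str = ""
    effect: Optional[float] = None
    drop_status: str = "none"
    replicates: tuple[ReplicateResult, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.exact_count <= self.signal_count <= self.n_replicates:
            raise ValueError(
                "hit counts must satisfy 0 <= exact <= signal <= n_replicates")

    @property
    def exact_sensitivity(self) -> float:
        return 100.0 * self.exact_count / self.n_replicates

    @property
    def signal_sensitivity(self) -> float:
        return 100.0 * self.signal_count / self.n_replicates


def exact_hit(best_loci: Sequence[str], functional_loci: Sequence[str],
              scenario_layout: str = "") -> bool:
    """Does the best model identify the functional loci exactly?

    By default the locus sets must be identical (so the order must match:
    a two-locus model containing the single functional SNP plus anything
    else does not count).  In the same-block scenario a model counts if it
    contains at least one functional locus and nothing non-functional.
    """
    best = set(best_loci)
    truth = set(functional_loci)
    if scenario_layout == "two_same_block":
        return bool(best) and best <= truth
    return best == truth


def signal_hit(best_loci: Sequence[str], functional_loci: Sequence[str],
               dprime_lookup: DprimeLookup,
               threshold: float = SIGNAL_DPRIME_THRESHOLD,
               scenario_layout: str = "",
               require_order_match: bool = True) -> bool:
    """Does the best model tag the functional loci at ``D' >= threshold``?

    Default rule: the model order must equal the number of functional
    loci and there must be a one-to-one matching of chosen loci to
    functional loci with each pair's pool ``D'`` at or above the
    threshold.  Same-block rule: any one- or two-locus model counts as
    long as *every* chosen locus tags some functional locus.  A chosen
    locus below the threshold against all functional loci always spoils
    the hit.  ``require_order_match=False`` applies the same-block
    (every-locus-tags-something) rule everywhere.
    """
    best = list(best_loci)
    truth = list(functional_loci)
    if scenario_layout == "two_same_block" or not require_order_match:
        return all(any(dprime_lookup(b, f) >= threshold for f in truth)
                   for b in best)
    if len(best) != len(truth):
        return False
    if len(best) == 1:
        return dprime_lookup(best[0], truth[0]) >= threshold
    b1, b2 = best
    f1, f2 = truth
    return ((dprime_lookup(b1, f1) >= threshold and dprime_lookup(b2, f2) >= threshold)
            or (dprime_lookup(b1, f2) >= threshold and dprime_lookup(b2, f1) >= threshold))


def _resolve_drop(drop_plan, functional_ids: tuple[str, ...]) -> tuple[str, ...]:
    if drop_plan in (None, "none"):
        return ()
    if drop_plan == "first":
        return (functional_ids[0],)
    if drop_plan == "second":
        if len(functional_ids) < 2:
            raise ValueError("drop plan 'second' needs a two-locus model")
        return (functional_ids[1],)
    if drop_plan in ("both", "all"):
        return tuple(functional_ids)
    return tuple(functional_ids[int(k)] for k in drop_plan)


def run_condition(pool: HaplotypePool, scenario: ScenarioSpec,
                  n_replicates: int = 100,
                  n_cases: int = 1000, n_controls: int = 1000,
                  drop_plan=None, seed: int = 0,
                  blocks: Optional[Sequence[LDBlock]] = None,
                  functional_loci: Optional[Sequence[int]] = None,
                  prevalence: float = 0.10,
                  n_folds: int = 10,
                  signal_threshold: float = SIGNAL_DPRIME_THRESHOLD,
                  ld_level: Optional[float] = None) -> SensitivityReport:
    """Run one experimental condition end to end.

    Chooses functional loci for the scenario (once per condition, as the
    source pools are reused across replicates), builds the penetrance
    table (additive odds-ratio model for one-locus scenarios at the given
    baseline ``prevalence``, purely epistatic model at the given
    heritability for two-locus scenarios), then for every replicate draws
    a balanced case-control dataset, applies the drop plan, runs the
    exhaustive MDR search and scores exact and signal hits.  Everything
    is reproducible from ``seed``.
    """
    master = np.random.SeedSequence(seed)
    rng_setup = np.random.default_rng(master.spawn(1)[0])
    if blocks is None:
        blocks = call_ld_blocks(pool)
    if functional_loci is None:
        functional_loci = select_functional_loci(pool, blocks, scenario, rng_setup)
    functional_loci = tuple(int(i) for i in functional_loci)
    functional_ids = tuple(pool.locus_ids[i] for i in functional_loci)

    p = allele_frequencies(pool)
    mafs = [float(min(p[i], 1.0 - p[i])) for i in functional_loci]
    if scenario.order == 1:
        table = additive_or_penetrance(prevalence, scenario.effect, mafs[0])
    else:
        table = epistatic_penetrance(scenario.effect, mafs[0], mafs[1],
                                     rng=rng_setup)

    to_drop = _resolve_drop(drop_plan, functional_ids)
    lookup = DprimeLookup(pool)
    results: list[ReplicateResult] = []
    for rep, child in enumerate(master.spawn(n_replicates + 1)[1:]):
        rng = np.random.default_rng(child)
        dataset = sample_case_control(pool, functional_loci, table,
                                      n_cases, n_controls, rng)
        if to_drop:
            dataset = drop_loci(dataset, list(to_drop))
        plan = make_cv_plan(dataset, n_folds=n_folds, rng=rng)
        best = exhaustive_search(dataset, plan, keep_fold_maps=False,
                                 rng=rng).best
        best_ids = tuple(dataset.locus_ids[i] for i in best.loci)
        ex = exact_hit(best_ids, functional_ids, scenario.layout)
        sig = signal_hit(best_ids, functional_ids, lookup,
                         threshold=signal_threshold,
                         scenario_layout=scenario.layout)
        # an exact hit is always a signal hit (self-D' = 1)
        sig = sig or ex
        results.append(ReplicateResult(rep, best_ids, best.order, ex, sig,
                                       dropped_loci=to_drop,
                                       scenario_layout=scenario.layout))

    drop_status = "none" if not to_drop else "+".join(to_drop)
    return SensitivityReport(
        n_replicates=n_replicates,
        exact_count=sum(r.exact for r in results),
        signal_count=sum(r.signal for r in results),
        ld_level=ld_level,
        scenario_layout=scenario.layout,
        effect=scenario.effect,
        drop_status=drop_status,
        replicates=tuple(results),
    )


def mean_over_effect_sizes(reports: Sequence[SensitivityReport]
                           ) -> tuple[float, float]:
    """Mean exact and signal sensitivity across effect sizes, to one decimal.

    All reports must describe the same condition apart from the effect
    size (same LD level, layout and drop status); differences between
    effect sizes are typically small, so the cross-effect mean is the
    comparison statistic.
    """
    if not reports:
        raise ValueError("need at least one report")
    keys = {(r.ld_level, r.scenario_layout, r.drop_status) for r in reports}
    if len(keys) > 1:
        raise ValueError(f"reports mix conditions: {sorted(map(str, keys))}")
    mean_exact = float(np.mean([r.exact_sensitivity for r in reports]))
    mean_signal = float(np.mean([r.signal_sensitivity for r in reports]))
    return round(mean_exact, 1), round(mean_signal, 1)


def tagging_ld_report(replicate_results: Sequence[ReplicateResult],
                      pool: HaplotypePool,
                      functional_loci: Sequence[str],
                      matching_order_only: bool = False) -> pd.DataFrame:
    """LD between chosen and functional loci, one row per locus pair.

    For every best model, reports ``D'``, ``r²`` and the minor-allele-
    frequency difference between each chosen locus and each functional
    locus.  With ``matching_order_only`` rows are restricted to best
    models whose order equals the number of functional loci (the
    convention used when examining two-locus choices for two-locus
    models).  High-``D'``/low-``r²`` rows are the tagging SNPs whose
    selection explains the gap between signal and exact sensitivity.
    """
    p = allele_frequencies(pool)
    maf = np.minimum(p, 1.0 - p)
    index = {lid: i for i, lid in enumerate(pool.locus_ids)}
    truth_order = len(functional_loci)
    rows = []
    for res in replicate_results:
        if matching_order_only and res.best_order != truth_order:
            continue
        for chosen in res.best_loci:
            for fun in functional_loci:
                ci, fi = index[chosen], index[fun]
                if chosen == fun:
                    dprime, r2 = 1.0, 1.0
                else:
                    stats = _ld.pairwise_ld(pool, ci, fi)
                    dprime, r2 = stats.Dprime, stats.r2
                rows.append((res.replicate_id, chosen, fun, dprime, r2,
                             abs(float(maf[ci] - maf[fi])), res.best_order))
    return pd.DataFrame(rows, columns=["replicate_id", "chosen_locus",
                                       "functional_locus", "Dprime", "r2",
                                       "maf_difference", "best_model_order"])
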