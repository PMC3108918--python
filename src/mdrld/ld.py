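"""Pairwise linkage-disequilibrium statistics, LD-block calling, and the
relative-LD summary used to classify simulated haplotype pools.

All statistics are computed on phased haplotypes (a pool of simulated
chromosomes), so haplotype frequencies are observed directly and no
EM phasing step is needed.  The three classical statistics are

* ``D``  — the disequilibrium coefficient, the frequency of the 1/1
  haplotype minus the product of the allele-1 frequencies;
* ``D'`` — ``|D|`` normalised by the maximum value it could attain given
  the allele frequencies, so ``D' = 1`` means at least one of the four
  possible haplotypes is absent;
* ``r²`` — the squared allelic correlation, ``D² / (pA(1-pA) pB(1-pB))``.

``r² = 1`` implies ``D' = 1`` but not conversely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypePool",
    "PairwiseLD",
    "LDBlock",
    "LDProfile",
    "allele_frequencies",
    "pairwise_ld",
    "dprime_matrix",
    "polymorphic_mask",
    "call_ld_blocks",
    "relative_ld",
    "pairwise_ld_table",
    "blocks_to_bed",
]

#: default pairwise criterion for "in LD with at least one other SNP";
#: the same constant used by the signal-sensitivity rule.
DEFAULT_LD_CRITERION = 0.90
#: loci with minor-allele frequency at or below this floor are excluded
#: from relative-LD denominators and from block membership.
DEFAULT_MAF_FLOOR = 0.01


@dataclass
class HaplotypePool:
    """A population of phased chromosomes.

    Parameters
    ----------
    haplotypes
        2-D array of binary alleles, rows = chromosomes, columns = loci.
    locus_ids
        Unique ordered locus labels, one per column.
    generation
        Forward-simulation generation index of this snapshot.
    map_positions
        Optional per-locus coordinates in arbitrary units.
    """

    haplotypes: np.ndarray
    locus_ids: list[str]
    generation: int = 0
    map_positions: Optional[np.ndarray] = None
    seed_provenance: Optional[str] = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D array")
        if self.haplotypes.shape[0] < 2:
            raise ValueError("a pool needs at least 2 haplotypes")
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be 0 or 1")
        self.locus_ids = [str(x) for x in self.locus_ids]
        if len(self.locus_ids) != self.haplotypes.shape[1]:
            raise ValueError("locus_ids length must equal the number of columns")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus_ids must be unique")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]

    def locus_index(self, locus: int | str) -> int:
        """Resolve a locus given either its column index or its label."""
        if isinstance(locus, str):
            try:
                return self.locus_ids.index(locus)
            except ValueError:
                raise KeyError(f"unknown locus id {locus!r}") from None
        return int(locus)


@dataclass(frozen=True)
class PairwiseLD:
    """LD statistics for one locus pair (allele 1 is the tracked allele)."""

    D: float
    Dprime: float
    r2: float
    pA: float
    pB: float


@dataclass(frozen=True)
class LDBlock:
    """A contiguous run of loci in strong mutual LD (inclusive indices)."""

    start_locus: int
    end_locus: int

    def __post_init__(self) -> None:
        if self.start_locus > self.end_locus:
            raise ValueError("block start must not exceed end")

    @property
    def member_loci(self) -> range:
        return range(self.start_locus, self.end_locus + 1)

    @property
    def size(self) -> int:
        return self.end_locus - self.start_locus + 1

    def __contains__(self, locus: int) -> bool:
        return self.start_locus <= locus <= self.end_locus


@dataclass(frozen=True)
class LDProfile:
    """Relative-LD summary of a pool.

    ``relative_ld`` is the ratio of SNPs in LD (pairwise ``D'`` at or
    above ``threshold_used``) with at least one other SNP to the total
    number of polymorphic SNPs.
    """

    relative_ld: float
    n_polymorphic: int
    n_in_ld: int
    threshold_used: float


def allele_frequencies(pool: HaplotypePool) -> np.ndarray:
    """Per-locus frequency of allele 1 (the column mean of the pool)."""
    if pool.n_haplotypes == 0 or pool.n_loci == 0:
        raise ValueError("empty pool has no allele frequencies")
    return pool.haplotypes.mean(axis=0)


def minor_allele_frequencies(pool: HaplotypePool) -> np.ndarray:
    p = allele_frequencies(pool)
    return np.minimum(p, 1.0 - p)


def polymorphic_mask(pool: HaplotypePool, maf_floor: float = DEFAULT_MAF_FLOOR) -> np.ndarray:
    """Boolean mask of loci whose minor-allele frequency exceeds ``maf_floor``."""
    return minor_allele_frequencies(pool) > maf_floor


def pairwise_ld(pool: HaplotypePool, i: int | str, j: int | str) -> PairwiseLD:
    """Compute ``D``, ``D'`` and ``r²`` between two polymorphic loci.

    ``D`` is the observed frequency of the 1/1 haplotype minus
    ``pA * pB``; ``D'`` is ``|D|`` over its bound given the allele
    frequencies; ``r²`` is ``D²`` over the product of the four allele
    variances.

    Raises
    ------
    ValueError
        If either locus is monomorphic (the normalisers are zero).
    """
    ii, jj = pool.locus_index(i), pool.locus_index(j)
    a = pool.haplotypes[:, ii].astype(float)
    b = pool.haplotypes[:, jj].astype(float)
    pA, pB = a.mean(), b.mean()
    for locus, p in ((i, pA), (j, pB)):
        if p <= 0.0 or p >= 1.0:
            raise ValueError(f"locus {locus!r} is monomorphic (freq {p}); LD undefined")
    p11 = (a * b).mean()
    D = p11 - pA * pB
    if D > 0:
        dmax = min(pA * (1.0 - pB), (1.0 - pA) * pB)
    else:
        dmax = min(pA * pB, (1.0 - pA) * (1.0 - pB))
    dprime = 0.0 if D == 0 else abs(D) / dmax
    r2 = D * D / (pA * (1.0 - pA) * pB * (1.0 - pB))
    # guard tiny float excursions above 1 from the mean computations
    return PairwiseLD(D=float(D), Dprime=float(min(dprime, 1.0)),
                      r2=float(min(r2, 1.0)), pA=float(pA), pB=float(pB))


def _ld_matrices(pool: HaplotypePool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full pairwise (D, D', r²) matrices; NaN where a locus is monomorphic."""
    H = pool.haplotypes.astype(np.float64)
    n, L = H.shape
    p = H.mean(axis=0)
    P11 = (H.T @ H) / n
    D = P11 - np.outer(p, p)
    q = 1.0 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        dmax_pos = np.minimum(np.outer(p, q), np.outer(q, p))
        dmax_neg = np.minimum(np.outer(p, p), np.outer(q, q))
        dmax = np.where(D > 0, dmax_pos, dmax_neg)
        dprime = np.abs(D) / dmax
        dprime = np.where(D == 0, 0.0, dprime)
        r2 = D * D / np.outer(p * q, p * q)
    mono = (p <= 0) | (p >= 1)
    dprime[mono, :] = np.nan
    dprime[:, mono] = np.nan
    r2[mono, :] = np.nan
    r2[:, mono] = np.nan
    np.fill_diagonal(dprime, np.nan)
    np.fill_diagonal(r2, np.nan)
    return D, np.clip(dprime, 0.0, 1.0), np.clip(r2, 0.0, 1.0)


def dprime_matrix(pool: HaplotypePool) -> np.ndarray:
    """Pairwise ``D'`` matrix with NaN on the diagonal and monomorphic loci."""
    return _ld_matrices(pool)[1]


def relative_ld(
    pool: HaplotypePool,
    criterion: float = DEFAULT_LD_CRITERION,
    maf_floor: float = DEFAULT_MAF_FLOOR,
) -> LDProfile:
    """Fraction of polymorphic SNPs in LD with at least one other SNP.

    A locus counts as "in LD" when its pairwise ``D'`` with some other
    polymorphic locus is at or above ``criterion``.  Loci at or below the
    ``maf_floor`` are excluded from both numerator and denominator.
    """
    poly = polymorphic_mask(pool, maf_floor)
    n_poly = int(poly.sum())
    if n_poly == 0:
        raise ValueError("pool has no polymorphic loci; relative LD undefined")
    dp = dprime_matrix(pool)
    dp = dp[np.ix_(poly, poly)]
    with np.errstate(invalid="ignore"):
        in_ld = np.nansum(dp >= criterion, axis=1) > 0
    n_in = int(in_ld.sum())
    return LDProfile(relative_ld=n_in / n_poly, n_polymorphic=n_poly,
                     n_in_ld=n_in, threshold_used=criterion)


def call_ld_blocks(
    pool: HaplotypePool,
    block_dprime: float = 0.90,
    min_fraction: float = 0.90,
    maf_floor: float = DEFAULT_MAF_FLOOR,
) -> list[LDBlock]:
    """Call contiguous LD blocks from the pairwise ``D'`` matrix.

    A block is a maximal run of consecutive polymorphic loci in which
    every adjacent pair has ``D' >= block_dprime`` and at least
    ``min_fraction`` of all within-run pairs meet the same cutoff.  A run
    that fails the all-pairs fraction is shrunk one locus at a time from
    whichever end is least connected to the rest of the run.  Blocks have
    at least two members; loci at or below ``maf_floor`` never join one.
    """
    poly = polymorphic_mask(pool, maf_floor)
    if int(poly.sum()) < 2:
        return []
    dp = dprime_matrix(pool)
    strong = np.zeros_like(dp, dtype=bool)
    with np.errstate(invalid="ignore"):
        strong[~np.isnan(dp)] = dp[~np.isnan(dp)] >= block_dprime
    L = pool.n_loci

    def frac_ok(lo: int, hi: int) -> bool:
        sub = strong[lo:hi + 1, lo:hi + 1]
        k = hi - lo + 1
        total = k * (k - 1) / 2
        return (np.triu(sub, 1).sum() / total) >= min_fraction

    blocks: list[LDBlock] = []
    i = 0
    while i < L - 1:
        if not (poly[i] and poly[i + 1] and strong[i, i + 1]):
            i += 1
            continue
        j = i + 1
        while j + 1 < L and poly[j + 1] and strong[j, j + 1]:
            j += 1
        lo, hi = i, j
        while hi - lo >= 1 and not frac_ok(lo, hi):
            left_conn = strong[lo, lo + 1:hi + 1].mean()
            right_conn = strong[hi, lo:hi].mean()
            if left_conn < right_conn:
                lo += 1
            else:
                hi -= 1
        if hi - lo >= 1:
            blocks.append(LDBlock(lo, hi))
        i = j + 1
    return blocks


def pairwise_ld_table(pool: HaplotypePool, maf_floor: float = DEFAULT_MAF_FLOOR) -> pd.DataFrame:
    """All-pairs LD statistics over polymorphic loci as a tidy DataFrame."""
    D, dp, r2 = _ld_matrices(pool)
    poly = np.flatnonzero(polymorphic_mask(pool, maf_floor))
    rows = []
    for a_idx, i in enumerate(poly):
        for j in poly[a_idx + 1:]:
            rows.append((pool.locus_ids[i], pool.locus_ids[j],
                         D[i, j], dp[i, j], r2[i, j]))
    return pd.DataFrame(rows, columns=["locus_i", "locus_j", "D", "Dprime", "r2"])


def blocks_to_bed(blocks: Sequence[LDBlock], chrom: str = "chr1") -> pd.DataFrame:
    """Blocks as BED-like half-open intervals on locus indices."""
    return pd.DataFrame(
        [(chrom, b.start_locus, b.end_locus + 1) for b in blocks],
        columns=["chrom", "start", "end"],
    )
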