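"""Penetrance models, scenario placement, and case-control sampling."""

import numpy as np
import pytest

from mdrld.disease import (CaseControlDataset, PenetranceTable, ScenarioSpec,
                           additive_or_penetrance, broad_sense_heritability,
                           drop_loci, epistatic_penetrance,
                           hwe_genotype_frequencies, layout_feasible,
                           marginal_penetrances, sample_case_control,
                           select_functional_loci)
from mdrld.ld import HaplotypePool, LDBlock, call_ld_blocks


def h2_oracle(pen, mafs):
    """Direct exhaustive-summation heritability, independent of the package."""
    pen = np.asarray(pen, dtype=float)
    f = hwe_genotype_frequencies(mafs[0])
    if pen.ndim == 2:
        f = np.outer(f, hwe_genotype_frequencies(mafs[1]))
    K = float((f * pen).sum())
    return float((f * (pen - K) ** 2).sum() / (K * (1 - K)))


class TestAdditiveModel:
    def test_null_odds_ratio_gives_flat_penetrance(self):
        t = additive_or_penetrance(0.1, 1.0, 0.3)
        np.testing.assert_allclose(t.penetrances, 0.1, atol=1e-10)

    def test_adjacent_genotype_odds_ratios_are_exact(self):
        t = additive_or_penetrance(0.05, 2.0, 0.25)
        odds = t.penetrances / (1 - t.penetrances)
        assert odds[1] / odds[0] == pytest.approx(2.0)
        assert odds[2] / odds[1] == pytest.approx(2.0)
        assert t.penetrances[0] < t.penetrances[1] < t.penetrances[2]

    @pytest.mark.parametrize("or_,maf,prev", [(3.0, 0.25, 0.10),
                                              (1.5, 0.4, 0.2),
                                              (2.0, 0.1, 0.05)])
    def test_prevalence_constraint_verified_by_summation(self, or_, maf, prev):
        t = additive_or_penetrance(prev, or_, maf)
        f = hwe_genotype_frequencies(maf)
        assert float((f * t.penetrances).sum()) == pytest.approx(prev, abs=1e-9)

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            additive_or_penetrance(0.0, 2.0, 0.3)


class TestHeritability:
    def test_constant_table_has_zero_heritability(self):
        t = PenetranceTable(np.full((3, 3), 0.2), (0.3, 0.3))
        assert broad_sense_heritability(t) == pytest.approx(0.0, abs=1e-15)

    def test_deterministic_table_saturates(self):
        pen = np.array([0.0, 1.0, 1.0])
        t = PenetranceTable(pen, (0.5,))
        assert broad_sense_heritability(t) == pytest.approx(1.0)

    def test_matches_nine_cell_summation(self):
        pen = np.array([[0.05, 0.1, 0.3],
                        [0.1, 0.2, 0.4],
                        [0.3, 0.4, 0.9]])
        t = PenetranceTable(pen, (0.3, 0.4))
        assert broad_sense_heritability(t) == pytest.approx(
            h2_oracle(pen, (0.3, 0.4)))

    def test_degenerate_prevalence_rejected(self):
        t = PenetranceTable(np.zeros((3, 3)), (0.3, 0.3))
        with pytest.raises(ValueError):
            broad_sense_heritability(t)


class TestEpistaticGenerator:
    def test_zero_target_returns_flat_table(self, rng):
        t = epistatic_penetrance(0.0, 0.3, 0.4, rng=rng)
        assert np.ptp(t.penetrances) == 0.0

    @pytest.mark.parametrize("target", [0.05, 0.15, 0.25])
    def test_constraints_verified_independently(self, target, rng):
        t = epistatic_penetrance(target, 0.3, 0.4, rng=rng)
        assert h2_oracle(t.penetrances, t.maf_context) == pytest.approx(
            target, abs=1e-3)
        f_b = hwe_genotype_frequencies(0.4)
        f_a = hwe_genotype_frequencies(0.3)
        K = t.prevalence
        marg_a = t.penetrances @ f_b
        marg_b = f_a @ t.penetrances
        assert np.abs(marg_a - K).max() <= 1e-3
        assert np.abs(marg_b - K).max() <= 1e-3

    def test_xor_style_table_has_flat_marginals_by_symmetry(self):
        """At MAF 0.5/0.5 a checkerboard deviation has zero marginals;
        the generator's projection must preserve that structure."""
        pen = 0.25 + 0.2 * np.array([[1, -1, 1], [-1, 1, -1], [1, -1, 1]],
                                    dtype=float)
        t = PenetranceTable(pen, (0.5, 0.5))
        ma, mb = marginal_penetrances(t)
        assert np.ptp(ma) == pytest.approx(0.0, abs=1e-12)
        assert np.ptp(mb) == pytest.approx(0.0, abs=1e-12)

    def test_marginal_detection_of_additive_table(self):
        pen = np.tile(np.array([0.1, 0.2, 0.3]), (3, 1)).T
        t = PenetranceTable(pen, (0.3, 0.3))
        ma, _ = marginal_penetrances(t)
        assert np.ptp(ma) > 0.1


class TestScenarioPlacement:
    def make_pool(self, rng):
        """200 haplotypes x 12 loci: a perfect 5-locus block (0-4), a
        perfect 3-locus block (7-9), independent elsewhere."""
        cols = []
        base1 = (rng.random(200) < 0.5).astype(np.uint8)
        base2 = (rng.random(200) < 0.4).astype(np.uint8)
        base1[:2] = [1, 0]; base2[:2] = [1, 0]
        for i in range(12):
            if i < 5:
                cols.append(base1)
            elif 7 <= i <= 9:
                cols.append(base2)
            else:
                c = (rng.random(200) < 0.3).astype(np.uint8)
                c[:2] = [1, 0]
                cols.append(c)
        return HaplotypePool(np.column_stack(cols),
                             [f"m{i}" for i in range(12)])

    def test_all_layouts_resolve_and_respect_maf(self, rng):
        pool = self.make_pool(rng)
        blocks = call_ld_blocks(pool)
        from mdrld.ld import minor_allele_frequencies
        maf = minor_allele_frequencies(pool)
        for layout in ("edge_of_block", "middle_of_block", "one_in_one_out",
                       "two_separate_blocks", "two_same_block"):
            spec = ScenarioSpec(layout, 2.0 if layout.startswith(("edge", "middle")) else 0.15)
            loci = select_functional_loci(pool, blocks, spec, rng)
            assert len(loci) == spec.order
            assert all(0.1 <= maf[i] <= 0.5 for i in loci)
        mid = select_functional_loci(
            pool, blocks, ScenarioSpec("middle_of_block", 2.0), rng)
        assert mid[0] in (1, 2, 3)  # strictly interior to the big block
        edge = select_functional_loci(
            pool, blocks, ScenarioSpec("edge_of_block", 2.0), rng)
        assert edge[0] in (0, 4, 7, 9)

    def test_same_block_layout_fails_without_big_blocks(self, rng):
        freqs = rng.uniform(0.3, 0.7, 10)
        haps = (rng.random((500, 10)) < freqs).astype(np.uint8)
        pool = HaplotypePool(haps, [str(i) for i in range(10)])
        blocks = call_ld_blocks(pool)  # no blocks in an independent pool
        spec = ScenarioSpec("two_same_block", 0.15)
        assert not layout_feasible(pool, blocks, spec)
        with pytest.raises(ValueError, match="unsatisfiable"):
            select_functional_loci(pool, blocks, spec, rng)


class TestCaseControlSampling:
    def make_pool(self, rng, n=400, L=6):
        freqs = rng.uniform(0.2, 0.5, L)
        haps = (rng.random((n, L)) < freqs).astype(np.uint8)
        return HaplotypePool(haps, [f"p{i}" for i in range(L)])

    def test_quotas_and_bookkeeping(self, rng):
        pool = self.make_pool(rng)
        table = additive_or_penetrance(0.1, 2.0, 0.3)
        ds = sample_case_control(pool, (2,), table, 150, 100, rng)
        assert ds.n_cases == 150 and ds.n_controls == 100
        assert ds.functional_loci == ["p2"]

    def test_degenerate_penetrance_rejected(self, rng):
        pool = self.make_pool(rng)
        ones = PenetranceTable(np.ones(3), (0.3,))
        with pytest.raises(ValueError, match="control quota"):
            sample_case_control(pool, (0,), ones, 10, 10, rng)

    def test_deterministic_disease_forces_genotype_two(self, rng):
        pool = self.make_pool(rng)
        table = PenetranceTable(np.array([0.0, 0.0, 1.0]), (0.3,))
        ds = sample_case_control(pool, (1,), table, 50, 50, rng)
        col = ds.genotypes[:, 1]
        assert (col[ds.status == 1] == 2).all()
        assert (col[ds.status == 0] != 2).all()

    def test_case_genotype_distribution_follows_bayes_rule(self, rng):
        """P(g | case) = f_g p_g / K within Monte-Carlo error."""
        pool = self.make_pool(rng, n=20_000)
        p1 = pool.haplotypes[:, 0].mean()
        maf = float(min(p1, 1 - p1))
        table = additive_or_penetrance(0.1, 3.0, maf)
        ds = sample_case_control(pool, (0,), table, 4000, 100, rng)
        f = hwe_genotype_frequencies(maf)
        post = f * table.penetrances
        post /= post.sum()
        col = ds.genotypes[ds.status == 1, 0]
        observed = np.bincount(col, minlength=3) / len(col)
        np.testing.assert_allclose(observed, post, atol=0.03)

    def test_flat_table_gives_indistinguishable_groups(self, rng):
        from scipy.stats import chi2_contingency
        pool = self.make_pool(rng, n=5000)
        flat = PenetranceTable(np.full(3, 0.2), (0.3,))
        rejections = 0
        for k in range(20):
            ds = sample_case_control(pool, (0,), flat, 300, 300,
                                     np.random.default_rng(k))
            obs = np.array([np.bincount(ds.genotypes[ds.status == s, 1],
                                        minlength=3) for s in (0, 1)])
            obs = obs[:, obs.sum(axis=0) > 0]
            if chi2_contingency(obs).pvalue < 0.01:
                rejections += 1
        assert rejections <= 3  # calibrated type-I rate at alpha = 0.01


class TestDropLoci:
    def make_dataset(self):
        g = np.array([[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 0, 0]],
                     dtype=np.int8)
        return CaseControlDataset(g, np.array([1, 1, 0, 0], dtype=np.int8),
                                  ["a", "b", "c"], functional_loci=["b"])

    def test_drop_empty_set_is_identity(self):
        ds = self.make_dataset()
        out = drop_loci(ds, [])
        assert out.locus_ids == ds.locus_ids
        assert (out.genotypes == ds.genotypes).all()

    def test_drop_preserves_rows_and_statuses(self):
        ds = self.make_dataset()
        out = drop_loci(ds, ["b"])
        assert out.locus_ids == ["a", "c"]
        assert out.n_cases == 2 and out.n_controls == 2
        assert out.functional_loci == []
        assert out.embedded_functional_loci == ["b"]
        assert (out.genotypes == ds.genotypes[:, [0, 2]]).all()

    def test_unknown_locus_rejected(self):
        with pytest.raises(KeyError):
            drop_loci(self.make_dataset(), ["zz"])
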