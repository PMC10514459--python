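"""Load counting, deleterious:synonymous ratios, R_xy and hard filters."""

import numpy as np
import pandas as pd
import pytest

from erosim.loadstats import (
    VariantTable,
    count_load,
    filter_variants,
    load_ratio,
    rxy,
)
from erosim.synth import SynthSpec, generate_table


class TestCountLoad:
    def test_counting_rule_single_individual(self):
        table = VariantTable(
            chrom=np.array(["1"] * 4, dtype=object),
            pos=np.array([10, 20, 30, 40], dtype=np.int64),
            category=np.array(["HIGH"] * 4, dtype=object),
            genotypes=np.array([[2], [1], [0], [-1]], dtype=np.int8),
            samples=["s0"],
            populations=np.array(["A"], dtype=object),
        )
        df = count_load(table, "A", "HIGH")
        row = df.loc["s0"]
        assert (row.n_hom, row.n_het, row.n_total_variants, row.n_alleles) == (1, 1, 2, 3)

    def test_matches_brute_force_tally(self, toy_table):
        for pop in ("A", "B"):
            idx = toy_table.sample_indices(pop)
            for cat in ("HIGH", "MODERATE", "SYNONYMOUS"):
                df = count_load(toy_table, pop, cat)
                mask = toy_table.category == cat
                g = toy_table.genotypes[mask][:, idx]
                np.testing.assert_array_equal(df.n_hom.to_numpy(), (g == 2).sum(axis=0))
                np.testing.assert_array_equal(df.n_het.to_numpy(), (g == 1).sum(axis=0))

    def test_drop_fixed_excludes_globally_fixed_site(self, toy_table):
        with_fixed = count_load(toy_table, "A", "SYNONYMOUS")
        without = count_load(toy_table, "A", "SYNONYMOUS", drop_fixed=True)
        # site 5 (pos 5000) is 2 in every sample
        assert (with_fixed.n_hom - without.n_hom == 1).all()

    def test_additive_over_disjoint_subsets(self, toy_table):
        full = count_load(toy_table, "B", "MODERATE")
        first = toy_table.subset_sites(toy_table.pos <= 5000)
        second = toy_table.subset_sites(toy_table.pos > 5000)
        sub = count_load(first, "B", "MODERATE") + count_load(second, "B", "MODERATE")
        pd.testing.assert_frame_equal(full, sub)

    def test_unknown_population_raises(self, toy_table):
        with pytest.raises(ValueError):
            count_load(toy_table, "C", "HIGH")


class TestLoadRatio:
    def test_simple_ratios(self, toy_table):
        ratio = load_ratio(toy_table, "A", "HIGH")
        counts_h = count_load(toy_table, "A", "HIGH").n_total_variants
        counts_s = count_load(toy_table, "A", "SYNONYMOUS").n_total_variants
        np.testing.assert_allclose(ratio.to_numpy(), (counts_h / counts_s).to_numpy())

    def test_zero_synonymous_reported_missing_with_warning(self):
        table = VariantTable(
            chrom=np.array(["1", "1"], dtype=object),
            pos=np.array([10, 20], dtype=np.int64),
            category=np.array(["HIGH", "SYNONYMOUS"], dtype=object),
            genotypes=np.array([[1], [0]], dtype=np.int8),
            samples=["s0"],
            populations=np.array(["A"], dtype=object),
        )
        with pytest.warns(UserWarning, match="zero synonymous"):
            ratio = load_ratio(table, "A", "HIGH")
        assert np.isnan(ratio.iloc[0])

    def test_rejects_synonymous_as_numerator(self, toy_table):
        with pytest.raises(ValueError):
            load_ratio(toy_table, "A", "SYNONYMOUS")


def _freq_table(fx, fy, cats, n=200, seed=0):
    """Deterministic table whose population frequencies are as given,
    using 2n haploid draws per site rounded to exact dosage totals."""
    rng = np.random.default_rng(seed)
    n_sites = len(cats)
    gt = np.zeros((n_sites, 2 * n), dtype=np.int8)
    for i, (a, b) in enumerate(zip(fx, fy)):
        for off, f in ((0, a), (n, b)):
            alleles = int(round(f * 2 * n))
            dosages = np.zeros(n, dtype=np.int8)
            full, rem = divmod(alleles, 2)
            dosages[:full] = 2
            if rem:
                dosages[full] = 1
            gt[i, off : off + n] = dosages
    return VariantTable(
        chrom=np.array(["1"] * n_sites, dtype=object),
        pos=np.arange(1, n_sites + 1, dtype=np.int64) * 100,
        category=np.asarray(cats, dtype=object),
        genotypes=gt,
        samples=[f"s{i}" for i in range(2 * n)],
        populations=np.array(["X"] * n + ["Y"] * n, dtype=object),
    )


class TestRxy:
    def test_identical_populations_give_exactly_one(self, toy_table):
        # duplicate population A as both x and y via a self comparison
        t = toy_table
        res = rxy(t, "A", "A", "HIGH", n_blocks=3, seed=0)
        assert res.point_estimate == pytest.approx(1.0, abs=1e-12)

    def test_reciprocal_inversion(self):
        rng = np.random.default_rng(3)
        cats = ["HIGH"] * 40 + ["INTERGENIC"] * 120
        fx = rng.uniform(0.05, 0.95, len(cats))
        fy = rng.uniform(0.05, 0.95, len(cats))
        t = _freq_table(fx, fy, cats, n=50)
        a = rxy(t, "X", "Y", "HIGH", n_blocks=5, seed=7)
        b = rxy(t, "Y", "X", "HIGH", n_blocks=5, seed=7)
        assert a.point_estimate == pytest.approx(1.0 / b.point_estimate, rel=1e-9)

    def test_hand_computed_example(self):
        # category frequencies fx=(0.8, 0.2), fy=(0.2, 0.8); intergenic equal
        cats = ["HIGH", "HIGH", "INTERGENIC", "INTERGENIC"]
        fx = [0.8, 0.2, 0.5, 0.4]
        fy = [0.2, 0.8, 0.5, 0.4]
        t = _freq_table(fx, fy, cats, n=100)
        res = rxy(t, "X", "Y", "HIGH", n_blocks=2, seed=1)
        # L_xy(C) = .8*.8 + .2*.2 = .68 = L_yx(C); L_xy(N) = L_yx(N) by symmetry
        assert res.point_estimate == pytest.approx(1.0, abs=1e-9)
        fx2 = [0.8, 0.6, 0.5, 0.4]
        fy2 = [0.2, 0.1, 0.5, 0.4]
        t2 = _freq_table(fx2, fy2, cats, n=100)
        lxy = 0.8 * 0.8 + 0.6 * 0.9
        lyx = 0.2 * 0.2 + 0.1 * 0.4
        lN = 0.5 * 0.5 + 0.4 * 0.6
        expected = (lxy / lN) / (lyx / lN)
        res2 = rxy(t2, "X", "Y", "HIGH", n_blocks=2, seed=1)
        assert res2.point_estimate == pytest.approx(expected, rel=1e-9)

    def test_refuses_insufficient_intergenic(self):
        cats = ["HIGH"] * 5 + ["INTERGENIC"] * 3
        t = _freq_table([0.5] * 8, [0.5] * 8, cats, n=10)
        with pytest.raises(ValueError, match="intergenic"):
            rxy(t, "X", "Y", "HIGH")

    def test_site_order_invariance(self):
        rng = np.random.default_rng(5)
        cats = ["MODERATE"] * 30 + ["INTERGENIC"] * 90
        fx = rng.uniform(0.1, 0.9, len(cats))
        fy = rng.uniform(0.1, 0.9, len(cats))
        t = _freq_table(fx, fy, cats, n=40)
        shuffled = t.subset_sites(rng.permutation(t.n_sites))
        a = rxy(t, "X", "Y", "MODERATE", n_blocks=4, seed=2)
        b = rxy(shuffled, "X", "Y", "MODERATE", n_blocks=4, seed=2)
        assert a.point_estimate == pytest.approx(b.point_estimate, rel=1e-12)

    def test_jackknife_se_positive_when_blocks_differ(self):
        rng = np.random.default_rng(6)
        cats = ["HIGH"] * 50 + ["INTERGENIC"] * 200
        fx = rng.uniform(0.1, 0.9, len(cats))
        fy = rng.uniform(0.1, 0.9, len(cats))
        t = _freq_table(fx, fy, cats, n=40)
        res = rxy(t, "X", "Y", "HIGH", n_blocks=10, seed=3)
        assert res.jackknife_se > 0

    def test_deficit_population_pushes_rxy_below_one(self):
        spec = SynthSpec(
            samples_per_pop=20,
            site_counts={"HIGH": 300, "MODERATE": 300, "SYNONYMOUS": 300, "INTERGENIC": 3000},
            rxy_deficit={"HIGH": 0.5},
            seed=11,
        )
        table, _ = generate_table(spec)
        below = 0
        for seed in range(5):
            res = rxy(table, "pop0", "pop1", "HIGH", seed=seed)
            below += res.point_estimate < 1
        assert below == 5

    def test_standardization_seed_stability(self):
        spec = SynthSpec(
            samples_per_pop=20,
            site_counts={"HIGH": 400, "MODERATE": 0, "SYNONYMOUS": 0, "INTERGENIC": 4000},
            seed=12,
        )
        table, _ = generate_table(spec)
        base = rxy(table, "pop0", "pop1", "HIGH", seed=0)
        for seed in (1, 2, 3):
            alt = rxy(table, "pop0", "pop1", "HIGH", seed=seed)
            assert abs(alt.point_estimate - base.point_estimate) < 3 * base.jackknife_se


class TestFilterVariants:
    def _aux_table(self):
        # 12-record fixture exercising every rule; expected survivors audited
        # by hand in test_rule_by_rule_audit.
        chrom = np.array(["1"] * 12, dtype=object)
        pos = np.array([100, 200, 300, 400, 500, 600, 700, 703, 800, 900, 1000, 1100], dtype=np.int64)
        category = np.array(["SYNONYMOUS"] * 12, dtype=object)
        gt = np.ones((12, 2), dtype=np.int8)  # all het
        gt[4] = [0, 2]
        qual = np.full(12, 60.0)
        qual[1] = 20.0  # fails QV >= 30
        depth = np.full((12, 2), 20, dtype=np.int32)
        depth[2, 0] = 4    # below 1/3 of mean -> genotype missing
        depth[3, 1] = 50   # above 2x mean -> genotype missing
        ad_ref = np.full((12, 2), 10, dtype=np.int32)
        ad_ref[5, 0] = 1   # balance 0.05 -> het dropped
        ad_ref[4, 0] = 20  # hom-ref; balance rule must not apply
        is_indel = np.zeros(12, dtype=bool)
        is_indel[6] = True  # indel dropped; site 7 is 3 bp away -> dropped
        return VariantTable(
            chrom=chrom, pos=pos, category=category, genotypes=gt,
            samples=["s0", "s1"], populations=np.array(["A", "A"], dtype=object),
            qual=qual, depth=depth, ad_ref=ad_ref, is_indel=is_indel,
        )

    def test_rule_by_rule_audit(self):
        table = self._aux_table()
        out = filter_variants(table, mean_depth=[20.0, 20.0])
        kept = set(out.pos.tolist())
        assert 200 not in kept        # low QV
        assert 700 not in kept        # indel
        assert 703 not in kept        # SNP within 5 bp of indel
        assert kept == {100, 300, 400, 500, 600, 800, 900, 1000, 1100}
        # depth failures became missing, not dropped
        assert out.genotypes[out.pos == 300, 0] == -1
        assert out.genotypes[out.pos == 400, 1] == -1
        # balance failure became missing; hom-ref untouched
        assert out.genotypes[out.pos == 600, 0] == -1
        assert out.genotypes[out.pos == 500, 0] == 0

    def test_complete_cases_drops_sites_with_missing(self):
        table = self._aux_table()
        out = filter_variants(table, mean_depth=[20.0, 20.0], complete_cases=True)
        assert set(out.pos.tolist()) == {100, 500, 800, 900, 1000, 1100}

    def test_missing_aux_field_is_named(self, toy_table):
        with pytest.raises(ValueError, match="qual"):
            filter_variants(toy_table)

    def test_clean_data_untouched(self):
        spec = SynthSpec(samples_per_pop=5, missingness=0.0, depth_mean=2000.0,
                         depth_overdispersion=1e6, seed=4)
        table, _ = generate_table(spec)
        out = filter_variants(table)
        assert out.n_sites == table.n_sites
        np.testing.assert_array_equal(out.genotypes, table.genotypes)
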