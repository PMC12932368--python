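"""Breeding operations: crossing plans, meiosis, DH lines, pools, phenotypes."""

import numpy as np
import pytest

from conftest import toy_map, toy_trait
from sparsetc.breeding import (
    calibrate_error_variance,
    derive_dh_lines,
    form_initial_pools,
    make_testcross,
    meiose,
    recombine,
    sample_half_diallel,
    simulate_phenotypes,
    LinePopulation,
)
from sparsetc.breeding import TestcrossSet as _TestcrossSet
from sparsetc.metrics import hybrid_value_matrix
from sparsetc.rng import child_rng


class TestHalfDiallel:
    def test_covers_all_parents_no_selfs_no_duplicates(self):
        plan = sample_half_diallel(40, 60, seed=1)
        assert plan.n_crosses == 60
        assert np.all(plan.pairs[:, 0] < plan.pairs[:, 1])
        assert len(np.unique(plan.pairs, axis=0)) == 60
        assert len(np.unique(plan.pairs)) == 40

    def test_two_parents_single_cross(self):
        plan = sample_half_diallel(2, 1, seed=2)
        assert np.array_equal(plan.pairs, [[0, 1]])

    def test_full_diallel_is_only_feasible_plan(self):
        plan = sample_half_diallel(4, 6, seed=3)
        expected = {(i, j) for i in range(4) for j in range(i + 1, 4)}
        assert {tuple(p) for p in plan.pairs} == expected

    def test_coverage_holds_over_many_seeds(self):
        for seed in range(1000):
            plan = sample_half_diallel(10, 6, seed=seed)
            assert len(np.unique(plan.pairs)) == 10

    def test_infeasible_requests_raise(self):
        with pytest.raises(ValueError):
            sample_half_diallel(4, 7, seed=1)  # exceeds C(4,2)
        with pytest.raises(ValueError):
            sample_half_diallel(10, 4, seed=1)  # cannot cover 10 parents


class TestMeiosis:
    def test_homozygous_parent_returns_either_haplotype(self):
        loci = toy_map(30)
        hap = np.tile(np.array([0, 1], dtype=np.uint8), 15)
        gamete = meiose(np.stack([hap, hap]), loci, seed=4)
        assert np.array_equal(gamete, hap)

    def test_crossover_count_mean_matches_map_length(self):
        """200 cM chromosome: mean crossovers per meiosis ~ Poisson(2)."""
        loci = toy_map(2, chr_length_cM=200.0)
        # count recombination events between complementary haplotypes at the
        # two terminal loci via the recombinant fraction instead; use many
        # loci for a direct crossover count
        loci = toy_map(201, chr_length_cM=200.0)
        hapA = np.zeros(201, dtype=np.uint8)
        hapB = np.ones(201, dtype=np.uint8)
        rng = child_rng(99, "x")
        n = 4000
        gam = recombine(
            np.repeat(hapA[None], n, axis=0), np.repeat(hapB[None], n, axis=0),
            loci, rng,
        )
        switches = np.abs(np.diff(gam.astype(int), axis=1)).sum(axis=1)
        # observed switches undercount crossovers that fall between the same
        # adjacent loci an even number of times; with 1 cM spacing the bias
        # is ~1%, well within the tolerance
        assert switches.mean() == pytest.approx(2.0, abs=0.1)

    def test_recombinant_fraction_follows_haldane(self):
        """Two loci 50 cM apart: recombinant fraction (1 - e^-1)/2 ~ 0.316."""
        n_loci = 2
        pos = np.array([25e6, 75e6], dtype=np.int64)
        from sparsetc.genome import LocusMap

        loci = LocusMap(
            chrom=np.zeros(n_loci, dtype=np.int16), pos_bp=pos, pos_cM=pos / 1e6,
            role=np.zeros(n_loci, dtype=np.uint8), chr_length_cM=100.0,
        )
        hapA = np.array([0, 0], dtype=np.uint8)
        hapB = np.array([1, 1], dtype=np.uint8)
        rng = child_rng(17, "haldane")
        n = 10_000
        gam = recombine(
            np.repeat(hapA[None], n, axis=0), np.repeat(hapB[None], n, axis=0),
            loci, rng,
        )
        rec_frac = np.mean(gam[:, 0] != gam[:, 1])
        expected = (1 - np.exp(-1.0)) / 2
        assert rec_frac == pytest.approx(expected, abs=3 * np.sqrt(0.25 / n) + 0.003)


class TestDoubledHaploids:
    def test_dh_lines_fully_homozygous_by_construction(self):
        loci = toy_map(50)
        rng = np.random.default_rng(3)
        f1 = rng.integers(0, 2, size=(2, 50)).astype(np.uint8)
        lines = derive_dh_lines(f1, loci, n=20, seed=5)
        assert lines.shape == (20, 50)
        # one haplotype per line IS the doubled genotype: heterozygosity 0
        assert set(np.unique(lines)) <= {0, 1}

    def test_homozygous_f1_gives_identical_dh(self):
        loci = toy_map(50)
        hap = np.random.default_rng(4).integers(0, 2, 50).astype(np.uint8)
        lines = derive_dh_lines(np.stack([hap, hap]), loci, n=5, seed=6)
        assert np.all(lines == hap)

    def test_mendelian_segregation_at_heterozygous_locus(self):
        loci = toy_map(1)
        f1 = np.array([[0], [1]], dtype=np.uint8)
        lines = derive_dh_lines(f1, loci, n=10_000, seed=7)
        assert lines.mean() == pytest.approx(0.5, abs=0.02)


class TestPoolFormation:
    def test_default_structure(self, small_founders):
        pools = form_initial_pools(
            small_founders, generations=3, seed=8,
            n_parents=10, n_crosses=12, dh_per_cross=5,
        )
        for pool in (pools.pool_f, pools.pool_m):
            assert pool.n_lines == 60
            assert len(np.unique(pool.family)) == 12
            assert np.bincount(pool.family).tolist() == [5] * 12
        assert pools.pool_f.pool == "female"
        assert len(pools.parents_f) == 10

    def test_zero_generations_returns_inbred_founders(self, small_founders):
        pools = form_initial_pools(small_founders, generations=0, seed=9)
        assert pools.pool_f.n_lines == 10
        assert pools.pool_m.n_lines == 10
        # every line's haplotype appears among the founder's two haplotypes
        # chromosome-wise (inbreeding doubles one of them)
        total = np.concatenate([pools.pool_f.geno, pools.pool_m.geno])
        founders = small_founders.haplotypes
        for c in small_founders.loci.chromosomes:
            sl = small_founders.loci.chrom_slice(int(c))
            pool_block = {bytes(row[sl]) for row in total}
            founder_block = {
                bytes(founders[i, h, sl]) for i in range(20) for h in range(2)
            }
            assert pool_block <= founder_block

    def test_deterministic_given_seed(self, small_founders):
        a = form_initial_pools(small_founders, generations=2, seed=10,
                               n_parents=6, n_crosses=6, dh_per_cross=3)
        b = form_initial_pools(small_founders, generations=2, seed=10,
                               n_parents=6, n_crosses=6, dh_per_cross=3)
        assert np.array_equal(a.pool_f.geno, b.pool_f.geno)
        assert np.array_equal(a.parents_m, b.parents_m)

    def test_drift_conserves_expected_allele_frequency(self, small_founders):
        """Without selection, the mean pool frequency over replicates stays
        near the starting frequency (drift is unbiased)."""
        start, end = [], []
        for seed in range(30):
            pools = form_initial_pools(
                small_founders, generations=1, seed=seed,
                n_parents=10, n_crosses=12, dh_per_cross=5,
            )
            # compare against the founder inbreds that seeded this pool split
            end.append(pools.pool_f.allele_frequencies()[:5])
        end = np.array(end)
        founder_freq = small_founders.allele_frequencies()[:5]
        assert np.all(np.abs(end.mean(axis=0) - founder_freq) < 0.15)


class TestTestcross:
    def test_dosage_table(self):
        line = np.array([2, 0, 2, 0])
        tester = np.array([0, 0, 2, 2])
        hybrid = make_testcross(line, tester)
        assert hybrid.tolist() == [1, 0, 2, 1]

    def test_identical_parents_reproduce_genotype(self):
        g = np.array([0, 2, 2, 0])
        assert np.array_equal(make_testcross(g, g), g)

    def test_heterozygous_input_rejected(self):
        with pytest.raises(ValueError, match="homozygous"):
            make_testcross(np.array([1, 0]), np.array([0, 2]))

    def test_hybrid_value_matches_per_locus_enumeration(self):
        rng = np.random.default_rng(11)
        trait = toy_trait(rng.normal(size=100), rng.normal(0.5, 0.4, size=100))
        bl = rng.integers(0, 2, 100)
        bt = rng.integers(0, 2, 100)
        hybrid = make_testcross(2 * bl, 2 * bt)
        from sparsetc.trait import genetic_value

        # enumerate the 4 allele combinations per locus
        expected = 0.0
        for i in range(100):
            if bl[i] and bt[i]:
                expected += trait.a[i]
            elif not bl[i] and not bt[i]:
                expected -= trait.a[i]
            else:
                expected += trait.d[i]
        assert genetic_value(hybrid, trait) == pytest.approx(expected)


class TestErrorCalibration:
    def _toy_pools(self):
        rng = np.random.default_rng(12)
        trait = toy_trait(rng.normal(size=30), rng.normal(0.5, 0.4, 30))
        Bf = rng.integers(0, 2, size=(3, 30)).astype(np.uint8)
        Bm = rng.integers(0, 2, size=(3, 30)).astype(np.uint8)
        return Bf, Bm, trait

    def test_h2_half_means_sigma_e_equals_sigma_g(self):
        Bf, Bm, trait = self._toy_pools()
        s2g = np.var(hybrid_value_matrix(Bf, Bm, trait))
        assert calibrate_error_variance(Bf, Bm, trait, H2=0.5) == pytest.approx(s2g)

    def test_h2_03_uses_seven_thirds(self):
        Bf, Bm, trait = self._toy_pools()
        s2g = np.var(hybrid_value_matrix(Bf, Bm, trait))
        assert calibrate_error_variance(Bf, Bm, trait, H2=0.3) == pytest.approx(
            s2g * 7 / 3
        )

    def test_sigma_g_is_variance_of_enumerated_hybrids(self):
        Bf, Bm, trait = self._toy_pools()
        values = [
            sum(
                trait.a[l] if Bf[i, l] and Bm[j, l]
                else -trait.a[l] if not Bf[i, l] and not Bm[j, l]
                else trait.d[l]
                for l in range(30)
            )
            for i in range(3)
            for j in range(3)
        ]
        s2g = np.var(values)
        assert calibrate_error_variance(Bf, Bm, trait, H2=0.5) == pytest.approx(s2g)

    def test_invalid_h2_rejected(self):
        Bf, Bm, trait = self._toy_pools()
        for h2 in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                calibrate_error_variance(Bf, Bm, trait, H2=h2)


class TestPhenotypes:
    def _ts(self, n, gv=None):
        return _TestcrossSet(
            line_idx=np.arange(n),
            tester_idx=np.zeros(n, dtype=int),
            genetic_values=np.zeros(n) if gv is None else gv,
        )

    def test_zero_error_returns_genetic_values(self):
        gv = np.random.default_rng(1).normal(size=50)
        out = simulate_phenotypes(self._ts(50, gv), 0.0, seed=13)
        assert np.array_equal(out.phenotypes, gv)

    def test_empirical_error_variance(self):
        out = simulate_phenotypes(self._ts(10_000), 21.0, seed=14)
        assert np.var(out.phenotypes) == pytest.approx(21.0, rel=0.06)

    def test_deterministic_given_seed(self):
        a = simulate_phenotypes(self._ts(100), 5.0, seed=15)
        b = simulate_phenotypes(self._ts(100), 5.0, seed=15)
        assert np.array_equal(a.phenotypes, b.phenotypes)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            simulate_phenotypes(self._ts(5), -1.0, seed=16)
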