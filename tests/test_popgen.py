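import math

import numpy as np
import pytest

from minecoast.io import GenotypeMatrix, PopulationMap
from minecoast.popgen import (
    InsufficientDataError,
    cross_population_mean_d,
    genotype_r2,
    haversine_km,
    ld_prune,
    nucleotide_diversity,
    paired_t,
    tajimas_d,
    wc_fst,
    wc_fst_components,
    welch_t,
)


def _gm_from(dosages, positions=None, scaffold="sc1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    n, s = dosages.shape
    pos = np.arange(1, s + 1) * 10 if positions is None else np.asarray(positions)
    return GenotypeMatrix(dosages, np.array([scaffold] * s, dtype=object),
                          pos, [f"i{k}" for k in range(n)]).validate()


def _pm_two(n_a, n_b):
    ind = {f"i{k}": ("A" if k < n_a else "B") for k in range(n_a + n_b)}
    return PopulationMap(ind, {"A": "coast", "B": "mine"}, {"A": "r", "B": "r"},
                         {"A": (50.0, -4.0), "B": (50.2, -4.0)})


def _wc_anova_oracle(dos_a, dos_b):
    """Independent ANOVA mean-squares route to the W&C components."""
    a_l, b_l, c_l = [], [], []
    for j in range(dos_a.shape[1]):
        groups = [dos_a[:, j], dos_b[:, j]]
        n = [len(g) for g in groups]
        p = [g.sum() / (2 * len(g)) for g in groups]
        ntot = sum(n)
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / ntot
        nc = ntot - sum(ni * ni for ni in n) / ntot
        ssg = sum((g == 1).sum() for g in groups) / 2.0
        ssi = sum(2 * ((g / 2.0 - pi) ** 2).sum() for g, pi in zip(groups, p))
        ssp = sum(2 * ni * (pi - pbar) ** 2 for ni, pi in zip(n, p))
        msg = ssg / ntot
        msi = ssi / (ntot - 2)
        msp = ssp / 1.0
        a_l.append((msp - msi) / (2 * nc))
        b_l.append((msi - msg) / 2.0)
        c_l.append(msg)
    return np.array(a_l), np.array(b_l), np.array(c_l)


class TestWcFst:
    def test_fixed_difference_gives_one(self):
        gm = _gm_from(np.vstack([np.zeros((20, 1)), np.full((20, 1), 2)]))
        res = wc_fst(gm, _pm_two(20, 20), "A", "B")
        assert res.multilocus_fst == pytest.approx(1.0)

    def test_identical_populations_give_nonpositive_fst(self):
        block = np.array([[0, 1], [1, 2], [2, 0], [1, 1]], dtype=np.int8)
        gm = _gm_from(np.vstack([block, block]))
        res = wc_fst(gm, _pm_two(4, 4), "A", "B")
        assert np.all(res.a[res.defined] <= 1e-12)
        assert res.multilocus_fst <= 0.0

    def test_worked_table_matches_hand_evaluation(self):
        # frozen from an independent ANOVA mean-squares evaluation
        dos_a = np.array([[0, 2], [1, 1], [0, 2], [1, 2]], dtype=np.int8)
        dos_b = np.array([[2, 0], [2, 1], [1, 0], [2, 0]], dtype=np.int8)
        gm = _gm_from(np.vstack([dos_a, dos_b]))
        res = wc_fst(gm, _pm_two(4, 4), "A", "B")
        assert res.a == pytest.approx([0.17708333, 0.265625])
        assert res.b == pytest.approx([-0.02083333, 0.0])
        assert res.c == pytest.approx([0.1875, 0.125])
        assert res.multilocus_fst == pytest.approx(0.6028368794326242)
        assert res.per_site_fst == pytest.approx([0.51515152, 0.68])

    def test_components_match_anova_route_on_random_data(self):
        rng = np.random.default_rng(42)
        dos_a = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        dos_b = rng.integers(0, 3, size=(9, 40)).astype(np.int8)
        from minecoast.popgen import site_allele_stats

        n1, p1, h1 = site_allele_stats(dos_a)
        n2, p2, h2 = site_allele_stats(dos_b)
        a, b, c, defined = wc_fst_components(n1, p1, h1, n2, p2, h2)
        ao, bo, co = _wc_anova_oracle(dos_a, dos_b)
        assert a[defined] == pytest.approx(ao[defined])
        assert b[defined] == pytest.approx(bo[defined])
        assert c[defined] == pytest.approx(co[defined])

    def test_symmetric_in_population_order(self, small_dataset):
        _, gm, pm, _ = small_dataset
        r1 = wc_fst(gm, pm, "WWA-M", "IRE-C")
        r2 = wc_fst(gm, pm, "IRE-C", "WWA-M")
        assert r1.multilocus_fst == pytest.approx(r2.multilocus_fst)

    def test_monomorphic_pair_rejected(self):
        gm = _gm_from(np.zeros((8, 3)))
        with pytest.raises(InsufficientDataError):
            wc_fst(gm, _pm_two(4, 4), "A", "B")

    def test_unknown_population_rejected(self, tiny_gm, tiny_pm):
        with pytest.raises(KeyError):
            wc_fst(tiny_gm, tiny_pm, "A", "Z")

    def test_random_label_permutation_centers_fst_at_zero(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 60)
        dos = rng.binomial(2, p, size=(30, 60)).astype(np.int8)
        vals = []
        for _ in range(200):
            rows = rng.permutation(30)
            gm = _gm_from(dos[rows])
            vals.append(wc_fst(gm, _pm_two(15, 15), "A", "B").multilocus_fst)
        vals = np.array(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 1e-4


class TestDiversity:
    def test_closed_form_single_site(self):
        # p = 0.5 with n = 10 alleles -> (10/9) * 0.5 = 0.5556
        gm = _gm_from(np.array([[0], [0], [1], [2], [2]]))
        pm = PopulationMap({f"i{k}": "A" for k in range(5)}, {"A": "coast"}, {}, {})
        res = nucleotide_diversity(gm, pm, "A")
        assert res.pi_per_variant_site == pytest.approx((10 / 9) * 0.5)

    def test_monomorphic_only_input_rejected(self):
        gm = _gm_from(np.full((4, 3), 2))
        pm = PopulationMap({f"i{k}": "A" for k in range(4)}, {"A": "coast"}, {}, {})
        with pytest.raises(InsufficientDataError):
            nucleotide_diversity(gm, pm, "A")

    def test_order_invariance(self, small_dataset):
        _, gm, pm, _ = small_dataset
        base = nucleotide_diversity(gm, pm, "ENG-M").pi_per_variant_site
        rng = np.random.default_rng(0)
        rows = rng.permutation(gm.n_individuals)
        gm2 = GenotypeMatrix(gm.dosages[rows], gm.site_scaffold, gm.site_pos,
                             [gm.sample_ids[i] for i in rows])
        assert nucleotide_diversity(gm2, pm, "ENG-M").pi_per_variant_site == pytest.approx(base)

    def test_balding_nichols_mean_matches_analytic_expectation(self):
        from minecoast.popgen import site_allele_stats
        from minecoast.synth import GeneratorConfig, gen_frequencies, gen_genotypes

        cfg = GeneratorConfig(n_per_pop=30, n_snps=4000, n_scaffolds=200, seed=91)
        freqs, scaf, pos, truth = gen_frequencies(cfg)
        gm = gen_genotypes(freqs, cfg, scaf, pos)
        rows = slice(0, 30)  # first population block (WWA-M)
        n, p, _ = site_allele_stats(gm.dosages[rows])
        alleles = 2.0 * n
        pi = alleles / (alleles - 1.0) * 2.0 * p * (1.0 - p)
        se = pi.std(ddof=1) / math.sqrt(len(pi))
        assert abs(pi.mean() - truth.expected_pi["WWA-M"]) < 2 * se


class TestTajimasD:
    def test_worked_example_matches_hand_computation(self):
        # 4 haplotypes over 3 segregating sites with alt counts 1, 2, 3:
        # pi = 5/3, thetaW = 3/a1, D = 0.16766 via the e1/e2 constants
        gm = _gm_from(np.array([[0, 0, 1], [1, 2, 2]]), positions=[5, 15, 25])
        pm = PopulationMap({"i0": "A", "i1": "A"}, {"A": "coast"}, {}, {})
        res = tajimas_d(gm, pm, "A", window_bp=100)
        (scaf, start, d, s) = res.tajima_d_windows[0]
        assert (scaf, start, s) == ("sc1", 1, 3)
        assert d == pytest.approx(0.1676557950339481)

    def test_singleton_excess_gives_negative_d(self):
        # n = 10 alleles, 5 segregating sites, every variant a singleton
        dos = np.zeros((5, 5), dtype=np.int8)
        for j in range(5):
            dos[j, j] = 1
        gm = _gm_from(dos)
        pm = PopulationMap({f"i{k}": "A" for k in range(5)}, {"A": "coast"}, {}, {})
        res = tajimas_d(gm, pm, "A")
        assert res.tajima_d_windows[0][2] < 0

    def test_no_segregating_sites_is_undefined(self):
        gm = _gm_from(np.zeros((4, 2)))
        pm = PopulationMap({f"i{k}": "A" for k in range(4)}, {"A": "coast"}, {}, {})
        res = tajimas_d(gm, pm, "A")
        assert all(math.isnan(w[2]) for w in res.tajima_d_windows)
        assert res.mean_d is None

    def test_fewer_than_four_alleles_is_flag_not_error(self):
        gm = _gm_from(np.array([[0, 1, 2]]))
        pm = PopulationMap({"i0": "A"}, {"A": "coast"}, {}, {})
        res = tajimas_d(gm, pm, "A")
        assert all(math.isnan(w[2]) for w in res.tajima_d_windows)

    def test_cross_population_mean_uses_common_windows(self, small_dataset):
        _, gm, pm, _ = small_dataset
        pops = ["WWA-C", "IRE-C"]
        results = [tajimas_d(gm, pm, p, window_bp=2000) for p in pops]
        means = cross_population_mean_d(results)
        assert set(means) == set(pops)
        common = set((s, w) for (s, w, d, _n) in results[0].tajima_d_windows
                     if not math.isnan(d))
        common &= set((s, w) for (s, w, d, _n) in results[1].tajima_d_windows
                      if not math.isnan(d))
        expect = np.mean([d for (s, w, d, _n) in results[0].tajima_d_windows
                          if (s, w) in common])
        assert means["WWA-C"] == pytest.approx(expect)


class TestLdPrune:
    def test_duplicate_column_pruned(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=20).astype(np.int8)
        gm = _gm_from(np.column_stack([col, col]))
        out = ld_prune(gm, r2_threshold=0.1, maf_threshold=0.0)
        assert out.n_sites == 1
        assert out.site_pos[0] == 10  # the earlier site survives

    def test_independent_columns_survive(self):
        rng = np.random.default_rng(3)
        dos = rng.binomial(2, 0.5, size=(200, 10)).astype(np.int8)
        gm = _gm_from(dos)
        out = ld_prune(gm, r2_threshold=0.5, maf_threshold=0.05)
        assert out.n_sites == 10

    def test_maf_filter_applied_first(self):
        dos = np.zeros((20, 2), dtype=np.int8)
        dos[0, 0] = 1  # MAF 1/40 = 0.025 < 0.05
        dos[:10, 1] = 2  # MAF 0.5
        gm = _gm_from(dos)
        out = ld_prune(gm)
        assert out.n_sites == 1 and out.site_pos[0] == 20

    def test_greedy_scan_matches_bruteforce_on_known_pattern(self):
        rng = np.random.default_rng(8)
        base = rng.binomial(2, 0.5, size=(100,)).astype(np.int8)
        other = rng.binomial(2, 0.5, size=(100, 3)).astype(np.int8)
        # sites: [base, noisy copy of base, independent, copy of independent, independent]
        noisy = base.copy()
        noisy[:5] = rng.integers(0, 3, 5)
        dos = np.column_stack([base, noisy, other[:, 0], other[:, 0], other[:, 1]])
        gm = _gm_from(dos)
        out = ld_prune(gm, r2_threshold=0.1, maf_threshold=0.0)
        # brute force: greedy over all pairs in order
        kept = []
        for j in range(5):
            if all(genotype_r2(dos[:, i], dos[:, j]) <= 0.1 for i in kept):
                kept.append(j)
        assert out.site_pos.tolist() == [(k + 1) * 10 for k in kept]


class TestHaversine:
    def test_identical_points(self):
        assert haversine_km((51.0, -4.0), (51.0, -4.0)) == 0.0

    def test_antipodal_points(self):
        assert haversine_km((0.0, 0.0), (0.0, 180.0)) == pytest.approx(20015.1144, abs=0.01)

    def test_matches_spherical_law_of_cosines(self):
        # London -> Paris, frozen from an independent law-of-cosines evaluation
        assert haversine_km((51.5, -0.12), (48.85, 2.35)) == pytest.approx(
            343.1283517719401, abs=0.5
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            haversine_km((95.0, 0.0), (0.0, 0.0))


class TestTTests:
    def test_welch_matches_hand_computation(self):
        res = welch_t([4.1, 5.0, 6.2, 5.5, 4.8], [3.1, 3.9, 4.4, 4.0, 3.6])
        assert res.t == pytest.approx(3.197710448535961)
        assert res.df == pytest.approx(6.660983588505989)
        assert res.p == pytest.approx(0.016164262633324517)

    def test_paired_identical_samples(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_paired_constant_difference_degenerate(self):
        res = paired_t([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.p == 0.0 and math.isinf(res.t) and res.degenerate

    def test_welch_zero_variance_equal_means(self):
        res = welch_t([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0 and res.degenerate

    def test_welch_agrees_with_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 2, 9)
        res = welch_t(x, y)
        t, p = stats.ttest_ind(x, y, equal_var=False)
        assert res.t == pytest.approx(t) and res.p == pytest.approx(p)
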