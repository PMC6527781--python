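import numpy as np
import pytest
from scipy import stats

from aglsgwas import (
    AglsConfig,
    PhenotypeTable,
    PtaTable,
    adjust_phenotypes,
    empirical_log10p,
    fit_empirical_tail,
    fit_snp,
    genotype_frequencies,
    run_gwas,
    snp_tests,
)


class TestAdjustPhenotypes:
    def test_direct_substitution(self):
        y = PhenotypeTable({"c1": {"MY": 100.0}})
        pta = PtaTable({"c1": {"MY": 10.0}})
        ids, ystar = adjust_phenotypes(y, pta, "MY")
        assert ids == ["c1"] and ystar[0] == 80.0

    def test_zero_pta_is_identity(self):
        y = PhenotypeTable({"c1": {"MY": 5.0}, "c2": {"MY": -3.0}})
        pta = PtaTable({"c1": {"MY": 0.0}, "c2": {"MY": 0.0}})
        _, ystar = adjust_phenotypes(y, pta, "MY")
        assert ystar.tolist() == [5.0, -3.0]

    def test_individuals_missing_either_value_dropped(self):
        y = PhenotypeTable({"c1": {"MY": 1.0}, "c2": {"MY": 2.0}})
        pta = PtaTable({"c1": {"MY": 0.5}})
        ids, _ = adjust_phenotypes(y, pta, "MY")
        assert ids == ["c1"]

    def test_perfect_pta_leaves_pure_noise(self, rng):
        """With PTA = a/2 exactly, y* equals the residual e."""
        n = 500
        a = rng.normal(0, 1, n)
        e = rng.normal(0, 1, n)
        ids = [f"i{k}" for k in range(n)]
        y = PhenotypeTable({i: {"t": float(ai + ei)} for i, ai, ei in zip(ids, a, e)})
        pta = PtaTable({i: {"t": float(ai / 2)} for i, ai in zip(ids, a)})
        got_ids, ystar = adjust_phenotypes(y, pta, "t")
        order = [ids.index(i) for i in got_ids]
        np.testing.assert_allclose(ystar, e[order], atol=1e-12)


class TestFitSnp:
    def test_two_class_means(self):
        fit = fit_snp(np.array([1.0, 2, 3, 4]), np.array([0, 0, 2, 2]), min_class_count=1)
        assert fit.g_hat[0] == 1.5 and fit.g_hat[2] == 3.5
        assert np.isnan(fit.g_hat[1])
        assert fit.k == 2 and fit.dominance_untestable

    def test_hand_least_squares_six_points(self):
        fit = fit_snp(np.array([1.0, 3, 2, 4, 0, 2]), np.array([0, 0, 1, 1, 2, 2]),
                      min_class_count=1)
        np.testing.assert_allclose(fit.g_hat, [2.0, 3.0, 1.0])
        assert fit.v2 == pytest.approx(2.0)  # RSS 6 over n-k = 3
        assert fit.k == 3 and fit.n == 6

    def test_translation_equivariance(self, rng):
        y = rng.normal(size=60)
        codes = rng.integers(0, 3, size=60)
        f0 = fit_snp(y, codes, min_class_count=1)
        f1 = fit_snp(y + 7.5, codes, min_class_count=1)
        np.testing.assert_allclose(f1.g_hat, f0.g_hat + 7.5)
        assert f1.v2 == pytest.approx(f0.v2)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            fit_snp(np.arange(4.0), np.zeros(4, dtype=int))


class TestSnpTests:
    def test_agrees_with_generic_ls_contrast_oracle(self, rng):
        """Balanced one-way layout: t matches the textbook contrast t to 1e-8."""
        m = 40
        codes = np.repeat([0, 1, 2], m)
        y = rng.normal(0, 1, codes.size) + np.array([0.0, 0.3, 0.8])[codes]
        fit = fit_snp(y, codes, min_class_count=1)
        freq = genotype_frequencies(codes)
        res = snp_tests(fit, freq)
        import statsmodels.api as sm

        X = np.zeros((codes.size, 3))
        X[np.arange(codes.size), codes] = 1.0
        ols = sm.OLS(y, X).fit()
        from aglsgwas import additive_contrast, dominance_contrast

        t_add_oracle = float(np.abs(ols.t_test(additive_contrast(freq).as_array()).tvalue).squeeze())
        t_dom_oracle = float(np.abs(ols.t_test(dominance_contrast().as_array()).tvalue).squeeze())
        assert res.t_add == pytest.approx(t_add_oracle, abs=1e-8)
        assert res.t_dom == pytest.approx(t_dom_oracle, abs=1e-8)
        # p-value consistency with the t tail at n-k df
        p = 2 * stats.t.sf(res.t_add, fit.n - fit.k)
        assert res.log10invp_add == pytest.approx(-np.log10(p), rel=1e-10)

    def test_flat_class_means_give_zero_statistics(self):
        codes = np.tile([0, 1, 2], 10)
        # equal class means exactly: within-class deviations cancel
        y = np.full(30, 2.0)
        y[codes == 0] += np.array([0.5, -0.5] * 5)
        y[codes == 1] += np.array([0.5, -0.5] * 5)
        y[codes == 2] += np.array([0.5, -0.5] * 5)
        fit = fit_snp(y, codes, min_class_count=1)
        freq = genotype_frequencies(codes)
        res = snp_tests(fit, freq)
        assert res.t_add == pytest.approx(0.0, abs=1e-12)
        assert res.t_dom == pytest.approx(0.0, abs=1e-12)
        assert res.log10invp_add == pytest.approx(0.0, abs=1e-12)

    def test_dominance_untestable_flag_propagates(self):
        fit = fit_snp(np.arange(8.0), np.array([0, 0, 0, 0, 2, 2, 2, 2]),
                      min_class_count=1)
        res = snp_tests(fit, genotype_frequencies(np.array([0, 0, 0, 0, 2, 2, 2, 2])))
        assert res.dominance_untestable and res.t_dom is None


class TestEmpiricalTail:
    @pytest.mark.parametrize(
        "t,expected,rel",
        [
            (61.81, 820.00, 1e-3),
            (41.50, 373.90, 1e-3),
            (41.30, 370.36, 1e-3),
            (157.00, 5150.79, 2e-3),
            (0.0, 0.0, 1e-12),
        ],
    )
    def test_power_law_anchor_values(self, t, expected, rel):
        assert empirical_log10p(t) == pytest.approx(expected, rel=rel, abs=1e-9)

    def test_strictly_increasing_and_negative_rejected(self):
        grid = np.linspace(0.1, 200, 500)
        vals = [empirical_log10p(t) for t in grid]
        assert np.all(np.diff(vals) > 0)
        with pytest.raises(ValueError):
            empirical_log10p(-1.0)

    def test_tracks_exact_tail_where_representable(self):
        """Near-perfect correlation with the exact -log10 p over a large-df t grid."""
        df = 294_079 - 3
        grid = np.linspace(5, 37, 200)  # p stays >= 1e-300 here
        exact = -np.log10(2 * stats.t.sf(grid, df))
        emp = np.array([empirical_log10p(t) for t in grid])
        r = np.corrcoef(exact, emp)[0, 1]
        assert r >= 0.999

    def test_refit_recovers_power_law(self):
        grid = np.linspace(5, 37, 50)
        lp = 0.31 * grid**1.87
        coef, expo = fit_empirical_tail(grid, lp)
        assert coef == pytest.approx(0.31, rel=1e-6)
        assert expo == pytest.approx(1.87, rel=1e-6)


class TestRunGwas:
    def test_row_cardinality_and_column_permutation(self, small_dataset):
        ds = small_dataset
        rows = run_gwas(ds.genotypes, ds.phenotypes, ds.pta)
        assert len(rows) == ds.genotypes.n_snps * 2
        perm = list(reversed(range(ds.genotypes.n_snps)))
        rows_perm = run_gwas(ds.genotypes.subset_snps(perm), ds.phenotypes, ds.pta)
        by_key = {(r.snp_id, r.trait): r for r in rows}
        for r in rows_perm:
            ref = by_key[(r.snp_id, r.trait)]
            assert r.t_add == pytest.approx(ref.t_add, rel=1e-12, abs=1e-12)
            assert r.rank_add == ref.rank_add

    def test_large_planted_effect_attains_rank_one(self, small_dataset):
        ds = small_dataset
        rows = run_gwas(ds.genotypes, ds.phenotypes, ds.pta)
        milk = [r for r in rows if r.trait == "milk"]
        top = min(milk, key=lambda r: r.rank_add if r.rank_add else 10**9)
        assert top.snp_id == "snp00004"  # causal index 3

    def test_antagonistic_pleiotropy_recovered_with_opposite_signs(self, small_dataset):
        ds = small_dataset
        rows = run_gwas(ds.genotypes, ds.phenotypes, ds.pta)
        by = {(r.snp_id, r.trait): r for r in rows}
        a_milk = by[("snp00004", "milk")].alpha
        a_fat = by[("snp00004", "fat")].alpha
        assert a_milk > 0 > a_fat
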