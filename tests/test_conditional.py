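import numpy as np
import pytest

from aglsgwas import (
    CausalEffect,
    SimulationConfig,
    TraitSpec,
    conditional_scan,
    fit_snp,
    residualize_on_index,
    retention_summary,
    simulate_dataset,
    adjust_phenotypes,
)


def aligned_y_star(ds, trait):
    ids, ystar = adjust_phenotypes(ds.phenotypes, ds.pta, trait)
    index = {ind: i for i, ind in enumerate(ds.genotypes.individuals)}
    out = np.full(ds.genotypes.n_individuals, np.nan)
    for i, v in zip(ids, ystar):
        out[index[i]] = v
    return out


@pytest.fixture(scope="module")
def ld_region():
    """Index SNP 0, SNPs 1-3 perfect LD copies, SNPs 4-5 independent causal."""
    cfg = SimulationConfig(
        n_individuals=2500,
        n_snps=20,
        seed=31,
        fixed_p1=0.5,
        ld_copies=[(0, 1, 0.0), (0, 2, 0.0), (0, 3, 0.0)],
        traits={"t": TraitSpec(sigma_a2=0.3, sigma_e2=0.7, pta_reliability=0.8)},
        causal=[
            CausalEffect(0, "t", alpha=2.0),
            CausalEffect(4, "t", alpha=1.0),
            CausalEffect(5, "t", alpha=1.0),
        ],
    )
    return simulate_dataset(cfg)


class TestResidualize:
    def test_subtracts_class_mean(self):
        y = np.array([10.0, 11.0, 12.0, 13.0])
        codes = np.array([0, 1, 2, 2])
        fit = fit_snp(y, codes, min_class_count=1)
        resid, keep = residualize_on_index(np.array([10.0]), np.array([2]), fit)
        assert resid[0] == pytest.approx(10.0 - fit.g_hat[2])

    def test_perfect_ld_snp_zeroed(self, ld_region):
        ds = ld_region
        y = aligned_y_star(ds, "t")
        col = ds.genotypes.codes[:, 0]
        fit = fit_snp(y, col)
        resid, _ = residualize_on_index(y, col, fit)
        rows = conditional_scan(ds.genotypes, ("1", 1, 4000), {"t": resid})
        by = {r.snp_id: r for r in rows}
        for sid in ("snp00001", "snp00002", "snp00003", "snp00004"):
            assert by[sid].t_add == pytest.approx(0.0, abs=1e-8)

    def test_idempotent(self, ld_region):
        ds = ld_region
        y = aligned_y_star(ds, "t")
        col = ds.genotypes.codes[:, 0]
        fit = fit_snp(y, col)
        r1, _ = residualize_on_index(y, col, fit)
        fit2 = fit_snp(r1, col)
        r2, _ = residualize_on_index(r1, col, fit2)
        np.testing.assert_allclose(r2, r1, atol=1e-8)


class TestConditionalScan:
    def test_self_conditioning_zeroes_index(self, ld_region):
        ds = ld_region
        y = aligned_y_star(ds, "t")
        col = ds.genotypes.codes[:, 0]
        fit = fit_snp(y, col)
        resid, _ = residualize_on_index(y, col, fit)
        rows = conditional_scan(ds.genotypes, ("1", 1, 1), {"t": resid})
        assert rows[0].snp_id == "snp00001"
        assert rows[0].t_add == pytest.approx(0.0, abs=1e-8)

    def test_row_count_is_region_snps_times_traits(self, ld_region):
        ds = ld_region
        y = aligned_y_star(ds, "t")
        rows = conditional_scan(ds.genotypes, ("1", 1, 10_000), {"t": y})
        # positions are 1 + 1000*j; j = 0..9 fall inside [1, 10000]
        assert len(rows) == 10

    def test_empty_region_rejected(self, ld_region):
        with pytest.raises(ValueError, match="empty region"):
            conditional_scan(ld_region.genotypes, ("9", 1, 2), {"t": np.zeros(1)})

    def test_independent_effects_survive_conditioning(self, ld_region):
        ds = ld_region
        y = aligned_y_star(ds, "t")
        col = ds.genotypes.codes[:, 0]
        fit = fit_snp(y, col)
        resid, _ = residualize_on_index(y, col, fit)
        region = ("1", 1, 20_000)
        before = conditional_scan(ds.genotypes, region, {"t": y})
        after = conditional_scan(ds.genotypes, region, {"t": resid})
        b = {r.snp_id: r for r in before}
        a = {r.snp_id: r for r in after}
        # tagged cluster eliminated, independent signals retained
        for sid in ("snp00001", "snp00002", "snp00003", "snp00004"):
            assert a[sid].log10invp_add < 2.0
        for sid in ("snp00005", "snp00006"):
            assert b[sid].log10invp_add > 20
            assert a[sid].log10invp_add > 20


class TestRetentionSummary:
    def test_identical_inputs_identical_counts(self, ld_region):
        ds = ld_region
        y = aligned_y_star(ds, "t")
        rows = conditional_scan(ds.genotypes, ("1", 1, 20_000), {"t": y})
        rep = retention_summary(rows, rows, ds.genotypes.snps[0], fraction=0.3)
        n_top, survived = rep.counts["t"]
        assert n_top == survived

    def test_planted_mixture_counts(self, ld_region):
        """Top set = LD cluster + independents; only independents survive."""
        ds = ld_region
        y = aligned_y_star(ds, "t")
        col = ds.genotypes.codes[:, 0]
        fit = fit_snp(y, col)
        resid, _ = residualize_on_index(y, col, fit)
        region = ("1", 1, 20_000)
        before = conditional_scan(ds.genotypes, region, {"t": y})
        after = conditional_scan(ds.genotypes, region, {"t": resid})
        rep = retention_summary(before, after, ds.genotypes.snps[0], fraction=0.3)
        n_top, survived = rep.counts["t"]
        assert n_top == 6  # ceil(0.3 * 20) = 6: the 4 LD SNPs + 2 independents
        assert survived == 2

    def test_mismatched_grids_rejected(self, ld_region):
        ds = ld_region
        y = aligned_y_star(ds, "t")
        rows = conditional_scan(ds.genotypes, ("1", 1, 20_000), {"t": y})
        with pytest.raises(ValueError, match="grids"):
            retention_summary(rows, rows[:-1], ds.genotypes.snps[0])
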