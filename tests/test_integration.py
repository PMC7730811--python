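"""Methylation-expression correlation, selection, directionality."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from necmethylome import SimulationConfig, simulate_dataset
from necmethylome.expression import DifferentialExpression
from necmethylome.integration import (
    MethylationExpressionIntegration,
    correlation_density,
    correlation_of_correlations,
    directionality_summary,
    gene_correlation,
    select_genes,
)
from necmethylome.regions import (
    RegionDifferentialMethylation,
    aggregate_region,
    promoter_regions,
)


class TestGeneCorrelation:
    def test_perfect_linear_relation(self):
        x = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        res = gene_correlation(x, 3 * x + 1)
        assert res["r"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(0.0, abs=1e-12)

    def test_five_point_fixture_closed_form(self):
        res = gene_correlation([1, 2, 3, 4, 5], [2, 1, 3, 2, 4])
        assert res["r"] == pytest.approx(0.6933752452815365, abs=1e-10)
        assert res["t"] == pytest.approx(1.666666666666667, abs=1e-10)
        assert res["p"] == pytest.approx(0.19417134561205848, abs=1e-10)

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            x, y = rng.normal(size=(2, 12))
            res = gene_correlation(x, y)
            r_ref, p_ref = stats.pearsonr(x, y)
            assert res["r"] == pytest.approx(r_ref, abs=1e-12)
            assert res["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_symmetric_in_arguments(self):
        x = np.array([1.0, 3, 2, 5, 4, 6])
        y = np.array([2.0, 2, 3, 4, 6, 5])
        assert gene_correlation(x, y)["r"] == pytest.approx(
            gene_correlation(y, x)["r"]
        )

    def test_zero_variance_excluded_with_reason(self):
        res = gene_correlation([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res["r"])
        assert res["reason"] == "zero variance"

    def test_too_few_pairs(self):
        res = gene_correlation([1, 2], [3, 4])
        assert np.isnan(res["r"]) and "3 pairs" in res["reason"]

    def test_all_small_fixtures_match_oracle(self):
        # exhaustive small-n check against the closed-form t mapping
        rng = np.random.default_rng(11)
        for n in (3, 4, 5, 6):
            for _ in range(5):
                x, y = rng.normal(size=(2, n))
                res = gene_correlation(x, y)
                r = np.corrcoef(x, y)[0, 1]
                t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
                assert res["t"] == pytest.approx(t, abs=1e-10)


class TestSelectGenes:
    def records(self, **over):
        base = {
            "p_meth": [0.01], "delta_logit": [1.5], "p_corr_adj": [0.05],
        }
        base.update(over)
        return pd.DataFrame(base)

    def test_failing_one_criterion_rejects(self):
        rec = self.records(delta_logit=[0.5])
        assert not select_genes(rec)["tier_01"].iloc[0]

    def test_vacuous_thresholds_select_all(self):
        rec = pd.DataFrame(
            {"p_meth": [0.9, 0.5], "delta_logit": [0.0, 0.1], "p_corr_adj": [1.0, 0.7]}
        )
        sel = select_genes(rec, p_meth=1, min_delta_logit=0, p_corr_adj=1,
                           p_corr_adj_strict=1)
        assert sel["tier_01"].all() and sel["tier_005"].all()

    def test_tiers_are_nested(self):
        rng = np.random.default_rng(3)
        rec = pd.DataFrame(
            {
                "p_meth": rng.uniform(size=200),
                "delta_logit": rng.normal(scale=2, size=200),
                "p_corr_adj": rng.uniform(size=200),
            }
        )
        sel = select_genes(rec)
        assert (sel["tier_005"] <= sel["tier_01"]).all()

    def test_coupled_gene_recovery(self):
        # half the DE genes coupled to strongly hypermethylated promoters:
        # the selection rule must find at least 70% of them
        cfg = SimulationConfig(
            n_cpg=30_000, n_genes=500, genome_length=15_000_000,
            n_samples_per_group=10, hyper_shift=2.5, frac_shifted_sites=1.0,
            coupling_frac=0.5, de_lfc_mean=2.0, seed=3,
        )
        ds = simulate_dataset(cfg)
        rm = aggregate_region(ds.methylation, promoter_regions(ds.annotation))
        reg = RegionDifferentialMethylation(rm).fit()
        de = DifferentialExpression(ds.expression).fit()
        res = MethylationExpressionIntegration(
            rm, ds.expression, reg.frame, de.frame
        ).fit()
        truth = ds.truth.genes.set_index("gene_id")
        f = res.frame.set_index("gene_id")
        coupled = truth.index[truth["is_coupled"]]
        recall = f.loc[coupled, "selected_tier_01"].mean()
        assert recall >= 0.7


class TestDirectionality:
    def test_printed_count_arithmetic(self):
        # 739 joined genes: 505 down (428 hyper), 234 up (153 hyper)
        joined = pd.DataFrame(
            {
                "expr_direction": ["down"] * 505 + ["up"] * 234,
                "meth_direction": (
                    ["hyper"] * 428 + ["hypo"] * 77 + ["hyper"] * 153 + ["hypo"] * 81
                ),
            }
        )
        out = directionality_summary(joined).set_index("expr_direction")
        assert round(100 * out.loc["down", "frac_of_total"], 1) == 68.3
        assert round(100 * out.loc["down", "frac_hyper"], 1) == 84.8
        assert round(100 * out.loc["up", "frac_hyper"], 1) == 65.4

    def test_row_fractions_sum_to_one_and_total_matches(self):
        rng = np.random.default_rng(6)
        joined = pd.DataFrame(
            {
                "expr_direction": rng.choice(["up", "down"], 300),
                "meth_direction": rng.choice(["hyper", "hypo"], 300),
            }
        )
        out = directionality_summary(joined)
        assert out["n"].sum() == 300
        np.testing.assert_allclose(out["frac_hyper"] + out["frac_hypo"], 1.0)
        assert out["frac_of_total"].sum() == pytest.approx(1.0)

    def test_empty_join(self):
        out = directionality_summary(
            pd.DataFrame(columns=["expr_direction", "meth_direction"])
        )
        assert len(out) == 0


class TestCorrelationOfCorrelations:
    def test_identical_records_give_unit_correlation(self):
        rng = np.random.default_rng(4)
        rec = pd.DataFrame(
            {"gene_id": [f"G{i}" for i in range(50)], "r": rng.uniform(-1, 1, 50)}
        )
        res = correlation_of_correlations(rec, rec)
        assert res["r_cc"] == pytest.approx(1.0)

    def test_independent_tissues_near_zero(self):
        rng = np.random.default_rng(9)
        genes = [f"G{i}" for i in range(800)]
        a = pd.DataFrame({"gene_id": genes, "r": rng.uniform(-0.6, 0.6, 800)})
        b = pd.DataFrame({"gene_id": genes, "r": rng.uniform(-0.6, 0.6, 800)})
        res = correlation_of_correlations(a, b)
        # null 95% CI for r at n=800 is about +/- 0.07
        assert abs(res["r_cc"]) < 0.07

    def test_shared_coupling_gives_positive_correlation(self):
        # same coupled genes in both tissues: correlated r profiles
        rng = np.random.default_rng(10)
        genes = [f"G{i}" for i in range(600)]
        coupled = rng.permutation(600)[:120]
        base = np.zeros(600)
        base[coupled] = -0.6
        a = pd.DataFrame({"gene_id": genes, "r": base + rng.normal(0, 0.2, 600)})
        b = pd.DataFrame({"gene_id": genes, "r": base + rng.normal(0, 0.2, 600)})
        res = correlation_of_correlations(a, b)
        assert res["r_cc"] > 0
        assert res["p"] < 0.05

    def test_too_few_shared_genes_raises(self):
        a = pd.DataFrame({"gene_id": ["G1", "G2"], "r": [0.1, 0.2]})
        with pytest.raises(ValueError, match="shared"):
            correlation_of_correlations(a, a.iloc[:1])


class TestCorrelationDensity:
    def test_all_zero_deltas_single_stratum(self):
        rec = pd.DataFrame({"r": [0.1, -0.2, 0.3], "delta_rate": [0.0, 0.0, 0.0]})
        out = correlation_density(rec)
        assert "low_delta" in out["strata"]
        assert "high_delta" not in out["strata"]
        assert any("high_delta" in n for n in out["notes"])

    def test_densities_integrate_to_one(self):
        rng = np.random.default_rng(12)
        rec = pd.DataFrame(
            {"r": rng.uniform(-1, 1, 500), "delta_rate": rng.normal(0, 0.3, 500)}
        )
        out = correlation_density(rec)
        for s in out["strata"].values():
            width = np.diff(s["edges"])
            assert (s["density"] * width).sum() == pytest.approx(1.0, abs=1e-6)

    def test_strong_coupling_shifts_high_delta_stratum_negative(self):
        cfg = SimulationConfig(
            n_cpg=30_000, n_genes=400, genome_length=15_000_000,
            n_samples_per_group=10, hyper_shift=2.5, frac_shifted_sites=1.0,
            coupling_frac=0.6, de_frac=0.4, de_lfc_mean=2.0, seed=14,
        )
        ds = simulate_dataset(cfg)
        rm = aggregate_region(ds.methylation, promoter_regions(ds.annotation))
        reg = RegionDifferentialMethylation(rm).fit()
        res = MethylationExpressionIntegration(rm, ds.expression, reg.frame).fit()
        out = correlation_density(res.frame, delta_threshold=0.2)
        assert (
            out["strata"]["high_delta"]["mean_r"]
            < out["strata"]["low_delta"]["mean_r"]
        )
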