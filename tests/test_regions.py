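"""Region aggregation, logit transform and DMR calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit as sp_logit

from necmethylome.containers import MethylationTable
from necmethylome.regions import (
    RegionDifferentialMethylation,
    RegionMethylation,
    aggregate_region,
    call_dmrs,
    logit_transform,
    promoter_regions,
    shared_dmrs,
)
from tests.conftest import make_samples


def table_from_rates(rates, coverage, samples, positions=None):
    rates = np.asarray(rates, float)
    coverage = np.asarray(coverage)
    meth = np.round(rates * coverage).astype(int)
    n = rates.shape[0]
    pos = positions if positions is not None else np.arange(1, n + 1) * 100
    sites = pd.DataFrame({"chrom": ["chr1"] * n, "pos": pos})
    return MethylationTable(sites, meth, coverage, samples)


class TestAggregateRegion:
    def test_simple_mean_of_site_rates(self):
        samples = make_samples(1, 1)
        mt = table_from_rates(
            [[0.2, 0.2], [0.4, 0.4], [0.6, 0.6]], np.full((3, 2), 10), samples,
            positions=[100, 200, 300],
        )
        regions = pd.DataFrame(
            {"region_id": ["R1"], "chrom": ["chr1"], "start": [1], "end": [1000]}
        )
        rm = aggregate_region(mt, regions, min_cov=5)
        np.testing.assert_allclose(rm.rates.loc["R1"], [0.4, 0.4])
        assert (rm.n_informative.loc["R1"] == 3).all()

    def test_single_site_region_is_site_rate(self):
        samples = make_samples(1, 1)
        mt = table_from_rates([[0.3, 0.7]], np.full((1, 2), 10), samples, [500])
        regions = pd.DataFrame(
            {"region_id": ["R1"], "chrom": ["chr1"], "start": [400], "end": [600]}
        )
        rm = aggregate_region(mt, regions)
        np.testing.assert_allclose(rm.rates.loc["R1"], [0.3, 0.7])

    def test_low_coverage_sites_are_not_informative(self):
        samples = make_samples(1, 1)
        cov = np.array([[10, 2], [10, 10]])
        mt = table_from_rates([[0.2, 0.9], [0.6, 0.5]], cov, samples, [100, 200])
        regions = pd.DataFrame(
            {"region_id": ["R1"], "chrom": ["chr1"], "start": [1], "end": [300]}
        )
        rm = aggregate_region(mt, regions, min_cov=5)
        assert rm.rates.loc["R1"].iloc[0] == pytest.approx(0.4)
        assert rm.rates.loc["R1"].iloc[1] == pytest.approx(0.5)  # 2x site excluded
        assert rm.n_informative.loc["R1"].tolist() == [2, 1]

    def test_region_without_informative_sites_is_missing_not_imputed(self):
        samples = make_samples(1, 1)
        mt = table_from_rates([[0.2, 0.2]], np.full((1, 2), 2), samples, [100])
        regions = pd.DataFrame(
            {"region_id": ["R1"], "chrom": ["chr1"], "start": [1], "end": [300]}
        )
        rm = aggregate_region(mt, regions, min_cov=5)
        assert rm.rates.loc["R1"].isna().all()

    def test_matches_brute_force_on_random_regions(self):
        rng = np.random.default_rng(9)
        samples = make_samples(3, 3)
        n_sites = 400
        pos = np.sort(rng.choice(100_000, n_sites, replace=False) + 1)
        cov = rng.integers(0, 30, size=(n_sites, 6))
        rates = rng.uniform(size=(n_sites, 6))
        mt = table_from_rates(rates, cov, samples, pos)
        starts = rng.integers(1, 90_000, size=100)
        regions = pd.DataFrame(
            {
                "region_id": [f"R{i}" for i in range(100)],
                "chrom": "chr1",
                "start": starts,
                "end": starts + rng.integers(100, 5_000, size=100),
            }
        )
        rm = aggregate_region(mt, regions, min_cov=5)
        r = mt.rates()
        for _, reg in regions.sample(20, random_state=0).iterrows():
            in_reg = (pos >= reg["start"]) & (pos <= reg["end"])
            for j in range(6):
                informative = in_reg & (cov[:, j] >= 5)
                expected = r[informative, j].mean() if informative.any() else np.nan
                got = rm.rates.loc[reg["region_id"]].iloc[j]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)

    def test_invariant_to_site_ordering(self):
        rng = np.random.default_rng(2)
        samples = make_samples(2, 2)
        pos = np.arange(1, 51) * 10
        cov = rng.integers(5, 20, size=(50, 4))
        rates = rng.uniform(size=(50, 4))
        regions = pd.DataFrame(
            {"region_id": ["A", "B"], "chrom": "chr1", "start": [1, 200], "end": [199, 600]}
        )
        mt = table_from_rates(rates, cov, samples, pos)
        base = aggregate_region(mt, regions)
        perm = rng.permutation(50)
        # re-sort sites after permuting rows: table requires sorted positions
        order = np.argsort(pos[perm])
        mt2 = table_from_rates(rates[perm][order], cov[perm][order], samples, pos[perm][order])
        again = aggregate_region(mt2, regions)
        pd.testing.assert_frame_equal(base.rates, again.rates)


class TestLogitTransform:
    def test_half_maps_to_zero(self):
        assert logit_transform(0.5) == pytest.approx(0.0)

    def test_zero_with_default_eps(self):
        assert logit_transform(0.0, eps=0.01) == pytest.approx(-4.59511985013459)

    def test_antisymmetry(self):
        r = np.linspace(0.01, 0.99, 25)
        np.testing.assert_allclose(
            logit_transform(r), -logit_transform(1 - r), atol=1e-12
        )


def region_sim(seed=13, n_regions=500, n_per_group=8, n_shift=50, shift=1.5, kappa=50):
    """Region-level rate simulation with a known shifted subset."""
    rng = np.random.default_rng(seed)
    m = rng.beta(5, 5, n_regions)
    shifted = np.zeros(n_regions, bool)
    shifted[rng.permutation(n_regions)[:n_shift]] = True
    samples = make_samples(n_per_group, n_per_group)
    nec = (samples["condition"] == "NEC").to_numpy()
    m_eff = np.where(
        shifted[:, None] & nec[None, :], expit(sp_logit(m) + shift)[:, None], m[:, None]
    )
    rates = rng.beta(kappa * m_eff, kappa * (1 - m_eff))
    idx = [f"R{i}" for i in range(n_regions)]
    rm = RegionMethylation(
        rates=pd.DataFrame(rates, index=idx, columns=samples["sample_id"]),
        n_informative=pd.DataFrame(5, index=idx, columns=samples["sample_id"]),
        samples=samples,
        min_cov=5,
    )
    return rm, np.array(idx)[shifted]


class TestCallDmrs:
    def test_delta_exactly_at_threshold_is_retained(self):
        frame = pd.DataFrame(
            {
                "region_id": ["R1"],
                "delta_rate": [0.1],
                "n_informative_min": [5],
                "p_value": [0.01],
            }
        )
        assert len(call_dmrs(frame)) == 1  # "at least 0.1" is inclusive

    def test_all_null_deltas_give_empty_table(self):
        frame = pd.DataFrame(
            {
                "region_id": ["R1", "R2"],
                "delta_rate": [0.0, 0.0],
                "n_informative_min": [5, 5],
                "p_value": [0.001, 0.2],
            }
        )
        assert len(call_dmrs(frame)) == 0

    def test_informative_cpg_rule_is_strictly_more_than_three(self):
        frame = pd.DataFrame(
            {
                "region_id": ["R1", "R2"],
                "delta_rate": [0.5, 0.5],
                "n_informative_min": [3, 4],
                "p_value": [0.01, 0.01],
            }
        )
        assert call_dmrs(frame)["region_id"].tolist() == ["R2"]

    def test_parameter_recovery_on_region_simulation(self):
        # 50 shifted of 500 regions, logit shift 1.5, 8v8
        rm, true_ids = region_sim()
        res = RegionDifferentialMethylation(rm).fit()
        called = set(call_dmrs(res.frame)["region_id"])
        truth = set(true_ids)
        recall = len(called & truth) / len(truth)
        fdr = len(called - truth) / max(len(called), 1)
        assert recall >= 0.8
        assert fdr <= 0.2


class TestModelProperties:
    def test_group_swap_negates_delta_preserves_p(self):
        rm, _ = region_sim(seed=21, n_regions=100, n_shift=10)
        res_a = RegionDifferentialMethylation(rm).fit()
        flipped = rm.samples.copy()
        flipped["condition"] = np.where(
            flipped["condition"] == "NEC", "non-NEC", "NEC"
        )
        rm_b = RegionMethylation(rm.rates, rm.n_informative, flipped, rm.min_cov)
        res_b = RegionDifferentialMethylation(rm_b).fit()
        np.testing.assert_allclose(
            res_a.frame["delta_rate"], -res_b.frame["delta_rate"], atol=1e-12
        )
        np.testing.assert_allclose(
            res_a.frame["p_value"], res_b.frame["p_value"], atol=1e-10
        )


class TestSharedDmrs:
    def test_disjoint_sets_empty(self):
        a = pd.DataFrame({"region_id": ["R1"], "p_value": [0.01]})
        b = pd.DataFrame({"region_id": ["R2"], "p_value": [0.01]})
        assert len(shared_dmrs(a, b)) == 0

    def test_identical_sets_full(self):
        a = pd.DataFrame({"region_id": ["R1", "R2"], "p_value": [0.01, 0.02]})
        assert len(shared_dmrs(a, a)) == 2

    def test_random_overlap_matches_set_intersection(self):
        rng = np.random.default_rng(5)
        ids = [f"R{i}" for i in range(200)]
        a_ids = list(rng.choice(ids, 80, replace=False))
        b_ids = list(rng.choice(ids, 90, replace=False))
        a = pd.DataFrame({"region_id": a_ids, "p_value": 0.01})
        b = pd.DataFrame({"region_id": b_ids, "p_value": 0.01})
        assert len(shared_dmrs(a, b)) == len(set(a_ids) & set(b_ids))


def test_promoter_regions_from_simulated_annotation(small_dataset):
    regions = promoter_regions(small_dataset.annotation)
    assert regions["region_id"].str.endswith(":promoter").all()
    assert len(regions) == len(small_dataset.annotation.genes)
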