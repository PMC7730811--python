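"""Region-level differential methylation: promoters and gene bodies.

Per sample, a region's methylation is the unweighted mean of the rates
of its informative CpGs (coverage >= ``min_cov`` in that sample).  The
mean rates are logit-transformed (with an epsilon guard against 0/1)
and tested region-by-region with a two-group linear model whose
variances are moderated by the shared empirical-Bayes machinery.  DMRs
are regions passing |delta rate| >= 0.1, > 3 informative CpGs in every
sample, and the p threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import MethylationTable
from .ebayes import moderated_t
from .multitest import adjust_pvalues

__all__ = [
    "RegionMethylation",
    "RegionDifferentialMethylation",
    "RegionDMResults",
    "aggregate_region",
    "logit_transform",
    "eb_moderated_test",
    "call_dmrs",
    "shared_dmrs",
    "promoter_regions",
    "gene_body_regions",
]

DEFAULT_EPS = 0.01
DEFAULT_MIN_COV = 5


def promoter_regions(annotation) -> pd.DataFrame:
    prom = annotation.get("promoter").copy()
    prom["region_id"] = prom["feature_id"].astype(str) + ":promoter"
    return prom[["region_id", "chrom", "start", "end", "feature_id"]]


def gene_body_regions(annotation) -> pd.DataFrame:
    g = annotation.genes
    return pd.DataFrame(
        {
            "region_id": g["gene_id"].astype(str) + ":gene_body",
            "chrom": g["chrom"],
            "start": g["gene_start"],
            "end": g["gene_end"],
            "feature_id": g["gene_id"],
        }
    )


@dataclass
class RegionMethylation:
    """Per-region per-sample mean methylation and informative-CpG counts."""

    rates: pd.DataFrame  # region_id x sample_id, mean rate (NaN = no informative CpG)
    n_informative: pd.DataFrame  # same shape, integer counts
    samples: pd.DataFrame
    min_cov: int

    def logits(self, eps: float = DEFAULT_EPS) -> pd.DataFrame:
        return pd.DataFrame(
            logit_transform(self.rates.to_numpy(), eps),
            index=self.rates.index,
            columns=self.rates.columns,
        )


def aggregate_region(
    table: MethylationTable,
    regions: pd.DataFrame,
    min_cov: int = DEFAULT_MIN_COV,
) -> RegionMethylation:
    """Average per-site rates over each region's informative CpGs, per sample.

    ``regions`` needs columns region_id, chrom, start, end (1-based
    closed).  A site is informative for a sample when its coverage is at
    least ``min_cov`` there.  Regions with no informative site in a
    sample are missing (NaN) for that sample, never imputed.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    if regions["region_id"].duplicated().any():
        raise ValueError("duplicate region_id")
    rates = table.rates()
    informative = table.coverage >= min_cov
    rates = np.where(informative, rates, np.nan)

    pos = table.sites["pos"].to_numpy()
    chrom = table.sites["chrom"].to_numpy()
    n_regions = len(regions)
    sums = np.zeros((n_regions, table.n_samples))
    cnts = np.zeros((n_regions, table.n_samples))
    reg = regions.reset_index(drop=True)
    for chrom_name, grp in reg.groupby("chrom"):
        mask = chrom == chrom_name
        if not mask.any():
            continue
        p = pos[mask]
        site_rows = np.flatnonzero(mask)
        # regions may overlap; test each region against the site array
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        rows = grp.index.to_numpy()
        lo = np.searchsorted(p, starts, side="left")
        hi = np.searchsorted(p, ends, side="right")
        for s, e, row in zip(lo, hi, rows):
            if e <= s:
                continue
            r = rates[site_rows[s:e]]
            valid = ~np.isnan(r)
            sums[row] = np.where(valid, r, 0.0).sum(axis=0)
            cnts[row] = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    idx = pd.Index(reg["region_id"], name="region_id")
    cols = list(table.samples["sample_id"])
    return RegionMethylation(
        rates=pd.DataFrame(mean, index=idx, columns=cols),
        n_informative=pd.DataFrame(cnts.astype(int), index=idx, columns=cols),
        samples=table.samples,
        min_cov=min_cov,
    )


def logit_transform(rate, eps: float = DEFAULT_EPS) -> np.ndarray:
    """ln(r'/(1-r')) with r' = clip(rate, eps, 1-eps); NaN passes through."""
    r = np.clip(np.asarray(rate, dtype=float), eps, 1 - eps)
    with np.errstate(invalid="ignore"):
        return np.log(r / (1 - r))


def eb_moderated_test(
    logits: pd.DataFrame,
    group: np.ndarray,
    min_per_group: int = 2,
    df_prior: float | None = None,
    s2_prior: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-region moderated t-test of logit methylation, NEC minus control.

    ``group`` is boolean per sample (True = NEC).  Regions with fewer
    than ``min_per_group`` non-missing samples in either group are
    reported untested (NaN statistics).  Forcing ``df_prior``/``s2_prior``
    bypasses hyperparameter estimation (limit identities).
    """
    x = logits.to_numpy(dtype=float)
    group = np.asarray(group, dtype=bool)
    valid = ~np.isnan(x)
    n1 = (valid & group).sum(axis=1)
    n0 = (valid & ~group).sum(axis=1)
    testable = (n1 >= min_per_group) & (n0 >= min_per_group)

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN group slices
        m1 = np.nanmean(np.where(group, x, np.nan), axis=1)
        m0 = np.nanmean(np.where(~group, x, np.nan), axis=1)
        v1 = _nanvar_sum(x, group)
        v0 = _nanvar_sum(x, ~group)
    delta = m1 - m0
    df_resid = n1 + n0 - 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = (v1 + v0) / df_resid
        scale = np.sqrt(1.0 / n1 + 1.0 / n0)

    out = pd.DataFrame(index=logits.index)
    out["delta_logit"] = np.where(testable, delta, np.nan)
    out["n_nec"] = n1
    out["n_ctrl"] = n0
    out["s2"] = np.where(testable, s2, np.nan)
    out["df_resid"] = np.where(testable, df_resid, np.nan)

    if testable.sum() < 2 and df_prior is None:
        # not enough regions to learn a prior: ordinary t-test fallback
        warnings.warn("fewer than 2 testable regions; falling back to ordinary t")
        df_prior, s2_prior = 0.0, 1.0
    res = moderated_t(
        delta[testable],
        s2[testable],
        df_resid[testable],
        scale[testable],
        df_prior=df_prior,
        s2_prior=s2_prior,
    )
    for col in ("t", "df_total", "p_value"):
        full = np.full(len(out), np.nan)
        full[testable] = res[col]
        out[col] = full
    out.attrs["df_prior"] = res["df_prior"]
    out.attrs["s2_prior"] = (
        float(np.mean(res["s2_prior"])) if np.ndim(res["s2_prior"]) else float(res["s2_prior"])
    )
    return out


def _nanvar_sum(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Sum of squared deviations from the group mean, ignoring NaN."""
    xg = np.where(mask, x, np.nan)
    m = np.nanmean(xg, axis=1, keepdims=True)
    return np.nansum((xg - m) ** 2, axis=1)


@dataclass
class RegionDMResults:
    frame: pd.DataFrame
    df_prior: float
    s2_prior: float
    eps: float

    def call_dmrs(self, **kwargs) -> pd.DataFrame:
        return call_dmrs(self.frame, **kwargs)

    def summary(self) -> str:
        tested = self.frame["p_value"].notna().sum()
        return "\n".join(
            [
                "Region differential methylation (moderated t on logit rates)",
                f"  regions: {len(self.frame)}  tested: {tested}",
                f"  prior df (d0): {self.df_prior:.3g}  prior variance (s0^2): "
                f"{self.s2_prior:.3g}",
                f"  DMRs at defaults: {len(call_dmrs(self.frame))}",
            ]
        )


class RegionDifferentialMethylation:
    """Model: promoter or gene-body methylation differences, NEC vs non-NEC."""

    def __init__(self, region_meth: RegionMethylation, eps: float = DEFAULT_EPS):
        self.region_meth = region_meth
        self.eps = eps
        self.group = (region_meth.samples["condition"] == "NEC").to_numpy()
        if self.group.all() or not self.group.any():
            raise ValueError("need both NEC and non-NEC samples")

    def fit(self, min_per_group: int = 2, alpha: float = 0.05) -> RegionDMResults:
        rm = self.region_meth
        logits = pd.DataFrame(
            logit_transform(rm.rates.to_numpy(), self.eps),
            index=rm.rates.index,
            columns=rm.rates.columns,
        )
        res = eb_moderated_test(logits, self.group, min_per_group)
        rates = rm.rates.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_nec = np.nanmean(np.where(self.group, rates, np.nan), axis=1)
            mean_ctrl = np.nanmean(np.where(~self.group, rates, np.nan), axis=1)
        res.insert(0, "delta_rate", mean_nec - mean_ctrl)
        res["mean_rate_nec"] = mean_nec
        res["mean_rate_ctrl"] = mean_ctrl
        res["n_informative_min"] = rm.n_informative.min(axis=1).to_numpy()
        bh = adjust_pvalues(res["p_value"], alpha=alpha)
        res["q_value"] = bh.q_values
        res.index.name = "region_id"
        return RegionDMResults(
            res.reset_index(), res.attrs["df_prior"], res.attrs["s2_prior"], self.eps
        )


def call_dmrs(
    results: pd.DataFrame,
    min_delta: float = 0.1,
    min_informative: int = 4,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """DMRs: |delta_rate| >= min_delta (inclusive), every sample with at least
    ``min_informative`` informative CpGs, p <= p_threshold."""
    keep = (
        (results["delta_rate"].abs() >= min_delta)
        & (results["n_informative_min"] >= min_informative)
        & (results["p_value"] <= p_threshold)
    )
    return results[keep.fillna(False)].sort_values("p_value", kind="mergesort")


def shared_dmrs(dmrs_a: pd.DataFrame, dmrs_b: pd.DataFrame) -> pd.DataFrame:
    """Regions called in both tissues (inner join on region_id)."""
    return dmrs_a.merge(dmrs_b, on="region_id", suffixes=("_colon", "_ileum"))
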