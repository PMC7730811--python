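"""Methylation–expression integration.

Per gene, the Pearson correlation between per-sample promoter (or gene
body) methylation rate and log2 median-of-ratios-normalised expression,
with a Student t test (n−2 df) and BH adjustment; the multi-criterion
gene selection (methylation p <= 0.05, |delta logit| >= 1, adjusted
correlation p <= 0.1, with a stricter nested 0.05 tier); directionality
2x2 summaries (hyper/hypo methylation vs up/down expression); and the
cross-tissue correlation of per-gene correlation coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .expression import DEFAULT_PSEUDOCOUNT, median_of_ratios
from .multitest import adjust_pvalues
from .regions import RegionMethylation

__all__ = [
    "gene_correlation",
    "MethylationExpressionIntegration",
    "IntegrationResults",
    "select_genes",
    "directionality_summary",
    "correlation_of_correlations",
    "correlation_density",
    "log2_normalized_expression",
]


def gene_correlation(methylation, expression) -> dict:
    """Pearson correlation of paired per-sample values with a t test.

    Pairs with a missing value on either side are dropped; fewer than 3
    complete pairs or zero variance make the correlation undefined
    (NaN, with a reason code).
    """
    x = np.asarray(methylation, dtype=float)
    y = np.asarray(expression, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return {"r": np.nan, "t": np.nan, "p": np.nan, "n": n, "reason": "fewer than 3 pairs"}
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"r": np.nan, "t": np.nan, "p": np.nan, "n": n, "reason": "zero variance"}
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return {"r": r, "t": np.inf * np.sign(r), "p": 0.0, "n": n, "reason": ""}
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2 * stats.t.sf(abs(t), n - 2)
    return {"r": r, "t": float(t), "p": float(p), "n": n, "reason": ""}


def log2_normalized_expression(
    expr: ExpressionMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """log2 of median-of-ratios-normalised counts (the integration scale)."""
    sf = median_of_ratios(expr.counts)
    return np.log2(expr.counts / sf + pseudocount)


@dataclass
class IntegrationResults:
    frame: pd.DataFrame
    region_type: str

    def selected(self, tier: float = 0.1) -> pd.DataFrame:
        col = "selected_tier_005" if tier <= 0.05 else "selected_tier_01"
        return self.frame[self.frame[col]]

    def summary(self) -> str:
        f = self.frame
        return "\n".join(
            [
                f"Methylation-expression integration ({self.region_type})",
                f"  genes with defined correlation: {f['r'].notna().sum()} / {len(f)}",
                f"  mean r: {f['r'].mean():.3f}",
                f"  selected (tier 0.1): {int(f['selected_tier_01'].sum())}; "
                f"tier 0.05: {int(f['selected_tier_005'].sum())}",
            ]
        )


class MethylationExpressionIntegration:
    """Model: per-gene association of region methylation with expression.

    Parameters
    ----------
    region_meth : RegionMethylation
        Promoter or gene-body per-sample mean rates (region ids of the
        form ``<gene_id>:<region_type>``).
    expr : ExpressionMatrix
        Counts for the same samples.
    region_results : pd.DataFrame
        Output frame of :class:`~necmethylome.regions.RegionDifferentialMethylation`
        (provides p_value, delta_logit, delta_rate per region).
    de_results : pd.DataFrame, optional
        DE frame; if given, expression direction is joined in.
    """

    def __init__(
        self,
        region_meth: RegionMethylation,
        expr: ExpressionMatrix,
        region_results: pd.DataFrame,
        de_results: pd.DataFrame | None = None,
        region_type: str = "promoter",
    ):
        if list(region_meth.rates.columns) != list(expr.counts.columns):
            raise ValueError("methylation and expression sample sets differ")
        self.region_meth = region_meth
        self.expr = expr
        self.region_results = region_results
        self.de_results = de_results
        self.region_type = region_type

    def fit(
        self,
        p_meth: float = 0.05,
        min_delta_logit: float = 1.0,
        p_corr_adj: float = 0.1,
        p_corr_adj_strict: float = 0.05,
    ) -> IntegrationResults:
        logex = log2_normalized_expression(self.expr)
        meth = self.region_meth.rates
        gene_of_region = meth.index.str.split(":").str[0]
        rows = []
        for region_id, gene_id in zip(meth.index, gene_of_region):
            if gene_id not in logex.index:
                continue
            res = gene_correlation(meth.loc[region_id], logex.loc[gene_id])
            rows.append({"region_id": region_id, "gene_id": gene_id, **res})
        frame = pd.DataFrame(rows).rename(columns={"p": "p_corr", "t": "t_stat"})
        bh = adjust_pvalues(frame["p_corr"], alpha=p_corr_adj)
        frame["p_corr_adj"] = bh.q_values

        reg = self.region_results.set_index("region_id")
        frame = frame.join(
            reg[["p_value", "delta_logit", "delta_rate"]].rename(
                columns={"p_value": "p_meth"}
            ),
            on="region_id",
        )
        frame["meth_direction"] = np.where(frame["delta_rate"] > 0, "hyper", "hypo")
        sel = select_genes(frame, p_meth, min_delta_logit, p_corr_adj, p_corr_adj_strict)
        frame["selected_tier_01"] = sel["tier_01"]
        frame["selected_tier_005"] = sel["tier_005"]
        if self.de_results is not None:
            de = self.de_results.set_index("gene_id")
            frame = frame.join(de[["lfc", "p_value", "direction"]].rename(
                columns={"p_value": "p_de", "direction": "expr_direction"}
            ), on="gene_id")
        return IntegrationResults(frame.reset_index(drop=True), self.region_type)


def select_genes(
    records: pd.DataFrame,
    p_meth: float = 0.05,
    min_delta_logit: float = 1.0,
    p_corr_adj: float = 0.1,
    p_corr_adj_strict: float = 0.05,
) -> pd.DataFrame:
    """Conjunctive selection criteria, as two nested tiers.

    Tier 0.1: methylation p <= ``p_meth`` AND |delta logit| >=
    ``min_delta_logit`` AND adjusted correlation p <= ``p_corr_adj``.
    Tier 0.05 additionally tightens the adjusted p to
    ``p_corr_adj_strict``; it is a subset of tier 0.1 by construction.
    """
    base = (
        (records["p_meth"] <= p_meth)
        & (records["delta_logit"].abs() >= min_delta_logit)
        & (records["p_corr_adj"] <= p_corr_adj)
    ).fillna(False)
    strict = base & (records["p_corr_adj"] <= p_corr_adj_strict).fillna(False)
    return pd.DataFrame({"tier_01": base, "tier_005": strict}, index=records.index)


def directionality_summary(joined: pd.DataFrame) -> pd.DataFrame:
    """2x2 counts of methylation direction vs expression direction.

    ``joined`` needs meth_direction (hyper/hypo) and expr_direction
    (up/down) columns.  Returns one row per expression direction with
    the count, its fraction of the join, and the hyper/hypo split with
    row fractions.
    """
    if len(joined) == 0:
        return pd.DataFrame(
            columns=["expr_direction", "n", "frac_of_total", "n_hyper", "n_hypo",
                     "frac_hyper", "frac_hypo"]
        )
    total = len(joined)
    rows = []
    for direction in ("down", "up"):
        sub = joined[joined["expr_direction"] == direction]
        n = len(sub)
        n_hyper = int((sub["meth_direction"] == "hyper").sum())
        rows.append(
            {
                "expr_direction": direction,
                "n": n,
                "frac_of_total": n / total,
                "n_hyper": n_hyper,
                "n_hypo": n - n_hyper,
                "frac_hyper": n_hyper / n if n else float("nan"),
                "frac_hypo": (n - n_hyper) / n if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def correlation_of_correlations(
    records_a: pd.DataFrame, records_b: pd.DataFrame
) -> dict:
    """Pearson correlation between the two tissues' per-gene r values."""
    a = records_a.dropna(subset=["r"]).set_index("gene_id")["r"]
    b = records_b.dropna(subset=["r"]).set_index("gene_id")["r"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes with defined correlations")
    res = gene_correlation(a.loc[shared].to_numpy(), b.loc[shared].to_numpy())
    return {"r_cc": res["r"], "t": res["t"], "p": res["p"], "n_genes": len(shared)}


def correlation_density(
    records: pd.DataFrame, delta_threshold: float = 0.2, n_bins: int = 40
) -> dict:
    """Density of per-gene r, stratified by |delta rate| above/below threshold.

    Returns per-stratum histograms over [-1, 1] (integrating to 1) and
    mean r; an empty stratum is omitted with a note.
    """
    out: dict = {"delta_threshold": delta_threshold, "strata": {}, "notes": []}
    rec = records.dropna(subset=["r", "delta_rate"])
    strata = {
        "high_delta": rec[rec["delta_rate"].abs() > delta_threshold],
        "low_delta": rec[rec["delta_rate"].abs() <= delta_threshold],
    }
    for name, sub in strata.items():
        if len(sub) == 0:
            out["notes"].append(f"stratum {name} empty; density omitted")
            continue
        density, edges = np.histogram(
            sub["r"], bins=n_bins, range=(-1.0, 1.0), density=True
        )
        out["strata"][name] = {
            "edges": edges,
            "density": density,
            "mean_r": float(sub["r"].mean()),
            "n_genes": len(sub),
        }
    return out
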