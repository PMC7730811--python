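"""RNA count normalisation, filtering and differential expression.

Counts are normalised to counts per million (CPM) for filtering and the
moderated-t DE test, and by the median-of-ratios method (per-sample
size factors from median count-to-geometric-mean ratios) for the
methylation–expression integration.  The DE test is a two-group linear
model on log2(CPM + pseudocount) with empirical-Bayes variance
moderation and a lowess mean–variance trend; genes are called at
p <= 0.05 with mean log2 abundance (LS mean) > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .ebayes import moderated_t
from .multitest import adjust_pvalues

__all__ = [
    "cpm_normalize",
    "median_of_ratios",
    "filter_genes",
    "DifferentialExpression",
    "DEResults",
    "de_summary",
    "DEFAULT_PSEUDOCOUNT",
]

DEFAULT_PSEUDOCOUNT = 0.5


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million: counts / library size * 1e6, per sample."""
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for samples: {list(zero.index)}")
    return counts / lib * 1e6


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Per-sample size factors: median ratio to the per-gene geometric mean.

    Reference genes are those with a positive geometric mean (no zero
    count in any sample).
    """
    x = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        loggeo = np.log(x).mean(axis=1)
    ref = np.isfinite(loggeo)
    if not ref.any():
        raise ValueError("no gene with nonzero counts in all samples")
    ratios = x[ref] / np.exp(loggeo[ref, None])
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


def filter_genes(
    normalized: pd.DataFrame,
    groups: np.ndarray | None = None,
    mode: str = "per_group",
) -> pd.DataFrame:
    """Abundance filter on normalised counts.

    A gene is dropped when its total normalised count is < 10, or when
    its average normalised count is below 1 — per group in the default
    ``per_group`` reading (every group mean < 1), or across all samples
    with ``mode='overall'``.  Returns a frame with the per-rule flags
    and the combined ``retained`` column.
    """
    total = normalized.sum(axis=1)
    low_total = total < 10
    if mode == "per_group":
        if groups is None:
            raise ValueError("per_group filtering needs group labels")
        g = np.asarray(groups, dtype=bool)
        mean1 = normalized.iloc[:, np.flatnonzero(g)].mean(axis=1)
        mean0 = normalized.iloc[:, np.flatnonzero(~g)].mean(axis=1)
        low_mean = (mean1 < 1) & (mean0 < 1)
    elif mode == "overall":
        low_mean = normalized.mean(axis=1) < 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(
        {
            "total_normalized": total,
            "low_total": low_total,
            "low_mean": low_mean,
            "retained": ~(low_total | low_mean),
        }
    )


@dataclass
class DEResults:
    """Differential-expression results (moderated t with mean–variance trend)."""

    frame: pd.DataFrame
    n_filtered: int
    n_degenerate: int
    df_prior: float

    def significant(self, p_threshold: float = 0.05, ls_mean_threshold: float = 1.0):
        f = self.frame
        return f[(f["p_value"] <= p_threshold) & (f["ls_mean"] > ls_mean_threshold)]

    def summary(self) -> str:
        sig = self.significant()
        up = (sig["direction"] == "up").sum()
        return "\n".join(
            [
                "Differential expression (moderated t, lowess trend)",
                f"  genes tested: {len(self.frame)}  filtered: {self.n_filtered}  "
                f"degenerate: {self.n_degenerate}",
                f"  prior df: {self.df_prior:.3g}",
                f"  significant (p <= 0.05, LS mean > 1): {len(sig)} "
                f"({up} up, {len(sig) - up} down in NEC)",
            ]
        )


class DifferentialExpression:
    """Model: per-gene NEC vs non-NEC expression differences within a tissue."""

    def __init__(
        self,
        expr: ExpressionMatrix,
        tissue: str | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        filter_mode: str = "per_group",
    ):
        if tissue is not None:
            expr = expr.subset_tissue(tissue)
        self.expr = expr
        self.pseudocount = pseudocount
        self.filter_mode = filter_mode
        self.group = expr.condition_mask("NEC")
        if self.group.all() or not self.group.any():
            raise ValueError("need both NEC and non-NEC samples")
        if min(self.group.sum(), (~self.group).sum()) < 2:
            raise ValueError("need >= 2 samples per group")

    def fit(self, trend: bool = True, alpha: float = 0.05) -> DEResults:
        cpm = cpm_normalize(self.expr.counts)
        flt = filter_genes(cpm, self.group, mode=self.filter_mode)
        kept = cpm[flt["retained"]]
        y = np.log2(kept.to_numpy() + self.pseudocount)
        g = self.group
        n1, n0 = int(g.sum()), int((~g).sum())

        m1 = y[:, g].mean(axis=1)
        m0 = y[:, ~g].mean(axis=1)
        lfc = m1 - m0
        ls_mean = y.mean(axis=1)
        ss = ((y[:, g] - m1[:, None]) ** 2).sum(axis=1) + (
            (y[:, ~g] - m0[:, None]) ** 2
        ).sum(axis=1)
        df_resid = n1 + n0 - 2
        s2 = ss / df_resid

        res = moderated_t(
            lfc,
            s2,
            float(df_resid),
            np.sqrt(1 / n1 + 1 / n0),
            covariate=ls_mean if trend else None,
        )
        # a gene is degenerate only if its statistic is undefined even
        # after moderation (zero posterior variance)
        degenerate = ~np.isfinite(res["t"])
        frame = pd.DataFrame(
            {
                "gene_id": kept.index[~degenerate],
                "lfc": lfc[~degenerate],
                "ls_mean": ls_mean[~degenerate],
                "t": res["t"][~degenerate],
                "df_total": res["df_total"][~degenerate],
                "p_value": res["p_value"][~degenerate],
            }
        )
        bh = adjust_pvalues(frame["p_value"], alpha=alpha)
        frame["q_value"] = bh.q_values
        frame["direction"] = np.where(frame["lfc"] > 0, "up", "down")
        return DEResults(
            frame=frame.reset_index(drop=True),
            n_filtered=int((~flt["retained"]).sum()),
            n_degenerate=int(degenerate.sum()),
            df_prior=res["df_prior"],
        )


def de_summary(
    de: pd.DataFrame | DEResults,
    p_threshold: float = 0.05,
    ls_mean_threshold: float = 1.0,
) -> dict:
    """Counts and fractions of up/down-regulated significant genes.

    With zero significant genes the fractions are reported undefined
    (NaN) rather than raising.
    """
    if isinstance(de, DEResults):
        sig = de.significant(p_threshold, ls_mean_threshold)
    else:
        sig = de
        if "p_value" in sig.columns:
            sig = sig[(sig["p_value"] <= p_threshold)]
            if "ls_mean" in sig.columns:
                sig = sig[sig["ls_mean"] > ls_mean_threshold]
    n_up = int((sig["direction"] == "up").sum())
    n_down = int((sig["direction"] == "down").sum())
    total = n_up + n_down
    return {
        "n_up": n_up,
        "n_down": n_down,
        "n_total": total,
        "frac_up": n_up / total if total else float("nan"),
        "frac_down": n_down / total if total else float("nan"),
    }
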