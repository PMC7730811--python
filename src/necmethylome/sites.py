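"""Per-CpG differential methylation: overdispersion-corrected logistic regression.

For each CpG site, methylation proportion is regressed on condition
(NEC vs non-NEC) in a binomial logistic model weighted by coverage.
With only a two-level factor the fit has a closed form: the fitted
proportions are the coverage-weighted pooled rates of each group, and
the group coefficient is their logit difference.  Overdispersion is
handled in the McCullagh–Nelder quasi-binomial fashion: the Pearson
statistic over samples divided by its residual degrees of freedom,
floored at 1, scales the squared Wald statistic, which is referred to a
chi-square(1) distribution.

Sign convention: positive ``meth_diff`` (percentage points) means higher
methylation in NEC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MethylationTable
from .multitest import BHResult, adjust_pvalues

__all__ = [
    "SiteDifferentialMethylation",
    "SiteDMResults",
    "site_test",
    "call_dms",
]

STATUS_OK = "ok"
STATUS_LOW_COVERAGE = "low_coverage"  # fewer than min_samples covered in a group
STATUS_DEGENERATE = "degenerate"  # pooled rate 0 or 1 even after repair


def _core_test(
    meth: np.ndarray,
    coverage: np.ndarray,
    group: np.ndarray,
    min_samples_per_group: int = 2,
    reference: str = "chisq",
) -> dict[str, np.ndarray]:
    """Vectorised quasi-binomial two-group test over all sites at once.

    ``group`` is boolean (True = NEC).  Degenerate sites (a pooled group
    rate of exactly 0 or 1, which makes the logit fit diverge) are
    repaired by adding 0.5 to both counts of each offending sample at
    that site only; this is the only place pseudocounts are used.
    """
    meth = np.asarray(meth, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    if meth.ndim == 1:
        meth = meth[None, :]
        coverage = coverage[None, :]
    group = np.asarray(group, dtype=bool)
    n_sites = meth.shape[0]

    covered = coverage > 0
    n_used = covered.sum(axis=1)
    n1 = (covered & group).sum(axis=1)
    n0 = (covered & ~group).sum(axis=1)
    testable = (n1 >= min_samples_per_group) & (n0 >= min_samples_per_group)

    def pooled(meth, coverage):
        M1 = (meth * group).sum(axis=1)
        C1 = (coverage * group).sum(axis=1)
        M0 = (meth * ~group).sum(axis=1)
        C0 = (coverage * ~group).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return M1 / C1, M0 / C0, C1, C0

    p1, p0, C1, C0 = pooled(meth, coverage)
    meth_diff = 100.0 * (p1 - p0)

    degenerate = testable & ((p1 == 0) | (p1 == 1) | (p0 == 0) | (p0 == 1))
    n_repaired = int(degenerate.sum())
    if n_repaired:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(covered, meth / coverage, np.nan)
        fix = degenerate[:, None] & covered & ((r == 0) | (r == 1))
        meth = meth + 0.5 * fix
        coverage = coverage + 1.0 * fix
        p1f, p0f, C1, C0 = pooled(meth, coverage)
    else:
        p1f, p0f = p1, p0

    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.log(p1f / (1 - p1f)) - np.log(p0f / (1 - p0f))
        var_beta = 1.0 / (C1 * p1f * (1 - p1f)) + 1.0 / (C0 * p0f * (1 - p0f))
        fitted = np.where(group[None, :], p1f[:, None], p0f[:, None])
        resid = np.where(covered, meth / np.where(covered, coverage, 1) - fitted, 0.0)
        pearson = (coverage * resid**2 / (fitted * (1 - fitted)))
        pearson = np.where(covered, pearson, 0.0).sum(axis=1)
        df_resid = np.maximum(n_used - 2, 1)
        phi = np.maximum(1.0, pearson / df_resid)
        wald = beta**2 / var_beta / phi

    with np.errstate(invalid="ignore"):
        if reference == "chisq":
            p_value = stats.chi2.sf(wald, 1)
        elif reference == "f":
            p_value = stats.f.sf(wald, 1, df_resid)
        else:
            raise ValueError(f"unknown reference {reference!r}")

    status = np.full(n_sites, STATUS_OK, dtype=object)
    status[~testable] = STATUS_LOW_COVERAGE
    still_bad = testable & ~np.isfinite(wald)
    status[still_bad] = STATUS_DEGENERATE
    p_value = np.where(status == STATUS_OK, p_value, np.nan)

    return {
        "p_value": p_value,
        "meth_diff": np.where(testable, meth_diff, np.nan),
        "rate_nec": p1,
        "rate_ctrl": p0,
        "n_samples_used": n_used,
        "dispersion": np.where(testable, phi, np.nan),
        "status": status,
        "n_repaired": n_repaired,
    }


def site_test(
    meth_counts,
    unmeth_counts,
    group_labels,
    min_samples_per_group: int = 2,
    reference: str = "chisq",
) -> dict:
    """Quasi-binomial test of one CpG site.

    ``meth_counts`` / ``unmeth_counts`` are per-sample counts;
    ``group_labels`` is boolean or {"NEC", "non-NEC"} per sample.
    Returns a dict with p_value, meth_diff (NEC − non-NEC, percentage
    points), per-group pooled rates, the dispersion estimate and a
    status code.
    """
    meth = np.asarray(meth_counts, dtype=float)
    unmeth = np.asarray(unmeth_counts, dtype=float)
    group = np.asarray(group_labels)
    if group.dtype.kind in "USO":
        group = group == "NEC"
    res = _core_test(meth, meth + unmeth, group, min_samples_per_group, reference)
    return {k: (v[0] if isinstance(v, np.ndarray) else v) for k, v in res.items()}


@dataclass
class SiteDMResults:
    """Per-site test results with BH-adjusted q-values."""

    frame: pd.DataFrame
    bh: BHResult
    n_repaired: int
    reference: str

    @property
    def realized_p_threshold(self) -> float:
        """Largest raw p still called at the BH alpha (the p↔q mapping)."""
        return self.bh.realized_p_threshold

    def call_dms(
        self,
        q_threshold: float = 0.05,
        min_diff: float = 0.0,
        annotation: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        return call_dms(self.frame, q_threshold, min_diff, annotation)

    def summary(self) -> str:
        tested = (self.frame["status"] == STATUS_OK).sum()
        called = ((self.frame["q_value"] < 0.05)).sum()
        lines = [
            "Site differential methylation (quasi-binomial logistic regression)",
            f"  sites: {len(self.frame)}  tested: {tested}  "
            f"untested: {len(self.frame) - tested}",
            f"  separation-repaired sites: {self.n_repaired}",
            f"  DMSs at q < 0.05: {called}",
            f"  realized p threshold at q <= {self.bh.alpha}: "
            f"{self.bh.realized_p_threshold:.3g}",
        ]
        return "\n".join(lines)


class SiteDifferentialMethylation:
    """Model: per-CpG NEC vs non-NEC methylation differences within a tissue.

    Parameters
    ----------
    table : MethylationTable
        Counts and sample metadata.  If ``tissue`` is given the table is
        restricted to that tissue first.
    """

    def __init__(self, table: MethylationTable, tissue: str | None = None):
        if tissue is not None:
            table = table.subset_tissue(tissue)
        if table.n_samples == 0:
            raise ValueError("no samples selected")
        self.table = table
        self.group = table.condition_mask("NEC")
        if self.group.all() or not self.group.any():
            raise ValueError("need both NEC and non-NEC samples")

    def fit(
        self,
        min_samples_per_group: int = 2,
        reference: str = "chisq",
        alpha: float = 0.05,
    ) -> SiteDMResults:
        res = _core_test(
            self.table.meth, self.table.coverage, self.group,
            min_samples_per_group, reference,
        )
        frame = pd.DataFrame(
            {
                "chrom": self.table.sites["chrom"],
                "pos": self.table.sites["pos"],
                "p_value": res["p_value"],
                "meth_diff": res["meth_diff"],
                "rate_nec": res["rate_nec"],
                "rate_ctrl": res["rate_ctrl"],
                "n_samples_used": res["n_samples_used"],
                "dispersion": res["dispersion"],
                "status": res["status"],
            }
        )
        bh = adjust_pvalues(frame["p_value"], alpha=alpha)
        frame["q_value"] = bh.q_values
        return SiteDMResults(frame, bh, res["n_repaired"], reference)


def call_dms(
    results: pd.DataFrame,
    q_threshold: float = 0.05,
    min_diff: float = 0.0,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Filter tested sites to DMSs: q < q_threshold and |meth_diff| >= min_diff.

    Sorted by (q, p).  If a site annotation is given (from
    :func:`necmethylome.annotate.annotate_sites`) its nearest-feature and
    membership columns are joined in, yielding the standard DMS report
    layout (chrom, start, end, p, q, meth.diff, feature, distance,
    membership flags).
    """
    if len(results) == 0:
        return results.copy()
    out = results[
        (results["q_value"] < q_threshold)
        & (results["meth_diff"].abs() >= min_diff)
    ].sort_values(["q_value", "p_value"], kind="mergesort")
    out = out.copy()
    out.insert(2, "start", out["pos"])
    out.insert(3, "end", out["pos"])
    if annotation is not None:
        keep = [
            c
            for c in (
                "nearest_feature_id", "dist_to_feature", "feature_strand",
                "promoter", "exon", "intron", "cgi", "shore", "enhancer",
            )
            if c in annotation.columns
        ]
        ann = annotation.set_index(["chrom", "pos"])[keep]
        out = out.join(ann, on=["chrom", "pos"])
    return out.drop(columns=["pos"])
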