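"""In-memory containers for methylation counts and expression counts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MethylationTable", "ExpressionMatrix"]

CONDITIONS = ("non-NEC", "NEC")


def _check_samples(samples: pd.DataFrame, n: int) -> pd.DataFrame:
    samples = samples.reset_index(drop=True)
    required = {"sample_id", "tissue", "condition"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if len(samples) != n:
        raise ValueError(f"sample sheet has {len(samples)} rows, data has {n} samples")
    bad = set(samples["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown conditions {sorted(bad)}; expected {CONDITIONS}")
    return samples


@dataclass
class MethylationTable:
    """Per-CpG methylated/total read counts for a set of samples.

    ``meth`` and ``coverage`` are (n_sites, n_samples) integer arrays;
    ``sites`` has columns chrom and pos (1-based, sorted); ``samples``
    carries sample_id, tissue and condition (NEC / non-NEC).
    """

    sites: pd.DataFrame
    meth: np.ndarray
    coverage: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.meth = np.asarray(self.meth)
        self.coverage = np.asarray(self.coverage)
        if self.meth.shape != self.coverage.shape:
            raise ValueError("meth and coverage shapes differ")
        if (self.meth < 0).any() or (self.coverage < 0).any():
            raise ValueError("negative counts")
        if (self.meth > self.coverage).any():
            raise ValueError("methylated count exceeds coverage")
        self.sites = self.sites.reset_index(drop=True)
        self.samples = _check_samples(self.samples, self.meth.shape[1])

    @property
    def n_sites(self) -> int:
        return self.meth.shape[0]

    @property
    def n_samples(self) -> int:
        return self.meth.shape[1]

    def rates(self) -> np.ndarray:
        """Per-site per-sample methylation rate; NaN where coverage is 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.coverage > 0, self.meth / self.coverage, np.nan)

    def condition_mask(self, condition: str) -> np.ndarray:
        return (self.samples["condition"] == condition).to_numpy()

    def pooled_rate(self, condition: str) -> np.ndarray:
        """Coverage-weighted pooled rate per site for one condition."""
        mask = self.condition_mask(condition)
        m = self.meth[:, mask].sum(axis=1)
        c = self.coverage[:, mask].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(c > 0, m / c, np.nan)

    def subset_tissue(self, tissue: str) -> "MethylationTable":
        mask = (self.samples["tissue"] == tissue).to_numpy()
        return MethylationTable(
            self.sites, self.meth[:, mask], self.coverage[:, mask], self.samples[mask]
        )


@dataclass
class ExpressionMatrix:
    """Gene-by-sample integer RNA counts plus the sample sheet."""

    counts: pd.DataFrame  # index gene_id, columns sample_id
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.samples = _check_samples(self.samples, self.counts.shape[1])
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise ValueError("count columns do not match sample sheet order")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def condition_mask(self, condition: str) -> np.ndarray:
        return (self.samples["condition"] == condition).to_numpy()

    def subset_tissue(self, tissue: str) -> "ExpressionMatrix":
        mask = (self.samples["tissue"] == tissue).to_numpy()
        return ExpressionMatrix(self.counts.iloc[:, mask], self.samples[mask])
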