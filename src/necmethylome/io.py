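"""Reading and writing the pipeline's on-disk formats.

Methylation counts use the Bismark coverage layout, one TSV per sample:
chrom, start, end, methylation percentage, count methylated, count
unmethylated (1-based, start == end for a single CpG).  Expression is a
gene-by-sample count TSV; the sample sheet is a CSV with sample_id,
tissue and condition columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, MethylationTable

__all__ = [
    "read_bismark_coverage",
    "write_bismark_coverage",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_counts",
    "write_counts",
]

_COV_COLS = ["chrom", "start", "end", "meth_pct", "count_methylated", "count_unmethylated"]


def write_bismark_coverage(table: MethylationTable, directory) -> list[Path]:
    """One ``<sample_id>.cov`` file per sample; sites with zero coverage are omitted."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    rates = table.rates()
    for j, sample_id in enumerate(table.samples["sample_id"]):
        cov = table.coverage[:, j]
        keep = cov > 0
        df = pd.DataFrame(
            {
                "chrom": table.sites["chrom"][keep],
                "start": table.sites["pos"][keep],
                "end": table.sites["pos"][keep],
                "meth_pct": np.round(100 * rates[keep, j], 6),
                "count_methylated": table.meth[keep, j],
                "count_unmethylated": cov[keep] - table.meth[keep, j],
            }
        )
        path = directory / f"{sample_id}.cov"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


def read_bismark_coverage(paths, samples: pd.DataFrame) -> MethylationTable:
    """Assemble per-sample coverage files into one table on the union of sites.

    ``paths`` pairs positionally with the rows of ``samples``.  Sites a
    sample does not report get coverage 0 for that sample.
    """
    paths = [Path(p) for p in paths]
    if len(paths) != len(samples):
        raise ValueError("number of files does not match sample sheet")
    per_sample = []
    for path in paths:
        df = pd.read_csv(path, sep="\t", header=None, names=_COV_COLS)
        per_sample.append(df)
    all_sites = (
        pd.concat([df[["chrom", "start"]] for df in per_sample])
        .drop_duplicates()
        .sort_values(["chrom", "start"])
        .reset_index(drop=True)
    )
    key = pd.MultiIndex.from_frame(all_sites)
    n = len(all_sites)
    meth = np.zeros((n, len(paths)), dtype=np.int64)
    cov = np.zeros_like(meth)
    for j, df in enumerate(per_sample):
        idx = key.get_indexer(pd.MultiIndex.from_frame(df[["chrom", "start"]]))
        meth[idx, j] = df["count_methylated"].to_numpy()
        cov[idx, j] = (df["count_methylated"] + df["count_unmethylated"]).to_numpy()
    sites = all_sites.rename(columns={"start": "pos"})
    return MethylationTable(sites, meth, cov, samples)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_counts(expr: ExpressionMatrix, path) -> None:
    expr.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_counts(path, samples: pd.DataFrame) -> ExpressionMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="gene_id")
    counts = counts[list(samples["sample_id"])]
    return ExpressionMatrix(counts, samples)
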