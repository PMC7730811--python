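"""Genomic element annotation of CpG sites.

Intervals are 1-based and fully closed throughout the package (a single
CpG has start == end).  BED files on disk are 0-based half-open; the
conversion happens only in :func:`read_bed` / :func:`write_bed`.

Element classes follow the stratification used for intestinal WGBS
profiling: promoter (TSS−1500..TSS+500, strand-aware), exon, intron,
CpG island (CGI), CGI shore (2 kb flanks), enhancer, and intergenic
(no promoter/exon/intron overlap).  A site may belong to several
classes at once (e.g. promoter ∧ CGI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnnotationSet",
    "ELEMENT_CLASSES",
    "build_promoters",
    "build_shores",
    "annotate_sites",
    "merge_intervals",
    "subtract_intervals",
    "read_bed",
    "write_bed",
    "read_gene_table",
    "write_gene_table",
]

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500
SHORE_WIDTH = 2000

ELEMENT_CLASSES = ("promoter", "exon", "intron", "cgi", "shore", "enhancer", "intergenic")

_INTERVAL_COLS = ["chrom", "start", "end", "strand", "feature_id"]


def _as_interval_frame(df: pd.DataFrame | None) -> pd.DataFrame:
    if df is None or len(df) == 0:
        return pd.DataFrame(columns=_INTERVAL_COLS)
    out = df.copy()
    if "strand" not in out:
        out["strand"] = "."
    if "feature_id" not in out:
        out["feature_id"] = [f"iv{i}" for i in range(len(out))]
    if (out["start"] > out["end"]).any():
        raise ValueError("interval with start > end")
    return out[_INTERVAL_COLS].reset_index(drop=True)


@dataclass
class AnnotationSet:
    """Strand-aware genomic intervals per element class, plus a gene table.

    ``elements`` maps class name -> DataFrame(chrom, start, end, strand,
    feature_id); ``genes`` has columns gene_id, chrom, tss, strand,
    gene_start, gene_end.
    """

    elements: dict[str, pd.DataFrame] = field(default_factory=dict)
    genes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "chrom", "tss", "strand", "gene_start", "gene_end"]
        )
    )

    def __post_init__(self) -> None:
        self.elements = {k: _as_interval_frame(v) for k, v in self.elements.items()}

    def get(self, element_class: str) -> pd.DataFrame:
        return self.elements.get(element_class, _as_interval_frame(None))

    @property
    def classes(self) -> list[str]:
        return list(self.elements)


def build_promoters(genes: pd.DataFrame) -> pd.DataFrame:
    """Promoter interval of each gene: TSS−1500..TSS+500 on the gene strand.

    On the − strand the window mirrors to TSS−500..TSS+1500.  Coordinates
    are clipped at 1, so every promoter spans at most 2001 bp.
    """
    if len(genes) == 0:
        return _as_interval_frame(None)
    strand = genes["strand"].astype(str)
    if (~strand.isin(["+", "-"])).any():
        bad = genes.loc[~strand.isin(["+", "-"]), "gene_id"].tolist()
        raise ValueError(f"promoter undefined for genes without strand: {bad[:5]}")
    tss = genes["tss"].to_numpy(dtype=np.int64)
    plus = (strand == "+").to_numpy()
    start = np.where(plus, tss - PROMOTER_UPSTREAM, tss - PROMOTER_DOWNSTREAM)
    end = np.where(plus, tss + PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM)
    return _as_interval_frame(
        pd.DataFrame(
            {
                "chrom": genes["chrom"].to_numpy(),
                "start": np.maximum(start, 1),
                "end": np.maximum(end, 1),
                "strand": strand.to_numpy(),
                "feature_id": genes["gene_id"].to_numpy(),
            }
        )
    )


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or bookended (adjacent) closed intervals per chromosome."""
    if len(df) == 0:
        return _as_interval_frame(None)
    rows = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + 1:  # closed coordinates: adjacent intervals merge
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return _as_interval_frame(out)


def subtract_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Bases of closed intervals ``a`` not covered by any interval of ``b``."""
    if len(a) == 0:
        return _as_interval_frame(None)
    if len(b) == 0:
        return merge_intervals(a)
    b_merged = merge_intervals(b)
    rows = []
    for _, iv in merge_intervals(a).iterrows():
        cuts = b_merged[b_merged["chrom"] == iv["chrom"]]
        pos = iv["start"]
        for s, e in zip(cuts["start"], cuts["end"]):
            if e < pos or s > iv["end"]:
                continue
            if s > pos:
                rows.append((iv["chrom"], pos, s - 1))
            pos = max(pos, e + 1)
            if pos > iv["end"]:
                break
        if pos <= iv["end"]:
            rows.append((iv["chrom"], pos, iv["end"]))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return _as_interval_frame(out)


def build_shores(cgis: pd.DataFrame, width: int = SHORE_WIDTH) -> pd.DataFrame:
    """2 kb flank regions of CpG islands.

    Flanks from adjacent islands are merged and any base lying inside a
    CGI is removed, so shores and islands never overlap.  Flanks are
    clipped at position 1.
    """
    if len(cgis) == 0:
        return _as_interval_frame(None)
    flanks = []
    for _, iv in cgis.iterrows():
        left_end = iv["start"] - 1
        if left_end >= 1:
            flanks.append((iv["chrom"], max(1, iv["start"] - width), left_end))
        flanks.append((iv["chrom"], iv["end"] + 1, iv["end"] + width))
    flank_df = pd.DataFrame(flanks, columns=["chrom", "start", "end"])
    return subtract_intervals(flank_df, cgis)


def _membership(chroms: np.ndarray, pos: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean membership of each (chrom, pos) in the merged interval set."""
    out = np.zeros(len(pos), dtype=bool)
    if len(intervals) == 0:
        return out
    merged = merge_intervals(intervals)
    for chrom, grp in merged.groupby("chrom"):
        mask = chroms == chrom
        if not mask.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        idx = np.searchsorted(starts, pos[mask], side="right") - 1
        hit = (idx >= 0) & (pos[mask] <= ends[np.clip(idx, 0, len(ends) - 1)])
        out[np.flatnonzero(mask)[hit]] = True
    return out


def _nearest_feature(
    chroms: np.ndarray, pos: np.ndarray, genes: pd.DataFrame, chunk: int = 2048
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nearest gene per site with signed strand-aware distance.

    Distance is 0 inside the gene body and negative upstream of the gene
    on the gene's strand.  Ties on |distance| break lexicographically on
    gene_id.  Sites on chromosomes with no genes get id '' and NaN.
    """
    n = len(pos)
    feature = np.full(n, "", dtype=object)
    dist = np.full(n, np.nan)
    strand_out = np.full(n, "", dtype=object)
    genes_sorted = genes.sort_values("gene_id")  # lexicographic tie-break via argmin on stable order
    for chrom, grp in genes_sorted.groupby("chrom"):
        mask = np.flatnonzero(chroms == chrom)
        if len(mask) == 0:
            continue
        gs = grp["gene_start"].to_numpy(dtype=np.int64)
        ge = grp["gene_end"].to_numpy(dtype=np.int64)
        gstrand = grp["strand"].to_numpy()
        gid = grp["gene_id"].to_numpy()
        minus = gstrand == "-"
        for lo in range(0, len(mask), chunk):
            sel = mask[lo : lo + chunk]
            p = pos[sel][:, None]
            # signed distance on + orientation: negative left of start, 0 inside
            d_plus = np.where(p < gs, p - gs, np.where(p > ge, p - ge, 0))
            d = np.where(minus[None, :], -d_plus, d_plus)
            order = np.argsort(np.abs(d), axis=1, kind="stable")[:, 0]
            feature[sel] = gid[order]
            dist[sel] = d[np.arange(len(sel)), order]
            strand_out[sel] = gstrand[order]
    return feature, dist, strand_out


def annotate_sites(sites: pd.DataFrame, annotation: AnnotationSet) -> pd.DataFrame:
    """Membership flags and nearest-gene distance for each CpG site.

    ``sites`` needs columns chrom and pos (sorted by chrom, pos).  Returns
    one row per site with boolean columns for each element class, the
    intergenic flag (true iff promoter, exon and intron are all false),
    nearest_feature_id, signed dist_to_feature and feature_strand.
    """
    chroms = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy(dtype=np.int64)
    out = pd.DataFrame(index=sites.index)
    if "cpg_id" in sites:
        out["cpg_id"] = sites["cpg_id"]
    out["chrom"] = chroms
    out["pos"] = pos
    for cls in ("promoter", "exon", "intron", "cgi", "shore", "enhancer"):
        out[cls] = _membership(chroms, pos, annotation.get(cls))
    out["intergenic"] = ~(out["promoter"] | out["exon"] | out["intron"])

    known = set(annotation.genes["chrom"].unique())
    orphan = ~np.isin(chroms, list(known)) if known else np.ones(len(pos), dtype=bool)
    if orphan.any() and known:
        logger.warning(
            "%d sites on chromosomes absent from the annotation; flagged intergenic",
            int(orphan.sum()),
        )
    feature, dist, fstrand = _nearest_feature(chroms, pos, annotation.genes)
    out["nearest_feature_id"] = feature
    out["dist_to_feature"] = dist
    out["feature_strand"] = fstrand
    return out


# ---------------------------------------------------------------------------
# I/O: BED6 (0-based half-open on disk) and gene tables

def read_bed(path) -> pd.DataFrame:
    """Read a BED6 file into internal 1-based closed intervals."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "feature_id", "score", "strand"],
        usecols=range(6),
    )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"] + 1,  # BED start is 0-based
            "end": df["end"],  # BED end is exclusive == closed end
            "strand": df["strand"].fillna("."),
            "feature_id": df["feature_id"],
        }
    )
    return _as_interval_frame(out)


def write_bed(df: pd.DataFrame, path) -> None:
    """Write internal 1-based closed intervals as BED6."""
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"] - 1,
            "end": df["end"],
            "name": df.get("feature_id", "."),
            "score": 0,
            "strand": df.get("strand", "."),
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_gene_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)
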