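"""Genome-wide methylome characterisation.

LM/IM/HM classification of pooled per-condition site rates, element-
stratified 2x3 contingency tables with Pearson chi-square, methylation
density profiles, per-chromosome spatial binning, and classical
(Torgerson) multidimensional scaling of samples.

Class boundaries: LM = [0, 0.20), IM = [0.20, 0.80], HM = (0.80, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import MethylationTable

__all__ = [
    "CLASS_LABELS",
    "classify_sites",
    "class_contingency_test",
    "methylation_class_table",
    "density_profile",
    "spatial_profile",
    "sample_mds",
]

CLASS_LABELS = ("LM", "IM", "HM")
COMPOSITE_CLASSES = {
    "CpG Island + CpG Shore": ("cgi", "shore"),
    "Exons + Introns": ("exon", "intron"),
}
SINGLE_CLASSES = {
    "Promoter": "promoter",
    "Exonic": "exon",
    "Intronic": "intron",
    "CpG Island": "cgi",
    "CpG Shore": "shore",
    "Enhancer": "enhancer",
    "Intergenic": "intergenic",
}


def classify_sites(rates) -> np.ndarray:
    """LM/IM/HM label per site from pooled rates; '' for NaN (unclassified)."""
    r = np.asarray(rates, dtype=float)
    labels = np.full(r.shape, "", dtype=object)
    labels[(r >= 0) & (r < 0.20)] = "LM"
    labels[(r >= 0.20) & (r <= 0.80)] = "IM"
    labels[(r > 0.80) & (r <= 1)] = "HM"
    return labels


def _class_counts(labels: np.ndarray) -> np.ndarray:
    return np.array([(labels == c).sum() for c in CLASS_LABELS], dtype=np.int64)


def class_contingency_test(counts_nec, counts_ctrl=None) -> dict:
    """Pearson chi-square on a 2x3 condition-by-class count table.

    Accepts either two LM/IM/HM count triples or two label arrays.
    Returns chi_square, df, p_value and per-condition percentages.  A
    zero row or column total makes the statistic undefined (NaN with a
    reason).
    """
    nec = np.asarray(counts_nec)
    ctrl = np.asarray(counts_ctrl)
    if nec.dtype.kind in "OSU":
        nec = _class_counts(nec)
        ctrl = _class_counts(ctrl)
    table = np.vstack([nec, ctrl]).astype(np.int64)
    out = {
        "counts_nec": table[0],
        "counts_ctrl": table[1],
        "pct_nec": 100 * table[0] / table[0].sum() if table[0].sum() else np.full(3, np.nan),
        "pct_ctrl": 100 * table[1] / table[1].sum() if table[1].sum() else np.full(3, np.nan),
    }
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        out.update(chi_square=np.nan, df=np.nan, p_value=np.nan,
                   reason="zero row or column total")
        return out
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    out.update(chi_square=float(chi2), df=int(df), p_value=float(p), reason="")
    return out


def methylation_class_table(
    table: MethylationTable, site_annotation: pd.DataFrame
) -> pd.DataFrame:
    """Element-stratified LM/IM/HM distribution with per-element chi-square.

    One row per element class (seven single classes, the two composite
    classes, and 'All'), comparing the pooled-rate classification of the
    NEC condition against non-NEC.
    """
    rate_nec = table.pooled_rate("NEC")
    rate_ctrl = table.pooled_rate("non-NEC")
    lab_nec = classify_sites(rate_nec)
    lab_ctrl = classify_sites(rate_ctrl)

    rows = []
    masks: dict[str, np.ndarray] = {}
    for name, col in SINGLE_CLASSES.items():
        masks[name] = site_annotation[col].to_numpy(dtype=bool)
    for name, cols in COMPOSITE_CLASSES.items():
        masks[name] = np.logical_or.reduce(
            [site_annotation[c].to_numpy(dtype=bool) for c in cols]
        )
    masks["All"] = np.ones(len(site_annotation), dtype=bool)

    for name, mask in masks.items():
        res = class_contingency_test(lab_nec[mask], lab_ctrl[mask])
        row = {"element_class": name}
        for i, cls in enumerate(CLASS_LABELS):
            row[f"n_{cls}_nec"] = res["counts_nec"][i]
            row[f"n_{cls}_ctrl"] = res["counts_ctrl"][i]
            row[f"pct_{cls}_nec"] = res["pct_nec"][i]
            row[f"pct_{cls}_ctrl"] = res["pct_ctrl"][i]
        row.update(chi_square=res["chi_square"], df=res["df"], p_value=res["p_value"])
        rows.append(row)
    return pd.DataFrame(rows)


def density_profile(rates, n_bins: int = 50) -> dict:
    """Normalised histogram of site rates over [0, 1].

    Returns bin edges and a density that integrates to 1.  NaN rates are
    dropped.
    """
    r = np.asarray(rates, dtype=float)
    r = r[~np.isnan(r)]
    if len(r) == 0:
        raise ValueError("no classified sites")
    density, edges = np.histogram(r, bins=n_bins, range=(0.0, 1.0), density=True)
    return {"edges": edges, "density": density, "n_sites": len(r)}


def spatial_profile(table: MethylationTable, bin_size: int) -> pd.DataFrame:
    """Coverage-weighted mean methylation per genomic bin per condition.

    Bins tile each chromosome; bins without sites are emitted with NaN
    means and n_sites = 0.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    pos = table.sites["pos"].to_numpy()
    chrom = table.sites["chrom"].to_numpy()
    rows = []
    for chrom_name in pd.unique(chrom):
        mask = chrom == chrom_name
        p = pos[mask]
        n_bins = int(p.max() // bin_size) + 1
        which = (p // bin_size).astype(int)
        for b in range(n_bins):
            sel = np.flatnonzero(mask)[which == b]
            row = {
                "chrom": chrom_name,
                "bin_start": b * bin_size + 1,
                "bin_end": (b + 1) * bin_size,
                "n_sites": len(sel),
            }
            for cond, key in (("NEC", "mean_rate_nec"), ("non-NEC", "mean_rate_ctrl")):
                cmask = table.condition_mask(cond)
                m = table.meth[np.ix_(sel, np.flatnonzero(cmask))].sum()
                c = table.coverage[np.ix_(sel, np.flatnonzero(cmask))].sum()
                row[key] = m / c if c > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def sample_mds(
    table: MethylationTable, min_cov: int = 5, n_components: int = 2
) -> pd.DataFrame:
    """Classical (Torgerson) MDS of samples on commonly covered site rates.

    Sites must have coverage >= ``min_cov`` in every sample.  Distances
    are Euclidean between per-sample rate vectors.  Coordinates are
    centred at the origin; orientation is fixed so the first sample's
    first coordinate is non-negative.
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples for MDS")
    common = (table.coverage >= min_cov).all(axis=1)
    if common.sum() < 3:
        raise ValueError(f"fewer than 3 sites covered >= {min_cov}x in all samples")
    r = (table.meth[common] / table.coverage[common]).T  # samples x sites
    d2 = ((r[:, None, :] - r[None, :, :]) ** 2).sum(axis=2)
    n = d2.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_components]
    lam = np.clip(vals[order], 0, None)
    coords = vecs[:, order] * np.sqrt(lam)[None, :]
    for k in range(coords.shape[1]):
        if coords[0, k] < 0:
            coords[:, k] = -coords[:, k]
    out = pd.DataFrame(
        coords, columns=[f"dim{k + 1}" for k in range(coords.shape[1])]
    )
    out.insert(0, "sample_id", table.samples["sample_id"].to_numpy())
    out["condition"] = table.samples["condition"].to_numpy()
    out["n_sites_used"] = int(common.sum())
    return out
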