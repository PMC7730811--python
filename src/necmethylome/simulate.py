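"""Synthetic WGBS + RNA-seq generator with known ground truth.

Emulates the data structure of an intestinal-epithelium methylome study
of surgical NEC: per-CpG methylated/unmethylated counts for two patient
groups, genomic element annotations, and paired bulk RNA counts.

Site methylation is a three-component beta mixture (LM/IM/HM: low,
intermediate, high).  Promoters and CpG islands are LM-enriched, as in
published element-stratified profiles of gut epithelium.  NEC
hypermethylation is modelled as a logit-scale shift of the site mean at
a seeded-shuffle subset of CpGs; per-sample rates add beta noise around
the site mean, read depth is negative binomial, and methylated counts
are binomial.  A subset of differentially expressed genes is coupled to
promoter hypermethylation with opposite sign, reproducing the
methylation–expression anti-correlation the analysis modules look for.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .annotate import (
    AnnotationSet,
    build_promoters,
    build_shores,
    subtract_intervals,
    write_bed,
    write_gene_table,
)
from .config import SimulationConfig
from .containers import ExpressionMatrix, MethylationTable
from .io import write_bismark_coverage, write_counts, write_sample_sheet

__all__ = [
    "TruthTable",
    "SimulatedDataset",
    "COMPONENT_BETAS",
    "ELEMENT_CLASS_WEIGHTS",
    "simulate_annotation",
    "simulate_methylation",
    "simulate_expression",
    "simulate_dataset",
    "write_dataset",
]

# LM/IM/HM component beta parameters.  Chosen so the genome-wide mixture
# lands near 2% LM with the remainder split between IM and HM, matching
# observed non-NEC gut epithelium profiles.
COMPONENT_BETAS = {
    "LM": (0.5, 8.0),
    "IM": (5.0, 5.0),
    "HM": (8.0, 0.5),
}
COMPONENTS = ("LM", "IM", "HM")

# Per-element LM/IM/HM component weights for control samples, from
# published non-NEC ileum element profiles (CGIs and promoters are
# LM-enriched; introns/intergenic follow the genome-wide weights).
ELEMENT_CLASS_WEIGHTS = {
    "cgi": (0.456, 0.208, 0.336),
    "shore": (0.160, 0.356, 0.484),
    "promoter": (0.214, 0.385, 0.401),
    "enhancer": (0.077, 0.503, 0.420),
    "exon": (0.047, 0.449, 0.504),
}
# priority when a site overlaps several element classes
_WEIGHT_PRIORITY = ("cgi", "shore", "promoter", "enhancer", "exon")

_MIN_GENE_GAP = 4000  # keeps neighbouring promoters disjoint and unclipped
_CHROM_MARGIN = 2000


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset.

    ``sites`` marks for every CpG its element class used for component
    weighting, the drawn LM/IM/HM component, the site mean methylation
    and whether the NEC shift was applied.  ``genes`` (filled by
    :func:`simulate_expression`) marks true-DE and coupled genes.
    ``promoter_rates`` / ``gene_body_rates`` are per-gene per-sample
    mean methylation rates realised in the simulated counts.
    """

    samples: pd.DataFrame
    sites: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None
    promoter_rates: pd.DataFrame | None = None
    gene_body_rates: pd.DataFrame | None = None
    promoter_shifted: pd.Series | None = None  # per gene: promoter holds a shifted CpG


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: AnnotationSet
    methylation: MethylationTable
    expression: ExpressionMatrix
    truth: TruthTable


def _chrom_bounds(config: SimulationConfig) -> list[tuple[str, int]]:
    """(name, length) per chromosome; genome split as evenly as possible."""
    base = config.genome_length // config.n_chrom
    rem = config.genome_length - base * config.n_chrom
    return [(f"chr{i + 1}", base + (1 if i < rem else 0)) for i in range(config.n_chrom)]


def simulate_annotation(config: SimulationConfig) -> AnnotationSet:
    """Place non-overlapping genes and derive all element classes.

    Gene bodies (2–20 kb) are partitioned into exons and introns;
    promoters are TSS−1500..TSS+500 (strand-aware); CpG islands are
    placed at a configured fraction of promoters, centred on the TSS;
    shores are 2 kb CGI flanks; enhancers sit inside large intergenic
    gaps; intergenic is the complement of promoter ∪ exon ∪ intron.

    Raises
    ------
    ValueError
        If ``genome_length`` cannot hold ``n_genes`` gene bodies plus
        the minimum inter-gene gaps.
    """
    rng = np.random.default_rng([config.seed, 0])
    chroms = _chrom_bounds(config)

    # distribute genes over chromosomes proportionally to length
    lengths = np.array([ln for _, ln in chroms], dtype=float)
    alloc = np.floor(config.n_genes * lengths / lengths.sum()).astype(int)
    for i in range(config.n_genes - alloc.sum()):
        alloc[i % len(chroms)] += 1

    gene_rows = []
    gid = 0
    for (chrom, chrom_len), n_on_chrom in zip(chroms, alloc):
        if n_on_chrom == 0:
            continue
        glens = rng.integers(2000, 20001, size=n_on_chrom)
        needed = int(glens.sum()) + (n_on_chrom + 1) * _MIN_GENE_GAP + 2 * _CHROM_MARGIN
        if needed > chrom_len:
            raise ValueError(
                f"cannot pack {n_on_chrom} gene bodies ({glens.sum()} bp) plus "
                f"minimum gaps into {chrom} of length {chrom_len}; "
                "increase genome_length or reduce n_genes"
            )
        extra = chrom_len - needed
        gaps = rng.multinomial(extra, np.full(n_on_chrom + 1, 1 / (n_on_chrom + 1)))
        pos = _CHROM_MARGIN
        for k in range(n_on_chrom):
            pos += _MIN_GENE_GAP + int(gaps[k])
            start = pos + 1
            end = start + int(glens[k]) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end
            gene_rows.append((f"G{gid:05d}", chrom, tss, strand, start, end))
            gid += 1
            pos = end
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "tss", "strand", "gene_start", "gene_end"]
    )

    elements: dict[str, pd.DataFrame] = {}
    exon_rows, intron_rows = [], []
    for _, g in genes.iterrows():
        glen = g["gene_end"] - g["gene_start"] + 1
        n_exons = int(rng.integers(1, 9))
        n_seg = 2 * n_exons - 1
        if n_seg == 1:
            bounds = [glen]
        else:
            props = rng.dirichlet(np.full(n_seg, 1.5))
            seg = np.maximum(1, np.round(props * glen).astype(int))
            seg[-1] = max(1, glen - int(seg[:-1].sum()))
            bounds = seg.tolist()
        pos = g["gene_start"]
        for i, ln in enumerate(bounds):
            s, e = pos, min(pos + ln - 1, g["gene_end"])
            if s > g["gene_end"]:
                break
            kind = exon_rows if i % 2 == 0 else intron_rows
            kind.append((g["chrom"], s, e, g["strand"], g["gene_id"]))
            pos = e + 1
    cols = ["chrom", "start", "end", "strand", "feature_id"]
    elements["exon"] = pd.DataFrame(exon_rows, columns=cols)
    elements["intron"] = pd.DataFrame(intron_rows, columns=cols)
    elements["promoter"] = build_promoters(genes)

    # CGIs at a fraction of promoters, centred on the TSS
    n_cgi = math.ceil(config.cgi_promoter_frac * len(genes))
    cgi_rows = []
    if n_cgi > 0 and len(genes) > 0:
        order = rng.permutation(len(genes))[:n_cgi]
        for j in order:
            g = genes.iloc[j]
            half = int(rng.integers(250, 751))
            cgi_rows.append(
                (g["chrom"], max(1, g["tss"] - half), g["tss"] + half, ".", f"CGI_{g['gene_id']}")
            )
    elements["cgi"] = pd.DataFrame(cgi_rows, columns=cols)
    elements["shore"] = build_shores(elements["cgi"])

    # intergenic = complement of promoter/exon/intron; enhancers inside big gaps
    genome = pd.DataFrame(
        [(chrom, 1, ln) for chrom, ln in chroms], columns=["chrom", "start", "end"]
    )
    genic = pd.concat([elements["promoter"], elements["exon"], elements["intron"]])
    intergenic = subtract_intervals(genome, genic)
    elements["intergenic"] = intergenic

    enh_rows = []
    big = intergenic[(intergenic["end"] - intergenic["start"]) >= 3000]
    for _, iv in big.iterrows():
        if rng.random() < 0.3:
            ln = int(rng.integers(200, 1001))
            mid = (iv["start"] + iv["end"]) // 2
            enh_rows.append((iv["chrom"], mid - ln // 2, mid - ln // 2 + ln - 1, ".",
                             f"ENH_{len(enh_rows):05d}"))
    elements["enhancer"] = pd.DataFrame(enh_rows, columns=cols)

    return AnnotationSet(elements=elements, genes=genes)


def _draw_positions(rng, n_cpg: int, config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sorted unique CpG positions on the genome, mapped to chromosomes."""
    pool = np.array([], dtype=np.int64)
    factor = 1.1
    while len(pool) < n_cpg:
        draw = rng.integers(1, config.genome_length + 1, size=int(n_cpg * factor) + 16)
        pool = np.unique(np.concatenate([pool, draw]))
        factor *= 1.5
    pos_global = np.sort(rng.choice(pool, size=n_cpg, replace=False))
    chroms = _chrom_bounds(config)
    offsets = np.cumsum([0] + [ln for _, ln in chroms])
    idx = np.searchsorted(offsets, pos_global, side="right") - 1
    chrom_arr = np.array([chroms[i][0] for i in idx], dtype=object)
    pos = pos_global - offsets[idx]
    return chrom_arr, pos


def _sample_sheet(config: SimulationConfig, tissue: str) -> pd.DataFrame:
    rows = []
    for cond, tag in (("non-NEC", "ctrl"), ("NEC", "nec")):
        for i in range(config.n_samples_per_group):
            rows.append((f"{tissue}_{tag}_{i + 1:02d}", tissue, cond))
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "condition"])


def _site_element(chrom: np.ndarray, pos: np.ndarray, annotation: AnnotationSet) -> np.ndarray:
    from .annotate import _membership

    element = np.full(len(pos), "other", dtype=object)
    for cls in reversed(_WEIGHT_PRIORITY):  # lowest priority first, highest overwrites
        hit = _membership(chrom, pos, annotation.get(cls))
        element[hit] = cls
    return element


def _map_sites_to_features(
    pos: np.ndarray, chrom: np.ndarray, intervals: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """(site_row, feature_row) pairs for sites inside non-overlapping intervals."""
    site_rows, feat_rows = [], []
    iv = intervals.reset_index(drop=True)
    for chrom_name, grp in iv.groupby("chrom"):
        mask = chrom == chrom_name
        if not mask.any():
            continue
        order = np.argsort(grp["start"].to_numpy())
        starts = grp["start"].to_numpy()[order]
        ends = grp["end"].to_numpy()[order]
        rows = grp.index.to_numpy()[order]
        p = pos[mask]
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = (idx >= 0) & (p <= ends[np.clip(idx, 0, len(ends) - 1)])
        site_rows.append(np.flatnonzero(mask)[ok])
        feat_rows.append(rows[idx[ok]])
    if not site_rows:
        return np.array([], dtype=int), np.array([], dtype=int)
    return np.concatenate(site_rows), np.concatenate(feat_rows)


def _region_sample_means(
    pos: np.ndarray, chrom: np.ndarray, rates: np.ndarray, intervals: pd.DataFrame,
    sample_ids,
) -> pd.DataFrame:
    """Per-feature per-sample unweighted mean of site rates (NaN-aware).

    Assumes the intervals of one feature set are non-overlapping, which
    holds for simulated promoters and gene bodies.
    """
    n_feat = len(intervals)
    out = np.full((n_feat, rates.shape[1]), np.nan)
    if n_feat:
        sums = np.zeros((n_feat, rates.shape[1]))
        cnts = np.zeros((n_feat, rates.shape[1]))
        site_rows, feat_rows = _map_sites_to_features(pos, chrom, intervals)
        r = rates[site_rows]
        valid = ~np.isnan(r)
        np.add.at(sums, feat_rows, np.where(valid, r, 0.0))
        np.add.at(cnts, feat_rows, valid.astype(float))
        with np.errstate(invalid="ignore"):
            out = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return pd.DataFrame(out, index=intervals["feature_id"].to_numpy(), columns=list(sample_ids))


def simulate_methylation(
    config: SimulationConfig, annotation: AnnotationSet, tissue: str = "colon"
) -> tuple[MethylationTable, TruthTable]:
    """Draw per-CpG methylated/total counts for both conditions.

    Returns the count table and a :class:`TruthTable` whose ``sites``
    frame records each CpG's element class, mixture component, site mean
    and whether it received the NEC hyper-shift.
    """
    rng = np.random.default_rng([config.seed, 1])
    samples = _sample_sheet(config, tissue)
    n_samp = len(samples)
    nec = (samples["condition"] == "NEC").to_numpy()

    chrom, pos = _draw_positions(rng, config.n_cpg, config)
    element = _site_element(chrom, pos, annotation)

    weights = np.tile(np.asarray(config.lmimhm_weights_control), (config.n_cpg, 1))
    for cls, w in ELEMENT_CLASS_WEIGHTS.items():
        weights[element == cls] = w
    u = rng.random(config.n_cpg)
    cum = np.cumsum(weights, axis=1)
    comp_idx = (u[:, None] > cum).sum(axis=1)

    a = np.array([COMPONENT_BETAS[c][0] for c in COMPONENTS])
    b = np.array([COMPONENT_BETAS[c][1] for c in COMPONENTS])
    m = rng.beta(a[comp_idx], b[comp_idx])
    m = np.clip(m, 1e-6, 1 - 1e-6)

    n_shift = math.ceil(config.frac_shifted_sites * config.n_cpg)
    shifted = np.zeros(config.n_cpg, dtype=bool)
    shifted[rng.permutation(config.n_cpg)[:n_shift]] = True

    m_shifted = expit(logit(m) + config.hyper_shift)
    m_eff = np.where(shifted[:, None] & nec[None, :], m_shifted[:, None], m[:, None])
    m_eff = np.clip(m_eff, 1e-6, 1 - 1e-6)

    kappa = config.site_noise_kappa
    p = rng.beta(kappa * m_eff, kappa * (1 - m_eff))
    size = config.coverage_dispersion
    prob = size / (size + config.coverage_mean)
    coverage = rng.negative_binomial(size, prob, size=(config.n_cpg, n_samp))
    meth = rng.binomial(coverage, p)

    sites = pd.DataFrame({"chrom": chrom, "pos": pos})
    table = MethylationTable(sites, meth, coverage, samples)

    truth_sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "element": element,
            "component": np.array(COMPONENTS, dtype=object)[comp_idx],
            "base_m": m,
            "shifted": shifted,
        }
    )
    rates = table.rates()
    promoters = annotation.get("promoter")
    bodies = annotation.genes.rename(
        columns={"gene_start": "start", "gene_end": "end", "gene_id": "feature_id"}
    )[["chrom", "start", "end", "feature_id"]] if len(annotation.genes) else pd.DataFrame(
        columns=["chrom", "start", "end", "feature_id"]
    )
    prom_shift = np.zeros(len(promoters), dtype=bool)
    if len(promoters):
        site_rows, feat_rows = _map_sites_to_features(pos, chrom, promoters)
        np.logical_or.at(prom_shift, feat_rows, shifted[site_rows])
    truth = TruthTable(
        samples=samples,
        sites=truth_sites,
        promoter_rates=_region_sample_means(pos, chrom, rates, promoters, samples["sample_id"]),
        gene_body_rates=_region_sample_means(pos, chrom, rates, bodies, samples["sample_id"]),
        promoter_shifted=pd.Series(prom_shift, index=promoters["feature_id"].to_numpy()),
    )
    return table, truth


def simulate_expression(
    config: SimulationConfig, truth: TruthTable
) -> tuple[ExpressionMatrix, TruthTable]:
    """Draw RNA counts whose truth links a subset of DE genes to promoter methylation.

    True-DE genes are the first ``ceil(de_frac * n_genes)`` genes of a
    seeded shuffle.  Coupled genes (a ``coupling_frac`` fraction of the
    DE set, restricted to genes whose promoter received the methylation
    shift) get a forced-negative fold change plus a per-sample expression
    term proportional to the group-centred promoter methylation rate, so
    methylation and expression are anti-correlated within groups as well
    as between them.
    """
    rng = np.random.default_rng([config.seed, 2])
    samples = truth.samples
    nec = (samples["condition"] == "NEC").to_numpy()
    gene_ids = (
        list(truth.promoter_rates.index)
        if truth.promoter_rates is not None
        else [f"G{i:05d}" for i in range(config.n_genes)]
    )
    n_genes = len(gene_ids)
    n_samp = len(samples)

    base = rng.normal(5.0, 2.0, size=n_genes).clip(0.0, None)
    perm = rng.permutation(n_genes)
    n_de = math.ceil(config.de_frac * n_genes)
    de_idx = perm[:n_de]
    is_de = np.zeros(n_genes, dtype=bool)
    is_de[de_idx] = True

    mag = np.abs(config.de_lfc_mean + config.de_lfc_sd * rng.standard_normal(n_genes))
    sign = np.where(rng.random(n_genes) < 0.5, 1.0, -1.0)
    lfc = np.where(is_de, sign * mag, 0.0)

    # coupled genes: DE genes whose promoter was shifted and has CpGs
    is_coupled = np.zeros(n_genes, dtype=bool)
    if truth.promoter_rates is not None and truth.promoter_shifted is not None and n_de > 0:
        prom = truth.promoter_rates.to_numpy()
        has_prom = ~np.isnan(prom).all(axis=1)
        shifted_prom = truth.promoter_shifted.to_numpy()
        eligible = [i for i in de_idx if has_prom[i] and shifted_prom[i]]
        n_coupled = min(math.ceil(config.coupling_frac * n_de), len(eligible))
        is_coupled[eligible[:n_coupled]] = True
        lfc[is_coupled] = -np.abs(lfc[is_coupled])

    log2_mu = base[:, None] + lfc[:, None] * nec[None, :].astype(float)
    if is_coupled.any():
        prom = truth.promoter_rates.to_numpy()[is_coupled]
        prom = np.where(np.isnan(prom), np.nanmean(prom, axis=1, keepdims=True), prom)
        centred = prom.copy()
        for grp_mask in (nec, ~nec):
            centred[:, grp_mask] -= prom[:, grp_mask].mean(axis=1, keepdims=True)
        log2_mu[is_coupled] -= config.coupling_strength * centred

    lib = rng.uniform(*config.libsize_range, size=n_samp)
    mu = lib[None, :] * np.exp2(log2_mu)
    alpha = config.expr_dispersion
    if alpha > 0:
        size = 1.0 / alpha
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)

    expr = ExpressionMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                     columns=list(samples["sample_id"])),
        samples,
    )
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_de": is_de,
            "true_lfc": lfc,
            "is_coupled": is_coupled,
            "base_log2": base,
        }
    )
    if truth.promoter_shifted is not None:
        genes["promoter_shifted"] = truth.promoter_shifted.to_numpy()
    truth.genes = genes
    return expr, truth


def simulate_dataset(
    config: SimulationConfig, tissue: str = "colon"
) -> SimulatedDataset:
    """Run the full generator: annotation, methylation counts, RNA counts."""
    annotation = simulate_annotation(config)
    methylation, truth = simulate_methylation(config, annotation, tissue=tissue)
    expression, truth = simulate_expression(config, truth)
    return SimulatedDataset(config, annotation, methylation, expression, truth)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write every external format: coverage TSVs, BED6 per class, counts,
    sample sheet, truth tables and the config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_bismark_coverage(ds.methylation, outdir / "coverage")
    for cls, df in ds.annotation.elements.items():
        write_bed(df, outdir / f"{cls}.bed")
    write_gene_table(ds.annotation.genes, outdir / "genes.tsv")
    write_counts(ds.expression, outdir / "rna_counts.tsv")
    write_sample_sheet(ds.truth.samples, outdir / "samples.csv")
    ds.truth.sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    if ds.truth.genes is not None:
        ds.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    ds.config.to_yaml(outdir / "config.yaml")
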