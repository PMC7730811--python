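"""Simulation configuration for the synthetic WGBS + RNA-seq generator.

The defaults describe the study conditions the package is built around:
two patient groups (surgical NEC vs non-NEC) sampled from one intestinal
tissue, whole-genome bisulfite sequencing summarised as per-CpG
methylated/unmethylated counts, and bulk RNA-seq gene counts on the same
samples.  Site-level methylation follows a three-component (LM/IM/HM)
beta mixture; NEC hypermethylation is a logit-scale shift applied to a
subset of CpGs; a subset of differentially expressed genes is coupled to
promoter hypermethylation with opposite sign.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

__all__ = ["SimulationConfig"]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset generator.

    Parameters
    ----------
    n_samples_per_group : int
        Samples per condition (NEC and non-NEC), one tissue at a time.
    n_cpg : int
        Number of autosomal CpG sites to simulate.
    n_genes : int
        Number of genes placed on the synthetic genome.
    genome_length : int
        Genome size in base pairs (single synthetic chromosome by default;
        split across ``n_chrom`` chromosomes of equal length).
    n_chrom : int
        Number of chromosomes the genome is divided into.
    coverage_mean : float
        Mean negative-binomial read depth per CpG per sample.
    coverage_dispersion : float
        Negative-binomial size (smaller = more dispersed coverage).
    lmimhm_weights_control : tuple of float
        Genome-wide probability of the LM/IM/HM mixture components for
        control samples; element-specific weights (promoters and CpG
        islands are LM-enriched) are derived from published element
        profiles, see :data:`necmethylome.simulate.ELEMENT_CLASS_WEIGHTS`.
    hyper_shift : float
        Logit-scale increase of the site mean methylation applied to the
        NEC group at shifted sites.  Non-negative; 0 gives a null dataset.
    frac_shifted_sites : float
        Fraction of CpGs receiving the shift (chosen by seeded shuffle so
        the shifted count is deterministic: ``ceil(frac * n_cpg)``).
    site_noise_kappa : float
        Beta precision of per-sample methylation around the site mean
        (per-sample rate ~ Beta(kappa*m, kappa*(1-m))).
    de_frac : float
        Fraction of genes with a true expression fold change.
    de_lfc_mean : float
        Mean absolute log2 fold change of true-DE genes.
    de_lfc_sd : float
        Spread of the absolute log2 fold change (0 = constant magnitude).
    coupling_frac : float
        Fraction of true-DE genes whose expression is anti-correlated
        with their (hypermethylated) promoter methylation.
    coupling_strength : float
        log2-expression decrease per unit increase of promoter
        methylation rate for coupled genes.
    expr_dispersion : float
        Negative-binomial dispersion (alpha) of RNA counts.
    libsize_range : tuple of float
        Library-size factors are drawn uniformly from this interval.
    cgi_promoter_frac : float
        Fraction of promoters carrying a CpG island.
    seed : int
        RNG seed; identical configs produce byte-identical outputs.
    """

    n_samples_per_group: int = 10
    n_cpg: int = 100_000
    n_genes: int = 2000
    genome_length: int = 50_000_000
    n_chrom: int = 1
    coverage_mean: float = 15.0
    coverage_dispersion: float = 5.0
    lmimhm_weights_control: tuple[float, float, float] = (0.02, 0.46, 0.52)
    hyper_shift: float = 0.5
    frac_shifted_sites: float = 0.3
    site_noise_kappa: float = 30.0
    de_frac: float = 0.2
    de_lfc_mean: float = 1.0
    de_lfc_sd: float = 0.0
    coupling_frac: float = 0.2
    coupling_strength: float = 4.0
    expr_dispersion: float = 0.05
    libsize_range: tuple[float, float] = (0.5, 1.5)
    cgi_promoter_frac: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.lmimhm_weights_control)
        if len(w) != 3 or any(x < 0 or x > 1 for x in w):
            raise ValueError("lmimhm_weights_control must be three probabilities in [0, 1]")
        if abs(sum(w) - 1.0) > 1e-9:
            raise ValueError(f"lmimhm_weights_control must sum to 1, got {sum(w)!r}")
        self.lmimhm_weights_control = w
        if self.hyper_shift < 0:
            raise ValueError("hyper_shift must be >= 0")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")
        for name in ("frac_shifted_sites", "de_frac", "coupling_frac", "cgi_promoter_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        if self.n_cpg < 0 or self.n_genes < 0 or self.genome_length <= 0:
            raise ValueError("n_cpg/n_genes must be >= 0 and genome_length > 0")
        if self.n_chrom < 1:
            raise ValueError("n_chrom must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("lmimhm_weights_control", "libsize_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)
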