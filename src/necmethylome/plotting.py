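"""Minimal plotting helpers for the profiling and integration outputs."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_density", "plot_mds", "plot_spatial", "plot_correlation_density"]


def plot_density(profiles: dict, path=None):
    """Overlay per-condition methylation-rate densities.

    ``profiles`` maps a label (e.g. 'NEC', 'non-NEC') to the dict
    returned by :func:`necmethylome.profile.density_profile`.
    """
    fig, ax = plt.subplots()
    for label, prof in profiles.items():
        centers = 0.5 * (prof["edges"][:-1] + prof["edges"][1:])
        ax.plot(centers, prof["density"], label=label)
    ax.set_xlabel("methylation rate")
    ax.set_ylabel("density")
    ax.legend()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_mds(coords: pd.DataFrame, path=None):
    fig, ax = plt.subplots()
    for cond, sub in coords.groupby("condition"):
        ax.scatter(sub["dim1"], sub["dim2"], label=cond)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.legend()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_spatial(profile: pd.DataFrame, path=None):
    fig, ax = plt.subplots()
    for chrom, sub in profile.groupby("chrom"):
        mid = 0.5 * (sub["bin_start"] + sub["bin_end"])
        ax.plot(mid, sub["mean_rate_nec"], color="firebrick", label=f"{chrom} NEC")
        ax.plot(mid, sub["mean_rate_ctrl"], color="steelblue", label=f"{chrom} non-NEC")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("mean methylation")
    ax.legend(fontsize="small")
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_correlation_density(dens: dict, path=None):
    fig, ax = plt.subplots()
    colors = {"high_delta": "firebrick", "low_delta": "steelblue"}
    for name, s in dens["strata"].items():
        centers = 0.5 * (s["edges"][:-1] + s["edges"][1:])
        ax.plot(centers, s["density"], color=colors.get(name), label=name)
    ax.set_xlabel("Pearson r (methylation vs expression)")
    ax.set_ylabel("density")
    ax.legend()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
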