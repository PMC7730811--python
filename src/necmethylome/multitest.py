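"""Benjamini–Hochberg adjustment shared by every module that reports q-values."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["BHResult", "adjust_pvalues"]


@dataclass
class BHResult:
    q_values: np.ndarray
    n_tested: int
    n_excluded: int  # NaN p-values, reported but not adjusted
    realized_p_threshold: float  # max{p_i : q_i <= alpha}; NaN if no q <= alpha
    alpha: float


def adjust_pvalues(p_values, method: str = "bh", alpha: float = 0.05) -> BHResult:
    """Benjamini–Hochberg step-up q-values.

    NaN p-values are excluded from the adjustment (they keep NaN q) and
    counted in ``n_excluded``.  ``realized_p_threshold`` is the largest
    raw p-value still called at FDR ``alpha`` — the realised p↔q mapping
    that lets q-based calls be compared with a fixed p cutoff.
    """
    if method.lower() not in {"bh", "fdr_bh"}:
        raise ValueError(f"unsupported method {method!r}")
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    called = ok & (q <= alpha)
    realized = float(p[called].max()) if called.any() else float("nan")
    return BHResult(
        q_values=q,
        n_tested=int(ok.sum()),
        n_excluded=int((~ok).sum()),
        realized_p_threshold=realized,
        alpha=alpha,
    )
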