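"""Univariate Spearman screening of scales against global quality of life.

Every scale is rank-correlated with the target (gQoL) at each time point;
p-values come from the two-sided t-test on Spearman's rho and are adjusted
per time point with Benjamini-Hochberg.  A scale enters the network when
the mean of |rho| across time points strictly exceeds the selection
threshold (0.3, the lower edge of a "moderate" correlation).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable

__all__ = [
    "spearman_screen",
    "bh_adjust",
    "select_nodes",
    "classify_strength",
    "significance_stars",
]

#: |rho| bands used to label correlation strength.
_BANDS = [(0.50, "strong"), (0.30, "moderate"), (0.10, "weak")]


def classify_strength(rho: float) -> str:
    """Label |rho|: weak 0.10-0.29, moderate 0.30-0.49, strong >= 0.50."""
    if np.isnan(rho):
        return "none"
    a = abs(rho)
    for lo, label in _BANDS:
        if a >= lo:
            return label
    return "none"


def significance_stars(q: float) -> str:
    if np.isnan(q):
        return ""
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and its two-sided t-test p-value on n-2 df."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need n >= 4 for the Spearman screen")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return np.nan, np.nan
    rho = stats.spearmanr(x, y).statistic
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(rho), float(p)


def spearman_screen(
    table: CohortTable, target: str, threshold: float = 0.3
) -> pd.DataFrame:
    """Screen every non-target scale against the target at each time point.

    Returns one row per scale with ``rho_<tp>``, ``p_<tp>``, ``q_<tp>``
    (BH-adjusted within that time point's family of tests),
    ``class_<tp>``, ``stars_<tp>``, plus ``mean_abs_rho`` and the strict
    ``selected`` flag.  Constant columns yield NaN rho with a warning.
    """
    if target not in table.scales:
        raise ValueError(f"target scale {target!r} not in table")
    others = [s for s in table.scales if s != target]
    out = pd.DataFrame(index=pd.Index(others, name="scale"))
    for tp in table.timepoints:
        scores = table.scores(tp)
        y = scores[target].to_numpy()
        rhos, ps = [], []
        for s in others:
            r, p = _spearman(scores[s].to_numpy(), y)
            if np.isnan(r):
                warnings.warn(
                    f"scale {s!r} is constant at {tp}; rho undefined",
                    stacklevel=2,
                )
            rhos.append(r)
            ps.append(p)
        rhos = np.asarray(rhos)
        ps = np.asarray(ps)
        qs = np.full_like(ps, np.nan)
        ok = ~np.isnan(ps)
        if ok.any():
            qs[ok] = bh_adjust(ps[ok])
        out[f"rho_{tp}"] = rhos
        out[f"p_{tp}"] = ps
        out[f"q_{tp}"] = qs
        out[f"class_{tp}"] = [classify_strength(r) for r in rhos]
        out[f"stars_{tp}"] = [significance_stars(q) for q in qs]
    rho_cols = [f"rho_{tp}" for tp in table.timepoints]
    out["mean_abs_rho"] = out[rho_cols].abs().mean(axis=1)
    out["selected"] = out["mean_abs_rho"] > threshold
    return out


def select_nodes(
    rows: pd.DataFrame, target: str, threshold: float = 0.3
) -> list[str]:
    """Nodes for the network: the target plus scales with mean |rho| > threshold.

    ``rows`` needs a ``mean_abs_rho`` column (as produced by
    :func:`spearman_screen`, or assembled from published correlations);
    comparison is strictly greater-than, and input order is preserved.
    """
    if "mean_abs_rho" not in rows.columns:
        raise ValueError("rows must carry a mean_abs_rho column")
    picked = [s for s in rows.index if rows.loc[s, "mean_abs_rho"] > threshold]
    return [target] + [s for s in picked if s != target]
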