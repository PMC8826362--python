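"""Bootstrap accuracy and stability of estimated networks.

Three procedures, all rerunning the identical correlation + EBIC-glasso
pipeline on resampled subjects:

* **case-dropping bootstrap** — re-estimate after dropping a growing
  proportion of subjects without replacement and correlate the resampled
  edge weights (and centralities) with the full-sample ones; summarized by
  the correlation-stability coefficient CS(cor=0.7): the largest drop
  proportion at which at least 95% of replicates still correlate >= 0.7
  with the original.  CS >= 0.25 is the conventional minimum for an index
  to be considered interpretable, CS > 0.5 preferable.
* **nonparametric edge bootstrap** — resample subjects with replacement
  and form 2.5%/97.5% quantile intervals per edge.
* **bootstrapped difference tests** — a pair of edges (or node strengths)
  differs significantly when the bootstrap interval of their difference
  excludes zero; deliberately uncorrected for multiple testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .estimator import NetworkEstimator
from .glasso import GGMNetwork

__all__ = [
    "DEFAULT_DROP_GRID",
    "case_drop_bootstrap",
    "edge_ci_bootstrap",
    "difference_tests",
    "cs_coefficient",
    "StabilityReport",
    "CaseDropResult",
    "EdgeBootstrapResult",
    "stability_report",
]

#: default case-dropping grid: 5% .. 75% in steps of 5%
DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.80, 0.05), 2))

_MAX_FAILURE_RATE = 0.05


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; 1.0 for identical vectors, NaN if degenerate."""
    if np.array_equal(a, b):
        return 1.0
    if np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def _strength(W: np.ndarray) -> np.ndarray:
    return np.abs(W).sum(axis=1)


def _closeness(W: np.ndarray) -> np.ndarray:
    from .metrics import centralities

    return centralities(W)["closeness"].to_numpy()


def _resolve_scores(table, timepoint, nodes):
    if isinstance(table, CohortTable):
        if timepoint is None:
            timepoint = table.timepoints[0]
        scores = table.scores(timepoint)
    else:
        scores = table
    if nodes is not None:
        scores = scores[list(nodes)]
    if scores.isna().any().any():
        raise ValueError("scores contain missing values; impute first")
    return scores


@dataclass
class CaseDropResult:
    """Stability curves and CS-coefficients from case-dropping bootstrap."""

    curves: pd.DataFrame  # columns: proportion, replicate, quantity, correlation
    cs: dict  # quantity -> CS value (NaN = below the minimum grid value)
    proportions: tuple
    B: int
    seed: int
    n_failed: int = 0

    def cs_coefficient(self, quantity: str = "edge", threshold: float = 0.7,
                       prob: float = 0.95) -> float:
        return cs_coefficient(self.curves, quantity, threshold, prob)


def cs_coefficient(
    curves: pd.DataFrame,
    quantity: str = "edge",
    threshold: float = 0.7,
    prob: float = 0.95,
) -> float:
    """CS(cor=threshold): largest drop proportion keeping stability.

    The largest grid proportion pi such that at pi and every smaller grid
    value, at least ``prob`` of the replicates correlate >= ``threshold``
    with the full-sample result.  NaN when even the smallest grid
    proportion fails (below-minimum marker).
    """
    sub = curves[curves["quantity"] == quantity]
    cs = np.nan
    for prop in sorted(sub["proportion"].unique()):
        r = sub.loc[sub["proportion"] == prop, "correlation"].to_numpy()
        ok = np.nan_to_num(r, nan=-1.0) >= threshold
        if ok.mean() >= prob:
            cs = float(prop)
        else:
            break
    return cs


def case_drop_bootstrap(
    table,
    timepoint: str | None = None,
    nodes: list[str] | None = None,
    estimator: NetworkEstimator | None = None,
    proportions: tuple = DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int = 0,
) -> CaseDropResult:
    """Case-dropping bootstrap of edge weights, strength and closeness.

    ``B`` replicates are spread evenly over the drop-proportion grid; each
    replicate drops ``ceil(pi * n)`` subjects without replacement, reruns
    the pipeline, and records the correlation of its edge-weight vector
    (and centrality vectors) with the full-sample network's.  Failed
    re-estimations are skipped and counted; more than 5% failures aborts.
    """
    estimator = estimator or NetworkEstimator()
    scores = _resolve_scores(table, timepoint, nodes)
    if B < 100:
        warnings.warn(f"B={B} < 100: stability quantiles will be coarse",
                      stacklevel=2)
    X = scores.to_numpy(dtype=float)
    n = X.shape[0]
    kinds = estimator.classify(X)
    W0 = estimator.fit_array(X, kinds)
    iu = np.triu_indices(W0.shape[0], 1)
    ref = {
        "edge": W0[iu],
        "strength": _strength(W0),
        "closeness": _closeness(W0),
    }
    rng = np.random.default_rng(seed)
    per_prop = max(1, int(round(B / len(proportions))))
    rows = []
    n_failed = 0
    n_total = 0
    for prop in proportions:
        keep = n - int(np.ceil(prop * n))
        for b in range(per_prop):
            n_total += 1
            idx = rng.choice(n, size=keep, replace=False)
            try:
                # dropping nothing reproduces the original network exactly
                W = W0 if keep == n else estimator.fit_array(X[idx], kinds)
            except Exception:
                n_failed += 1
                if n_failed > _MAX_FAILURE_RATE * max(n_total, 20):
                    raise RuntimeError(
                        f"case-dropping bootstrap failure rate exceeded "
                        f"{_MAX_FAILURE_RATE:.0%} ({n_failed}/{n_total})"
                    )
                continue
            rep = {
                "edge": W[iu],
                "strength": _strength(W),
                "closeness": _closeness(W),
            }
            for q in ref:
                rows.append(
                    {
                        "proportion": prop,
                        "replicate": b,
                        "quantity": q,
                        "correlation": _safe_corr(ref[q], rep[q]),
                    }
                )
    curves = pd.DataFrame(rows)
    cs = {q: cs_coefficient(curves, q) for q in ref}
    return CaseDropResult(
        curves=curves, cs=cs, proportions=tuple(proportions),
        B=per_prop * len(proportions), seed=seed, n_failed=n_failed,
    )


@dataclass
class EdgeBootstrapResult:
    """Nonparametric bootstrap replicates of edges and strengths."""

    node_names: list[str]
    observed: np.ndarray        # full-sample weight matrix
    boot_edges: np.ndarray      # B x n_pairs upper-triangle weights
    boot_strength: np.ndarray   # B x p node strengths
    ci: pd.DataFrame            # per-edge observed value + quantile CI
    B: int
    seed: int
    n_failed: int = 0

    @property
    def pair_labels(self) -> list[tuple[str, str]]:
        p = len(self.node_names)
        iu = np.triu_indices(p, 1)
        return [(self.node_names[i], self.node_names[j])
                for i, j in zip(*iu)]


def edge_ci_bootstrap(
    table,
    timepoint: str | None = None,
    nodes: list[str] | None = None,
    estimator: NetworkEstimator | None = None,
    B: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> EdgeBootstrapResult:
    """Resample subjects with replacement; per-edge quantile CIs."""
    estimator = estimator or NetworkEstimator()
    scores = _resolve_scores(table, timepoint, nodes)
    if B < 100:
        warnings.warn(f"B={B} < 100: CI quantiles will be coarse", stacklevel=2)
    X = scores.to_numpy(dtype=float)
    n = X.shape[0]
    kinds = estimator.classify(X)
    W0 = estimator.fit_array(X, kinds)
    p = W0.shape[0]
    iu = np.triu_indices(p, 1)
    rng = np.random.default_rng(seed)
    edges, strengths = [], []
    n_failed = 0
    b = 0
    while len(edges) < B:
        b += 1
        idx = rng.integers(0, n, size=n)
        try:
            W = estimator.fit_array(X[idx], kinds)
        except Exception:
            n_failed += 1
            if n_failed > _MAX_FAILURE_RATE * max(b, 20):
                raise RuntimeError(
                    f"edge bootstrap failure rate exceeded "
                    f"{_MAX_FAILURE_RATE:.0%} ({n_failed}/{b})"
                )
            continue
        edges.append(W[iu])
        strengths.append(_strength(W))
    boot_edges = np.asarray(edges)
    boot_strength = np.asarray(strengths)
    a = (1.0 - ci_level) / 2.0
    lo = np.quantile(boot_edges, a, axis=0)
    hi = np.quantile(boot_edges, 1.0 - a, axis=0)
    names = list(scores.columns)
    ci = pd.DataFrame(
        {
            "node_i": [names[i] for i in iu[0]],
            "node_j": [names[j] for j in iu[1]],
            "observed": W0[iu],
            "boot_mean": boot_edges.mean(axis=0),
            "ci_lower": lo,
            "ci_upper": hi,
        }
    )
    return EdgeBootstrapResult(
        node_names=names, observed=W0, boot_edges=boot_edges,
        boot_strength=boot_strength, ci=ci, B=B, seed=seed, n_failed=n_failed,
    )


def difference_tests(
    boot: EdgeBootstrapResult, ci_level: float = 0.95
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise bootstrapped difference tests for edges and strengths.

    A pair differs when the bootstrap quantile interval of the difference
    of the two quantities excludes 0.  No multiple-testing correction is
    applied.  Returns (edge_matrix, strength_matrix) of booleans; the
    diagonal (self-comparisons) is always False.
    """
    a = (1.0 - ci_level) / 2.0

    def _sig(mat: np.ndarray, labels: list) -> pd.DataFrame:
        m = mat.shape[1]
        sig = np.zeros((m, m), dtype=bool)
        for e in range(m):
            diff = mat[:, e][:, None] - mat  # B x m
            lo = np.quantile(diff, a, axis=0)
            hi = np.quantile(diff, 1.0 - a, axis=0)
            sig[e] = (lo > 0) | (hi < 0)
            sig[e, e] = False
        return pd.DataFrame(sig, index=labels, columns=labels)

    edge_labels = ["--".join(pair) for pair in boot.pair_labels]
    edge_sig = _sig(boot.boot_edges, edge_labels)
    strength_sig = _sig(boot.boot_strength, boot.node_names)
    return edge_sig, strength_sig


@dataclass
class StabilityReport:
    """Aggregate of the three bootstrap analyses for one network."""

    case_drop: CaseDropResult
    edge_boot: EdgeBootstrapResult
    edge_differences: pd.DataFrame
    strength_differences: pd.DataFrame
    B: int
    seed: int

    @property
    def cs(self) -> dict:
        return self.case_drop.cs


def stability_report(
    table,
    timepoint: str | None = None,
    nodes: list[str] | None = None,
    estimator: NetworkEstimator | None = None,
    proportions: tuple = DEFAULT_DROP_GRID,
    B: int = 1000,
    seed: int = 0,
) -> StabilityReport:
    """Run all three bootstrap analyses with sub-seeds derived from seed."""
    case = case_drop_bootstrap(
        table, timepoint, nodes, estimator, proportions, B, seed=seed,
    )
    boot = edge_ci_bootstrap(
        table, timepoint, nodes, estimator, B, seed=seed + 1,
    )
    edge_sig, strength_sig = difference_tests(boot)
    return StabilityReport(
        case_drop=case, edge_boot=boot, edge_differences=edge_sig,
        strength_differences=strength_sig, B=B, seed=seed,
    )
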