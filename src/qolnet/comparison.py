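"""Paired permutation comparison of two networks over time.

The dependent-samples variant of the permutation network-comparison test:
the same subjects are measured at both time points, so the null of equal
networks is simulated by independently swapping, per subject with
probability 1/2, the subject's two score vectors, and re-estimating both
networks with the identical pipeline.  Compared statistics:

* network structure  M = max_ij |w1_ij - w2_ij|
* global strength difference |S1 - S2|, S = sum of |edge weights|
* per-edge absolute differences and per-node strength differences
  (uncorrected for multiple testing).

p-values use the add-one convention p = (1 + #{perm >= obs}) / (1 + iters)
and so are never exactly zero.  Note the permutation scheme treats the
subject's pair of vectors as exchangeable under the null; as with the
original procedure this dependent-data variant is heuristic rather than
formally validated, which is why a conservative alpha (0.005) is the
default decision level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable
from .estimator import NetworkEstimator
from .glasso import GGMNetwork

__all__ = [
    "NCTResult",
    "nct_paired",
    "DifferenceNetwork",
    "difference_network",
    "edge_weight_correlation",
]


@dataclass
class NCTResult:
    """Observed statistics, permutation references and p-values."""

    node_names: list[str]
    m_structure: float
    p_structure: float
    global_strength: tuple[float, float]   # (S1, S2)
    global_strength_diff: float
    p_global_strength: float
    edge_diff: pd.DataFrame                # observed |w1 - w2| matrix
    edge_p: pd.DataFrame                   # per-edge p-value matrix
    strength_diff: pd.Series               # per-node |s1 - s2|
    strength_p: pd.Series
    perm_m: np.ndarray
    perm_strength: np.ndarray
    iterations: int
    alpha: float
    seed: int

    def significant_edges(self) -> pd.DataFrame:
        """Edges whose uncorrected permutation p < alpha."""
        iu = np.triu_indices(len(self.node_names), 1)
        rows = []
        P = self.edge_p.to_numpy()
        D = self.edge_diff.to_numpy()
        for i, j in zip(*iu):
            if P[i, j] < self.alpha:
                rows.append(
                    {"node_i": self.node_names[i], "node_j": self.node_names[j],
                     "abs_difference": D[i, j], "p": P[i, j]}
                )
        return pd.DataFrame(rows, columns=["node_i", "node_j", "abs_difference", "p"])

    def summary(self) -> str:
        lines = [
            "Paired permutation network comparison",
            f"  nodes: {len(self.node_names)}   iterations: {self.iterations}"
            f"   alpha: {self.alpha}",
            f"  structure M = {self.m_structure:.4f}   p = {self.p_structure:.4f}",
            f"  global strength: {self.global_strength[0]:.3f} vs "
            f"{self.global_strength[1]:.3f}   |diff| = "
            f"{self.global_strength_diff:.4f}   p = {self.p_global_strength:.4f}",
            f"  edges with p < alpha: {len(self.significant_edges())}",
            f"  nodes with strength p < alpha: "
            f"{int((self.strength_p < self.alpha).sum())}",
        ]
        return "\n".join(lines)


def _net_stats(W1: np.ndarray, W2: np.ndarray, iu):
    d = np.abs(W1 - W2)[iu]
    m = float(d.max()) if d.size else 0.0
    s1 = float(np.abs(W1[iu]).sum())
    s2 = float(np.abs(W2[iu]).sum())
    st1 = np.abs(W1).sum(axis=1)
    st2 = np.abs(W2).sum(axis=1)
    return m, abs(s1 - s2), d, np.abs(st1 - st2), s1, s2


def nct_paired(
    table: CohortTable,
    nodes: list[str] | None = None,
    timepoints: tuple[str, str] | None = None,
    estimator: NetworkEstimator | None = None,
    iterations: int = 5000,
    alpha: float = 0.005,
    seed: int = 0,
) -> NCTResult:
    """Dependent (paired) permutation test of network differences.

    Every subject must be observed (post-imputation) at both time points.
    Each permutation swaps, per subject with probability 1/2, the two
    timepoint score vectors, and both networks are re-estimated with the
    identical correlation + EBIC-glasso pipeline.
    """
    estimator = estimator or NetworkEstimator()
    if timepoints is None:
        if len(table.timepoints) != 2:
            raise ValueError("table must have exactly 2 timepoints (or pass them)")
        timepoints = tuple(table.timepoints)
    if iterations < 100:
        warnings.warn(
            f"iterations={iterations} < 100: permutation p-values unreliable",
            stacklevel=2,
        )
    s1 = table.scores(timepoints[0])
    s2 = table.scores(timepoints[1])
    if nodes is not None:
        s1, s2 = s1[list(nodes)], s2[list(nodes)]
    if not s1.index.equals(s2.index):
        common = s1.index.intersection(s2.index)
        missing = set(s1.index).symmetric_difference(s2.index)
        if missing:
            raise ValueError(
                f"{len(missing)} subject(s) present at only one timepoint"
            )
        s2 = s2.loc[common]
    if s1.isna().any().any() or s2.isna().any().any():
        raise ValueError("scores contain missing values; impute first")
    names = list(s1.columns)
    X1 = s1.to_numpy(dtype=float)
    X2 = s2.to_numpy(dtype=float)
    n, p = X1.shape
    kinds = estimator.classify(np.vstack([X1, X2]))
    iu = np.triu_indices(p, 1)
    W1 = estimator.fit_array(X1, kinds)
    W2 = estimator.fit_array(X2, kinds)
    m_obs, sdiff_obs, edge_obs, strength_obs, S1, S2 = _net_stats(W1, W2, iu)
    rng = np.random.default_rng(seed)
    perm_m = np.empty(iterations)
    perm_sdiff = np.empty(iterations)
    ge_edge = np.zeros(edge_obs.shape[0])
    ge_strength = np.zeros(p)
    for it in range(iterations):
        swap = rng.random(n) < 0.5
        A = np.where(swap[:, None], X2, X1)
        B = np.where(swap[:, None], X1, X2)
        Wa = estimator.fit_array(A, kinds)
        Wb = estimator.fit_array(B, kinds)
        m, sd, ed, st, _, _ = _net_stats(Wa, Wb, iu)
        perm_m[it] = m
        perm_sdiff[it] = sd
        ge_edge += ed >= edge_obs
        ge_strength += st >= strength_obs
    denom = 1.0 + iterations
    p_m = (1.0 + np.sum(perm_m >= m_obs)) / denom
    p_s = (1.0 + np.sum(perm_sdiff >= sdiff_obs)) / denom
    edge_p_vec = (1.0 + ge_edge) / denom
    strength_p = (1.0 + ge_strength) / denom
    edge_diff_mat = np.zeros((p, p))
    edge_p_mat = np.ones((p, p))
    edge_diff_mat[iu] = edge_obs
    edge_diff_mat += edge_diff_mat.T
    edge_p_mat[iu] = edge_p_vec
    edge_p_mat[(iu[1], iu[0])] = edge_p_vec
    return NCTResult(
        node_names=names,
        m_structure=m_obs,
        p_structure=float(p_m),
        global_strength=(S1, S2),
        global_strength_diff=sdiff_obs,
        p_global_strength=float(p_s),
        edge_diff=pd.DataFrame(edge_diff_mat, index=names, columns=names),
        edge_p=pd.DataFrame(edge_p_mat, index=names, columns=names),
        strength_diff=pd.Series(strength_obs, index=names, name="strength_diff"),
        strength_p=pd.Series(strength_p, index=names, name="p"),
        perm_m=perm_m,
        perm_strength=perm_sdiff,
        iterations=iterations,
        alpha=alpha,
        seed=seed,
    )


@dataclass
class DifferenceNetwork:
    """Entrywise |w1| - |w2| with the direction of change recorded.

    A positive entry means the association weakened from the first network
    to the second; negative means it strengthened.  Antisymmetric under
    swapping the inputs.  ``display_threshold`` only affects export.
    """

    node_names: list[str]
    values: np.ndarray
    display_threshold: float = 0.04

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_names,
                            columns=self.node_names)

    def edge_list(self, threshold: float | None = None) -> pd.DataFrame:
        thr = self.display_threshold if threshold is None else threshold
        p = len(self.node_names)
        rows = []
        for i in range(p):
            for j in range(i + 1, p):
                v = self.values[i, j]
                if v != 0.0 and abs(v) > thr:
                    rows.append(
                        {
                            "node_i": self.node_names[i],
                            "node_j": self.node_names[j],
                            "difference": v,
                            "change": "decrease" if v > 0 else "increase",
                        }
                    )
        return pd.DataFrame(
            rows, columns=["node_i", "node_j", "difference", "change"]
        )


def difference_network(
    net1: GGMNetwork, net2: GGMNetwork, display_threshold: float = 0.04
) -> DifferenceNetwork:
    """|w1| - |w2| between two networks over the same nodes."""
    if list(net1.node_names) != list(net2.node_names):
        raise ValueError("networks must share an identical node set/order")
    vals = np.abs(net1.weights) - np.abs(net2.weights)
    np.fill_diagonal(vals, 0.0)
    return DifferenceNetwork(
        node_names=list(net1.node_names),
        values=vals,
        display_threshold=display_threshold,
    )


def edge_weight_correlation(net1: GGMNetwork, net2: GGMNetwork):
    """Spearman correlation of the two edge-weight vectors (zeros kept)."""
    if list(net1.node_names) != list(net2.node_names):
        raise ValueError("networks must share an identical node set/order")
    v1 = net1.edge_vector()
    v2 = net2.edge_vector()
    if v1.size < 3:
        raise ValueError("need at least 3 node pairs")
    if np.unique(v1).size < 2 or np.unique(v2).size < 2:
        raise ValueError("edge-weight vector is constant; rho undefined")
    res = stats.spearmanr(v1, v2)
    return float(res.statistic), float(res.pvalue)
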