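"""Model/Results interface for partial-correlation network analysis.

Usage follows the fit-then-inspect idiom::

    model = QolNetworkModel.from_cohort(table, timepoint="M0", nodes=nodes)
    res = model.fit()                       # EBIC-glasso network
    print(res.summary())
    cent = res.centrality()                 # strength / closeness / betweenness
    part = res.communities(seed=0)          # best-modularity partition
    stab = res.stability(B=1000, seed=0)    # bootstrap accuracy + CS
    diff = res.difference(other_res)        # change network vs another fit

The model holds the data and estimation settings; the results object
carries the selected network, the correlation input, and hangs the
diagnostic machinery off it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .comparison import DifferenceNetwork, difference_network, edge_weight_correlation
from .correlation import CorrelationMatrix
from .estimator import NetworkEstimator
from .glasso import GGMNetwork, ebicglasso_path
from .metrics import CommunityPartition, centralities, detect_communities
from .stability import (
    DEFAULT_DROP_GRID,
    StabilityReport,
    stability_report,
)

__all__ = ["QolNetworkModel", "QolNetworkResults"]


class QolNetworkModel:
    """Gaussian graphical model of questionnaire scales at one time point.

    Parameters
    ----------
    scores : DataFrame
        Subjects-by-scales score matrix without missing values
        (reverse/impute upstream).
    gamma, n_lambda, lambda_min_ratio : float
        EBIC-glasso settings (see :func:`qolnet.glasso.ebicglasso_path`).
    """

    def __init__(
        self,
        scores: pd.DataFrame,
        gamma: float = 0.5,
        n_lambda: int = 100,
        lambda_min_ratio: float = 0.01,
        tol: float = 1e-6,
    ) -> None:
        if scores.isna().any().any():
            raise ValueError("scores contain missing values; impute first")
        self.scores = scores
        self.estimator = NetworkEstimator(
            gamma=gamma, n_lambda=n_lambda,
            lambda_min_ratio=lambda_min_ratio, tol=tol,
        )

    @classmethod
    def from_cohort(
        cls,
        table: CohortTable,
        timepoint: str,
        nodes: list[str] | None = None,
        **kwargs,
    ) -> "QolNetworkModel":
        scores = table.scores(timepoint)
        if nodes is not None:
            missing = [s for s in nodes if s not in scores.columns]
            if missing:
                raise ValueError(f"nodes not in cohort: {missing}")
            scores = scores[list(nodes)]
        return cls(scores, **kwargs)

    @property
    def nobs(self) -> int:
        return len(self.scores)

    def fit(self) -> "QolNetworkResults":
        """Estimate mixed correlations, run the glasso path, select by EBIC."""
        corr = self.estimator.correlation(self.scores)
        net = ebicglasso_path(
            corr,
            gamma=self.estimator.gamma,
            n_lambda=self.estimator.n_lambda,
            lambda_min_ratio=self.estimator.lambda_min_ratio,
            tol=self.estimator.tol,
        )
        return QolNetworkResults(model=self, correlation=corr, network=net)


@dataclass
class QolNetworkResults:
    """Fitted partial-correlation network plus diagnostics."""

    model: QolNetworkModel
    correlation: CorrelationMatrix
    network: GGMNetwork

    # -- convenience views -------------------------------------------------
    @property
    def weights(self) -> pd.DataFrame:
        return self.network.to_frame()

    @property
    def node_names(self) -> list[str]:
        return self.network.node_names

    def centrality(self) -> pd.DataFrame:
        return centralities(self.network)

    def communities(self, seed: int = 0) -> CommunityPartition:
        return detect_communities(self.network, seed=seed)

    def stability(
        self,
        B: int = 1000,
        seed: int = 0,
        proportions: tuple = DEFAULT_DROP_GRID,
    ) -> StabilityReport:
        return stability_report(
            self.model.scores,
            estimator=self.model.estimator,
            proportions=proportions,
            B=B,
            seed=seed,
        )

    def difference(self, other: "QolNetworkResults",
                   display_threshold: float = 0.04) -> DifferenceNetwork:
        return difference_network(self.network, other.network,
                                  display_threshold=display_threshold)

    def edge_correlation(self, other: "QolNetworkResults"):
        """Spearman rho (and p) between this and another fit's edges."""
        return edge_weight_correlation(self.network, other.network)

    def summary(self) -> str:
        net = self.network
        p = net.p
        n_pairs = p * (p - 1) // 2
        meth = self.correlation.methods_frame().to_numpy()
        iu = np.triu_indices(p, 1)
        counts = pd.Series(meth[iu]).value_counts().to_dict()
        top = net.edge_list().reindex(
            net.edge_list()["weight"].abs().sort_values(ascending=False).index
        ).head(5)
        lines = [
            "Regularized partial-correlation network (EBIC-glasso)",
            "=" * 56,
            f"nodes: {p}    n subjects: {net.n}    gamma: {net.gamma}",
            f"selected lambda: {net.lambda_selected:.4f}",
            f"edges: {net.edge_count} / {n_pairs} possible "
            f"({net.edge_count / n_pairs:.1%})",
            f"global strength (sum |w|): {net.global_strength:.3f}",
            "correlation methods: "
            + ", ".join(f"{k}={v}" for k, v in sorted(counts.items())),
            f"PSD repair applied: {self.correlation.pd_repaired} "
            f"(min eigenvalue before: {self.correlation.min_eigenvalue_before:.2e})",
            "strongest edges:",
        ]
        for _, r in top.iterrows():
            lines.append(f"  {r['node_i']} -- {r['node_j']}: {r['weight']:+.3f}")
        return "\n".join(lines)
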