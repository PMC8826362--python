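"""One-call network estimation: mixed correlations + EBIC-glasso.

:class:`NetworkEstimator` bundles the two estimation stages and their
settings so that resampling procedures (bootstrap, permutation) can rerun
the identical pipeline thousands of times.  Variable-type classification
is done once on the full sample and frozen for all resamples, both for
speed and so that a resample cannot silently switch a scale between the
Pearson and polychoric treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .correlation import (
    CorrelationMatrix,
    classify_variable,
    mixed_matrix,
    nearest_correlation,
    _corr_array,
)
from .glasso import GGMNetwork, ebicglasso_path

__all__ = ["NetworkEstimator"]


@dataclass(frozen=True)
class NetworkEstimator:
    """Settings for the correlation + glasso estimation pipeline."""

    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    tol: float = 1e-6
    max_iter: int = 500
    eig_floor: float = 1e-8

    def correlation(self, scores: pd.DataFrame) -> CorrelationMatrix:
        return mixed_matrix(scores, eig_floor=self.eig_floor)

    def fit(self, scores: pd.DataFrame, keep_path: bool = True) -> GGMNetwork:
        """Estimate the network from a subjects-by-scales frame."""
        S = self.correlation(scores)
        return ebicglasso_path(
            S,
            gamma=self.gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            tol=self.tol,
            max_iter=self.max_iter,
            keep_path=keep_path,
        )

    # -- fast array-level interface for resampling loops -------------------
    def classify(self, X: np.ndarray) -> list[str]:
        return [classify_variable(X[:, j]) for j in range(X.shape[1])]

    def fit_array(self, X: np.ndarray, kinds: list[str]) -> np.ndarray:
        """Weight matrix only, no report objects (hot-loop variant)."""
        R = _corr_array(X, kinds)
        R, _, _ = nearest_correlation(R, eig_floor=self.eig_floor)
        net = ebicglasso_path(
            R,
            n=X.shape[0],
            gamma=self.gamma,
            n_lambda=self.n_lambda,
            lambda_min_ratio=self.lambda_min_ratio,
            tol=self.tol,
            max_iter=self.max_iter,
            keep_path=False,
        )
        return net.weights
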