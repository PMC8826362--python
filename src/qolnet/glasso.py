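"""Sparse Gaussian graphical model estimation: glasso path + EBIC selection.

The network of interest is the regularized partial-correlation network: an
L1-penalized precision matrix Theta is fitted over a descending log-spaced
penalty path, the penalty is chosen by minimizing the extended Bayesian
information criterion

    EBIC = -n [log det Theta - tr(S Theta)] + E log n + 4 E gamma log p,

with E the number of nonzero upper-triangle entries of Theta, and edge
weights are the partial correlations of the selected penalized fit,
w_ij = -Theta_ij / sqrt(Theta_ii Theta_jj).  gamma = 0.5 is the
conventional choice, trading a few weak true edges for far fewer spurious
ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _fast
from .correlation import CorrelationMatrix

__all__ = ["GGMNetwork", "graphical_lasso", "ebic", "ebicglasso_path", "kkt_residuals"]


def _as_matrix(S) -> tuple[np.ndarray, list[str] | None, int | None]:
    if isinstance(S, CorrelationMatrix):
        return np.asarray(S.values, dtype=float), list(S.node_names), S.n or None
    return np.asarray(S, dtype=float), None, None


@dataclass
class GGMNetwork:
    """A regularized partial-correlation network.

    ``weights`` is the symmetric partial-correlation matrix with zero
    diagonal; ``precision`` the penalized precision it was derived from.
    ``ebic_path`` records (lambda, edge count, log-likelihood, EBIC) for
    every penalty on the path.
    """

    node_names: list[str]
    weights: np.ndarray
    precision: np.ndarray
    lambda_selected: float
    gamma: float
    n: int
    ebic_path: pd.DataFrame | None = None

    @property
    def p(self) -> int:
        return len(self.node_names)

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, 1)
        return int(np.count_nonzero(self.weights[iu]))

    @property
    def global_strength(self) -> float:
        """Sum of absolute edge weights over the upper triangle."""
        iu = np.triu_indices(self.p, 1)
        return float(np.abs(self.weights[iu]).sum())

    def edge_vector(self) -> np.ndarray:
        """Upper-triangle weights in a fixed (row-major) order."""
        iu = np.triu_indices(self.p, 1)
        return self.weights[iu].copy()

    def node_strength(self) -> pd.Series:
        s = np.abs(self.weights).sum(axis=1)
        return pd.Series(s, index=self.node_names, name="strength")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.node_names, columns=self.node_names)

    def edge_list(self, threshold: float = 0.0) -> pd.DataFrame:
        rows = []
        for i in range(self.p):
            for j in range(i + 1, self.p):
                w = self.weights[i, j]
                if w != 0.0 and abs(w) > threshold:
                    rows.append(
                        {"node_i": self.node_names[i], "node_j": self.node_names[j],
                         "weight": w}
                    )
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])


def graphical_lasso(
    S, lam: float, tol: float = 1e-6, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the glasso problem at one penalty.

    Maximizes ``log det T - tr(S T) - lam * sum_{i!=j} |T_ij|`` (diagonal
    unpenalized).  Returns (precision, covariance_estimate); raises on
    non-convergence with the residual reported.
    """
    S, _, _ = _as_matrix(S)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Theta, W, it = _fast.glasso(S, float(lam), tol, max_iter)
    if it >= max_iter:
        resid = kkt_residuals(Theta, S, lam)
        raise RuntimeError(
            f"glasso did not converge in {max_iter} iterations "
            f"(KKT residual {max(resid):.3g})"
        )
    return Theta, W


def kkt_residuals(Theta: np.ndarray, S: np.ndarray, lam: float) -> tuple[float, float]:
    """(zero-entry, nonzero-entry) KKT residuals of a glasso solution.

    At an optimum, |S_ij - W_ij| <= lam where Theta_ij = 0 and
    S_ij - W_ij = -lam * sign(Theta_ij) otherwise (W = inverse(Theta),
    off-diagonal entries).  Returns the worst violation of each condition.
    """
    W = np.linalg.inv(Theta)
    R = S - W
    off = ~np.eye(Theta.shape[0], dtype=bool)
    zero = off & (Theta == 0)
    nonzero = off & (Theta != 0)
    r_zero = float(np.max(np.abs(R[zero]) - lam)) if zero.any() else -lam
    r_nz = (
        float(np.max(np.abs(R[nonzero] + lam * np.sign(Theta[nonzero]))))
        if nonzero.any()
        else 0.0
    )
    return max(r_zero, 0.0), r_nz


def ebic(precision: np.ndarray, S, n: int, gamma: float) -> float:
    """Extended BIC of a fitted precision matrix.

    ``-n [log det T - tr(S T)] + E log n + 4 E gamma log p``; gamma = 0
    reduces to the ordinary BIC.  Raises if the precision is not SPD.
    """
    S, _, _ = _as_matrix(S)
    Theta = np.asarray(precision, dtype=float)
    sign, logdet = np.linalg.slogdet(Theta)
    if sign <= 0:
        raise ValueError("precision must be positive definite")
    ev_min = np.linalg.eigvalsh(Theta).min()
    if ev_min <= 0:
        raise ValueError("precision must be positive definite")
    p = Theta.shape[0]
    iu = np.triu_indices(p, 1)
    E = int(np.count_nonzero(Theta[iu]))
    loglik = logdet - float(np.sum(S * Theta))
    return float(-n * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p))


def pcor_from_precision(Theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(Theta))
    P = -Theta / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    return P


def ebicglasso_path(
    S,
    n: int | None = None,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    node_names: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    keep_path: bool = True,
) -> GGMNetwork:
    """Fit a glasso path and return the EBIC-minimizing network.

    The penalty path is log-spaced from ``lambda_max`` (the largest
    absolute off-diagonal of S, at which the model is empty) down to
    ``lambda_max * lambda_min_ratio``, fitted large-to-small.  The selected
    network's edge weights are the partial correlations of the penalized
    precision.  Individual non-converged fits are skipped; the whole path
    failing raises.
    """
    Sm, names, n_from_S = _as_matrix(S)
    p = Sm.shape[0]
    if node_names is None:
        node_names = names or [f"V{i}" for i in range(p)]
    if n is None:
        n = n_from_S
    if n is None:
        raise ValueError("sample size n is required")
    if n <= p:
        warnings.warn(f"n={n} <= p={p}: estimates will be heavily regularized",
                      stacklevel=2)
    iu = np.triu_indices(p, 1)
    lam_max = float(np.max(np.abs(Sm[iu]))) if p > 1 else 1.0
    if lam_max == 0.0:
        lam_max = 1e-4
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    Thetas, logdets, traces, iters = _fast.glasso_path(
        Sm, lambdas, tol, max_iter
    )
    E = np.count_nonzero(Thetas[:, iu[0], iu[1]], axis=1)
    loglik = logdets - traces
    scores = -n * loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p)
    valid = np.isfinite(scores) & (iters < max_iter)
    if not valid.any():
        raise RuntimeError(f"all {n_lambda} glasso fits failed on the path")
    scores_masked = np.where(valid, scores, np.inf)
    k = int(np.argmin(scores_masked))
    lam_sel, Theta_sel = lambdas[k], Thetas[k]
    path = None
    if keep_path:
        path = pd.DataFrame(
            {"lambda": lambdas, "edges": E, "loglik": loglik, "ebic": scores,
             "converged": valid}
        )
    weights = pcor_from_precision(Theta_sel)
    return GGMNetwork(
        node_names=list(node_names),
        weights=weights,
        precision=Theta_sel,
        lambda_selected=float(lam_sel),
        gamma=gamma,
        n=int(n),
        ebic_path=path,
    )
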