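"""Mixed-type correlation matrices: Pearson, polyserial, polychoric.

Questionnaire scales are a mix of (near-)continuous multi-item scores and
coarse single-item ordinal scores.  Following the usual latent-normal
treatment, a variable with fewer than 7 distinct observed values is taken
as ordinal, and pairwise correlations are estimated as

* Pearson for continuous-continuous,
* polyserial (two-step ML) for continuous-ordinal,
* polychoric (two-step ML) for ordinal-ordinal,

where "two-step" means the normal thresholds are fixed at the inverse-CDF
of the marginal cumulative proportions and only the latent correlation is
optimized.  The assembled matrix need not be positive semidefinite; it is
repaired by eigenvalue clipping and rescaling to a unit diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import _fast
from .cohort import CohortTable

__all__ = [
    "classify_variable",
    "polychoric",
    "polyserial",
    "nearest_correlation",
    "mixed_matrix",
    "CorrelationMatrix",
    "ORDINAL_LEVEL_RULE",
]

#: variables with fewer distinct observed values than this are ordinal
ORDINAL_LEVEL_RULE = 7

_RHO_BOUND = 0.999


def classify_variable(values) -> str:
    """'ordinal' iff the number of distinct observed values is < 7."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    n_distinct = np.unique(v).size
    if n_distinct < 2:
        raise ValueError("constant column: cannot classify or correlate")
    return "ordinal" if n_distinct < ORDINAL_LEVEL_RULE else "continuous"


def _thresholds(codes: np.ndarray, n_cat: int) -> np.ndarray:
    """Normal thresholds from marginal cumulative proportions."""
    counts = np.bincount(codes, minlength=n_cat).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    return stats.norm.ppf(cum)


def _codes(values: np.ndarray) -> tuple[np.ndarray, int]:
    cats, codes = np.unique(values, return_inverse=True)
    return codes.astype(np.int64), cats.size


def _maximize_rho(nll) -> float:
    res = optimize.minimize_scalar(
        nll, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    if abs(rho) >= _RHO_BOUND - 1e-6:
        warnings.warn(
            "latent correlation at the boundary; association is (near) "
            "perfect, estimate clamped",
            stacklevel=3,
        )
    return rho


def polychoric(x, y) -> float:
    """Two-step polychoric correlation between two ordinal variables."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    cx, nx = _codes(x[ok])
    cy, ny = _codes(y[ok])
    if nx < 2 or ny < 2:
        raise ValueError("polychoric needs >= 2 observed categories per variable")
    counts = np.zeros((nx, ny))
    np.add.at(counts, (cx, cy), 1.0)
    tau_x = _thresholds(cx, nx)
    tau_y = _thresholds(cy, ny)
    return _maximize_rho(
        lambda r: _fast.polychoric_nll(counts, tau_x, tau_y, float(r))
    )


def polyserial(x, y) -> float:
    """Two-step polyserial correlation: x continuous, y ordinal.

    Thresholds come from y's marginals; rho maximizes the conditional
    likelihood of the categories given standardized x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if np.std(x) == 0:
        raise ValueError("continuous variable is constant")
    cy, ny = _codes(y)
    if ny < 2:
        raise ValueError("polyserial needs >= 2 observed categories")
    z = (x - x.mean()) / x.std()
    tau = _thresholds(cy, ny)
    return _maximize_rho(lambda r: _fast.polyserial_nll(z, cy, tau, float(r)))


def nearest_correlation(
    R: np.ndarray, eig_floor: float = 1e-8
) -> tuple[np.ndarray, bool, float]:
    """Repair a symmetric matrix to a PSD correlation matrix.

    Eigenvalues below ``eig_floor`` are clipped up to it and the result is
    rescaled to a unit diagonal.  Returns (repaired, was_repaired,
    min_eigenvalue_before).  A no-op (input returned, flag False) when the
    matrix already satisfies the floor.
    """
    R = np.asarray(R, dtype=float)
    w, V = np.linalg.eigh((R + R.T) / 2.0)
    min_eig = float(w.min())
    if min_eig >= eig_floor:
        return R, False, min_eig
    w = np.clip(w, eig_floor, None)
    fixed = (V * w) @ V.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True, min_eig


def _corr_array(
    X: np.ndarray,
    kinds: list[str],
    names: list[str] | None = None,
    return_methods: bool = False,
):
    """Raw mixed-type correlation matrix for a complete-data array.

    ``kinds[j]`` is 'ordinal' or 'continuous' for column j.  No PSD repair
    is applied here.
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if names is None:
        names = [f"V{j}" for j in range(p)]
    methods = np.full((p, p), "", dtype=object)
    if all(k == "continuous" for k in kinds) and not np.isnan(X).any():
        R = np.corrcoef(X.T)
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
        methods[~np.eye(p, dtype=bool)] = "pearson"
        return (R, methods) if return_methods else R
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            xi, xj = X[:, i], X[:, j]
            ki, kj = kinds[i], kinds[j]
            try:
                if ki == "continuous" and kj == "continuous":
                    ok = ~np.isnan(xi) & ~np.isnan(xj)
                    r = float(stats.pearsonr(xi[ok], xj[ok]).statistic)
                    m = "pearson"
                elif ki == "ordinal" and kj == "ordinal":
                    r = polychoric(xi, xj)
                    m = "polychoric"
                elif ki == "continuous":
                    r = polyserial(xi, xj)
                    m = "polyserial"
                else:
                    r = polyserial(xj, xi)
                    m = "polyserial"
            except ValueError as err:
                raise ValueError(
                    f"correlation failed for pair ({names[i]}, {names[j]}): {err}"
                ) from err
            R[i, j] = R[j, i] = r
            methods[i, j] = methods[j, i] = m
    return (R, methods) if return_methods else R


@dataclass
class CorrelationMatrix:
    """Symmetric mixed-type correlation matrix with method provenance."""

    node_names: list[str]
    values: np.ndarray
    methods: np.ndarray  # per-pair labels: pearson / polyserial / polychoric
    pd_repaired: bool = False
    min_eigenvalue_before: float = np.nan
    n: int = 0

    @property
    def p(self) -> int:
        return len(self.node_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.node_names, columns=self.node_names)

    def methods_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.methods, index=self.node_names, columns=self.node_names)


def mixed_matrix(
    scores: pd.DataFrame | CohortTable,
    nodes: list[str] | None = None,
    timepoint: str | None = None,
    eig_floor: float = 1e-8,
) -> CorrelationMatrix:
    """Assemble the mixed Pearson/polyserial/polychoric matrix.

    ``scores`` is a subjects-by-scales frame (post-imputation: no missing
    values) or a :class:`CohortTable` with ``timepoint`` given.  The
    per-pair method follows :func:`classify_variable`; the matrix is
    PSD-repaired if needed and the repair recorded.
    """
    if isinstance(scores, CohortTable):
        if timepoint is None:
            raise ValueError("timepoint required when passing a CohortTable")
        scores = scores.scores(timepoint)
    if nodes is not None:
        missing = [s for s in nodes if s not in scores.columns]
        if missing:
            raise ValueError(f"nodes not in table: {missing}")
        scores = scores[nodes]
    nodes = list(scores.columns)
    X = scores.to_numpy(dtype=float)
    p = len(nodes)
    kinds = {}
    for j, name in enumerate(nodes):
        try:
            kinds[name] = classify_variable(X[:, j])
        except ValueError as err:
            raise ValueError(f"scale {name!r}: {err}") from err
    R, methods = _corr_array(
        X, [kinds[n] for n in nodes], names=nodes, return_methods=True
    )
    repaired, flag, min_eig = nearest_correlation(R, eig_floor=eig_floor)
    return CorrelationMatrix(
        node_names=nodes,
        values=repaired,
        methods=methods,
        pd_repaired=flag,
        min_eigenvalue_before=min_eig,
        n=len(scores),
    )
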