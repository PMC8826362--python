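"""Synthetic two-timepoint questionnaire cohorts with known network truth.

Data are generated from a latent Gaussian copula: a sparse precision
matrix defines the true partial-correlation network; latent multivariate
normal vectors are drawn per subject at each time point (correlated across
time points coordinate-wise), then pushed through per-scale margins —
affine for continuous scales, equal-probability threshold discretization
for ordinal ones — onto the instrument's reporting scale.  Missingness is
MCAR at a fixed expected cell rate.

Because the truth (support and signed partial correlations) is known
exactly, every downstream stage — screening, mixed correlations,
EBIC-glasso, stability, network comparison — can be validated for recovery
and calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .cohort import CohortTable, ScaleDefinition
import pandas as pd

__all__ = ["PrecisionSpec", "make_precision_spec", "generate_cohort"]


def _pcor_from_precision(precision: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(precision))
    p = -precision / np.outer(d, d)
    np.fill_diagonal(p, 0.0)
    return p


@dataclass
class PrecisionSpec:
    """Ground-truth precision matrix for a latent Gaussian network.

    ``true_pcor`` is the implied partial-correlation matrix
    -Theta_ij / sqrt(Theta_ii * Theta_jj) with a zero diagonal; its zero
    pattern coincides with the off-diagonal zero pattern of ``precision``.
    """

    node_names: list[str]
    precision: np.ndarray
    density: float = field(default=0.0)

    def __post_init__(self) -> None:
        P = np.asarray(self.precision, dtype=float)
        if P.shape[0] != P.shape[1] or P.shape[0] != len(self.node_names):
            raise ValueError("precision shape must match node_names")
        if not np.allclose(P, P.T, atol=1e-12):
            raise ValueError("precision must be symmetric")
        ev = np.linalg.eigvalsh(P)
        if ev.min() <= 0:
            raise ValueError(f"precision not positive definite (min eig {ev.min():.3g})")
        self.precision = P

    @property
    def p(self) -> int:
        return len(self.node_names)

    @property
    def true_pcor(self) -> np.ndarray:
        return _pcor_from_precision(self.precision)

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    @property
    def latent_correlation(self) -> np.ndarray:
        """Marginal correlation matrix of the latent Gaussian."""
        C = self.covariance
        d = np.sqrt(np.diag(C))
        return C / np.outer(d, d)

    def support(self) -> np.ndarray:
        """Boolean upper-triangle-symmetric matrix of true edges."""
        s = self.precision != 0
        np.fill_diagonal(s, False)
        return s


def make_precision_spec(
    p: int,
    density: float,
    weight_range: tuple[float, float] = (0.25, 0.45),
    seed: int = 0,
    node_names: list[str] | None = None,
) -> PrecisionSpec:
    """Draw a random sparse SPD precision matrix with given edge density.

    Off-diagonal support is a uniform random subset of the C(p,2) pairs of
    size round(density * C(p,2)); entries get magnitudes uniform in
    ``weight_range`` with random signs (negative precision entries give
    positive partial correlations, the common case for questionnaire
    scales, so signs are drawn 75% negative).  Positive definiteness is
    guaranteed by an eigenvalue shift followed by rescaling to a unit
    diagonal, which preserves the support and the sign pattern.
    """
    if not 2 <= p <= 50:
        raise ValueError("p must be in [2, 50]")
    if not 0 <= density <= 1:
        raise ValueError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, 1)
    n_pairs = len(iu[0])
    n_edges = int(round(density * n_pairs))
    A = np.zeros((p, p))
    if n_edges:
        pick = rng.choice(n_pairs, size=n_edges, replace=False)
        mags = rng.uniform(*weight_range, size=n_edges)
        signs = np.where(rng.random(n_edges) < 0.75, -1.0, 1.0)
        A[iu[0][pick], iu[1][pick]] = signs * mags
        A += A.T
    Theta = A + np.eye(p)
    ev = np.linalg.eigvalsh(Theta)
    if ev.min() < 0.1:
        Theta += (0.1 - ev.min()) * np.eye(p)
    d = np.sqrt(np.diag(Theta))
    Theta = Theta / np.outer(d, d)
    if node_names is None:
        node_names = [f"scale_{i:02d}" for i in range(p)]
    return PrecisionSpec(
        node_names=list(node_names),
        precision=Theta,
        density=n_edges / n_pairs if n_pairs else 0.0,
    )


def _resolve(value, timepoint, default):
    if value is None:
        return default
    if isinstance(value, dict):
        return value[timepoint]
    return float(value)


def _clipped_normal_moments(m: float, s: float, lo: float, hi: float):
    a = (lo - m) / s
    b = (hi - m) / s
    Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    mid = Fb - Fa
    mean = lo * Fa + hi * (1.0 - Fb) + m * mid + s * (fa - fb)
    ez2 = (
        lo * lo * Fa
        + hi * hi * (1.0 - Fb)
        + m * m * mid
        + 2.0 * m * s * (fa - fb)
        + s * s * (mid + a * fa - b * fb)
    )
    var = max(ez2 - mean * mean, 0.0)
    return mean, np.sqrt(var)


@lru_cache(maxsize=512)
def _clipped_normal_params(mean: float, sd: float, lo: float, hi: float):
    """(m, s) of the pre-clip normal whose clip to [lo, hi] has the target
    mean/SD.  Bounded scales with means near a bound (ceiling effects) get
    a pre-clip mean beyond the bound and visible mass at it, as real
    questionnaire scales do.  Falls back to (mean, sd) if no solution."""

    def loss(q):
        m, logs = q
        mu, sig = _clipped_normal_moments(m, np.exp(logs), lo, hi)
        return [mu - mean, sig - sd]

    try:
        sol = optimize.least_squares(
            loss, x0=[mean, np.log(sd)], xtol=1e-12, ftol=1e-12
        )
        m, s = float(sol.x[0]), float(np.exp(sol.x[1]))
        mu, sig = _clipped_normal_moments(m, s, lo, hi)
        if abs(mu - mean) < 0.05 and abs(sig - sd) < 0.05:
            return m, s
    except Exception:
        pass
    return float(mean), float(sd)


def _apply_margin(
    z: np.ndarray, d: ScaleDefinition, timepoint: str
) -> np.ndarray:
    """Map standard-normal latents to the scale's reporting values."""
    lo, hi = d.range
    if d.kind == "continuous":
        mean = _resolve(d.mean, timepoint, (lo + hi) / 2.0)
        sd = _resolve(d.sd, timepoint, (hi - lo) / 6.0)
        m, s = _clipped_normal_params(float(mean), float(sd), float(lo), float(hi))
        return np.clip(m + s * z, lo, hi)
    # ordinal: equal-probability cuts of the standard normal
    cuts = stats.norm.ppf(np.arange(1, d.levels) / d.levels)
    cat = np.searchsorted(cuts, z)
    return np.asarray(d.attainable_values())[cat]


def generate_cohort(
    spec: PrecisionSpec,
    scale_defs: list[ScaleDefinition],
    n: int,
    subject_corr: float = 0.5,
    missing_rate: float = 0.0,
    seed: int = 0,
    timepoints: tuple[str, str] = ("M0", "M12"),
) -> CohortTable:
    """Simulate a paired two-timepoint cohort from a latent network.

    Latent vectors are N(0, Sigma) with Sigma the correlation matrix
    implied by ``spec.precision``; the two time points share the latent
    network and are paired coordinate-wise with correlation
    ``subject_corr``.  Each subject has its own deterministic random
    substream, so enlarging ``n`` leaves earlier subjects' data unchanged.

    Returns a :class:`CohortTable`; missing cells (MCAR at expected rate
    ``missing_rate``) are NaN.
    """
    if len(scale_defs) != spec.p:
        raise ValueError("scale_defs length must equal spec node count")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if not 0 <= subject_corr < 1:
        raise ValueError("subject_corr must be in [0, 1)")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    Sigma = spec.latent_correlation
    L = np.linalg.cholesky(Sigma)
    p = spec.p
    c = subject_corr
    tp0, tp1 = timepoints
    Z = np.empty((2, n, p))
    miss = np.empty((2, n, p), dtype=bool)
    for i in range(n):
        srng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        z0 = L @ srng.standard_normal(p)
        e = L @ srng.standard_normal(p)
        Z[0, i] = z0
        Z[1, i] = c * z0 + np.sqrt(1 - c * c) * e
        miss[:, i, :] = srng.random((2, p)) < missing_rate
    scores = np.empty((2, n, p))
    for t, tp in enumerate((tp0, tp1)):
        for j, d in enumerate(scale_defs):
            scores[t, :, j] = _apply_margin(Z[t, :, j], d, tp)
    scores[miss] = np.nan
    subjects = [f"S{i:05d}" for i in range(n)]
    frames = []
    for t, tp in enumerate((tp0, tp1)):
        frames.append(
            pd.DataFrame(
                scores[t],
                index=pd.MultiIndex.from_tuples(
                    [(s, tp) for s in subjects], names=["subject_id", "timepoint"]
                ),
                columns=[d.name for d in scale_defs],
            )
        )
    data = pd.concat(frames).sort_index()
    return CohortTable(data, scale_defs, timepoint_order=list(timepoints))
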