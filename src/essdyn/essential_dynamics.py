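"""Essential dynamics: PCA of the coordinate matrix with component retention.

The coordinate matrix (frames x 3N) is optionally standardized column-wise
(correlation-matrix PCA, the default) or merely centered (classical
covariance-based essential dynamics).  The decomposition is computed through
an SVD of the centered data, which is exact and much faster than forming the
3N x 3N covariance when frames << columns.  Component retention follows
Horn's parallel analysis: observed eigenvalues are kept while they exceed a
chosen percentile of eigenvalues obtained from column-wise permuted (or
Gaussian) null data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError
from .trajectory import CoordinateMatrix

__all__ = [
    "EssentialDynamicsResult",
    "ParallelAnalysisResult",
    "StandardizationInfo",
    "standardize_columns",
    "pca",
    "parallel_analysis",
    "scree_data",
]


@dataclass
class StandardizationInfo:
    mean: np.ndarray
    sd: np.ndarray
    zero_variance_columns: np.ndarray  # boolean mask


@dataclass
class EssentialDynamicsResult:
    """Eigen-decomposition of the coordinate covariance/correlation.

    ``loadings`` are unit-norm eigenvectors (3N x k); ``scores`` are the
    centered data projected onto them (frames x k), so the sample variance of
    score column c equals ``eigenvalues[c]``.  ``variance_proportion`` sums
    to 1 over the full spectrum.  Sign convention: each loading column is
    flipped so its largest-magnitude entry is positive.
    """

    eigenvalues: np.ndarray
    variance_proportion: np.ndarray
    cumulative_proportion: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    k_retained: int
    standardized: bool
    column_labels: list[tuple[int, str]] = field(default_factory=list)
    frame_labels: list[tuple[int, float]] = field(default_factory=list)


@dataclass
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    noise_percentiles: np.ndarray
    k_retained: int
    n_draws: int
    percentile: float
    seed: int
    method: str


def standardize_columns(
    m: CoordinateMatrix,
) -> tuple[CoordinateMatrix, StandardizationInfo]:
    """Scale every column to mean 0, sample sd 1.

    Zero-variance columns are left at 0 and flagged rather than divided by
    zero; they carry no motion information.
    """
    if m.n_frames < 2:
        raise DataError("standardization requires at least 2 frames")
    mean = m.values.mean(axis=0)
    sd = m.values.std(axis=0, ddof=1)
    zero = sd <= 1e-300
    safe_sd = np.where(zero, 1.0, sd)
    values = (m.values - mean) / safe_sd
    values[:, zero] = 0.0
    out = CoordinateMatrix(
        values=values,
        column_labels=list(m.column_labels),
        frame_labels=list(m.frame_labels),
        standardized=True,
    )
    return out, StandardizationInfo(mean=mean, sd=sd, zero_variance_columns=zero)


def _spectrum(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered SVD -> (eigenvalues over full column count, scores, loadings)."""
    n, p = values.shape
    centered = values - values.mean(axis=0)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    eig = s**2 / (n - 1)
    full_eig = np.zeros(p)
    full_eig[: eig.size] = eig
    scores = U * s
    loadings = Vt.T
    return full_eig, scores, loadings


def pca(m: CoordinateMatrix, mode: str | None = None) -> EssentialDynamicsResult:
    """Principal component analysis of a coordinate matrix.

    ``mode='correlation'`` standardizes columns first (the default for raw
    input); ``mode='covariance'`` centers only — classical essential
    dynamics.  If the matrix is already standardized it is used as-is.
    """
    if not np.all(np.isfinite(m.values)):
        raise DataError("coordinate matrix contains non-finite entries")
    if m.n_frames < 2:
        raise DataError("PCA requires at least 2 frames")
    standardized = m.standardized
    values = m.values
    if mode is None:
        mode = "correlation" if not standardized else "as-is"
    if mode == "correlation" and not standardized:
        std, _ = standardize_columns(m)
        values = std.values
        standardized = True
    elif mode == "covariance":
        standardized = False

    eigenvalues, scores, loadings = _spectrum(values)
    # deterministic sign: largest-|entry| of each loading column positive
    flip = np.sign(loadings[np.argmax(np.abs(loadings), axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = scores * flip

    total = eigenvalues.sum()
    prop = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return EssentialDynamicsResult(
        eigenvalues=eigenvalues,
        variance_proportion=prop,
        cumulative_proportion=np.cumsum(prop),
        scores=scores,
        loadings=loadings,
        k_retained=int(min(scores.shape[1], eigenvalues.size)),
        standardized=standardized,
        column_labels=list(m.column_labels),
        frame_labels=list(m.frame_labels),
    )


def parallel_analysis(
    m: CoordinateMatrix,
    n_draws: int = 100,
    percentile: float = 0.95,
    seed: int = 0,
    method: str = "permutation",
) -> ParallelAnalysisResult:
    """Horn's parallel analysis for component retention.

    Null eigenvalue spectra come from ``n_draws`` datasets with the observed
    marginal structure destroyed: ``method='permutation'`` permutes each
    column independently; ``method='normal'`` draws i.i.d. standard normals
    of the same shape.  A component is retained while its observed eigenvalue
    exceeds the per-rank noise percentile, stopping at the first failure.
    """
    import warnings as _warnings

    if not m.standardized:
        raise DataError("parallel analysis expects a standardized matrix")
    if n_draws < 10:
        _warnings.warn(
            f"n_draws={n_draws} gives unstable noise percentiles",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n, p = m.values.shape
    rank = min(n - 1, p)
    observed, _, _ = _spectrum(m.values)
    observed = observed[:rank]
    noise = np.empty((n_draws, rank))
    for d in range(n_draws):
        if method == "permutation":
            null = rng.permuted(m.values, axis=0)
        elif method == "normal":
            null = rng.standard_normal((n, p))
        else:
            raise ValueError(f"unknown method {method!r}")
        null_eig, _, _ = _spectrum(null)
        noise[d] = null_eig[:rank]
    thresholds = np.quantile(noise, percentile, axis=0)
    k = 0
    for obs, thr in zip(observed, thresholds):
        if obs > thr:
            k += 1
        else:
            break
    return ParallelAnalysisResult(
        observed_eigenvalues=observed,
        noise_percentiles=thresholds,
        k_retained=k,
        n_draws=n_draws,
        percentile=percentile,
        seed=seed,
        method=method,
    )


def scree_data(res: EssentialDynamicsResult, n_show: int = 10) -> pd.DataFrame:
    """First ``n_show`` components as (component, eigenvalue, proportion,
    cumulative proportion %) — the layout of a PCA summary table."""
    rank = int(np.sum(res.eigenvalues > 0)) or 1
    n = min(n_show, rank)
    return pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(n)],
            "eigenvalue": res.eigenvalues[:n],
            "proportion_of_variance": res.variance_proportion[:n],
            "cumulative_proportion_pct": 100.0 * res.cumulative_proportion[:n],
        }
    )
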