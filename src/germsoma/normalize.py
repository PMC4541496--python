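"""Expression filtering and precision-weighted log-transformation.

Implements the published voom formulation: counts become
``log2((count + 0.5) / (library + 1) * 1e6)``, optionally quantile
normalised across samples; gene-wise linear fits under the experimental
design give residual standard deviations, a lowess curve of
``sqrt(residual sd)`` against mean log-count models the mean-variance
trend, and each observation's precision weight is the predicted standard
deviation to the power -4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .io import CountMatrix


def design_matrix(samples: pd.DataFrame, by: str = "condition") -> pd.DataFrame:
    """Cell-means design matrix (one indicator column per condition).

    ``by='condition'`` combines genotype and rnai into a single factor;
    otherwise ``by`` names a column of the sample sheet.
    """
    if by == "condition":
        labels = (
            samples["genotype"].astype(str) + "/" + samples["rnai"].astype(str)
        )
    else:
        labels = samples[by].astype(str)
    design = pd.get_dummies(labels, dtype=float)
    design.index = samples.index
    return design


def cpm(counts: CountMatrix) -> pd.DataFrame:
    """Counts per million mapped reads."""
    lib = counts.library_sizes
    if (lib <= 0).any():
        bad = list(lib.index[lib <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    return counts.counts / lib * 1e6


def cpm_filter(
    counts: CountMatrix, min_cpm: float = 1.0, min_samples: int = 2
) -> CountMatrix:
    """Keep genes with CPM >= min_cpm in at least min_samples samples."""
    keep = (cpm(counts) >= min_cpm).sum(axis=1) >= min_samples
    return counts.subset_genes(counts.counts.index[keep])


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the mean empirical distribution.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; ties within a column receive the average of the values
    their tied ranks map to.
    """
    arr = values.to_numpy(dtype=float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    n = arr.shape[0]
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average")  # 1..n, ties averaged
        # fractional ranks interpolate between adjacent order statistics
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


@dataclass
class WeightedLogExpression:
    """log2-CPM matrix with per-observation precision weights.

    ``log_expr`` and ``weights`` are genes x samples DataFrames of equal
    shape; ``library_sizes`` records the per-sample totals used in the
    transform; ``design`` is the design matrix the mean-variance trend was
    estimated under.
    """

    log_expr: pd.DataFrame
    weights: pd.DataFrame
    library_sizes: pd.Series
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.log_expr.shape != self.weights.shape:
            raise ValueError("log_expr and weights shapes differ")
        w = self.weights.to_numpy()
        if not np.all(np.isfinite(w)) or (w <= 0).any():
            raise ValueError("weights must be strictly positive and finite")


def _ols_batch(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted per-gene OLS: coefficients and residual SD.

    X is samples x p, Y is genes x samples.  Returns (beta: genes x p,
    sigma: genes).
    """
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    df = n - np.linalg.matrix_rank(X)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma = np.sqrt((resid**2).sum(axis=0) / df)
    return beta.T, sigma


def voom_transform(
    counts: CountMatrix,
    design: pd.DataFrame | None = None,
    quantile: bool = True,
    span: float = 0.5,
) -> WeightedLogExpression:
    """Counts -> log2-CPM with mean-variance precision weights.

    ``design`` defaults to the condition cell-means matrix from the sample
    sheet.  ``span`` is the lowess smoothing fraction for the trend.
    """
    if design is None:
        design = design_matrix(counts.samples)
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    if n != counts.n_samples:
        raise ValueError("design rows must match samples")

    lib = counts.library_sizes.to_numpy(dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero library size")
    raw = counts.counts.to_numpy(dtype=float)
    y = np.log2((raw + 0.5) / (lib + 1.0) * 1e6)
    ydf = pd.DataFrame(y, index=counts.counts.index, columns=counts.counts.columns)
    if quantile:
        ydf = quantile_normalize(ydf)
        y = ydf.to_numpy()

    beta, sigma = _ols_batch(X, y)
    # mean log2-count per gene, recovered from mean log2-CPM
    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)
    trend = _lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]

    fitted = beta @ X.T  # genes x samples, fitted log2-CPM
    fitted_logcount = fitted + (np.log2(lib + 1.0) - np.log2(1e6))[None, :]
    pred_sqrt_sd = np.interp(fitted_logcount, tx, ty)  # clamps at the ends
    pred_sqrt_sd = np.maximum(pred_sqrt_sd, 1e-6)
    weights = pred_sqrt_sd**-4

    wdf = pd.DataFrame(weights, index=ydf.index, columns=ydf.columns)
    return WeightedLogExpression(ydf, wdf, counts.library_sizes, design)
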