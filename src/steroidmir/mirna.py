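"""Filtering, normalization and batch checking of miRNA count matrices.

Count matrices are pandas DataFrames with miRNAs on the rows and
subjects on the columns. Low-abundance miRNAs are dropped by the
"fewer than ``min_count`` reads in at least ``min_frac`` of subjects"
rule; normalization uses median-of-ratios size factors (the DESeq
estimator); batch effects are screened with guided PCA (gPCA), which
compares the variance captured along the batch-guided leading
direction with the unguided first principal component and calibrates
the ratio by permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import DegenerateInputError


@dataclass
class NormalizedMatrix:
    """Size-factor-scaled (and optionally log2(x+1)) expression matrix."""

    values: pd.DataFrame  # miRNA x subject
    size_factors: pd.Series  # per subject, > 0
    transform: str  # "none" or "log2p1"


@dataclass
class GpcaResult:
    delta: float
    p_value: float
    n_permutations: int
    var_guided: float
    var_unguided: float


def filter_low_counts(
    counts: pd.DataFrame, min_count: int = 5, min_frac: float = 0.5
) -> pd.DataFrame:
    """Drop miRNAs with < ``min_count`` reads in >= ``min_frac`` of subjects.

    The boundary is inclusive: a miRNA with exactly ``min_frac`` of its
    subjects below threshold is removed. Row/column order is preserved.
    """
    if counts.size == 0:
        raise ValueError("empty count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("count matrix has negative entries")
    frac_below = (counts < min_count).mean(axis=1)
    return counts.loc[frac_below < min_frac]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    factor_j = median over reference miRNAs of count_ij / geomean_i,
    where the reference set is every miRNA with a strictly positive
    geometric mean across subjects (i.e. no zero count).
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise DegenerateInputError(
            "no miRNA with all-positive counts; size factors undefined"
        )
    logx = np.log(x[positive])
    log_geomean = logx.mean(axis=1)
    log_ratios = logx - log_geomean[:, None]
    sf = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, transform: str = "log2p1") -> NormalizedMatrix:
    """Scale columns by size factors, then optionally log2(x + 1).

    log2(normalized + 1) is the predictor scale used by the downstream
    association stage: per-unit odds ratios then correspond to a
    doubling of normalized abundance, the scale on which small effects
    (OR ~ 1.05-1.25 per unit) are naturally expressed.
    """
    if transform not in ("none", "log2p1"):
        raise ValueError(f"unknown transform: {transform!r}")
    sf = size_factors(counts)
    vals = counts.astype(float) / sf
    if transform == "log2p1":
        vals = np.log2(vals + 1.0)
    return NormalizedMatrix(values=vals, size_factors=sf, transform=transform)


def _first_pc_var(X: np.ndarray) -> float:
    """Variance of sample scores along the first principal axis of X (n x p)."""
    s = np.linalg.svd(X, compute_uv=False)
    return float(s[0] ** 2 / (X.shape[0] - 1))


def _guided_var(X: np.ndarray, onehot: np.ndarray) -> float:
    """Variance of X's sample scores along the batch-guided direction.

    The guide direction is the leading right singular vector of Y'X,
    with Y the batch one-hot indicator: the feature-space axis along
    which batch means separate most.
    """
    M = onehot.T @ X
    _, _, vt = np.linalg.svd(M, full_matrices=False)
    scores = X @ vt[0]
    return float(scores.var(ddof=1))


def gpca_batch_test(
    matrix: NormalizedMatrix | pd.DataFrame,
    batch: pd.Series,
    n_permutations: int = 1000,
    seed: int = 0,
) -> GpcaResult:
    """Guided-PCA batch-effect test.

    delta = var(first guided PC) / var(first unguided PC), in [0, 1];
    p is the permutation tail probability of delta under random batch
    relabelling, with the add-one correction (p in the (b+1)/(B+1)
    grid). Samples are the matrix columns.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    batch = batch.loc[values.columns]
    levels, codes = np.unique(batch.to_numpy(), return_inverse=True)
    if len(levels) < 2:
        raise ValueError("gPCA needs >= 2 batches")
    if np.min(np.bincount(codes)) < 2:
        raise ValueError("every batch needs >= 2 subjects")

    X = values.to_numpy(dtype=float).T  # subjects x miRNAs
    X = X - X.mean(axis=0)
    if not np.any(np.abs(X) > 0):
        raise DegenerateInputError("constant expression matrix")

    var_u = _first_pc_var(X)
    onehot = np.eye(len(levels))[codes]
    var_g = _guided_var(X, onehot)
    delta = var_g / var_u

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _guided_var(X, np.eye(len(levels))[perm]) / var_u >= delta:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    return GpcaResult(
        delta=float(delta),
        p_value=float(p),
        n_permutations=n_permutations,
        var_guided=var_g,
        var_unguided=var_u,
    )
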