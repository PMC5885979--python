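"""Geometric mean of pairwise ratios (GMPR) size factors.

GMPR estimates the relative sequencing depth of each sample in a
zero-inflated count table in two steps.  For every ordered pair of samples
(*i*, *j*) it computes

    r_ij = median over { k : c_ki * c_kj != 0 } of c_ki / c_kj,

the median count ratio restricted to the features observed in both samples.
The size factor of sample *i* is then the geometric mean of its pairwise
ratios,

    s_i = ( prod_j r_ij )^(1/n),

with the self-ratio r_ii = 1 included.  Restricting each comparison to the
pairwise-shared features sidesteps the need for a global zero-free
reference, which sparse tables frequently lack; the median makes each
pairwise ratio robust to differential or outlier features, and the
geometric mean pools the pairwise evidence.

When two samples share fewer than ``min_shared`` nonzero features their
ratio is treated as undefined and simply dropped from the geometric mean
(the exponent becomes one over the number of defined ratios).  A sample
with no defined partner at all is an error rather than a silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NormalizationError, ValidationError
from .io import CountTable, SizeFactors, rescale_by_median

__all__ = [
    "PairwiseRatioMatrix",
    "pairwise_ratio",
    "pairwise_ratio_matrix",
    "gmpr_size_factors",
    "rescale_by_median",
]


@dataclass
class PairwiseRatioMatrix:
    """All pairwise median count ratios of a table.

    ``ratios[i, j]`` holds r_ij, or NaN where fewer than ``min_shared``
    features are nonzero in both samples.  The diagonal is always 1 (a
    sample compared with itself), and ``shared_counts[i, i]`` is the number
    of nonzero features of sample *i*.
    """

    sample_ids: list[str]
    ratios: np.ndarray
    shared_counts: np.ndarray
    min_shared: int


def pairwise_ratio(sample_i: np.ndarray, sample_j: np.ndarray, min_shared: int = 1) -> float:
    """Median ratio c_ki/c_kj over features nonzero in both samples.

    Returns NaN ("undefined") when fewer than ``min_shared`` features are
    shared.
    """
    x = np.asarray(sample_i, dtype=float)
    y = np.asarray(sample_j, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("count vectors must be 1-D and of equal length")
    if min_shared < 1:
        raise ValidationError("min_shared must be >= 1")
    shared = (x != 0) & (y != 0)
    if int(shared.sum()) < min_shared:
        return float("nan")
    return float(np.median(x[shared] / y[shared]))


def pairwise_ratio_matrix(table: CountTable, min_shared: int = 2) -> PairwiseRatioMatrix:
    """Compute every r_ij for a table.

    Both triangle entries are computed from the same shared set; note that
    with the midpoint median convention r_ij = 1/r_ji holds exactly only
    for odd shared-set sizes.
    """
    counts = table.counts.astype(float)
    n = table.n_samples
    nz = counts != 0
    ratios = np.full((n, n), np.nan)
    shared_counts = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(ratios, 1.0)
    np.fill_diagonal(shared_counts, nz.sum(axis=0))
    for i in range(n):
        ci = counts[:, i]
        for j in range(i + 1, n):
            shared = nz[:, i] & nz[:, j]
            m = int(shared.sum())
            shared_counts[i, j] = shared_counts[j, i] = m
            if m >= min_shared:
                q = ci[shared] / counts[shared, j]
                ratios[i, j] = np.median(q)
                ratios[j, i] = np.median(1.0 / q)
    return PairwiseRatioMatrix(list(table.sample_ids), ratios, shared_counts, min_shared)


def gmpr_size_factors(table: CountTable, min_shared: int = 2) -> SizeFactors:
    """GMPR size factors: geometric mean of defined pairwise median ratios.

    The geometric mean is taken in log space over the defined ratios of each
    sample, including the self-ratio r_ii = 1 (a factor of one that still
    counts in the exponent, matching the product-over-all-samples form).

    Raises
    ------
    NormalizationError
        If a sample has no nonzero count, or no defined ratio with any
        other sample (isolated support).
    """
    if table.n_samples < 2:
        raise NormalizationError("GMPR needs at least two samples")
    nnz = (table.counts > 0).sum(axis=0)
    empty = [table.sample_ids[i] for i in np.nonzero(nnz == 0)[0]]
    if empty:
        raise NormalizationError(f"all-zero samples cannot be normalized: {empty[:5]}")
    prm = pairwise_ratio_matrix(table, min_shared=min_shared)
    defined = np.isfinite(prm.ratios)
    off_diag = defined.copy()
    np.fill_diagonal(off_diag, False)
    isolated = [table.sample_ids[i] for i in np.nonzero(off_diag.sum(axis=1) == 0)[0]]
    if isolated:
        raise NormalizationError(
            "samples share fewer than "
            f"{min_shared} nonzero features with every other sample: {isolated[:5]}"
        )
    with np.errstate(invalid="ignore"):
        logr = np.where(defined, np.log(prm.ratios), 0.0)
    values = np.exp(logr.sum(axis=1) / defined.sum(axis=1))
    return SizeFactors(list(table.sample_ids), values, method="GMPR")
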