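"""Comparator size-factor methods: TSS, RLE(+), TMM(+), CSS.

These re-implement, on the :class:`~gmprnorm.io.CountTable` contract, the
standard normalizations GMPR is benchmarked against:

* **TSS** — total-sum scaling; the size factor is the library size itself.
* **RLE** — relative log expression (median-of-ratios): each sample is
  compared to a reference profile of per-feature geometric means, and the
  median ratio is the size factor.  Only zero-free features define the
  reference, so sparse tables can make RLE fail outright; the ``+`` variant
  adds a pseudo-count of 1 to every cell first.
* **TMM** — trimmed mean of M-values: log ratios against a reference
  *sample* are trimmed on both M (log ratio) and A (mean log abundance)
  and combined with precision weights; the scaled size factor is the TMM
  factor times the library size.
* **CSS** — cumulative-sum scaling: the size factor is the sum of each
  sample's counts up to a percentile chosen by a data-driven stability
  search on quantile profiles.  This is a reproducible CSS-compatible
  variant, not a bit-identical port of the original implementation.

``rle``/``tmm`` scaled factors follow the convention that the method's
relative normalization factor is multiplied by the total read count, so all
methods are comparable on one scale after median rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import NormalizationError, RLEFailureError, ValidationError
from .gmpr import gmpr_size_factors
from .io import CountTable, SizeFactors

__all__ = [
    "ReferenceProfile",
    "TMMConfig",
    "tss_size_factors",
    "rle_size_factors",
    "tmm_size_factors",
    "css_size_factors",
    "compute_size_factors",
    "METHODS",
]


@dataclass
class ReferenceProfile:
    """Per-feature geometric means over samples (the RLE reference).

    Defined only for features nonzero in every sample (or for all features
    after pseudo-count addition).
    """

    feature_ids: list[str]
    geometric_means: np.ndarray


@dataclass
class TMMConfig:
    log_ratio_trim: float = 0.30
    abs_expr_trim: float = 0.05
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        for t in (self.log_ratio_trim, self.abs_expr_trim):
            if not (0 <= t < 0.5):
                raise ValidationError("trim fractions must lie in [0, 0.5)")


def tss_size_factors(table: CountTable) -> SizeFactors:
    """Total-sum scaling: s_i = total read count of sample i."""
    totals = table.column_sums().astype(float)
    if np.any(totals <= 0):
        bad = [table.sample_ids[i] for i in np.nonzero(totals <= 0)[0]]
        raise NormalizationError(f"zero-total samples: {bad[:5]}")
    return SizeFactors(list(table.sample_ids), totals, method="TSS")


def reference_profile(table: CountTable, pseudo_count: float = 0.0) -> ReferenceProfile:
    counts = table.counts.astype(float) + pseudo_count
    if pseudo_count > 0:
        keep = np.ones(table.n_features, dtype=bool)
    else:
        keep = np.all(counts > 0, axis=1)
    gm = np.exp(np.mean(np.log(counts[keep]), axis=1))
    return ReferenceProfile([f for f, k in zip(table.feature_ids, keep) if k], gm)


def rle_size_factors(table: CountTable, pseudo_count: float = 0.0) -> SizeFactors:
    """Median-of-ratios size factors against a geometric-mean reference.

    With ``pseudo_count=0`` only zero-free features enter the reference;
    if there are none the method fails with :class:`RLEFailureError`.
    The direct median ratio already carries the depth scale (it equals the
    edgeR-style relative factor multiplied by the total read count), so it
    is returned as the scaled size factor.
    """
    if pseudo_count < 0:
        raise ValidationError("pseudo_count must be >= 0")
    ref = reference_profile(table, pseudo_count)
    if len(ref.feature_ids) == 0:
        raise RLEFailureError(
            "RLE fails: no feature is nonzero in every sample "
            "(use pseudo_count=1 for the RLE+ variant)"
        )
    counts = table.counts.astype(float) + pseudo_count
    keep = (
        np.ones(table.n_features, dtype=bool)
        if pseudo_count > 0
        else np.all(counts > 0, axis=1)
    )
    ratios = counts[keep] / ref.geometric_means[:, np.newaxis]
    values = np.median(ratios, axis=0)
    method = "RLE+" if pseudo_count > 0 else "RLE"
    if np.any(values <= 0):
        raise NormalizationError(f"{method} produced a non-positive size factor")
    return SizeFactors(list(table.sample_ids), values, method=method)


def _tmm_reference_index(counts: np.ndarray, totals: np.ndarray) -> int:
    # sample whose upper quartile of depth-scaled counts is closest to the mean
    f75 = np.quantile(counts / totals[np.newaxis, :], 0.75, axis=0)
    return int(np.argmin(np.abs(f75 - f75.mean())))


def tmm_size_factors(
    table: CountTable,
    cfg: TMMConfig | None = None,
    pseudo_count: float = 0.0,
) -> SizeFactors:
    """Trimmed-mean-of-M-values factors, scaled by library size.

    For each sample, over the features nonzero in both it and the
    reference sample, M_k = log2 of the depth-scaled count ratio and
    A_k = mean log2 depth-scaled abundance are formed; after two-sided rank
    trimming on M (default 30%) and on A (default 5%), the TMM factor is
    2 to the precision-weighted mean of the surviving M values, with
    inverse asymptotic binomial variances as weights.  The scaled size
    factor is the TMM factor times the sample's total count.  If no
    feature survives trimming the factor falls back to 1 with a warning.
    """
    cfg = cfg or TMMConfig()
    if pseudo_count < 0:
        raise ValidationError("pseudo_count must be >= 0")
    counts = table.counts.astype(float) + pseudo_count
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise NormalizationError("zero-total sample in TMM")
    if cfg.reference_sample is not None:
        r = table.sample_ids.index(cfg.reference_sample)
    else:
        r = _tmm_reference_index(counts, totals)
    cr, nr = counts[:, r], totals[r]
    values = np.empty(table.n_samples)
    for i in range(table.n_samples):
        ci, ni = counts[:, i], totals[i]
        ok = (ci > 0) & (cr > 0)
        pi, pr = ci[ok] / ni, cr[ok] / nr
        m = np.log2(pi / pr)
        a = 0.5 * np.log2(pi * pr)
        # two-sided rank trimming (edgeR convention: keep ranks in
        # [floor(n*trim)+1, n-floor(n*trim)])
        nf = len(m)
        if nf == 0:
            warnings.warn(
                f"sample {table.sample_ids[i]!r} shares no features with the "
                "TMM reference; factor set to 1"
            )
            values[i] = ni
            continue
        lo_m = np.floor(nf * cfg.log_ratio_trim) + 1
        lo_a = np.floor(nf * cfg.abs_expr_trim) + 1
        rm, ra = rankdata(m), rankdata(a)
        keep = (rm >= lo_m) & (rm <= nf + 1 - lo_m) & (ra >= lo_a) & (ra <= nf + 1 - lo_a)
        if not np.any(keep):
            warnings.warn(
                f"no features survive TMM trimming for sample "
                f"{table.sample_ids[i]!r}; factor set to 1"
            )
            values[i] = ni
            continue
        w = 1.0 / ((ni - ci[ok]) / (ni * ci[ok]) + (nr - cr[ok]) / (nr * cr[ok]))
        values[i] = 2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])) * ni
    method = "TMM+" if pseudo_count > 0 else "TMM"
    return SizeFactors(list(table.sample_ids), values, method=method)


def css_size_factors(
    table: CountTable,
    rel_threshold: float = 0.1,
    floor_quantile: float = 0.5,
    grid_size: int = 101,
) -> SizeFactors:
    """Cumulative-sum scaling with a data-driven percentile.

    The percentile search works on a common probability grid: (1) each
    sample's quantile function of its *nonzero* counts; (2) a reference
    curve, the per-probability mean of the full (zero-inclusive) sorted
    count columns; (3) an instability profile, the median across samples of
    the absolute deviation from the reference; (4) the chosen percentile is
    the smallest grid point at which the relative increment of the profile
    exceeds ``rel_threshold``, floored at ``floor_quantile``; (5) the size
    factor is each sample's sum of counts at or below its own chosen
    quantile of nonzero counts.
    """
    counts = table.counts.astype(float)
    if np.any((counts > 0).sum(axis=0) == 0):
        raise NormalizationError("all-zero sample in CSS")
    probs = np.linspace(0.0, 1.0, grid_size)
    n = table.n_samples
    sample_q = np.empty((grid_size, n))
    for i in range(n):
        nz = counts[counts[:, i] > 0, i]
        sample_q[:, i] = np.quantile(nz, probs)
    ref_q = np.quantile(counts, probs, axis=0).mean(axis=1)
    instability = np.median(np.abs(sample_q - ref_q[:, np.newaxis]), axis=1)
    inc = np.diff(instability)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_inc = inc / np.where(instability[:-1] > 0, instability[:-1], np.nan)
    trigger = np.nonzero(np.nan_to_num(rel_inc, nan=0.0) > rel_threshold)[0]
    if len(trigger) == 0:
        if not np.any(inc != 0):
            warnings.warn("degenerate CSS instability profile; using floor quantile")
        chosen = floor_quantile
    else:
        chosen = max(float(probs[trigger[0] + 1]), floor_quantile)
    values = np.empty(n)
    for i in range(n):
        nz = counts[counts[:, i] > 0, i]
        cut = np.quantile(nz, chosen)
        values[i] = counts[counts[:, i] <= cut, i].sum()
    if np.any(values <= 0):
        raise NormalizationError("CSS produced a non-positive size factor")
    return SizeFactors(list(table.sample_ids), values, method="CSS")


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

METHODS = ("gmpr", "tss", "rle", "rle+", "tmm", "tmm+", "css")


def compute_size_factors(table: CountTable, method: str, **kwargs) -> SizeFactors:
    """Dispatch on a method name from :data:`METHODS` (case-insensitive)."""
    m = method.lower()
    if m == "gmpr":
        return gmpr_size_factors(table, **kwargs)
    if m == "tss":
        return tss_size_factors(table)
    if m == "rle":
        return rle_size_factors(table, pseudo_count=kwargs.pop("pseudo_count", 0.0))
    if m == "rle+":
        return rle_size_factors(table, pseudo_count=kwargs.pop("pseudo_count", 1.0))
    if m == "tmm":
        return tmm_size_factors(table, **kwargs)
    if m == "tmm+":
        kwargs.setdefault("pseudo_count", 1.0)
        return tmm_size_factors(table, **kwargs)
    if m == "css":
        return css_size_factors(table, **kwargs)
    raise ValidationError(f"unknown method {method!r}; expected one of {METHODS}")
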