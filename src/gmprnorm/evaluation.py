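"""Scoring normalizations: correlation benchmarks, variance ranking,
prevalence stratification, paired signed-rank comparison, and ICC.

The perturbation benchmark is the simulation harness: Dirichlet-multinomial
tables with known library sizes are corrupted by fixed or random
perturbations; each normalization's size factors are correlated with the
*pre-perturbation* library sizes, and the mean correlation with a normal
95% confidence interval over repetitions is reported per grid cell.

For real tables without known depths, the fallback measure is inter-sample
variability: per feature, the variance of normalized abundances across
samples; methods are ranked per dataset on the median of those variances
(smaller = better), overall or stratified by feature prevalence, and rank
differences between methods are compared by a paired Wilcoxon signed-rank
test.  Reproducibility across technical replicates is quantified by the
intraclass correlation rho = sigma_b^2 / (sigma_b^2 + sigma_e^2) from a
one-way random-effects ANOVA.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr, rankdata, spearmanr

from .comparators import compute_size_factors
from .errors import NormalizationError, ValidationError
from .io import CountTable, SampleLabels, SizeFactors, normalize_counts, rescale_by_median
from .simulate import (
    DMParams,
    PerturbationSpec,
    SPARSITY_PRESETS,
    calibrate_dispersion,
    default_dm_params,
    perturb_counts,
    sample_library_sizes,
    simulate_dm_counts,
)

__all__ = [
    "BenchmarkGrid",
    "BenchmarkReport",
    "ICCResult",
    "VarianceRankResult",
    "sizefactor_correlation",
    "run_perturbation_benchmark",
    "variance_rank_analysis",
    "prevalence_stratify",
    "paired_signed_rank",
    "icc",
]


# ---------------------------------------------------------------------------
# size factor vs true library size
# ---------------------------------------------------------------------------


def sizefactor_correlation(
    sf: SizeFactors,
    true_sizes: np.ndarray,
    method: str = "spearman",
) -> float:
    """Correlation between estimated size factors and true library sizes.

    Spearman by default (rank agreement is what the robustness benchmark
    cares about); Pearson also available.  Returns NaN for a constant
    vector, where the coefficient is undefined.
    """
    x = np.asarray(sf.values, dtype=float)
    y = np.asarray(true_sizes, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValidationError("need aligned vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    if method == "pearson":
        return float(pearsonr(x, y).statistic)
    raise ValidationError("method must be 'spearman' or 'pearson'")


# ---------------------------------------------------------------------------
# perturbation benchmark
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkGrid:
    """Simulation grid of the perturbation benchmark."""

    zero_targets: tuple[float, ...] = tuple(SPARSITY_PRESETS.values())
    modes: tuple[str, ...] = ("fixed", "random")
    strengths: tuple[str, ...] = ("strong", "moderate")
    fractions: tuple[float, ...] = (0.0, 0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64)
    n_samples: int = 98
    n_features: int = 625


@dataclass
class BenchmarkReport:
    """Per-cell mean correlations with 95% CIs across repetitions."""

    table: pd.DataFrame
    reps: int
    seed: int
    correlation: str

    def to_json(self) -> str:
        payload = {
            "reps": self.reps,
            "seed": self.seed,
            "correlation": self.correlation,
            "cells": self.table.to_dict(orient="records"),
        }
        return json.dumps(payload, sort_keys=True, indent=1, allow_nan=True)


def run_perturbation_benchmark(
    grid: BenchmarkGrid,
    methods: tuple[str, ...] = ("gmpr", "tss", "rle", "rle+", "tmm", "tmm+", "css"),
    reps: int = 25,
    seed: int = 0,
    correlation: str = "spearman",
    params_by_target: dict[float, DMParams] | None = None,
) -> BenchmarkReport:
    """Simulate, perturb, normalize, correlate — for every grid cell.

    ``params_by_target`` may supply pre-calibrated DM parameters per zero
    target (they are calibrated from the default stool-like preset
    otherwise).  RLE failures on sparse tables are recorded as NaN cells,
    not raised.  The whole report is a pure function of (grid, methods,
    reps, seed).
    """
    if params_by_target is None:
        params_by_target = {}
        for tgt in grid.zero_targets:
            base = default_dm_params(q=grid.n_features)
            params_by_target[tgt] = calibrate_dispersion(base, tgt, n=grid.n_samples)
    rows = []
    for it, tgt in enumerate(grid.zero_targets):
        params = params_by_target[tgt]
        for imode, mode in enumerate(grid.modes):
            for istr, strength in enumerate(grid.strengths):
                for ifrac, frac in enumerate(grid.fractions):
                    cell_seed = seed * 1_000_003 + ((it * 11 + imode) * 13 + istr) * 101 + ifrac
                    corrs: dict[str, list[float]] = {m: [] for m in methods}
                    for rep in range(reps):
                        rng = np.random.default_rng([cell_seed % (2**31), rep])
                        sizes = sample_library_sizes(grid.n_samples, params, rng)
                        clean = simulate_dm_counts(params, sizes, rng)
                        spec = PerturbationSpec(
                            mode=mode,
                            fraction=frac,
                            strength=strength,
                            seed=int(rng.integers(2**31)),
                        )
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            perturbed = perturb_counts(clean, spec).table
                        for m in methods:
                            try:
                                with warnings.catch_warnings():
                                    warnings.simplefilter("ignore")
                                    sf = compute_size_factors(perturbed, m)
                            except NormalizationError:
                                corrs[m].append(float("nan"))
                                continue
                            corrs[m].append(
                                sizefactor_correlation(sf, sizes, method=correlation)
                            )
                    for m in methods:
                        vals = np.asarray(corrs[m], dtype=float)
                        ok = vals[np.isfinite(vals)]
                        if ok.size:
                            mean = float(ok.mean())
                            se = float(ok.std(ddof=1) / math.sqrt(ok.size)) if ok.size > 1 else 0.0
                            lo, hi = mean - 1.96 * se, mean + 1.96 * se
                        else:
                            mean = lo = hi = float("nan")
                        rows.append(
                            {
                                "zero_target": tgt,
                                "mode": mode,
                                "strength": strength,
                                "fraction": frac,
                                "method": m,
                                "mean_corr": mean,
                                "ci_low": lo,
                                "ci_high": hi,
                                "n_ok": int(ok.size),
                                "n_na": int(np.isnan(vals).sum()),
                            }
                        )
    return BenchmarkReport(pd.DataFrame(rows), reps=reps, seed=seed, correlation=correlation)


# ---------------------------------------------------------------------------
# inter-sample variability ranking
# ---------------------------------------------------------------------------


@dataclass
class VarianceRankResult:
    """Median-variance method ranks per dataset plus per-feature ranks.

    ``median_variance``/``method_ranks``: datasets × methods (rank 1 =
    smallest median variance; average ranks on ties; NaN where a method
    failed).  ``per_feature_ranks``: one frame per dataset of each
    feature's variance rank among methods.
    """

    median_variance: pd.DataFrame
    method_ranks: pd.DataFrame
    per_feature_ranks: list[pd.DataFrame] = field(repr=False, default_factory=list)


def _normalized_matrix(table: CountTable, method: str) -> np.ndarray:
    if method == "raw":
        return table.counts.astype(float)
    sf = rescale_by_median(compute_size_factors(table, method))
    return normalize_counts(table, sf)


def variance_rank_analysis(
    tables: list[CountTable],
    methods: tuple[str, ...] = ("raw", "gmpr", "tss", "css"),
    strata: dict[int, np.ndarray] | None = None,
) -> VarianceRankResult:
    """Rank methods by median across-feature variance of normalized data.

    ``strata`` optionally restricts each dataset (by index) to a boolean
    feature mask, e.g. one prevalence stratum.  The pseudo-method ``raw``
    (no normalization) may be included.  A method failing on a dataset
    (e.g. RLE without zero-free features) gets NaN there and is excluded
    from that dataset's ranking.
    """
    if len(methods) < 2:
        raise ValidationError("need at least two methods to rank")
    med_rows, rank_rows, per_feature = [], [], []
    for d, table in enumerate(tables):
        mask = np.ones(table.n_features, dtype=bool) if strata is None else strata[d]
        variances = {}
        for m in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mat = _normalized_matrix(table, m)
                variances[m] = mat[mask].var(axis=1, ddof=1)
            except NormalizationError:
                variances[m] = None
        med = {m: (float(np.median(v)) if v is not None else float("nan"))
               for m, v in variances.items()}
        med_rows.append(med)
        vals = np.array([med[m] for m in methods])
        ranks = np.full(len(methods), np.nan)
        ok = np.isfinite(vals)
        ranks[ok] = rankdata(vals[ok])
        rank_rows.append(dict(zip(methods, ranks)))
        ok_methods = [m for m in methods if variances[m] is not None]
        vmat = np.column_stack([variances[m] for m in ok_methods])
        pf = pd.DataFrame(
            rankdata(vmat, axis=1),
            columns=ok_methods,
            index=[f for f, keep in zip(table.feature_ids, mask) if keep],
        )
        per_feature.append(pf)
    idx = [f"dataset{d+1}" for d in range(len(tables))]
    return VarianceRankResult(
        median_variance=pd.DataFrame(med_rows, index=idx),
        method_ranks=pd.DataFrame(rank_rows, index=idx),
        per_feature_ranks=per_feature,
    )


def prevalence_stratify(table: CountTable, n_strata: int = 3) -> np.ndarray:
    """Assign features to prevalence strata: "top", "middle", "bottom".

    Cutpoints are the terciles of the prevalence values (fraction of
    samples with a nonzero count); a feature on a cutpoint goes to the
    higher stratum, so a table whose features are all equally prevalent is
    entirely "top" (degenerate but well defined).
    """
    if table.n_features < n_strata:
        raise ValidationError(f"need at least {n_strata} features")
    if n_strata != 3:
        raise ValidationError("only tercile stratification is supported")
    prev = table.prevalence()
    c_low, c_high = np.quantile(prev, [1 / 3, 2 / 3])
    out = np.where(prev >= c_high, "top", np.where(prev >= c_low, "middle", "bottom"))
    return out.astype(object)


# ---------------------------------------------------------------------------
# paired signed-rank test
# ---------------------------------------------------------------------------


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    # DP over the distribution of W+ under random signs; midranks are
    # multiples of 1/2, so doubling gives exact integer support
    scaled = np.rint(2 * ranks).astype(int)
    total = int(scaled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        dist[r:] = dist[r:] + dist[:-r] if r > 0 else dist[r:] * 2
    dist /= dist.sum()
    w = int(round(2 * w_plus))
    p_low = float(dist[: w + 1].sum())
    p_high = float(dist[w:].sum())
    return min(1.0, 2.0 * min(p_low, p_high))


def paired_signed_rank(ranks_a: np.ndarray, ranks_b: np.ndarray, exact_max: int = 25) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences and NaN pairs are dropped; ties among the absolute
    differences receive midranks.  The null distribution is enumerated
    exactly (dynamic programming over sign assignments) for m <= 25 pairs
    and approximated by the tie-corrected normal otherwise.  All
    differences zero gives p = 1 by convention.
    """
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired vectors must be 1-D and of equal length")
    d = a - b
    d = d[np.isfinite(d)]
    d = d[d != 0]
    m = d.size
    if m == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if m <= exact_max:
        return _signed_rank_exact_p(ranks, w_plus)
    mean = m * (m + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    # continuity correction toward the mean
    cc = min(0.5, abs(w_plus - mean))
    z = (w_plus - mean - math.copysign(cc, w_plus - mean)) / math.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# intraclass correlation
# ---------------------------------------------------------------------------


@dataclass
class ICCResult:
    """One-way random-effects variance components and their ratio."""

    sigma_b_sq: float
    sigma_e_sq: float
    rho: float


def icc(values: np.ndarray, subjects: SampleLabels | list[str] | np.ndarray) -> ICCResult:
    """Intraclass correlation from one-way random-effects ANOVA.

    ``subjects`` gives the subject of each observation; replicates of the
    same subject share a label.  Estimates sigma_e^2 = MSW and
    sigma_b^2 = max(0, (MSB - MSW) / k0), with k0 the average group size
    adjusted for unbalanced designs, and returns
    rho = sigma_b^2 / (sigma_b^2 + sigma_e^2) clamped to [0, 1].
    """
    y = np.asarray(values, dtype=float)
    labels = subjects.group if isinstance(subjects, SampleLabels) else list(subjects)
    labels = np.asarray([str(s) for s in labels])
    if y.ndim != 1 or y.size != labels.size:
        raise ValidationError("values and subjects must be aligned 1-D vectors")
    uniq, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    a = uniq.size
    if a < 2:
        raise ValidationError("ICC needs at least two subjects")
    if np.all(counts < 2):
        raise ValidationError("ICC needs replicates for at least one subject")
    n_total = y.size
    grand = y.mean()
    group_means = np.bincount(inverse, weights=y) / counts
    ssb = float(np.sum(counts * (group_means - grand) ** 2))
    ssw = float(np.sum((y - group_means[inverse]) ** 2))
    msb = ssb / (a - 1)
    msw = ssw / (n_total - a)
    k0 = (n_total - float(np.sum(counts**2)) / n_total) / (a - 1)
    sigma_e = msw
    sigma_b = max(0.0, (msb - msw) / k0)
    denom = sigma_b + sigma_e
    rho = sigma_b / denom if denom > 0 else 0.0
    return ICCResult(sigma_b, sigma_e, float(min(max(rho, 0.0), 1.0)))
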