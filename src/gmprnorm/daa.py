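"""Differential abundance analysis with size-factor offsets.

Each feature is tested with a per-feature negative-binomial Wald GLM: the
counts are regressed on the two-level group indicator with the log size
factor as offset,

    c_ki ~ NB(mu_ki, phi_k),   log mu_ki = beta0_k + beta1_k * g_i + log s_i,

where the NB variance is mu + phi*mu^2.  The per-feature dispersion phi_k
is profiled by maximum likelihood (method-of-moments start, safeguarded
Newton steps on log phi), the mean model is fit by iteratively reweighted
least squares, and a two-sided Wald test of beta1_k = 0 yields the
p-value.  Benjamini-Hochberg adjustment, observed-FDR bookkeeping and ROC
curves complete the benchmark loop.

This is a deliberately plain, fully specified test engine: no
empirical-Bayes dispersion shrinkage, no outlier refitting, no independent
filtering, so that benchmark contrasts between *normalizations* are not
confounded by test-engine heuristics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import CountTable, SampleLabels, SizeFactors

__all__ = [
    "DAAResult",
    "ConfusionCounts",
    "fit_nb_wald",
    "bh_adjust",
    "confusion_counts",
    "observed_fdr",
    "roc_curve",
]

_PHI_FLOOR = 1e-8
_PHI_CEIL = 1e4


@dataclass
class ConfusionCounts:
    """FP/TP/FN/TN at one decision threshold."""

    fp: int
    tp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.fp + self.tp + self.fn + self.tn


#: Per-feature test results; columns: feature_id, log2fc, se, stat, pvalue,
#: qvalue, converged.
DAAResult = pd.DataFrame


def _nb_negloglik(counts: np.ndarray, mu: np.ndarray, phi: float) -> float:
    inv = 1.0 / phi
    return -float(
        np.sum(
            gammaln(counts + inv)
            - gammaln(inv)
            - gammaln(counts + 1.0)
            + counts * np.log(phi * mu / (1.0 + phi * mu))
            - inv * np.log1p(phi * mu)
        )
    )


def _estimate_phi(counts: np.ndarray, mu: np.ndarray) -> float:
    """Profile ML estimate of the NB dispersion for fixed means.

    Method-of-moments start; safeguarded Newton on log phi (numeric
    derivatives of the profile log-likelihood), falling back to a golden
    section scan if Newton leaves the bracket.
    """
    resid = (counts - mu) ** 2 - mu
    denom = float(np.sum(mu**2))
    phi = max(float(np.sum(resid)) / denom, 1e-3) if denom > 0 else 1e-3
    phi = min(max(phi, _PHI_FLOOR), _PHI_CEIL)
    x = math.log(phi)
    lo, hi = math.log(_PHI_FLOOR), math.log(_PHI_CEIL)

    def nll(logphi: float) -> float:
        return _nb_negloglik(counts, mu, math.exp(logphi))

    h = 1e-4
    for _ in range(25):
        f0, fp_, fm = nll(x), nll(x + h), nll(x - h)
        g = (fp_ - fm) / (2 * h)
        hess = (fp_ - 2 * f0 + fm) / h**2
        if abs(g) < 1e-8:
            break
        step = -g / hess if hess > 1e-12 else -math.copysign(0.5, g)
        step = max(min(step, 2.0), -2.0)
        x_new = min(max(x + step, lo), hi)
        if abs(x_new - x) < 1e-6:
            x = x_new
            break
        x = x_new
    else:  # pragma: no cover - Newton nearly always converges here
        grid = np.linspace(lo, hi, 61)
        x = float(grid[int(np.argmin([nll(g) for g in grid]))])
    return math.exp(x)


def _nb_irls(
    counts: np.ndarray,
    g: np.ndarray,
    offset: np.ndarray,
    phi: float,
    beta: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS for the two-parameter NB log-linear model with offset.

    Returns (beta, covariance, converged); the covariance is the inverse
    expected information at the final iterate.
    """
    X = np.column_stack([np.ones_like(g, dtype=float), g.astype(float)])
    converged = False
    for _ in range(max_iter):
        eta = X @ beta + offset
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + phi * mu)
        z = eta - offset + (counts - mu) / mu
        xtw = X.T * w
        A = xtw @ X
        try:
            beta_new = np.linalg.solve(A, xtw @ z)
        except np.linalg.LinAlgError:
            return beta, np.full((2, 2), np.nan), False
        if not np.all(np.isfinite(beta_new)):
            return beta, np.full((2, 2), np.nan), False
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + phi * mu)
    A = (X.T * w) @ X
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
    return beta, cov, converged


def fit_nb_wald(table: CountTable, labels: SampleLabels, sf: SizeFactors) -> DAAResult:
    """Per-feature NB Wald test of a two-level group effect.

    Features observed in fewer than two samples are not tested (p = 1,
    ``converged=False``); numerical failures are likewise flagged rather
    than raised.  The reported effect is the log2 fold change of group B
    over group A (lexicographic level order).
    """
    labels = labels.aligned_to(table)
    sf = sf.aligned_to(table)
    levels = sorted(set(labels.group))
    if len(levels) != 2:
        raise ValidationError(f"exactly two groups required, got {levels}")
    g = np.array([1.0 if x == levels[1] else 0.0 for x in labels.group])
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValidationError("each group needs at least two samples")
    offset = np.log(sf.values)
    ln2 = math.log(2.0)

    rows = []
    for k in range(table.n_features):
        counts = table.counts[k].astype(float)
        if int((counts > 0).sum()) < 2:
            rows.append((table.feature_ids[k], np.nan, np.nan, np.nan, 1.0, False))
            continue
        # a group with no observed counts has its NB estimate on the
        # boundary; a 0.5 continuity correction keeps the fold estimate
        # finite with an honestly large standard error
        if counts[g == 0].sum() == 0 or counts[g == 1].sum() == 0:
            counts = counts + 0.5
        m0 = (counts[g == 0] / sf.values[g == 0]).mean()
        m1 = (counts[g == 1] / sf.values[g == 1]).mean()
        beta = np.array([math.log(m0 + 0.5), math.log(m1 + 0.5) - math.log(m0 + 0.5)])
        beta, _, _ = _nb_irls(counts, g, offset, phi=0.0, beta=beta)  # Poisson pass
        ok = True
        phi = 1.0
        for _ in range(3):
            eta = np.clip(np.column_stack([np.ones_like(g), g]) @ beta + offset, -30, 30)
            phi_new = _estimate_phi(counts, np.exp(eta))
            beta, cov, conv = _nb_irls(counts, g, offset, phi_new, beta)
            if not conv or not np.all(np.isfinite(cov)):
                ok = False
                break
            if abs(math.log(phi_new) - math.log(phi)) < 1e-4:
                phi = phi_new
                break
            phi = phi_new
        se = math.sqrt(cov[1, 1]) if ok and cov[1, 1] > 0 else np.nan
        if not ok or not np.isfinite(se):
            rows.append((table.feature_ids[k], np.nan, np.nan, np.nan, 1.0, False))
            continue
        stat = beta[1] / se
        p = 2.0 * float(norm.sf(abs(stat)))
        rows.append((table.feature_ids[k], beta[1] / ln2, se / ln2, stat, min(p, 1.0), True))

    out = pd.DataFrame(rows, columns=["feature_id", "log2fc", "se", "stat", "pvalue", "converged"])
    out["qvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out[["feature_id", "log2fc", "se", "stat", "pvalue", "qvalue", "converged"]]


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, in [0, 1])."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def confusion_counts(calls: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValidationError("calls and truth must align")
    return ConfusionCounts(
        fp=int(np.sum(calls & ~truth)),
        tp=int(np.sum(calls & truth)),
        fn=int(np.sum(~calls & truth)),
        tn=int(np.sum(~calls & ~truth)),
    )


def observed_fdr(result: DAAResult, truth: np.ndarray, q_cutoff: float = 0.05) -> float:
    """Observed false discovery rate FP / max(1, FP + TP) at a q cutoff."""
    calls = result["qvalue"].to_numpy() <= q_cutoff
    cc = confusion_counts(calls, truth)
    return cc.fp / max(1, cc.fp + cc.tp)


def roc_curve(result: DAAResult, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC over p-value thresholds: (FPR, TPR, trapezoidal AUC).

    The curve runs from (0, 0) to (1, 1); smaller p-values score higher.
    """
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValidationError("truth needs at least one positive and one negative")
    score = -result["pvalue"].to_numpy()
    fpr, tpr, _ = _sk_roc_curve(truth.astype(int), score, drop_intermediate=False)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))
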