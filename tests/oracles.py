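"""Independent brute-force reference implementations used only by tests.

Everything here is written with explicit loops and elementary statistics,
deliberately avoiding the code paths (and where possible the libraries)
used by the package, so that agreement is informative.
"""

from __future__ import annotations

import itertools
import math
import statistics

import numpy as np


def gmpr_bruteforce(counts: np.ndarray, min_shared: int = 1) -> list[float]:
    """Materialize every shared set and median explicitly."""
    q, n = counts.shape
    out = []
    for i in range(n):
        logs = [0.0]  # self-ratio r_ii = 1
        for j in range(n):
            if j == i:
                continue
            ratios = [
                counts[k, i] / counts[k, j]
                for k in range(q)
                if counts[k, i] > 0 and counts[k, j] > 0
            ]
            if len(ratios) >= min_shared:
                logs.append(math.log(statistics.median(ratios)))
        out.append(math.exp(sum(logs) / len(logs)))
    return out


def rle_bruteforce(counts: np.ndarray, pseudo_count: float = 0.0) -> list[float] | None:
    """Median-of-ratios against geometric means of zero-free features.

    Returns None where the method is undefined (no zero-free feature and
    no pseudo-count).
    """
    q, n = counts.shape
    c = counts.astype(float) + pseudo_count
    keep = [k for k in range(q) if all(c[k, i] > 0 for i in range(n))]
    if not keep:
        return None
    gms = {k: math.exp(sum(math.log(c[k, i]) for i in range(n)) / n) for k in keep}
    return [statistics.median([c[k, i] / gms[k] for k in keep]) for i in range(n)]


def _midranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def tmm_bruteforce(
    counts: np.ndarray,
    log_ratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> list[float]:
    """Step-by-step TMM with explicit sorting and trimming."""
    q, n = counts.shape
    c = counts.astype(float)
    totals = [sum(c[:, i]) for i in range(n)]
    # reference: 75th percentile of depth-scaled counts closest to the mean
    f75 = []
    for i in range(n):
        scaled = sorted(c[:, i] / totals[i])
        f75.append(float(np.quantile(scaled, 0.75)))
    mean75 = sum(f75) / n
    r = min(range(n), key=lambda i: abs(f75[i] - mean75))
    out = []
    for i in range(n):
        shared = [k for k in range(q) if c[k, i] > 0 and c[k, r] > 0]
        ms, as_, ws = [], [], []
        for k in shared:
            pi, pr = c[k, i] / totals[i], c[k, r] / totals[r]
            ms.append(math.log2(pi / pr))
            as_.append(0.5 * math.log2(pi * pr))
            ws.append(
                1.0
                / (
                    (totals[i] - c[k, i]) / (totals[i] * c[k, i])
                    + (totals[r] - c[k, r]) / (totals[r] * c[k, r])
                )
            )
        nf = len(ms)
        if nf == 0:
            out.append(totals[i])
            continue
        lo_m = math.floor(nf * log_ratio_trim) + 1
        lo_a = math.floor(nf * abs_expr_trim) + 1
        rm, ra = _midranks(ms), _midranks(as_)
        keep = [
            t
            for t in range(nf)
            if lo_m <= rm[t] <= nf + 1 - lo_m and lo_a <= ra[t] <= nf + 1 - lo_a
        ]
        if not keep:
            out.append(totals[i])
            continue
        wmean = sum(ws[t] * ms[t] for t in keep) / sum(ws[t] for t in keep)
        out.append(2**wmean * totals[i])
    return out


def css_bruteforce(
    counts: np.ndarray,
    rel_threshold: float = 0.1,
    floor_quantile: float = 0.5,
    grid_size: int = 101,
) -> list[float]:
    """Literal steps (1)-(5) of the CSS percentile search."""
    q, n = counts.shape
    c = counts.astype(float)
    probs = [g / (grid_size - 1) for g in range(grid_size)]
    sample_q = []
    for i in range(n):
        nz = sorted(v for v in c[:, i] if v > 0)
        sample_q.append([float(np.quantile(nz, p)) for p in probs])
    full_q = []
    for i in range(n):
        col = sorted(c[:, i])
        full_q.append([float(np.quantile(col, p)) for p in probs])
    ref = [sum(full_q[i][g] for i in range(n)) / n for g in range(grid_size)]
    instab = [
        statistics.median([abs(sample_q[i][g] - ref[g]) for i in range(n)])
        for g in range(grid_size)
    ]
    chosen = None
    for g in range(1, grid_size):
        prev = instab[g - 1]
        if prev > 0 and (instab[g] - prev) / prev > rel_threshold:
            chosen = max(probs[g], floor_quantile)
            break
    if chosen is None:
        chosen = floor_quantile
    out = []
    for i in range(n):
        nz = [v for v in c[:, i] if v > 0]
        cut = float(np.quantile(nz, chosen))
        out.append(sum(v for v in c[:, i] if v <= cut))
    return out


def bh_bruteforce(pvalues: list[float]) -> list[float]:
    """Step-up Benjamini-Hochberg with explicit loops."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvalues[i] * m / rank_from_top)
        q[i] = running
    return q


def signed_rank_bruteforce(a: list[float], b: list[float]) -> float:
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = [x - y for x, y in zip(a, b) if x != y]
    m = len(d)
    if m == 0:
        return 1.0
    ranks = _midranks([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    dist = []
    for signs in itertools.product([0, 1], repeat=m):
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    n_tot = len(dist)
    p_low = sum(1 for w in dist if w <= w_obs + 1e-9) / n_tot
    p_high = sum(1 for w in dist if w >= w_obs - 1e-9) / n_tot
    return min(1.0, 2.0 * min(p_low, p_high))


def icc_bruteforce(values: np.ndarray, subject_of: list[str]) -> tuple[float, float, float]:
    """Direct one-way variance components (handles unbalanced groups)."""
    groups: dict[str, list[float]] = {}
    for v, s in zip(values, subject_of):
        groups.setdefault(s, []).append(float(v))
    a = len(groups)
    n_tot = len(values)
    grand = sum(values) / n_tot
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups.values())
    ssw = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups.values())
    msb = ssb / (a - 1)
    msw = ssw / (n_tot - a)
    k0 = (n_tot - sum(len(g) ** 2 for g in groups.values()) / n_tot) / (a - 1)
    sigma_e = msw
    sigma_b = max(0.0, (msb - msw) / k0)
    rho = sigma_b / (sigma_b + sigma_e) if sigma_b + sigma_e > 0 else 0.0
    return sigma_b, sigma_e, rho
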