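"""Synthetic benchmark data: Dirichlet-multinomial tables, perturbations,
and two-group zero-inflated negative binomial (ZINB) tables.

Two generators drive the benchmarks:

* A **Dirichlet-multinomial (DM)** model with known library sizes.  Each
  sample's composition is drawn from a Dirichlet distribution around a
  common stool-like mean vector, then counts are drawn multinomially at a
  library size sampled from a truncated log-normal.  The column sum is the
  "true" library size that normalization methods try to recover.  The
  dispersion parameter θ controls zero inflation and is calibrated by
  bisection to hit target zero fractions (the sparsity presets ~60%, 70%,
  80%).
* A **ZINB** model for differential-abundance benchmarks: each count is a
  point mass at zero with probability p_k (structural absence) or a
  negative binomial with mean μ_k and dispersion φ_k (variance μ + φμ²).
  A fraction of features is made differential between two groups by a
  fold-change multiplier; the "unbalanced" scene additionally makes the
  two most abundant features (relative abundances 0.168 and 0.083)
  differential in one fixed group, creating strong compositional effects.

Perturbation operators corrupt DM tables in a "fixed" mode (the same
feature set shifted in the same direction in every sample, mimicking
differential abundance) or a "random" mode (per-sample feature sets and
directions, mimicking sample-specific outliers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .io import CountTable, SampleLabels

__all__ = [
    "DMParams",
    "PerturbationSpec",
    "PerturbationResult",
    "ZINBParams",
    "DAADesign",
    "SPARSITY_PRESETS",
    "default_dm_params",
    "sample_library_sizes",
    "simulate_dm_counts",
    "realized_zero_fraction",
    "calibrate_dispersion",
    "perturb_counts",
    "default_zinb_params",
    "make_daa_design",
    "simulate_zinb_counts",
]

#: Target zero fractions of the three sparsity presets (low, middle, high).
SPARSITY_PRESETS = {"low": 0.60, "middle": 0.70, "high": 0.80}

PERTURB_FRACTIONS = (0.0, 0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64)


def _round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


# ---------------------------------------------------------------------------
# Dirichlet-multinomial
# ---------------------------------------------------------------------------


@dataclass
class DMParams:
    """Generative parameters of the Dirichlet-multinomial simulator.

    ``mean_proportions`` is a simplex vector π over features; ``dispersion``
    is the overdispersion θ in (0, 1) (Dirichlet concentration
    α = π·(1−θ)/θ, so θ→0 recovers the plain multinomial).  Library sizes
    follow a log-normal on the log scale, truncated to
    [``lib_min``, ``lib_max``] and rounded.
    """

    mean_proportions: np.ndarray
    dispersion: float
    lib_log_mean: float
    lib_log_sd: float
    lib_min: int
    lib_max: int

    def __post_init__(self) -> None:
        pi = np.asarray(self.mean_proportions, dtype=float)
        if pi.ndim != 1 or pi.size < 2:
            raise ValidationError("mean_proportions must be a vector of length >= 2")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise ValidationError("mean_proportions must be a simplex vector")
        if not (0 < self.dispersion < 1):
            raise ValidationError("dispersion must lie in (0, 1)")
        if self.lib_log_sd < 0 or self.lib_min < 1 or self.lib_max < self.lib_min:
            raise ValidationError("invalid library-size model")
        self.mean_proportions = pi

    @property
    def n_features(self) -> int:
        return self.mean_proportions.size


def default_dm_params(q: int = 625, profile: str = "stool-like") -> DMParams:
    """Stool-like preset: a ranked power-law mean vector.

    Real stool communities are dominated by a few abundant taxa with a long
    tail of rare ones; a power law π_k ∝ k^(-1.2) over ranked features
    reproduces that shape.  Library sizes are log-normal (median ≈ 15,000
    reads, log-sd 0.6) truncated to [2,000, 150,000].  The default
    dispersion targets the middle sparsity preset once calibrated.
    """
    if q < 2:
        raise ValidationError("q must be >= 2")
    if profile != "stool-like":
        raise ValidationError(f"unknown profile {profile!r}")
    ranks = np.arange(1, q + 1, dtype=float)
    pi = ranks ** -1.2
    pi /= pi.sum()
    return DMParams(
        mean_proportions=pi,
        dispersion=0.005,
        lib_log_mean=float(np.log(15_000)),
        lib_log_sd=0.6,
        lib_min=2_000,
        lib_max=150_000,
    )


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_library_sizes(n: int, params: DMParams, seed: int | np.random.Generator) -> np.ndarray:
    """Draw n truncated log-normal library sizes (rejection sampling)."""
    if n < 2:
        raise ValidationError("need at least two samples")
    rng = _as_rng(seed)
    out = np.empty(n)
    filled = 0
    for _ in range(1000):
        draw = np.exp(rng.normal(params.lib_log_mean, params.lib_log_sd, size=n - filled))
        ok = draw[(draw >= params.lib_min) & (draw <= params.lib_max)]
        out[filled : filled + ok.size] = ok
        filled += ok.size
        if filled == n:
            break
    else:  # pragma: no cover - pathological truncation bounds
        out[filled:] = np.clip(
            np.exp(rng.normal(params.lib_log_mean, params.lib_log_sd, size=n - filled)),
            params.lib_min,
            params.lib_max,
        )
    return _round_half_up(out).astype(np.int64)


def simulate_dm_counts(
    params: DMParams,
    library_sizes: np.ndarray,
    seed: int | np.random.Generator,
) -> CountTable:
    """Simulate a feature × sample DM count table at given library sizes.

    Column sums equal the library sizes exactly — the totals are the
    "true" depths the perturbation benchmark scores against.
    """
    rng = _as_rng(seed)
    sizes = np.asarray(library_sizes, dtype=np.int64)
    if np.any(sizes <= 0):
        raise ValidationError("library sizes must be positive")
    q, n = params.n_features, sizes.size
    alpha = params.mean_proportions * (1.0 - params.dispersion) / params.dispersion
    # gamma representation of the Dirichlet; tiny concentrations can yield
    # exact zeros, which simply become structural zero counts
    gam = rng.gamma(np.broadcast_to(alpha, (n, q)))
    row_sums = gam.sum(axis=1)
    dead = row_sums == 0
    if np.any(dead):  # pragma: no cover - vanishingly rare
        gam[dead, 0] = 1.0
        row_sums = gam.sum(axis=1)
    comp = gam / row_sums[:, np.newaxis]
    counts = np.empty((q, n), dtype=np.int64)
    for i in range(n):
        counts[:, i] = rng.multinomial(sizes[i], comp[i])
    return CountTable(
        [f"OTU{k+1}" for k in range(q)],
        [f"S{i+1}" for i in range(n)],
        counts,
    )


def realized_zero_fraction(
    params: DMParams,
    n: int,
    reps: int = 4,
    seed: int | np.random.Generator = 0,
) -> float:
    """Mean fraction of zero cells over ``reps`` simulated tables."""
    rng = _as_rng(seed)
    fracs = []
    for _ in range(reps):
        sizes = sample_library_sizes(n, params, rng)
        table = simulate_dm_counts(params, sizes, rng)
        fracs.append(float((table.counts == 0).mean()))
    return float(np.mean(fracs))


def calibrate_dispersion(
    params: DMParams,
    target_zero_fraction: float,
    n: int = 98,
    tol: float = 0.01,
    reps: int = 4,
    seed: int = 20_180_402,
    theta_bounds: tuple[float, float] = (1e-4, 0.95),
    max_iter: int = 40,
) -> DMParams:
    """Adjust θ by bisection so the realized zero fraction matches a target.

    The realized zero fraction is a (noisy) nondecreasing function of θ;
    common random numbers (a fixed internal seed per θ evaluation) make the
    simulated response monotone enough for bisection.  Raises if the target
    lies outside what the θ bounds can reach for this mean vector.
    """
    if not (0 < target_zero_fraction < 1):
        raise ValidationError("target zero fraction must lie in (0, 1)")

    def f(theta: float) -> float:
        return realized_zero_fraction(replace(params, dispersion=theta), n, reps, seed)

    lo, hi = theta_bounds
    f_lo, f_hi = f(lo), f(hi)
    if not (f_lo - tol <= target_zero_fraction <= f_hi + tol):
        raise ValidationError(
            f"target zero fraction {target_zero_fraction:.3f} outside the "
            f"attainable range [{f_lo:.3f}, {f_hi:.3f}] for theta in {theta_bounds}"
        )
    theta = params.dispersion
    if not (lo < theta < hi):
        theta = 0.5 * (lo + hi)
    for _ in range(max_iter):
        val = f(theta)
        if abs(val - target_zero_fraction) <= tol:
            return replace(params, dispersion=theta)
        if val < target_zero_fraction:
            lo = theta
        else:
            hi = theta
        theta = 0.5 * (lo + hi)
    return replace(params, dispersion=theta)


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


@dataclass
class PerturbationSpec:
    """How to corrupt a count table.

    ``mode`` is "fixed" (one global feature set, one direction per feature,
    applied to all samples) or "random" (independent set and directions per
    sample).  ``strength`` "strong" maps counts to √c (decrease) or c²
    (increase); "moderate" to 0.25·c or 4·c.  Results are rounded half-up;
    zeros remain zeros.
    """

    mode: str
    fraction: float
    strength: str
    seed: int

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "random"):
            raise ValidationError("mode must be 'fixed' or 'random'")
        if self.strength not in ("strong", "moderate"):
            raise ValidationError("strength must be 'strong' or 'moderate'")
        if not (0 <= self.fraction <= 1):
            raise ValidationError("fraction must lie in [0, 1]")


@dataclass
class PerturbationResult:
    table: CountTable
    #: per-sample arrays of perturbed feature indices (identical in fixed mode)
    feature_sets: list[np.ndarray]
    #: per-sample +1 (increase) / -1 (decrease) aligned to feature_sets
    directions: list[np.ndarray]
    mode: str


def _apply_perturbation(col: np.ndarray, idx: np.ndarray, direc: np.ndarray, strength: str) -> None:
    c = col[idx].astype(float)
    if strength == "strong":
        new = np.where(direc > 0, c**2, np.sqrt(c))
    else:
        new = np.where(direc > 0, 4.0 * c, 0.25 * c)
    col[idx] = _round_half_up(new).astype(col.dtype)


def perturb_counts(table: CountTable, spec: PerturbationSpec) -> PerturbationResult:
    """Perturb a fraction of features; the only step that decouples the
    observed column sums from the true library sizes."""
    q, n = table.n_features, table.n_samples
    n_pert = int(_round_half_up(spec.fraction * q))
    counts = table.counts.copy()
    if spec.fraction > 0 and n_pert == 0:
        warnings.warn("perturbation fraction rounds to zero features; no-op")
    rng = np.random.default_rng(spec.seed)
    feature_sets: list[np.ndarray] = []
    directions: list[np.ndarray] = []
    if spec.mode == "fixed":
        idx = rng.choice(q, size=n_pert, replace=False)
        direc = rng.choice([-1, 1], size=n_pert)
        for i in range(n):
            _apply_perturbation(counts[:, i], idx, direc, spec.strength)
            feature_sets.append(idx)
            directions.append(direc)
    else:
        for i in range(n):
            idx = rng.choice(q, size=n_pert, replace=False)
            direc = rng.choice([-1, 1], size=n_pert)
            _apply_perturbation(counts[:, i], idx, direc, spec.strength)
            feature_sets.append(idx)
            directions.append(direc)
    out = CountTable(list(table.feature_ids), list(table.sample_ids), counts)
    return PerturbationResult(out, feature_sets, directions, spec.mode)


# ---------------------------------------------------------------------------
# ZINB two-group simulation
# ---------------------------------------------------------------------------


@dataclass
class ZINBParams:
    """Per-feature ZINB parameters plus a library-size heterogeneity model.

    ``prevalence`` p_k is the structural-zero probability, ``abundance``
    μ_k the negative-binomial mean at unit depth multiplier, and
    ``dispersion`` φ_k the NB overdispersion (variance μ + φμ²).  Each
    sample receives a log-normal depth multiplier on μ (log-sd
    ``lib_log_sd``, median 1) so that size factors are identifiable.
    """

    prevalence: np.ndarray
    abundance: np.ndarray
    dispersion: np.ndarray
    lib_log_sd: float = 0.7

    def __post_init__(self) -> None:
        p = np.asarray(self.prevalence, dtype=float)
        mu = np.asarray(self.abundance, dtype=float)
        phi = np.asarray(self.dispersion, dtype=float)
        if not (p.shape == mu.shape == phi.shape) or p.ndim != 1:
            raise ValidationError("prevalence/abundance/dispersion must be equal-length vectors")
        if np.any((p < 0) | (p > 1)):
            raise ValidationError("prevalence must lie in [0, 1]")
        if np.any(mu <= 0) or np.any(phi <= 0):
            raise ValidationError("abundance and dispersion must be positive")
        self.prevalence, self.abundance, self.dispersion = p, mu, phi

    @property
    def n_features(self) -> int:
        return self.prevalence.size

    def relative_abundance(self) -> np.ndarray:
        m = (1.0 - self.prevalence) * self.abundance
        return m / m.sum()


#: Relative abundances of the two dominant features in the unbalanced scene.
UNBALANCED_TOP_PROPORTIONS = (0.168, 0.083)


def default_zinb_params(q: int = 625, seed: int = 7, mean_depth: float = 10_000.0) -> ZINBParams:
    """Stool-like ZINB preset.

    The two most abundant features are pinned at relative (expected)
    abundances 0.168 and 0.083 — the dominant taxa used to create
    compositional effects in the unbalanced scene — and the remaining mass
    follows a ranked power law.  Prevalence of structural zeros grows with
    rarity; dispersions are log-normal around ~0.8, the strong
    overdispersion typical of stool taxa.
    """
    if q < 10:
        raise ValidationError("q must be >= 10")
    rng = np.random.default_rng(seed)
    ranks = np.arange(1, q - 1, dtype=float)
    tail = ranks ** -1.8
    tail *= (1.0 - sum(UNBALANCED_TOP_PROPORTIONS)) / tail.sum()
    rel = np.concatenate([np.asarray(UNBALANCED_TOP_PROPORTIONS), tail])
    # structural zeros concentrate in the rare tail; dominant taxa are
    # near-universally present, as in real stool communities
    p = 0.02 + 0.93 * (np.arange(q) / (q - 1)) ** 2.0
    mu = rel * mean_depth / (1.0 - p)  # so that (1-p)·μ matches the target mass
    phi = np.exp(rng.normal(np.log(0.8), 0.6, size=q))
    return ZINBParams(prevalence=p, abundance=mu, dispersion=phi)


@dataclass
class DAADesign:
    """Two-group differential-abundance design.

    ``diff_set`` are the differential feature indices; ``diff_group`` maps
    each to the group ("A"/"B") whose mean is multiplied by ``fold``.
    ``unbalanced_features`` lists the abundant features forced differential
    in one group (empty in the balanced scene); ``truth`` flags every
    differential feature.
    """

    n_per_group: int
    diff_fraction: float
    fold: float
    diff_set: np.ndarray
    diff_group: dict[int, str]
    unbalanced_features: np.ndarray
    truth: np.ndarray
    scene: str = "balanced"

    def __post_init__(self) -> None:
        if set(self.unbalanced_features) - set(self.diff_set):
            raise ValidationError("unbalanced features must be differential")


def make_daa_design(
    q: int,
    n_per_group: int = 49,
    diff_fraction: float = 0.05,
    fold: float = 4.0,
    scene: str = "balanced",
    seed: int = 0,
) -> DAADesign:
    """Pick the differential features and their affected groups.

    Balanced scene: round(diff_fraction·q) features drawn uniformly, each
    with its affected group drawn uniformly.  Unbalanced scene: on top of
    the balanced picks, the two dominant features (indices 0 and 1 of the
    default preset) are forced differential in group "B".
    """
    if scene not in ("balanced", "unbalanced"):
        raise ValidationError("scene must be 'balanced' or 'unbalanced'")
    n_diff = int(_round_half_up(diff_fraction * q))
    if diff_fraction > 0 and n_diff < 1:
        raise ValidationError("diff_fraction rounds to zero features")
    rng = np.random.default_rng(seed)
    diff_set = np.sort(rng.choice(q, size=n_diff, replace=False))
    groups = rng.choice(["A", "B"], size=n_diff)
    diff_group = {int(k): str(g) for k, g in zip(diff_set, groups)}
    unbalanced = np.array([], dtype=int)
    if scene == "unbalanced":
        unbalanced = np.array([0, 1], dtype=int)
        for k in unbalanced:
            diff_group[int(k)] = "B"
        diff_set = np.unique(np.concatenate([diff_set, unbalanced]))
    truth = np.zeros(q, dtype=bool)
    truth[diff_set] = True
    return DAADesign(
        n_per_group=n_per_group,
        diff_fraction=diff_fraction,
        fold=fold,
        diff_set=diff_set,
        diff_group=diff_group,
        unbalanced_features=unbalanced,
        truth=truth,
        scene=scene,
    )


def simulate_zinb_counts(
    params: ZINBParams,
    design: DAADesign,
    seed: int | np.random.Generator,
) -> tuple[CountTable, SampleLabels, np.ndarray, np.ndarray]:
    """Simulate a two-group ZINB table.

    Returns ``(table, labels, truth, depth_multipliers)``; the depth
    multipliers are the "true" size factors of the simulated samples.
    """
    q = params.n_features
    if design.truth.size != q:
        raise ValidationError("design does not match the number of features")
    rng = _as_rng(seed)
    n = 2 * design.n_per_group
    group = np.array(["A"] * design.n_per_group + ["B"] * design.n_per_group)
    depth = np.exp(rng.normal(0.0, params.lib_log_sd, size=n))
    fold_matrix = np.ones((q, n))
    for k, g in design.diff_group.items():
        fold_matrix[k, group == g] = design.fold
    mu = params.abundance[:, np.newaxis] * fold_matrix * depth[np.newaxis, :]
    phi = params.dispersion[:, np.newaxis]
    # NB draw via gamma-Poisson mixture: mean μ, variance μ + φμ²
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
    counts = rng.poisson(lam)
    structural = rng.random((q, n)) < params.prevalence[:, np.newaxis]
    counts[structural] = 0
    table = CountTable(
        [f"OTU{k+1}" for k in range(q)],
        [f"S{i+1}" for i in range(n)],
        counts.astype(np.int64),
    )
    labels = SampleLabels(list(table.sample_ids), list(group))
    return table, labels, design.truth.copy(), depth
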