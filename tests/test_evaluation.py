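import numpy as np
import pytest
from scipy.stats import wilcoxon

from gmprnorm.errors import ValidationError
from gmprnorm.evaluation import (
    BenchmarkGrid,
    icc,
    paired_signed_rank,
    prevalence_stratify,
    run_perturbation_benchmark,
    sizefactor_correlation,
    variance_rank_analysis,
)
from gmprnorm.io import CountTable, SampleLabels, SizeFactors
from gmprnorm.simulate import default_dm_params

from conftest import random_table
from oracles import icc_bruteforce, signed_rank_bruteforce


def _sf(values):
    return SizeFactors([f"s{i}" for i in range(len(values))], np.asarray(values, float), "x")


class TestSizefactorCorrelation:
    def test_identity_gives_one(self):
        v = np.array([3.0, 1.0, 2.0, 5.0])
        for m in ("pearson", "spearman"):
            assert sizefactor_correlation(_sf(v), v, method=m) == pytest.approx(1.0)

    def test_monotone_transform_keeps_spearman(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        assert sizefactor_correlation(_sf(np.exp(v)), v, "spearman") == pytest.approx(1.0)
        assert sizefactor_correlation(_sf(np.exp(v)), v, "pearson") < 1.0

    def test_reversed_ranks_give_minus_one(self):
        assert sizefactor_correlation(_sf([1, 2, 3]), np.array([3, 2, 1])) == -1.0

    def test_constant_vector_is_nan(self):
        assert np.isnan(sizefactor_correlation(_sf([2, 2, 2]), np.array([1.0, 2, 3])))


class TestPerturbationBenchmark:
    @pytest.fixture()
    def small_report(self, request):
        cache = getattr(request.session, "_small_report_cache", None)
        if cache is None:
            grid = BenchmarkGrid(
                zero_targets=(0.6,),
                modes=("fixed",),
                strengths=("strong",),
                fractions=(0.0, 0.16),
                n_samples=40,
                n_features=200,
            )
            cache = run_perturbation_benchmark(
                grid, methods=("gmpr", "tss", "rle"), reps=4, seed=11
            )
            request.session._small_report_cache = cache
        return cache

    def test_unperturbed_methods_track_truth(self, small_report):
        cell = small_report.table.query("fraction == 0.0")
        gm = cell[cell.method == "gmpr"]["mean_corr"].item()
        ts = cell[cell.method == "tss"]["mean_corr"].item()
        assert ts == pytest.approx(1.0)
        assert gm > 0.9

    def test_gmpr_never_na(self, small_report):
        assert (small_report.table.query("method == 'gmpr'")["n_na"] == 0).all()

    def test_rle_failures_recorded_not_raised(self, small_report):
        # at 60% zeros with q=120 RLE may or may not fail; either way the
        # report has a row with consistent bookkeeping
        row = small_report.table.query("method == 'rle' and fraction == 0.0").iloc[0]
        assert row["n_ok"] + row["n_na"] == small_report.reps

    def test_ci_bounds_ordered(self, small_report):
        ok = small_report.table.dropna(subset=["mean_corr"])
        assert (ok["ci_low"] <= ok["mean_corr"] + 1e-12).all()
        assert (ok["mean_corr"] <= ok["ci_high"] + 1e-12).all()

    def test_report_bit_reproducible_under_seed(self):
        grid = BenchmarkGrid(
            zero_targets=(0.6,),
            modes=("random",),
            strengths=("moderate",),
            fractions=(0.08,),
            n_samples=20,
            n_features=80,
        )
        params = {0.6: default_dm_params(q=80)}
        a = run_perturbation_benchmark(grid, ("gmpr", "tss"), reps=3, seed=5,
                                       params_by_target=params)
        b = run_perturbation_benchmark(grid, ("gmpr", "tss"), reps=3, seed=5,
                                       params_by_target=params)
        assert a.to_json() == b.to_json()


class TestVarianceRanks:
    def test_tied_methods_share_average_rank(self):
        # on zero-free multiplicative data TSS and RLE normalize identically,
        # so their median variances tie and both get the average rank
        rng = np.random.default_rng(5)
        m = rng.integers(1, 40, size=12).astype(float)
        counts = np.outer(m, [1.0, 3.0, 5.0])
        t = CountTable([f"f{k}" for k in range(12)], ["a", "b", "c"], counts, allow_real=True)
        res = variance_rank_analysis([t], methods=("tss", "rle", "raw"))
        assert list(res.method_ranks.iloc[0]) == [1.5, 1.5, 3.0]

    def test_exact_normalization_beats_raw_on_multiplicative_data(self):
        rng = np.random.default_rng(0)
        m = rng.integers(1, 40, size=10).astype(float)
        counts = np.outer(m, [1.0, 2.0, 4.0])
        t = CountTable([f"f{k}" for k in range(10)], ["a", "b", "c"], counts, allow_real=True)
        res = variance_rank_analysis([t], methods=("raw", "tss"))
        med = res.median_variance.iloc[0]
        assert med["tss"] == pytest.approx(0.0, abs=1e-18)
        assert med["raw"] > 0
        assert res.method_ranks.iloc[0]["raw"] == 2.0

    def test_ranks_invariant_to_global_scaling(self):
        rng = np.random.default_rng(1)
        t = random_table(rng, 40, 10, zero_prob=0.4)
        t10 = CountTable(t.feature_ids, t.sample_ids, t.counts * 10)
        r1 = variance_rank_analysis([t], methods=("raw", "gmpr", "tss"))
        r2 = variance_rank_analysis([t10], methods=("raw", "gmpr", "tss"))
        assert r1.method_ranks.equals(r2.method_ranks)

    def test_per_feature_ranks_have_method_columns(self, worked_table):
        res = variance_rank_analysis([worked_table], methods=("raw", "tss"))
        pf = res.per_feature_ranks[0]
        assert list(pf.columns) == ["raw", "tss"]
        assert len(pf) == worked_table.n_features


class TestPrevalenceStratify:
    def test_uniform_prevalence_is_all_top(self):
        t = CountTable(["a", "b", "c"], ["s1", "s2"], np.ones((3, 2), dtype=int))
        assert list(prevalence_stratify(t)) == ["top"] * 3

    def test_three_distinct_levels_one_each(self):
        counts = np.array(
            [[1, 1, 1, 1], [1, 1, 0, 0], [1, 0, 0, 0]]
        )
        t = CountTable(["hi", "mid", "lo"], [f"s{i}" for i in range(4)], counts)
        assert list(prevalence_stratify(t)) == ["top", "middle", "bottom"]

    @pytest.mark.parametrize("q", [6, 7, 8, 9, 30])
    def test_stratum_sizes_balanced_for_distinct_prevalences(self, q):
        n = q + 1
        counts = np.zeros((q, n), dtype=int)
        for k in range(q):
            counts[k, : k + 1] = 1  # prevalence (k+1)/n, all distinct
        t = CountTable([f"f{k}" for k in range(q)], [f"s{i}" for i in range(n)], counts)
        strata = prevalence_stratify(t)
        sizes = [np.sum(strata == s) for s in ("top", "middle", "bottom")]
        assert max(sizes) - min(sizes) <= 1


class TestPairedSignedRank:
    def test_identical_vectors_give_one(self):
        assert paired_signed_rank([1, 2, 3], [1, 2, 3]) == 1.0

    def test_five_positive_differences_exact(self):
        assert paired_signed_rank([2, 3, 4, 5, 6], [1, 1, 1, 1, 1]) == pytest.approx(
            2 / 2**5
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 11))
        a = list(np.round(rng.normal(size=m), 3))
        b = list(np.round(rng.normal(size=m), 3))
        assert paired_signed_rank(a, b) == pytest.approx(signed_rank_bruteforce(a, b))

    def test_agrees_with_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=15), rng.normal(size=15)
        ours = paired_signed_rank(a, b)
        theirs = wilcoxon(a, b, mode="exact").pvalue
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_exact_and_normal_branches_agree_at_crossover(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            a, b = rng.normal(size=25), rng.normal(size=25)
            exact = paired_signed_rank(a, b, exact_max=25)
            approx = paired_signed_rank(a, b, exact_max=0)
            assert abs(exact - approx) < 0.01


class TestICC:
    def test_pure_between_subject_signal_gives_one(self):
        values = np.array([1.0, 1.0, 5.0, 5.0, 9.0, 9.0])
        subjects = ["a", "a", "b", "b", "c", "c"]
        assert icc(values, subjects).rho == 1.0

    def test_pure_noise_clamps_to_zero(self):
        values = np.array([0.0, 2.0, 2.0, 0.0, 0.0, 2.0, 2.0, 0.0])
        subjects = ["a", "a", "b", "b", "c", "c", "d", "d"]
        assert icc(values, subjects).rho == 0.0

    def test_single_subject_rejected(self):
        with pytest.raises(ValidationError):
            icc(np.array([1.0, 2.0]), ["a", "a"])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_unbalanced_designs(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(1, 5, size=5)
        sizes[0] = max(sizes[0], 2)
        subjects = [f"subj{j}" for j, c in enumerate(sizes) for _ in range(c)]
        values = rng.normal(size=len(subjects))
        ours = icc(values, subjects)
        b, e, rho = icc_bruteforce(values, subjects)
        assert ours.sigma_b_sq == pytest.approx(b)
        assert ours.sigma_e_sq == pytest.approx(e)
        assert ours.rho == pytest.approx(rho)

    def test_recovers_known_variance_ratio(self):
        # sigma_b^2 = 3, sigma_e^2 = 1 -> rho = 0.75
        rng = np.random.default_rng(0)
        rhos = []
        for _ in range(200):
            subj_effect = rng.normal(0, np.sqrt(3.0), size=20)
            y = np.repeat(subj_effect, 3) + rng.normal(0, 1.0, size=60)
            subjects = np.repeat([f"p{j}" for j in range(20)], 3)
            rhos.append(icc(y, list(subjects)).rho)
        assert np.mean(rhos) == pytest.approx(0.75, abs=0.03)

    def test_accepts_sample_labels_container(self):
        lab = SampleLabels(["s1", "s2", "s3", "s4"], ["a", "a", "b", "b"])
        assert icc(np.array([1.0, 1.0, 3.0, 3.0]), lab).rho == 1.0
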