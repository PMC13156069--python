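import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssep.core_data import ActivityRecord, aggregate_measurements
from ssep.evaluation import (
    bin_activity,
    evaluate_scores,
    jonckheere_test,
    kruskal_wallis,
    per_substrate_auc_summary,
    per_substrate_benchmark,
    rank_error,
    rmse,
    roc_auc,
    spearman,
)


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def spearman_rho_formula(x, y):
    """1 - 6*sum(d^2)/(n(n^2-1)) for tie-free data."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    d = rx - ry
    n = len(x)
    return 1 - 6 * (d ** 2).sum() / (n * (n ** 2 - 1))


def jt_bruteforce(groups):
    """JT statistic by direct pair counting."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for a in groups[i]:
                for b in groups[j]:
                    jt += (a < b) + 0.5 * (a == b)
    return jt


def perm_pvalue(groups, statistic):
    """One-sided permutation p for any group statistic, by full enumeration
    of multiset permutations of the pooled values."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    obs = statistic(groups)
    count = total = 0
    for perm in set(itertools.permutations(pooled)):
        regrouped, off = [], 0
        for s in sizes:
            regrouped.append(list(perm[off:off + s]))
            off += s
        total += 1
        if statistic(regrouped) >= obs - 1e-12:
            count += 1
    return count / total


class TestSpearman:
    def test_monotone_invariance(self, rng):
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        r1, _ = spearman(x, y)
        r2, _ = spearman(np.exp(x), y)
        assert r1 == pytest.approx(r2)
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        # d = (-1, 1, -1, 1, 0), sum d^2 = 4 -> rho = 1 - 24/120 = 0.8
        rho, _ = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_rho_matches_formula_oracle(self, rng):
        for _ in range(10):
            x = rng.permutation(8).astype(float)
            y = rng.permutation(8).astype(float)
            assert spearman(x, y)[0] == pytest.approx(spearman_rho_formula(x, y))

    def test_exact_p_matches_enumeration_oracle(self, rng):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        rho, p = spearman(x, y)
        count = total = 0
        for perm in itertools.permutations(range(5)):
            total += 1
            if abs(spearman_rho_formula(x[list(perm)], y)) >= abs(rho) - 1e-12:
                count += 1
        assert p == pytest.approx(count / total)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])


class TestErrorMetrics:
    def test_perfect_prediction(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert np.all(rank_error([1, 2, 3], [1, 2, 3]) == 0)

    def test_constant_shift(self):
        obs = np.array([0.1, 0.5, -0.2, 0.9])
        assert rmse(obs + 1, obs) == pytest.approx(1.0)
        assert np.all(rank_error(obs + 1, obs) == 0)

    def test_four_point_rank_table(self):
        pred = [10.0, 20.0, 30.0, 40.0]
        obs = [40.0, 30.0, 20.0, 10.0]
        # ranks reversed: |1-4|, |2-3|, |3-2|, |4-1| over n=4
        assert rank_error(pred, obs) == pytest.approx([0.75, 0.25, 0.25, 0.75])


class TestBinActivity:
    @pytest.mark.parametrize("u, label", [
        (49.9, "decreased"), (50.0, "neutral"), (200.0, "neutral"),
        (201.0, "increased"), (100.0, "neutral"),
    ])
    def test_three_bin_strict_boundaries(self, u, label):
        assert bin_activity(u) == label

    def test_inclusive_variant(self):
        assert bin_activity(50.0, inclusive=True) == "decreased"
        assert bin_activity(200.0, inclusive=True) == "increased"

    @pytest.mark.parametrize("scheme, u, expected", [
        ("threshold_50", 30.0, 1), ("threshold_50", 50.0, 0),
        ("threshold_75", 74.0, 1), ("threshold_125", 130.0, 1),
        ("threshold_150", 150.0, 0), ("threshold_150", 151.0, 1),
    ])
    def test_threshold_schemes(self, scheme, u, expected):
        assert bin_activity(u, scheme) == expected


class TestJonckheere:
    def test_maximal_trend_exact(self):
        jt, p = jonckheere_test([[1, 2], [3, 4], [5, 6]])
        assert jt == 12.0
        assert p == pytest.approx(1 / 90)

    def test_statistic_matches_bruteforce(self, rng):
        groups = [rng.integers(0, 20, 4).astype(float) for _ in range(3)]
        jt, _ = jonckheere_test(groups)
        assert jt == pytest.approx(jt_bruteforce(groups))

    def test_exact_p_matches_permutation_oracle(self, rng):
        groups = [[3.0, 1.0], [2.0, 5.0], [4.0, 6.0]]
        _, p = jonckheere_test(groups)
        assert p == pytest.approx(perm_pvalue(groups, jt_bruteforce))

    def test_no_trend_in_constants(self):
        _, p = jonckheere_test([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])
        assert p == pytest.approx(1.0)

    def test_reversed_trend_p_near_one(self):
        _, p = jonckheere_test([[5, 6], [3, 4], [1, 2]])
        assert p > 0.98

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_test([[1, 2, 3]])

    def test_normal_approx_close_to_exact(self, rng):
        """On tie-free n <= 10 instances the asymptotic one-sided p stays
        within 0.02 of the exact permutation p."""
        for i in range(8):
            vals = rng.permutation(9).astype(float)
            groups = [vals[:3], vals[3:6], vals[6:]]
            _, p_exact = jonckheere_test(groups, method="exact")
            _, p_norm = jonckheere_test(groups, method="asymptotic")
            assert abs(p_norm - p_exact) < 0.02


class TestKruskalWallis:
    def test_matches_scipy_h_and_permutation_oracle(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]
        h, p = kruskal_wallis(groups)
        assert h == pytest.approx(stats.kruskal(*groups).statistic)

        def h_stat(gs):
            return stats.kruskal(*gs).statistic

        assert p == pytest.approx(perm_pvalue(groups, h_stat))

    def test_large_sample_matches_scipy(self, rng):
        groups = [rng.normal(loc, 1.0, 30) for loc in (0.0, 0.3, 0.8)]
        h, p = kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert h == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_identical_groups_h_zero(self):
        h, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert h == 0.0
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], [], [2.0]])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_pair_counting_example(self):
        # 3 of 4 (pos, neg) pairs concordant
        assert roc_auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == 0.75

    def test_null_is_half(self, rng):
        scores = rng.standard_normal(4000)
        labels = rng.integers(0, 2, 4000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_negation_symmetry(self, rng):
        scores = rng.standard_normal(50)  # tie-free almost surely
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_matches_bruteforce_pair_count(self, rng):
        scores = rng.integers(0, 5, 12).astype(float)  # with ties
        labels = np.array([1, 0] * 6)
        pos, neg = scores[labels == 1], scores[labels == 0]
        brute = np.mean([(a > b) + 0.5 * (a == b) for a in pos for b in neg])
        assert roc_auc(scores, labels) == pytest.approx(brute)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


def _benchmark_fixture(rng, n_variants=15, n_substrates=3):
    """Activity table plus a generator-true and a noise prediction method."""
    records, truth_rows, noise_rows = [], [], []
    for s in range(n_substrates):
        sub = f"drug{s}"
        for i in range(n_variants):
            var = f"p.A{i + 2}V"
            u = float(rng.uniform(10, 300))
            records.append(ActivityRecord("G1", var, sub, u))
            truth_rows.append({"gene": "G1", "variant": var, "substrate": sub,
                               "score": np.log10(u / 100)})
            noise_rows.append({"gene": "G1", "variant": var, "substrate": sub,
                               "score": float(rng.standard_normal())})
    table = aggregate_measurements(records)
    return table, pd.DataFrame(truth_rows), pd.DataFrame(noise_rows)


class TestBenchmarks:
    def test_identical_methods_give_null_kw(self, rng):
        table, truth, _ = _benchmark_fixture(rng)
        out = per_substrate_benchmark({"m1": truth, "m2": truth.copy()}, table,
                                      min_variants=10)
        assert out["kruskal_wallis_p"] > 0.5
        assert out["medians"]["m1"] == pytest.approx(out["medians"]["m2"])

    def test_generator_method_wins(self, rng):
        table, truth, noise = _benchmark_fixture(rng)
        out = per_substrate_benchmark({"truth": truth, "noise": noise}, table,
                                      min_variants=10)
        assert out["medians"]["truth"] > out["medians"]["noise"]
        assert out["medians"]["truth"] == pytest.approx(1.0)

    def test_small_substrate_excluded(self, rng):
        table, truth, noise = _benchmark_fixture(rng, n_variants=9)
        with pytest.raises(ValueError, match="no substrate"):
            per_substrate_benchmark({"truth": truth, "noise": noise}, table,
                                    min_variants=10)

    def test_auc_summary_generator_beats_noise(self, rng):
        table, truth, noise = _benchmark_fixture(rng, n_variants=40)
        out = per_substrate_auc_summary({"truth": truth, "noise": noise}, table,
                                        scheme="threshold_50", min_variants=10)
        assert out["truth"]["mean_auc"] > out["noise"]["mean_auc"]
        assert out["truth"]["mean_auc"] == pytest.approx(1.0)

    def test_auc_summary_single_substrate_sem_zero(self, rng):
        table, truth, _ = _benchmark_fixture(rng, n_variants=20, n_substrates=1)
        out = per_substrate_auc_summary(
            {"truth": truth, "shifted": truth.assign(score=truth["score"] + 1)},
            table, min_variants=10)
        assert out["truth"]["n_substrates"] == 1
        assert out["truth"]["sem"] == 0.0

    def test_constant_method_excluded_with_warning(self, rng):
        table, truth, noise = _benchmark_fixture(rng, n_variants=20)
        const = truth.assign(score=1.0)
        with pytest.warns(UserWarning, match="constant"):
            out = per_substrate_auc_summary({"truth": truth, "const": const}, table,
                                            min_variants=10)
        assert out["const"]["n_substrates"] == 0


class TestEvaluateScores:
    def test_full_report_on_planted_scores(self, rng):
        table, truth, _ = _benchmark_fixture(rng, n_variants=25)
        scores = truth.rename(columns={"score": "ssep_score"})
        report = evaluate_scores(scores, table)
        assert report.spearman_rho == pytest.approx(1.0)
        assert report.rmse == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(1.0) for v in report.per_substrate_rho.values())
        assert report.per_gene_auc["G1"] == pytest.approx(1.0)
        assert report.jonckheere_p is not None and report.jonckheere_p < 0.01
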