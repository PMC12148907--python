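import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from attenurank.fidelity import (
    DiscreteDistribution,
    DistributionError,
    contingency_similarity,
    correlation_similarity,
    discretize_pair,
    hellinger,
    ks_complement,
    mixed_pair_similarity,
    quality_report,
    tv_complement,
)


def dist(*probs):
    return DiscreteDistribution(tuple(range(len(probs))), tuple(probs))


class TestHellinger:
    def test_identical_distributions_give_zero(self):
        assert hellinger(dist(0.2, 0.3, 0.5), dist(0.2, 0.3, 0.5)) == 0.0

    def test_disjoint_support_gives_one(self):
        assert hellinger(dist(1, 0, 0), dist(0, 0, 1)) == pytest.approx(1.0)

    def test_point_mass_vs_uniform(self):
        # sqrt(1/2 * ((1-sqrt(.5))^2 + .5)) = sqrt(1 - sqrt(.5)) = 0.5412
        assert hellinger(dist(1.0, 0.0), dist(0.5, 0.5)) == pytest.approx(
            np.sqrt(1 - np.sqrt(0.5)), abs=1e-12
        )

    def test_unnormalized_input_rejected(self):
        with pytest.raises(DistributionError):
            DiscreteDistribution((0, 1), (0.5, 0.6))

    def test_symmetry_and_bounds_random(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            h = hellinger(dist(*p), dist(*q))
            assert 0.0 <= h <= 1.0
            assert h == pytest.approx(hellinger(dist(*q), dist(*p)))

    def test_triangle_inequality(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            p, q, r = (rng.dirichlet(np.ones(4)) for _ in range(3))
            assert hellinger(dist(*p), dist(*r)) <= (
                hellinger(dist(*p), dist(*q)) + hellinger(dist(*q), dist(*r)) + 1e-12
            )


class TestDiscretizePair:
    def test_identical_columns_identical_distributions(self):
        p, q = discretize_pair([1, 2, 3], [1, 2, 3], 4)
        assert p == q

    def test_non_overlapping_ranges_are_disjoint(self):
        p, q = discretize_pair([0.0, 0.4], [10.0, 10.4], 2)
        assert hellinger(p, q) == pytest.approx(1.0)

    def test_hand_binning(self):
        # 3 equal-width bins over [1, 4]; numpy convention: last bin closed.
        p, q = discretize_pair([1, 1, 2, 4], [1, 3, 3, 4], 3)
        np.testing.assert_allclose(p.probabilities, (0.5, 0.25, 0.25))
        np.testing.assert_allclose(q.probabilities, (0.25, 0.0, 0.75))

    def test_zero_range_degenerates_to_single_bin(self):
        p, q = discretize_pair([2.0, 2.0], [2.0], 5)
        assert p.probabilities == (1.0,)
        assert hellinger(p, q) == 0.0


# ---------------------------------------------------------------- oracles
def brute_ks_complement(real, synth):
    """ECDF scan over every pooled point."""
    real, synth = np.asarray(real, float), np.asarray(synth, float)
    gap = 0.0
    for x in np.concatenate([real, synth]):
        gap = max(gap, abs(np.mean(real <= x) - np.mean(synth <= x)))
    return 1.0 - gap


def brute_tv_complement(real, synth):
    cats = set(real) | set(synth)
    total = 0.0
    for c in cats:
        total += abs(
            sum(v == c for v in real) / len(real) - sum(v == c for v in synth) / len(synth)
        )
    return 1.0 - total / 2.0


def brute_correlation_similarity(rp, sp):
    def pearson(a, b):
        a, b = np.asarray(a, float), np.asarray(b, float)
        am, bm = a - a.mean(), b - b.mean()
        return float(np.sum(am * bm) / np.sqrt(np.sum(am**2) * np.sum(bm**2)))

    return 1.0 - abs(pearson(*rp) - pearson(*sp)) / 2.0


def brute_contingency_similarity(rp, sp):
    cells = set(zip(rp[0], rp[1])) | set(zip(sp[0], sp[1]))
    total = 0.0
    n_r, n_s = len(rp[0]), len(sp[0])
    for cell in cells:
        pr = sum(1 for pair in zip(rp[0], rp[1]) if pair == cell) / n_r
        ps = sum(1 for pair in zip(sp[0], sp[1]) if pair == cell) / n_s
        total += abs(pr - ps)
    return 1.0 - total / 2.0


def brute_mixed_pair(rp, sp, n_bins):
    r_num, s_num = np.asarray(rp[0], float), np.asarray(sp[0], float)
    lo, hi = min(r_num.min(), s_num.min()), max(r_num.max(), s_num.max())
    if hi == lo:
        rb, sb = np.zeros(len(r_num), int), np.zeros(len(s_num), int)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        rb = np.clip(np.digitize(r_num, edges[1:-1]), 0, n_bins - 1)
        sb = np.clip(np.digitize(s_num, edges[1:-1]), 0, n_bins - 1)
    return brute_contingency_similarity((list(rb), list(rp[1])), (list(sb), list(sp[1])))


class TestMetricOracleEquivalence:
    @pytest.fixture(scope="class")
    def random_tables(self):
        rng = np.random.default_rng(42)
        tables = []
        for _ in range(100):
            n_r, n_s = rng.integers(5, 30, 2)
            tables.append(
                (
                    pd.DataFrame(
                        {
                            "num1": rng.normal(size=n_r),
                            "num2": rng.normal(size=n_r) + rng.normal() * np.arange(n_r) / n_r,
                            "cat1": rng.choice(list("abc"), n_r),
                            "cat2": rng.integers(0, 2, n_r),
                        }
                    ),
                    pd.DataFrame(
                        {
                            "num1": rng.normal(rng.normal(), 1 + rng.random(), n_s),
                            "num2": rng.normal(size=n_s),
                            "cat1": rng.choice(list("abcd"), n_s),
                            "cat2": rng.integers(0, 2, n_s),
                        }
                    ),
                )
            )
        return tables

    def test_ks_complement_matches_bruteforce(self, random_tables):
        for real, synth in random_tables:
            assert ks_complement(real["num1"], synth["num1"]) == pytest.approx(
                brute_ks_complement(real["num1"], synth["num1"]), abs=1e-12
            )

    def test_tv_complement_matches_bruteforce(self, random_tables):
        for real, synth in random_tables:
            assert tv_complement(real["cat1"], synth["cat1"]) == pytest.approx(
                brute_tv_complement(list(real["cat1"]), list(synth["cat1"])), abs=1e-12
            )

    def test_correlation_similarity_matches_bruteforce(self, random_tables):
        for real, synth in random_tables:
            rp = (real["num1"], real["num2"])
            sp = (synth["num1"], synth["num2"])
            assert correlation_similarity(rp, sp) == pytest.approx(
                brute_correlation_similarity(rp, sp), abs=1e-12
            )

    def test_contingency_similarity_matches_bruteforce(self, random_tables):
        for real, synth in random_tables:
            rp = (list(real["cat1"]), list(real["cat2"]))
            sp = (list(synth["cat1"]), list(synth["cat2"]))
            assert contingency_similarity(rp, sp) == pytest.approx(
                brute_contingency_similarity(rp, sp), abs=1e-12
            )

    def test_mixed_pair_similarity_matches_bruteforce(self, random_tables):
        for real, synth in random_tables:
            rp = (real["num1"], list(real["cat1"]))
            sp = (synth["num1"], list(synth["cat1"]))
            assert mixed_pair_similarity(rp, sp, 5) == pytest.approx(
                brute_mixed_pair(rp, sp, 5), abs=1e-12
            )


class TestPairMetricsAnchors:
    def test_ks_complement_examples(self):
        assert ks_complement([1, 2], [1, 2]) == 1.0
        assert ks_complement([1, 2, 3], [10, 11]) == 0.0
        assert ks_complement([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(0.75)

    def test_tv_complement_examples(self):
        assert tv_complement(list("ab"), list("ab")) == 1.0
        assert tv_complement(list("aa"), list("bb")) == 0.0
        assert tv_complement(list("ab"), list("aaab")) == pytest.approx(0.75)

    def test_correlation_similarity_examples(self):
        x = np.arange(10.0)
        assert correlation_similarity((x, x), (x, x)) == 1.0
        assert correlation_similarity((x, x), (x, -x)) == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(DistributionError):
            correlation_similarity((x, np.ones(10)), (x, x))

    def test_contingency_2x2_example(self):
        real = (["a"] * 4 + ["a"] + ["b"] + ["b"] * 4, ["x"] * 4 + ["y"] + ["x"] + ["y"] * 4)
        synth = (["a", "a", "b", "b"], ["x", "y", "x", "y"])
        assert contingency_similarity(real, synth) == pytest.approx(0.7)


class TestQualityReport:
    def test_self_comparison_scores_one(self, cohort41):
        table = cohort41.drop(columns=["athlete_id"])
        report = quality_report(table, table)
        assert report.overall_score == pytest.approx(1.0)
        assert report.column_shapes_score == pytest.approx(1.0)
        assert report.aggregate_hellinger == pytest.approx(0.0)

    def test_aggregates_equal_hand_means(self):
        rng = np.random.default_rng(3)
        real = pd.DataFrame(
            {"a": rng.normal(size=40), "b": rng.normal(size=40), "c": rng.integers(0, 2, 40)}
        )
        synth = pd.DataFrame(
            {"a": rng.normal(0.5, 1, 40), "b": rng.normal(size=40), "c": rng.integers(0, 2, 40)}
        )
        report = quality_report(real, synth)
        shape_scores = [
            ks_complement(real["a"], synth["a"]),
            ks_complement(real["b"], synth["b"]),
            tv_complement(real["c"], synth["c"]),
        ]
        assert report.column_shapes_score == pytest.approx(np.mean(shape_scores))
        pair_scores = [
            correlation_similarity((real["a"], real["b"]), (synth["a"], synth["b"])),
            mixed_pair_similarity((real["a"], list(real["c"])), (synth["a"], list(synth["c"]))),
            mixed_pair_similarity((real["b"], list(real["c"])), (synth["b"], list(synth["c"]))),
        ]
        assert report.column_pair_trends_score == pytest.approx(np.mean(pair_scores))
        assert report.overall_score == pytest.approx(
            (report.column_shapes_score + report.column_pair_trends_score) / 2
        )

    def test_tier_thresholds(self):
        from attenurank.fidelity import _tier

        assert _tier(0.92) == "high"
        assert _tier(0.82) == "moderate"
        assert _tier(0.70) == "lower"

    def test_schema_mismatch_names_columns(self):
        real = pd.DataFrame({"a": [1.0, 2.0]})
        synth = pd.DataFrame({"b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="schema mismatch"):
            quality_report(real, synth)

    @settings(max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_hellinger_bounds_on_random_binned_columns(self, seed):
        rng = np.random.default_rng(seed)
        p, q = discretize_pair(rng.normal(size=30), rng.normal(rng.normal(), 1, 30), 10)
        assert 0.0 <= hellinger(p, q) <= 1.0
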