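from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutspot import (
    base_weights,
    concordance_analysis,
    cpr_curve,
    enumerate_permutations,
    gaussian_quantile,
    genetic_distance,
    inter_intra_group_test,
    pairwise_weight_correlation,
    pbc_test,
    position_error_rate,
    significance_threshold,
    simulate_base_count_matrix,
)

from _oracles import binom_upper_tail_exact, norm_ppf_acklam

SAMPLES = ["T1", "T2", "T3", "R1", "R2"]


class TestBaseWeights:
    def test_pure_and_split_counts(self):
        np.testing.assert_allclose(
            base_weights(np.array([100, 0, 0, 0])), [1, 0, 0, 0]
        )
        np.testing.assert_allclose(
            base_weights(np.array([50, 50, 0, 0])), [0.5, 0.5, 0, 0]
        )

    @given(
        st.lists(st.integers(0, 10_000), min_size=4, max_size=4).filter(
            lambda c: sum(c) > 0
        )
    )
    @settings(deadline=None, max_examples=100)
    def test_weights_are_counts_over_total(self, counts):
        w = base_weights(np.array(counts))
        tc = sum(counts)
        np.testing.assert_allclose(w, [c / tc for c in counts])
        assert abs(w.sum() - 1) < 1e-12

    def test_uncovered_position_flagged_nan(self):
        assert np.isnan(base_weights(np.zeros(4))).all()


class TestCorrelation:
    def test_identical_samples_give_r_one(self, small_matrix):
        m = small_matrix
        m.counts[:, :, :] = np.random.default_rng(0).integers(
            1, 100, m.counts.shape
        )
        m.counts[:, 1, :] = m.counts[:, 0, :]
        r = pairwise_weight_correlation(m, "T1", "T2")
        assert r == pytest.approx(1.0)

    def test_matches_direct_covariance(self, small_matrix):
        m = small_matrix
        rng = np.random.default_rng(1)
        m.counts[:, :, :] = rng.integers(1, 100, m.counts.shape)
        r = pairwise_weight_correlation(m, "T1", "R1")
        wa = (m.counts[:, 0] / m.counts[:, 0].sum(1, keepdims=True)).ravel()
        wb = (m.counts[:, 3] / m.counts[:, 3].sum(1, keepdims=True)).ravel()
        expect = (
            ((wa - wa.mean()) * (wb - wb.mean())).sum()
            / np.sqrt(((wa - wa.mean()) ** 2).sum())
            / np.sqrt(((wb - wb.mean()) ** 2).sum())
        )
        assert r == pytest.approx(expect, abs=1e-12)

    def test_noise_only_samples_highly_correlated(self):
        m, _ = simulate_base_count_matrix(
            2000, depth_law=(4000, 20), error_law=(0.005, 2000), seed=5
        )
        r = pairwise_weight_correlation(m, "T1", "R1")
        assert r > 0.99

    def test_zero_variance_undefined(self, small_matrix):
        # uniform base composition everywhere: constant weight vector
        small_matrix.counts[:, :, :] = 250
        assert np.isnan(pairwise_weight_correlation(small_matrix, "T1", "T2"))


class TestInterIntra:
    def test_identical_groups_give_p_one(self):
        assert inter_intra_group_test([0.5, 0.5], [0.5, 0.5]) == 1.0

    def test_hand_computed_example(self):
        # pooled-variance t: means 0.15 vs 0.85, each group var 0.005,
        # t = -0.7 / sqrt(0.005 * (1/2 + 1/2)) = -9.8995, df = 2
        p = inter_intra_group_test([0.1, 0.2], [0.8, 0.9])
        assert p == pytest.approx(0.010050506338833, rel=1e-9)

    def test_null_calibration(self):
        # no group-specific signal: p roughly uniform across seeds
        pvals = []
        for seed in range(30):
            m, _ = simulate_base_count_matrix(
                300, depth_law=(4000, 20), error_law=(0.005, 2000), seed=seed
            )
            res = concordance_analysis(m, ["R1", "R2"], ["T1", "T2", "T3"])
            pvals.append(res.inter_intra_p)
        pvals = np.array(pvals)
        assert (pvals < 0.05).mean() < 0.2
        assert pvals.mean() > 0.2


class TestGeneticDistance:
    def test_identical_weights_zero(self):
        assert genetic_distance([0.25] * 4, [0.25] * 4) == 0.0

    def test_maximal_case(self):
        d = genetic_distance([1, 0, 0, 0], [0, 1, 0, 0])
        assert d == pytest.approx(np.sqrt(2))

    @given(
        st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
        st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
        st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
    )
    @settings(deadline=None, max_examples=100)
    def test_metric_axioms(self, a, b, c):
        a, b, c = (np.array(v) / np.sum(v) for v in (a, b, c))
        dab = genetic_distance(a, b)
        assert dab == pytest.approx(
            np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
        )
        assert dab == genetic_distance(b, a)
        assert genetic_distance(a, a) == 0
        assert dab <= genetic_distance(a, c) + genetic_distance(c, b) + 1e-12


class TestErrorModel:
    def test_zero_background_gives_zero_per(self, small_matrix):
        em = position_error_rate(small_matrix, ["R1", "R2"])
        assert (em.per == 0).all()
        assert (em.p0 == 0).all()

    def test_per_arithmetic(self):
        counts = np.zeros((1, 2, 4), dtype=np.int64)
        counts[0, :, 0] = 3980
        counts[0, :, 1] = 20
        import pandas as pd

        from mutspot import BaseCountMatrix

        m = BaseCountMatrix(
            counts, pd.DataFrame({"chrom": ["c"], "pos": [1]}), ["R1", "R2"]
        )
        em = position_error_rate(m, ["R1", "R2"])
        assert em.per[0] == pytest.approx(40 / 8000)
        assert em.tc_ref[0] == 4000
        assert em.p0[0] == pytest.approx(
            0.005 + 1.64 * np.sqrt(0.005 / 4000)
        )

    def test_summed_tc_mode(self):
        m, _ = simulate_base_count_matrix(50, seed=3)
        em_mean = position_error_rate(m, ["R1", "R2"], tc_mode="mean")
        em_sum = position_error_rate(m, ["R1", "R2"], tc_mode="sum")
        pos = em_mean.per > 0
        assert (em_sum.p0[pos] < em_mean.p0[pos]).all()


class TestGaussianQuantile:
    def test_printed_value(self):
        assert round(gaussian_quantile(0.95), 2) == 1.64

    def test_median_is_zero(self):
        assert gaussian_quantile(0.5) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("order", [0.975, 0.8, 0.05, 0.5, 0.999])
    def test_matches_independent_rational_approximation(self, order):
        assert gaussian_quantile(order) == pytest.approx(
            norm_ppf_acklam(order), abs=1e-6
        )

    @pytest.mark.parametrize("order", [0.0, 1.0, -0.1])
    def test_boundary_orders_rejected(self, order):
        with pytest.raises(ValueError):
            gaussian_quantile(order)


class TestPBC:
    def test_zero_background_gives_p_one(self, small_matrix):
        em = position_error_rate(small_matrix, ["R1", "R2"])
        pbc = pbc_test(small_matrix, ["T1", "T2", "T3"], em)
        assert (pbc == 1.0).all()

    def test_matches_exact_binomial_summation(self):
        # successes 10, trials 4000, p0 = 0.005: exact rational tail
        import pandas as pd

        from mutspot import BaseCountMatrix
        from mutspot.concordance import ErrorModel

        counts = np.zeros((1, 3, 4), dtype=np.int64)
        counts[0, :, 0] = 3990
        counts[0, :, 1] = 10
        m = BaseCountMatrix(
            counts, pd.DataFrame({"chrom": ["c"], "pos": [1]}),
            ["T1", "T2", "T3"],
        )
        em = ErrorModel(
            per=np.array([0.004]),
            tc_ref=np.array([4000.0]),
            tc_ref_sum=np.array([8000.0]),
            p0=np.array([0.005]),
        )
        pbc = pbc_test(m, ["T1", "T2", "T3"], em)
        exact = float(binom_upper_tail_exact(10, 4000, Fraction(1, 200)))
        assert pbc[0] == pytest.approx(exact, rel=1e-9)

    def test_monotone_in_successes_and_p0(self):
        from scipy import stats

        p = [stats.binom.sf(k - 1, 4000, 0.005) for k in range(0, 60, 5)]
        assert all(x >= y for x, y in zip(p, p[1:]))
        q = [stats.binom.sf(19, 4000, p0) for p0 in (0.001, 0.005, 0.01)]
        assert all(x <= y for x, y in zip(q, q[1:]))

    def test_planted_variant_passes_family_threshold(self):
        m, _ = simulate_base_count_matrix(
            100,
            planted_variants=[(7, ("T1", "T2", "T3"), 0.5)],
            error_law=(0.001, 2000),
            seed=8,
        )
        em = position_error_rate(m, ["R1", "R2"])
        pbc = pbc_test(m, ["T1", "T2", "T3"], em)
        assert pbc[7] < significance_threshold(0.001, 13_855)

    def test_zero_per_floor_prevents_impossible_null(self):
        # references see zero background, tests see 2 mismatched reads:
        # an unfloored p0 = 0 would declare that impossible (PBC = 0)
        import pandas as pd

        from mutspot import BaseCountMatrix

        counts = np.zeros((1, 5, 4), dtype=np.int64)
        counts[0, :, 0] = 4000
        counts[0, :3, 0] = 3998
        counts[0, :3, 2] = 2
        m = BaseCountMatrix(
            counts, pd.DataFrame({"chrom": ["c"], "pos": [1]}),
            ["T1", "T2", "T3", "R1", "R2"],
        )
        em = position_error_rate(m, ["R1", "R2"])
        assert em.per[0] == 0.0 and em.p0[0] == 0.0
        pbc = pbc_test(m, ["T1", "T2", "T3"], em)
        # floored null p = 1/8001: P(X >= 2 | 4000, 1/8001) ~ 0.09
        exact = float(binom_upper_tail_exact(2, 4000, Fraction(1, 8001)))
        assert pbc[0] == pytest.approx(exact, rel=1e-9)
        assert 0.0 < pbc[0] < 1.0


class TestThreshold:
    def test_printed_value(self):
        t = significance_threshold(0.001, 13_855)
        assert t == pytest.approx(7.218e-8, rel=1e-3)

    @pytest.mark.parametrize(
        "alpha,n,expect", [(0.05, 1, 0.05), (0.001, 10**6, 1e-9)]
    )
    def test_arithmetic(self, alpha, n, expect):
        assert significance_threshold(alpha, n) == pytest.approx(expect)


class TestPermutations:
    def test_ten_schemes_one_case(self):
        schemes = enumerate_permutations(SAMPLES, ["R1", "R2"])
        assert len(schemes) == 10
        assert sum(s.is_case for s in schemes) == 1
        assert sum(not s.is_case for s in schemes) == 9

    def test_schemes_match_exhaustive_2subsets(self):
        from itertools import combinations

        schemes = enumerate_permutations(SAMPLES, ["R1", "R2"])
        got = {frozenset(s.reference_pair) for s in schemes}
        expect = {frozenset(p) for p in combinations(SAMPLES, 2)}
        assert got == expect
        for s in schemes:
            assert set(s.reference_pair) | set(s.test_set) == set(SAMPLES)
            assert not set(s.reference_pair) & set(s.test_set)

    def test_unknown_case_pair_rejected(self):
        with pytest.raises(ValueError):
            enumerate_permutations(SAMPLES, ["R1", "X9"])


class TestCPR:
    def test_symmetric_counts_give_half(self):
        p = {"case": np.full(100, 0.05), "perm": np.full(100, 0.05)}
        df = cpr_curve(p, "case", np.array([0.01, 0.06, 0.1]))
        by_t = df.set_index("threshold")
        assert np.isnan(by_t.loc[0.01, "cpr"])  # 0/0 undefined
        assert by_t.loc[0.06, "cpr"] == 0.5
        assert by_t.loc[0.1, "cpr"] == 0.5

    def test_ratio_arithmetic(self):
        p = {
            "case": np.concatenate([np.zeros(30), np.ones(70)]),
            "perm": np.concatenate([np.zeros(10), np.ones(90)]),
        }
        df = cpr_curve(p, "case", np.array([0.5]))
        assert df["cpr"].iloc[0] == pytest.approx(30 / 40)

    def test_np_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        p = {"case": rng.random(500), "perm": rng.random(500)}
        df = cpr_curve(p, "case", np.linspace(0, 1, 11))
        np_case = df.groupby("threshold")["np_case"].first()
        assert (np.diff(np_case.to_numpy()) >= 0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cpr_curve({"case": np.ones(3), "p": np.ones(3)}, "case",
                      np.array([]))


class TestPipeline:
    def test_label_equivariance(self):
        # PBC for any permutation scheme equals a fresh run where that
        # scheme is declared the case grouping
        m, _ = simulate_base_count_matrix(200, seed=13)
        res = concordance_analysis(m, ["R1", "R2"], ["T1", "T2", "T3"])
        res2 = concordance_analysis(m, ["T1", "R1"], ["T2", "T3", "R2"])
        label = "T1+R1"
        np.testing.assert_allclose(res.pbc[label], res2.pbc[label])
        assert res2.case_label == label
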