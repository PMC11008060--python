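"""Reliability (ICC) and one-tailed Spearman statistics against independent
oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mandair.errors import InsufficientDataError, UndefinedStatisticError
from mandair.stats import (
    benjamini_hochberg,
    describe,
    icc_a1,
    spearman_one_tailed,
)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def icc_a1_oracle(data):
    """Brute-force ICC(A,1) from explicitly looped two-way mean squares."""
    data = np.asarray(data, float)
    n, k = data.shape
    grand = data.sum() / (n * k)
    ssr = sum(k * (data[i].mean() - grand) ** 2 for i in range(n))
    ssc = sum(n * (data[:, j].mean() - grand) ** 2 for j in range(k))
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def spearman_enumeration_oracle(x, y, direction):
    """Exact one-tailed permutation p and rho by full n! enumeration, using
    rank-Pearson computed independently via np.corrcoef."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    rhos = np.array(
        [np.corrcoef(rx, ry[list(p)])[0, 1] for p in itertools.permutations(range(len(x)))]
    )
    if direction == "positive":
        p = np.mean(rhos >= rho_obs - 1e-12)
    else:
        p = np.mean(rhos <= rho_obs + 1e-12)
    return rho_obs, p


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


class TestIccA1:
    def test_perfect_agreement_is_one(self):
        data = np.column_stack([np.arange(10.0), np.arange(10.0)])
        res = icc_a1(data)
        assert res.estimate == pytest.approx(1.0, abs=1e-12)
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_matches_brute_force_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 11))
            data = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1)) * rng.uniform(0, 3)
            res = icc_a1(data)
            assert res.estimate == pytest.approx(icc_a1_oracle(data), abs=1e-10)

    def test_matches_pingouin_estimate_and_ci(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        data = rng.normal(size=(12, 2)) + 2.0 * rng.normal(size=(12, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 2),
                "rater": np.tile([0, 1], 12),
                "score": data.ravel(),
            }
        )
        table = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        ref = table[table["Type"].isin(["ICC2", "ICC(A,1)"])].iloc[0]
        ci = ref[[c for c in table.columns if c.startswith("CI95")][0]]
        res = icc_a1(data)
        assert res.estimate == pytest.approx(ref["ICC"], abs=1e-9)
        # pingouin reports the CI rounded to 2 decimals
        assert res.ci_low == pytest.approx(ci[0], abs=5.1e-3)
        assert res.ci_high == pytest.approx(ci[1], abs=5.1e-3)

    def test_independent_ratings_estimate_near_zero(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(500, 2))  # no subject effect at all
        res = icc_a1(data)
        assert abs(res.estimate) < 0.1

    def test_zero_subject_variance_flagged(self, caplog):
        data = np.tile([[5.0, 6.0]], (6, 1))
        with caplog.at_level("WARNING"):
            res = icc_a1(data)
        assert res.degenerate
        assert res.estimate <= 0.0 or math.isnan(res.estimate)

    def test_affine_invariance(self, rng):
        data = rng.normal(size=(9, 2)) + rng.normal(size=(9, 1))
        a, b = 3.7, -11.0
        r0 = icc_a1(data)
        r1 = icc_a1(a * data + b)
        assert r1.estimate == pytest.approx(r0.estimate, abs=1e-12)
        assert r1.ci_low == pytest.approx(r0.ci_low, abs=1e-9)

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientDataError):
            icc_a1(np.array([[1.0, 2.0], [2.0, 3.0]]))


# ---------------------------------------------------------------------------
# Spearman
# ---------------------------------------------------------------------------


class TestSpearmanOneTailed:
    def test_monotone_increasing_gives_rho_one_minimal_p(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [2.0, 4.0, 5.0, 7.0, 11.0, 20.0]
        res = spearman_one_tailed(x, y, "positive")
        assert res.rho == pytest.approx(1.0)
        assert res.p_one_tailed == pytest.approx(1.0 / math.factorial(6))

    def test_reversed_direction_has_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = spearman_one_tailed(x, x[::-1], "positive")
        assert res.rho == pytest.approx(-1.0)
        assert res.p_one_tailed == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", ["positive", "negative"])
    def test_exact_p_matches_enumeration_with_ties(self, direction, rng):
        for _ in range(5):
            x = rng.integers(0, 4, size=7).astype(float)  # plenty of ties
            y = rng.integers(0, 4, size=7).astype(float)
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            res = spearman_one_tailed(x, y, direction)
            rho_ref, p_ref = spearman_enumeration_oracle(x, y, direction)
            assert res.method == "exact"
            assert res.rho == pytest.approx(rho_ref, abs=1e-12)
            assert res.p_one_tailed == pytest.approx(p_ref, abs=1e-12)

    def test_two_tails_sum_to_one_plus_point_mass(self, rng):
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        p_pos = spearman_one_tailed(x, y, "positive").p_one_tailed
        p_neg = spearman_one_tailed(x, y, "negative").p_one_tailed
        # exact permutation null: P(T>=t) + P(T<=t) = 1 + P(T=t)
        assert p_pos + p_neg >= 1.0
        assert p_pos + p_neg <= 1.0 + 1.0  # point mass bounded by 1
        from scipy.stats import rankdata

        rx, ry = rankdata(x), rankdata(y)
        s_obs = float(rx @ ry)
        perms = np.array(list(itertools.permutations(range(7))))
        s_all = ry[perms] @ rx
        point = np.mean(np.abs(s_all - s_obs) <= 1e-9)
        assert p_pos + p_neg == pytest.approx(1.0 + point, abs=1e-12)

    def test_t_approximation_matches_scipy(self, rng):
        from scipy.stats import spearmanr

        x = rng.normal(size=25)
        y = 0.5 * x + rng.normal(size=25)
        res = spearman_one_tailed(x, y, "positive")
        ref = spearmanr(x, y, alternative="greater")
        assert res.method == "t-approximation"
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_one_tailed == pytest.approx(ref.pvalue, rel=1e-6)

    def test_rho_invariant_under_monotone_transforms(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        r0 = spearman_one_tailed(x, y).rho
        r1 = spearman_one_tailed(np.exp(x), np.arctan(y)).rho
        assert r1 == pytest.approx(r0, abs=1e-12)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(0, 5), min_size=4, max_size=7),
        st.lists(st.integers(0, 5), min_size=4, max_size=7),
    )
    def test_rho_bounded_and_p_valid_for_arbitrary_small_samples(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if len(set(x)) == 1 or len(set(y)) == 1:
            return
        res = spearman_one_tailed(x, y, "positive")
        assert -1.0 <= res.rho <= 1.0
        assert 0.0 < res.p_one_tailed <= 1.0

    def test_constant_vector_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_one_tailed([1.0] * 6, [1, 2, 3, 4, 5, 6])

    def test_too_short_vectors(self):
        with pytest.raises(InsufficientDataError):
            spearman_one_tailed([1, 2, 3], [3, 2, 1])


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------


class TestDescribe:
    def test_worked_example(self):
        s = describe([1, 2, 3, 4, 5])
        assert (s.median, s.q1, s.q3) == (3.0, 2.0, 4.0)

    def test_single_value(self):
        s = describe([7.0])
        assert (s.median, s.q1, s.q3) == (7.0, 7.0, 7.0)

    def test_matches_sort_based_quantile_oracle(self, rng):
        def quantile_oracle(values, q):
            v = sorted(values)
            pos = q * (len(v) - 1)
            lo = int(math.floor(pos))
            hi = min(lo + 1, len(v) - 1)
            return v[lo] + (pos - lo) * (v[hi] - v[lo])

        for _ in range(20):
            v = rng.normal(size=int(rng.integers(1, 40)))
            s = describe(v)
            assert s.q1 == pytest.approx(quantile_oracle(v, 0.25), abs=1e-12)
            assert s.median == pytest.approx(quantile_oracle(v, 0.5), abs=1e-12)
            assert s.q3 == pytest.approx(quantile_oracle(v, 0.75), abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
            min_size=1,
            max_size=40,
        )
    )
    def test_quartiles_bracket_median(self, values):
        s = describe(values)
        assert s.q1 <= s.median <= s.q3
        assert min(values) <= s.median <= max(values)

    def test_empty_raises(self):
        with pytest.raises(InsufficientDataError):
            describe([])


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=12)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
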