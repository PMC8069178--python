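"""Univariate screening statistics against independent oracles, FDR
behavior, and HOMA-IR."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import metsynkit as mk
from metsynkit.screen import by_fdr


# -- independent oracles -------------------------------------------------------

def exact_mwu_oracle(x, y):
    """U of x and its exact two-sided p by exhaustive label enumeration."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])

    def u_of(idx_x):
        xs = pooled[list(idx_x)]
        ys = np.delete(pooled, list(idx_x))
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_of(range(n))
    us = [u_of(c) for c in combinations(range(n + m), n)]
    mu = n * m / 2
    p = sum(abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us) / len(us)
    return u_obs, min(p, 1.0)


def bh_stepup_oracle(p):
    """Literal Benjamini–Hochberg step-up definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running_min = np.inf
    for i in range(m - 1, -1, -1):
        running_min = min(running_min, p[order[i]] * m / (i + 1))
        q_sorted[i] = min(running_min, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


# -- Mann-Whitney --------------------------------------------------------------

class TestMannWhitney:
    def test_complete_separation(self):
        u, p = mk.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_symmetric_u_for_identical_samples(self):
        x = [1.5, 2.5, 3.5, 4.5]
        u, p = mk.mann_whitney_u(x, x)
        assert u == len(x) * len(x) / 2

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mk.mann_whitney_u([], [1.0])

    def test_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            n = int(rng.integers(2, 6))
            m = int(rng.integers(2, 13 - n))
            pooled = rng.permutation(np.arange(n + m, dtype=float))  # tie-free
            x, y = pooled[:n], pooled[n:]
            u, p = mk.mann_whitney_u(x, y)
            u0, p0 = exact_mwu_oracle(x, y)
            assert u == pytest.approx(u0)
            assert p == pytest.approx(p0, abs=1e-12)

    def test_ties_fall_back_to_corrected_normal(self):
        x = [1.0, 2.0, 2.0]
        y = [2.0, 3.0, 4.0]
        u, p = mk.mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert (u, p) == (ref.statistic, ref.pvalue)


# -- Spearman ------------------------------------------------------------------

class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert mk.spearman_rho(x, np.exp(x))[0] == pytest.approx(1.0)
        assert mk.spearman_rho(x, -x**3)[0] == pytest.approx(-1.0)

    def test_ties_equal_rank_pearson_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(4, 15))
            x = rng.integers(0, 4, n).astype(float)   # many ties
            y = rng.integers(0, 4, n).astype(float)
            if np.unique(x).size < 2 or np.unique(y).size < 2:
                continue
            rho, _ = mk.spearman_rho(x, y)
            oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_flagged(self):
        rho, p = mk.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and p == 1.0

    def test_length_contracts(self):
        with pytest.raises(ValueError):
            mk.spearman_rho([1, 2], [1, 2])
        with pytest.raises(ValueError):
            mk.spearman_rho([1, 2, 3], [1, 2])


# -- BH FDR --------------------------------------------------------------------

class TestBH:
    def test_hand_stepup_example(self):
        np.testing.assert_allclose(mk.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert mk.bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        p = rng.random(20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(mk.bh_fdr(p)[perm], mk.bh_fdr(p[perm]))

    @given(st.integers(0, 2**31 - 1))
    def test_equals_brute_force_stepup(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 51)))
        np.testing.assert_allclose(mk.bh_fdr(p), bh_stepup_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mk.bh_fdr([0.5, 1.2])

    def test_by_variant_more_conservative(self):
        p = np.array([0.001, 0.01, 0.02, 0.5])
        assert (by_fdr(p) >= mk.bh_fdr(p) - 1e-12).all()


# -- screens -------------------------------------------------------------------

class TestScreens:
    def test_group_screen_recovers_planted(self, small_pre, small_cohort):
        truth = small_cohort[1]
        labels = np.where(truth.ir_labels, "IR", "N-IR")
        results = mk.screen_groups(small_pre, labels)
        by_p = sorted(results, key=lambda r: r.p_value)
        planted = {f"met_{i:04d}" for i in (0, 1, 2)}
        # all planted columns rank near the top, the strongest one leads,
        # and at least one survives FDR at this small n
        assert planted <= {r.metabolite_id for r in by_p[:10]}
        assert by_p[0].metabolite_id in planted
        assert any(r.metabolite_id in planted for r in mk.significant(results))

    def test_single_class_rejected(self, small_pre):
        with pytest.raises(ValueError):
            mk.screen_groups(small_pre, ["IR"] * small_pre.n_samples)

    def test_missing_values_rejected(self, small_table):
        labels = ["a"] * 20 + ["b"] * 20
        with pytest.raises(ValueError, match="missing"):
            mk.screen_groups(small_table, labels)

    def test_group_screen_matches_scalar_path(self, small_pre, small_cohort):
        truth = small_cohort[1]
        labels = np.where(truth.ir_labels, "IR", "N-IR")
        results = mk.screen_groups(small_pre, labels)
        x = small_pre.abundances.to_numpy()
        a, b = x[labels == "IR"], x[labels == "N-IR"]
        for j in [0, 7, 31]:
            ref = stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided",
                                     method="asymptotic")
            assert results[j].statistic == pytest.approx(ref.statistic)
            assert results[j].p_value == pytest.approx(ref.pvalue)

    def test_self_correlation_tops_screen(self, small_pre):
        outcome = small_pre.abundances.iloc[:, 5].to_numpy()
        results = mk.screen_correlation(small_pre, outcome)
        best = min(results, key=lambda r: (r.q_value, -abs(r.statistic)))
        assert best.metabolite_id == small_pre.metabolite_ids[5]
        assert best.statistic == pytest.approx(1.0)

    def test_correlation_matches_scipy_spearman(self, small_pre, small_cohort):
        truth = small_cohort[1]
        outcome = truth.fram_driver
        results = mk.screen_correlation(small_pre, outcome)
        x = small_pre.abundances.to_numpy()
        for j in [0, 3, 17]:
            rho, p = stats.spearmanr(x[:, j], outcome)
            assert results[j].statistic == pytest.approx(rho, abs=1e-10)
            assert results[j].p_value == pytest.approx(p, rel=1e-6)

    def test_permuted_labels_kill_hits(self, small_pre, small_cohort):
        truth = small_cohort[1]
        rng = np.random.default_rng(4)
        labels = np.where(rng.permutation(truth.ir_labels), "IR", "N-IR")
        results = mk.screen_groups(small_pre, labels)
        assert len(mk.significant(results)) <= 2


# -- HOMA-IR -------------------------------------------------------------------

class TestHomaIR:
    def test_unit_conversion_identity(self):
        # insulin 6.945 pmol/L is 1 uU/mL, so HOMA-IR = glucose/22.5
        assert mk.homa_ir(5.0, 6.945) == pytest.approx(5.0 / 22.5)

    def test_linear_in_insulin(self):
        assert mk.homa_ir(5.0, 200.0) == pytest.approx(2 * mk.homa_ir(5.0, 100.0))

    def test_direct_evaluation(self):
        assert mk.homa_ir(5.72, 109.0) == pytest.approx(3.9896, abs=1e-3)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            mk.homa_ir(0.0, 100.0)
        with pytest.raises(ValueError):
            mk.homa_ir(5.0, -1.0)
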