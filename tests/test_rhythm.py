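import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dielnet.rhythm import (
    JtkConfig,
    bh_qvalues,
    classify_rhythmic,
    cosinor_fit,
    exact_null,
    jt_statistic,
    jtk_scan,
    jtk_scan_matrix,
    reference_ordering,
    rhythm_summaries,
)
from oracles import (
    bh_brute,
    jt_null_by_permutation,
    jt_statistic_brute,
    two_sided_p_from_null,
)

TIMES_12x4 = np.repeat(np.arange(0, 48, 4.0), 4)


class TestReferenceOrdering:
    def test_peak_and_trough_positions(self):
        t = np.arange(0, 24, 4.0)
        r = reference_ordering(t, 24, 0)
        assert r[0] == r.max()  # t = 0 at the crest
        assert r[list(t).index(12.0)] == r.min()

    def test_periodicity_in_phase(self):
        t = np.arange(0, 48, 4.0)
        np.testing.assert_allclose(
            reference_ordering(t, 24, 6), reference_ordering(t, 24, 30)
        )

    def test_antiphase_reverses_ordering(self):
        t = np.arange(0, 48, 4.0)
        a = reference_ordering(t, 24, 0)
        b = reference_ordering(t, 24, 12)
        np.testing.assert_allclose(a + b, (len(t) + 1) * np.ones(len(t)))

    def test_replicates_share_tie_groups(self):
        r = reference_ordering(TIMES_12x4, 24, 0)
        for tp in np.unique(TIMES_12x4):
            assert len(set(r[TIMES_12x4 == tp])) == 1

    def test_invalid_period(self):
        with pytest.raises(ValueError):
            reference_ordering([0, 4], 0, 0)


class TestJtStatistic:
    @pytest.mark.parametrize(
        "y,ref,expected",
        [
            ([1, 2, 3], [1, 2, 3], 3),
            ([1, 3, 2], [1, 2, 3], 1),
            ([5, 5, 5], [1, 2, 3], 0),
        ],
    )
    def test_examples(self, y, ref, expected):
        assert jt_statistic(y, ref) == expected

    @given(
        st.lists(st.integers(0, 5), min_size=3, max_size=8),
        st.lists(st.integers(0, 3), min_size=3, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force(self, y, ref):
        n = min(len(y), len(ref))
        y, ref = y[:n], ref[:n]
        assert jt_statistic(y, ref) == jt_statistic_brute(y, ref)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            jt_statistic([1, 2], [1, 2, 3])


class TestExactNull:
    def test_mass_sums_to_one_and_symmetry(self):
        ref = reference_ordering(TIMES_12x4, 24, 0)
        s, p = exact_null(ref)
        assert abs(p.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(p, p[::-1], atol=1e-15)  # P(S=s) = P(S=-s)

    def test_matches_exhaustive_permutation_n5(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s_vals, probs = exact_null(ref)
        null = jt_null_by_permutation(ref)
        for s, p in zip(s_vals, probs):
            assert abs(p - null.get(int(s), 0.0)) < 1e-12

    def test_matches_permutation_with_ties(self):
        ref = np.array([1.5, 1.5, 3.0, 4.5, 4.5, 6.0])
        s_vals, probs = exact_null(ref)
        null = jt_null_by_permutation(ref)
        for s, p in zip(s_vals, probs):
            assert abs(p - null.get(int(s), 0.0)) < 1e-12


class TestJtkScan:
    def test_noiseless_cosine_hits_design_minimum(self):
        t = np.arange(0, 48, 4.0)
        y = 100 * 2 ** np.cos(2 * np.pi * (t - 8) / 24)
        cfg = JtkConfig()
        res = jtk_scan(y, t, cfg)
        assert res.best_period_h == 24.0
        assert res.phase_zt == 8.0
        # p equals the minimum attainable for this design and scan grid
        probe = jtk_scan_matrix(y[None, :], t, cfg)
        ref = reference_ordering(t, 24, 8)
        _, probs = exact_null(ref)
        n_distinct = 3  # six phases in antiphase-mirrored pairs
        assert res.p_value == pytest.approx(2 * probs[0] * n_distinct)

    def test_mirror_series_same_p_opposite_phase(self):
        t = TIMES_12x4
        rng = np.random.default_rng(1)
        y = np.cos(2 * np.pi * (t - 4) / 24) + rng.normal(0, 0.2, len(t))
        a = jtk_scan(y, t)
        b = jtk_scan(-y, t)
        assert a.p_value == pytest.approx(b.p_value)
        assert (a.phase_zt - b.phase_zt) % 24 == pytest.approx(12.0)

    def test_scale_shift_invariance(self):
        t = TIMES_12x4
        rng = np.random.default_rng(2)
        y = np.cos(2 * np.pi * t / 24) + rng.normal(0, 0.3, len(t))
        a = jtk_scan(y, t)
        b = jtk_scan(3.5 * y + 10, t)
        assert a.p_value == b.p_value
        assert a.phase_zt == b.phase_zt

    def test_constant_series_degenerate(self):
        t = np.arange(0, 48, 4.0)
        res = jtk_scan(np.full(len(t), 7.0), t)
        assert res.p_value == 1.0
        assert res.fold_change == 1.0

    def test_null_p_uniform_for_single_ordering(self):
        """Exact per-ordering p-values are uniform under pure noise."""
        rng = np.random.default_rng(3)
        y = rng.normal(size=(500, len(TIMES_12x4)))
        cfg = JtkConfig(candidate_periods_h=[24.0], candidate_phases_h=[0.0])
        res = jtk_scan_matrix(y, TIMES_12x4, cfg)
        ks = stats.kstest(res["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_scan_p_is_conservative_under_null(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=(500, len(TIMES_12x4)))
        res = jtk_scan_matrix(y, TIMES_12x4)
        for x in (0.01, 0.05, 0.2):
            assert (res["p_value"] <= x).mean() <= x + 0.02


class TestBhQvalues:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_qvalues([0.01, 0.04, 0.03, 0.05]), [0.04, 0.05, 0.05, 0.05]
        )

    def test_single_and_equal(self):
        assert bh_qvalues([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_qvalues([0.2] * 5), [0.2] * 5)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_step_up(self, p):
        np.testing.assert_allclose(bh_qvalues(p), bh_brute(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.5])


class TestClassify:
    def _frame(self, rows):
        import pandas as pd

        return pd.DataFrame(
            rows, columns=["q_value", "best_period_h"],
            index=[f"g{i}" for i in range(len(rows))],
        )

    def test_rules(self):
        frame = self._frame([[0.05, 24.0], [0.05, 28.0], [0.2, 24.0]])
        assert classify_rhythmic(frame) == {"g0"}

    def test_relaxed_window_admits_28h(self):
        frame = self._frame([[0.05, 28.0]])
        cfg = JtkConfig(period_window_h=(22.0, 28.0))
        assert classify_rhythmic(frame, cfg) == {"g0"}


class TestCosinor:
    def test_exact_cosine(self):
        t = np.arange(0, 48, 4.0)
        res = cosinor_fit(np.cos(2 * np.pi * t / 24), t)
        assert res.amplitude == pytest.approx(1.0)
        assert res.acrophase_zt == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_series_flagged(self):
        t = np.arange(0, 48, 4.0)
        res = cosinor_fit(np.full(len(t), 2.0), t)
        assert res.amplitude == 0.0
        assert res.p_value == 1.0

    def test_recovers_planted_coefficients(self):
        rng = np.random.default_rng(5)
        t = TIMES_12x4
        w = 2 * np.pi * t / 24
        y = 5 + 1.0 * np.cos(w) + 1.0 * np.sin(w) + rng.normal(0, 0.1, len(t))
        # oracle: normal-equations solution
        X = np.column_stack([np.ones_like(t), np.cos(w), np.sin(w)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        res = cosinor_fit(y, t)
        resid_sd = 0.1
        se = resid_sd * np.sqrt(np.diag(np.linalg.inv(X.T @ X)))
        assert abs(res.mesor - 5) < 3 * se[0]
        np.testing.assert_allclose(
            [res.mesor, np.hypot(beta[1], beta[2])],
            [beta[0], res.amplitude],
            rtol=1e-10,
        )

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError):
            cosinor_fit([1.0, 2.0, 3.0, 4.0], [0.0, 0.0, 0.0, 0.0])


class TestSummaries:
    def test_median_and_bins(self):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "fold_change": [1.5, 2.0, 3.0],
                "phase_zt": [6.0, 6.0, 6.0],
            },
            index=["a", "b", "c"],
        )
        out = rhythm_summaries(frame, {"a", "b", "c"})
        assert out["median_fold_change"] == 2.0
        assert sum(c > 0 for c in out["phase_counts"]) == 1

    def test_empty_set_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            rhythm_summaries(pd.DataFrame(columns=["fold_change", "phase_zt"]), set())

    def test_detected_median_fold_near_planted_median(self, default_sim):
        from dielnet.preprocess import filter_background
        from dielnet.rhythm import classify_rhythmic

        m, truth = default_sim
        filtered, _ = filter_background(m)
        res = jtk_scan_matrix(
            filtered.values.to_numpy(), filtered.zt, gene_ids=filtered.gene_ids
        )
        called = classify_rhythmic(res)
        out = rhythm_summaries(res, called)
        assert abs(out["median_fold_change"] - 2.06) / 2.06 < 0.10

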