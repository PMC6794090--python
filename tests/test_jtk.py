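"""JTK rhythmicity test: reference patterns, Kendall S, exact null, recovery."""

import itertools

import numpy as np
import pytest

from flyclock.jtk import (
    ExpressionTimeCourse,
    exact_null,
    exact_p_two_sided,
    jtk_cycle,
    kendall_s,
    reference_patterns,
)
from flyclock.simulate import SyntheticTimecourseParams, simulate_timecourse

CT7 = (1.0, 5.0, 9.0, 13.0, 17.0, 21.0, 25.0)


class TestReferencePatterns:
    def test_period24_lags_dedup_to_at_most_six(self):
        pats = reference_patterns(CT7, periods_h=[24.0], lag_step_h=4.0)
        assert 1 <= len(pats) <= 6
        # CT1 and CT25 are one cycle apart: tied in every period-24 pattern
        for p in pats:
            assert p.ranks[0] == p.ranks[-1]

    def test_lag_shift_by_full_period_collapses(self):
        a = reference_patterns(CT7, periods_h=[24.0], lag_step_h=24.0)
        assert len(a) == 1 and a[0].lag_h == 0.0

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            reference_patterns([1.0, 1.0], periods_h=[24.0])

    def test_empty_period_list_rejected(self):
        with pytest.raises(ValueError):
            reference_patterns(CT7, periods_h=[])


class TestKendallS:
    def test_perfect_concordance(self):
        s, tau = kendall_s([1.0, 2.0, 3.0, 4.0], [1, 2, 3, 4])
        assert s == 6 and tau == pytest.approx(1.0)

    def test_perfect_reversal(self):
        s, tau = kendall_s([4.0, 3.0, 2.0, 1.0], [1, 2, 3, 4])
        assert s == -6 and tau == pytest.approx(-1.0)

    def test_three_value_pair_enumeration(self):
        # pairs of (1,3,2) vs (1,2,3): (1,3)+, (1,2)+, (3,2)- -> S = 1
        s, tau = kendall_s([1.0, 3.0, 2.0], [1, 2, 3])
        assert s == 1
        assert tau == pytest.approx(1 / 3)

    def test_ties_contribute_zero(self):
        s, _ = kendall_s([1.0, 1.0, 2.0], [1, 2, 3])
        assert s == 2  # only the two untied pairs count

    def test_all_tied_flagged(self):
        _, tau = kendall_s([5.0, 5.0, 5.0], [1, 2, 3])
        assert tau is None


class TestExactNull:
    @pytest.mark.parametrize(
        "ranks",
        [(1, 2, 3), (1, 1, 2, 3), (1, 1, 2, 2), (1, 2, 3, 4, 5), (1, 1, 1, 2, 3)],
    )
    def test_matches_exhaustive_enumeration(self, ranks):
        n = len(ranks)
        s_vals, probs = exact_null(ranks)
        brute: dict[int, int] = {}
        for perm in itertools.permutations(range(1, n + 1)):
            s, _ = kendall_s(np.asarray(perm, float), np.asarray(ranks, float))
            brute[s] = brute.get(s, 0) + 1
        total = sum(brute.values())
        for s, p in zip(s_vals, probs):
            assert p == pytest.approx(brute.get(int(s), 0) / total, abs=1e-12)

    def test_total_mass_one_and_symmetric(self):
        ranks = (1, 1, 2, 3, 3, 4, 1)
        s_vals, probs = exact_null(ranks)
        assert probs.sum() == pytest.approx(1.0)
        lookup = dict(zip(s_vals.tolist(), probs.tolist()))
        for s, p in lookup.items():
            assert p == pytest.approx(lookup[-s])

    def test_p_matches_permutation_sampling(self):
        rng = np.random.default_rng(0)
        ranks = np.array([1, 1, 2, 2, 3, 3, 4, 4])
        s_vals, probs = exact_null(tuple(ranks))
        data = rng.normal(size=ranks.size)
        s_obs, _ = kendall_s(data, ranks.astype(float))
        p_exact = exact_p_two_sided(s_obs, s_vals, probs)
        n_perm = 10_000
        hits = 0
        for _ in range(n_perm):
            s, _ = kendall_s(rng.permutation(data), ranks.astype(float))
            hits += abs(s) >= abs(s_obs)
        p_mc = hits / n_perm
        assert abs(p_exact - p_mc) < 4 * np.sqrt(p_exact * (1 - p_exact) / n_perm) + 1e-3


class TestJtkCycle:
    def test_noiseless_cosine_recovery(self):
        tc = simulate_timecourse(
            SyntheticTimecourseParams(noise_cv=0.0, acrophase_ct=13.0, seed=0)
        )
        res = jtk_cycle(tc)
        assert res.rhythmic
        assert res.best_period_h == 24.0
        assert abs(res.best_lag_h - 13.0) <= 4.0
        assert res.tau > 0

    def test_bonferroni_bound(self):
        tc = simulate_timecourse(SyntheticTimecourseParams(seed=1))
        res = jtk_cycle(tc)
        assert res.p_adj == pytest.approx(min(1.0, res.p_exact * res.n_alternatives))
        assert res.p_adj >= res.p_exact

    def test_monotone_transform_invariance(self):
        tc = simulate_timecourse(SyntheticTimecourseParams(seed=2))
        # a common strictly monotone map preserves every rank, hence the result
        common = ExpressionTimeCourse(
            gene=tc.gene, timepoints=tc.timepoints, values=[np.exp(v) for v in tc.values]
        )
        a, b = jtk_cycle(tc), jtk_cycle(common)
        assert a.tau == pytest.approx(b.tau)
        assert a.p_exact == pytest.approx(b.p_exact)
        assert a.best_period_h == b.best_period_h

    def test_replicate_order_invariance(self):
        tc = simulate_timecourse(SyntheticTimecourseParams(seed=3))
        shuffled = ExpressionTimeCourse(
            gene=tc.gene,
            timepoints=tc.timepoints,
            values=[v[::-1].copy() for v in tc.values],
        )
        a, b = jtk_cycle(tc), jtk_cycle(shuffled)
        assert a.tau == pytest.approx(b.tau)
        assert a.p_exact == pytest.approx(b.p_exact)

    def test_flat_course_type_one_error(self):
        hits = 0
        n_sim = 300
        for i in range(n_sim):
            tc = simulate_timecourse(
                SyntheticTimecourseParams(rel_amplitude=0.0, noise_cv=0.2, seed=9000 + i)
            )
            hits += jtk_cycle(tc).rhythmic
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert hits / n_sim <= 0.05 + 3 * se

    def test_power_at_double_noise_amplitude(self):
        hits = 0
        n_sim = 150
        for i in range(n_sim):
            tc = simulate_timecourse(
                SyntheticTimecourseParams(
                    rel_amplitude=0.4, noise_cv=0.2, acrophase_ct=13.0, seed=7000 + i
                )
            )
            hits += jtk_cycle(tc).rhythmic
        assert hits / n_sim >= 0.9
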