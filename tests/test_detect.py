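"""Umbrella rank test: statistic, exact null, moments, BH, detection table."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from polarhythm.design import TimeSeriesDesign
from polarhythm.detect import (
    EXACT_N_MAX, UmbrellaPattern, all_patterns, bh_adjust, detect_rhythms,
    fold_timepoints, jt_statistic, pattern_p, umbrella_test,
    _enumerate_assignments, _exact_null_survival, _h_matrix, _null_moments,
    _pattern_constants, _row_tie_stats,
)


# --------------------------------------------------------------------------
# independent oracles (deliberately written differently from the library)
# --------------------------------------------------------------------------

def oracle_pattern_p(groups, pattern):
    """Right-tail p by looping over every group assignment in pure Python."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    m = len(groups)
    pairs = pattern.pairs(m)

    def stat(assign):
        u = 0.0
        for i, j in pairs:
            for a in assign[i]:
                for b in assign[j]:
                    if pooled[a] < pooled[b]:
                        u += 1.0
                    elif pooled[a] == pooled[b]:
                        u += 0.5
        return u

    obs = stat([list(range(sum(sizes[:k]), sum(sizes[:k + 1]))) for k in range(m)])

    def assignments(remaining, k):
        if k == m - 1:
            yield [sorted(remaining)]
            return
        for combo in itertools.combinations(sorted(remaining), sizes[k]):
            rest = set(remaining) - set(combo)
            for tail in assignments(rest, k + 1):
                yield [list(combo)] + tail

    total = hits = 0
    for assign in assignments(set(range(len(pooled))), 0):
        total += 1
        if stat(assign) >= obs - 1e-9:
            hits += 1
    return hits / total


def oracle_bh(pvals):
    """Step-up BH by direct application of the textbook formula."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# --------------------------------------------------------------------------
# folding
# --------------------------------------------------------------------------

class TestFoldTimepoints:
    @pytest.mark.parametrize(
        "period, sizes",
        [(24.0, (6, 3, 3, 3, 3, 3)), (20.0, (6, 6, 3, 3, 3)),
         (16.0, (6, 6, 6, 3)), (12.0, (9, 6, 6))],
    )
    def test_default_design_group_sizes(self, default_design, period, sizes):
        fold = fold_timepoints(default_design, period)
        assert fold.sizes == sizes
        assert sum(fold.sizes) == default_design.n_samples

    def test_every_sample_in_exactly_one_group(self, default_design):
        fold = fold_timepoints(default_design, 16.0)
        seen = sorted(i for g in fold.groups for i in g)
        assert seen == list(range(default_design.n_samples))

    def test_untestable_period_raises(self):
        design = TimeSeriesDesign((0.0, 4.0, 8.0), replicates=2)
        with pytest.raises(ValueError, match="untestable"):
            fold_timepoints(design, 4.0)


# --------------------------------------------------------------------------
# statistic
# --------------------------------------------------------------------------

ASC2 = UmbrellaPattern(peak_index=1, rise_length=1)


class TestJTStatistic:
    def test_hand_counts(self):
        assert jt_statistic([[1, 2], [3, 4]], ASC2) == 4.0
        assert jt_statistic([[3, 4], [1, 2]], ASC2) == 0.0
        assert jt_statistic([[1], [2], [1]], UmbrellaPattern(1, 1)) == 2.0

    def test_pattern_count_is_m_times_m_minus_1(self):
        for m in (2, 3, 4, 5, 6):
            assert len(all_patterns(m)) == m * (m - 1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            jt_statistic([[1, 2], []], ASC2)


class TestPatternP:
    def test_two_group_ascending_equals_one_sixth(self):
        assert pattern_p([[1, 2], [3, 4]], ASC2) == pytest.approx(1 / 6, abs=1e-12)

    def test_all_tied_values_give_p_one(self):
        assert pattern_p([[1, 1], [1, 1], [1, 1]], UmbrellaPattern(1, 1)) == 1.0

    def test_exact_matches_bruteforce_n9_with_ties(self, rng):
        values = rng.integers(0, 5, 9).astype(float)
        groups = [values[:3], values[3:6], values[6:]]
        for pat in all_patterns(3):
            assert pattern_p(groups, pat) == pytest.approx(
                oracle_pattern_p(groups, pat), abs=1e-12
            )

    def test_dp_survival_matches_enumeration_at_boundary(self, rng):
        # the convolution used beyond the enumeration limit must agree with
        # enumeration on untied data where both apply
        for sizes in [(3, 3, 3), (4, 3, 3), (2, 2, 2, 2)]:
            values = rng.permutation(sum(sizes)).astype(float)
            h = _h_matrix(values)
            labels = _enumerate_assignments(sizes)
            for pat in all_patterns(len(sizes))[: 6]:
                pairs = tuple(pat.pairs(len(sizes)))
                u_all = np.zeros(labels.shape[0])
                for i, j in pairs:
                    mi = (labels == i).astype(float)
                    mj = (labels == j).astype(float)
                    u_all += ((mi @ h) * mj).sum(axis=1)
                sf = _exact_null_survival(sizes, pairs)
                for u in range(len(sf)):
                    assert sf[u] == pytest.approx(
                        float(np.mean(u_all >= u - 1e-9)), abs=1e-12
                    )

    def test_null_moments_match_enumeration_with_ties(self, rng):
        # closed-form permutation mean/variance vs the enumerated distribution
        for sizes in [(3, 3, 3), (2, 3, 2, 2)]:
            values = rng.integers(0, 4, sum(sizes)).astype(float)
            h = _h_matrix(values)
            labels = _enumerate_assignments(sizes)
            stats = _row_tie_stats(h)
            for pat in all_patterns(len(sizes)):
                pairs = tuple(pat.pairs(len(sizes)))
                u_all = np.zeros(labels.shape[0])
                for i, j in pairs:
                    mi = (labels == i).astype(float)
                    mj = (labels == j).astype(float)
                    u_all += ((mi @ h) * mj).sum(axis=1)
                c = _pattern_constants(sizes, pat)
                mean, var = _null_moments(stats, c)
                assert float(mean) == pytest.approx(u_all.mean(), abs=1e-9)
                assert float(var) == pytest.approx(u_all.var(), abs=1e-8)


class TestUmbrellaTest:
    def test_constant_row_is_null(self, default_design):
        fold = fold_timepoints(default_design, 24.0)
        raw_p, _ = umbrella_test(np.full(21, 3.0), fold)
        assert raw_p == 1.0

    def test_rank_invariance_under_monotone_transform(self, default_design, rng):
        fold = fold_timepoints(default_design, 24.0)
        row = rng.normal(size=21)
        p1, pat1 = umbrella_test(row, fold)
        p2, pat2 = umbrella_test(np.exp(row), fold)
        assert p1 == p2
        assert pat1 == pat2

    def test_circular_shift_moves_peak_index(self, rng):
        # exactly cyclic design: 6 positions, no duplicated endpoint
        design = TimeSeriesDesign((0.0, 4.0, 8.0, 12.0, 16.0, 20.0), replicates=3)
        fold = fold_timepoints(design, 24.0)
        row = rng.normal(size=design.n_samples) + np.cos(
            2 * np.pi * np.array(design.sample_times()) / 24.0
        ) * 2.0
        p1, pat1 = umbrella_test(row, fold)
        shifted = row.reshape(6, 3)[np.r_[1:6, 0]].ravel()  # rotate one step
        p2, pat2 = umbrella_test(shifted, fold)
        assert p1 == pytest.approx(p2, abs=1e-12)
        assert pat2.peak_index == (pat1.peak_index - 1) % 6

    def test_bonferroni_never_below_best_pattern_p(self, default_design, rng):
        fold = fold_timepoints(default_design, 12.0)
        row = rng.normal(size=21)
        raw_p, best = umbrella_test(row, fold)
        best_p = pattern_p([row[list(g)] for g in fold.groups], best)
        assert raw_p == pytest.approx(min(1.0, best_p * len(all_patterns(3))))


# --------------------------------------------------------------------------
# BH adjustment
# --------------------------------------------------------------------------

class TestBHAdjust:
    def test_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_one(self):
        assert bh_adjust([1.0]) == pytest.approx([1.0])

    def test_rejects_out_of_range(self):
        for bad in ([0.0], [-0.1], [1.5], [np.nan]):
            with pytest.raises(ValueError):
                bh_adjust(bad)

    @given(st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=40))
    def test_matches_textbook_stepup_and_invariants(self, pvals):
        adj = bh_adjust(pvals)
        expected = oracle_bh(pvals)
        assert np.allclose(adj, expected, atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all((adj > 0) & (adj <= 1))

    @given(st.lists(st.floats(1e-9, 1.0), min_size=2, max_size=20),
           st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        adj = bh_adjust(pvals)
        adj_perm = bh_adjust([pvals[i] for i in perm])
        assert np.allclose([adj[i] for i in perm], adj_perm)


# --------------------------------------------------------------------------
# detection table
# --------------------------------------------------------------------------

class TestDetectRhythms:
    def test_constant_matrix_detects_nothing(self, default_design):
        mat = pd.DataFrame(np.full((5, 21), 2.0),
                           index=[f"t{i}" for i in range(5)])
        res = detect_rhythms(mat, default_design)
        assert (res["assigned_adj_p"] == 1.0).all()

    def test_planted_12h_rows_classified_ultradian(self, default_design, rng):
        t = np.array(default_design.sample_times())
        rows = np.array([
            10 * (1 + (1 + np.cos(2 * np.pi * t / 12.0))) * np.exp(rng.normal(0, 0.05, t.size))
            for _ in range(5)
        ])
        res = detect_rhythms(rows, default_design)
        assert (res["assigned_period_h"] == 12.0).all()
        assert (res["period_range"] == "ultradian").all()

    def test_assignment_is_argmin_of_joint_adjustment(self, default_design, rng):
        rows = rng.normal(size=(30, 21)) ** 2 + 0.1
        res = detect_rhythms(rows, default_design)
        adj_cols = res[[c for c in res.columns if c.startswith("adj_p_")]]
        assert np.allclose(res["assigned_adj_p"], adj_cols.min(axis=1))

    def test_monotone_power_in_amplitude(self, default_design):
        t = np.array(default_design.sample_times())
        rates = []
        for amp in (0.5, 1.0, 2.0, 5.0):
            rng = np.random.default_rng(5)
            rows = np.array([
                10 * (1 + amp / 2 * (1 + np.cos(2 * np.pi * (t - 4 * (i % 6)) / 24)))
                * np.exp(rng.normal(0, 0.25, t.size))
                for i in range(40)
            ])
            res = detect_rhythms(rows, default_design, periods=[24.0])
            rates.append((res["raw_p_24"] < 0.01).mean())
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_small_design_uses_exact_enumeration(self, rng):
        design = TimeSeriesDesign((0.0, 8.0, 16.0), replicates=3)
        rows = rng.normal(size=(4, 9))
        res = detect_rhythms(rows, design, periods=[24.0])
        fold = fold_timepoints(design, 24.0)
        for i in range(4):
            expect, _ = umbrella_test(rows[i], fold, exact_n_max=EXACT_N_MAX)
            assert res["raw_p_24"].iloc[i] == pytest.approx(expect, abs=1e-12)
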