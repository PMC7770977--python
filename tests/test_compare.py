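"""Cross-station taxonomy and multi-cutoff summary tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from polarhythm.compare import (
    CATEGORIES, categorize, compare_stations, comparison_summary,
    cutoff_summary, rhythm_status,
)
from polarhythm.detect import detect_rhythms
from polarhythm.simulate import ScenarioConfig, two_station_scenario


def _results(adj, periods):
    rng_cls = ["daily" if p in (20.0, 24.0) else "ultradian" for p in periods]
    return pd.DataFrame(
        {"assigned_period_h": periods, "assigned_adj_p": adj, "period_range": rng_cls},
        index=[f"t{i}" for i in range(len(adj))],
    )


class TestRhythmStatus:
    @pytest.mark.parametrize(
        "adj, rng_cls, alpha, expected",
        [(0.0005, "daily", 0.001, "daily"),
         (0.0005, "ultradian", 0.001, "ultradian"),
         (0.002, "daily", 0.001, "none")],
    )
    def test_rule(self, adj, rng_cls, alpha, expected):
        assert rhythm_status(adj, rng_cls, alpha) == expected


class TestCategorize:
    @pytest.mark.parametrize(
        "a, b, expected",
        [("daily", "none", "excl_A"), ("none", "ultradian", "excl_B"),
         ("daily", "daily", "both_same_daily"),
         ("ultradian", "ultradian", "both_same_ultradian"),
         ("daily", "ultradian", "switch_daily_to_ultradian"),
         ("ultradian", "daily", "switch_ultradian_to_daily"),
         ("none", "none", "nonrhythmic")],
    )
    def test_mapping(self, a, b, expected):
        assert categorize(a, b) == expected

    @given(st.sampled_from(["none", "daily", "ultradian"]),
           st.sampled_from(["none", "daily", "ultradian"]))
    def test_total_function_and_swap_symmetry(self, a, b):
        cat = categorize(a, b)
        assert cat in CATEGORIES
        swapped = categorize(b, a)
        mirror = {"excl_A": "excl_B", "excl_B": "excl_A",
                  "switch_daily_to_ultradian": "switch_ultradian_to_daily",
                  "switch_ultradian_to_daily": "switch_daily_to_ultradian"}
        assert swapped == mirror.get(cat, cat)


class TestCutoffSummary:
    def test_construction(self):
        res = _results([1e-4] * 4 + [0.9] * 6, [24.0] * 10)
        out = cutoff_summary(res, [0.001, 0.01, 0.05], n_total=10)
        assert out.loc[(0.001, "24"), "count"] == 4
        assert out.loc[(0.001, "all"), "count"] == 4
        assert out.loc[(0.001, "all"), "pct"] == pytest.approx(40.0)

    def test_nesting_and_conservation_on_synthetic_run(self, default_design, rng):
        t = np.array(default_design.sample_times())
        rows = [10 * (1 + (1 + np.cos(2 * np.pi * (t - p) / per)))
                * np.exp(rng.normal(0, s, t.size))
                for per in (24.0, 12.0) for p, s in zip((0, 4, 8, 12), (0.05, 0.2, 0.5, 1.0))]
        rows += [np.exp(rng.normal(0, 0.3, t.size)) for _ in range(30)]
        res = detect_rhythms(np.array(rows), default_design)
        out = cutoff_summary(res, [0.001, 0.01, 0.05], n_total=len(rows))
        for key in ("24", "20", "16", "12", "daily", "ultradian", "all"):
            counts = [out.loc[(a, key), "count"] for a in (0.001, 0.01, 0.05)]
            assert counts == sorted(counts)
        for a in (0.001, 0.01, 0.05):
            assert (out.loc[(a, "daily"), "count"] + out.loc[(a, "ultradian"), "count"]
                    == out.loc[(a, "all"), "count"])

    def test_universe_smaller_than_results_rejected(self):
        res = _results([0.5, 0.5], [24.0, 24.0])
        with pytest.raises(ValueError):
            cutoff_summary(res, [0.05], n_total=1)


class TestCompareStations:
    def test_partition_and_symmetry(self):
        adj = [1e-5, 1e-5, 0.5, 1e-5, 0.5]
        pa = [24.0, 12.0, 24.0, 20.0, 12.0]
        pb = [12.0, 12.0, 24.0, 20.0, 12.0]
        adj_b = [1e-5, 0.5, 1e-5, 1e-5, 0.5]
        a, b = _results(adj, pa), _results(adj_b, pb)
        tab = compare_stations(a, b, 0.001)
        assert len(tab) == 5
        counts = tab["category"].value_counts()
        assert counts.sum() == 5
        swapped = compare_stations(b, a, 0.001)
        mirror = {"excl_A": "excl_B", "excl_B": "excl_A",
                  "switch_daily_to_ultradian": "switch_ultradian_to_daily",
                  "switch_ultradian_to_daily": "switch_daily_to_ultradian"}
        for tid in tab.index:
            cat = tab.loc[tid, "category"]
            assert swapped.loc[tid, "category"] == mirror.get(cat, cat)

    def test_universe_mismatch_raises_with_difference_size(self):
        a = _results([0.5, 0.5], [24.0, 24.0])
        b = _results([0.5, 0.5, 0.5], [24.0, 24.0, 24.0])
        with pytest.raises(ValueError, match="1 transcripts"):
            compare_stations(a, b, 0.001)

    def test_nested_rhythmic_sets_across_alphas(self, default_design, rng):
        rows = rng.normal(size=(60, 21)) ** 2 + 0.1
        res = detect_rhythms(rows, default_design)
        sets = [set(res.index[res["assigned_adj_p"] < a]) for a in (0.001, 0.01, 0.05)]
        assert sets[0] <= sets[1] <= sets[2]


class TestComparisonSummaryEndToEnd:
    def test_zero_noise_switch_recovery_among_detected(self):
        # deterministic small scenario: every detected pair keeps its planted
        # relationship; the partition always sums to the universe
        cfg = ScenarioConfig(
            n_excl_a=10, n_excl_b=10, n_both_same_daily=10, n_both_same_ultradian=0,
            n_switch_daily_to_ultradian=0, n_switch_ultradian_to_daily=0,
            n_null=30, excl_a_daily_frac=1.0, excl_b_daily_frac=1.0,
            noise_sigma=0.0,
        )
        sim = two_station_scenario(cfg, seed=3)
        res_a = detect_rhythms(sim["A"][0], sim["design_A"])
        res_b = detect_rhythms(sim["B"][0], sim["design_B"])
        out = comparison_summary(res_a, res_b, alpha=0.001)
        assert out["counts"].sum() == cfg.n_total
        # no planted switches: none may be recovered
        assert out["counts"]["switch_daily_to_ultradian"] == 0
        assert out["counts"]["switch_ultradian_to_daily"] == 0

    def test_per_set_breakdown_counts_only_rhythmic(self):
        a = _results([1e-5, 1e-5, 0.5], [24.0, 12.0, 24.0])
        b = _results([1e-5, 0.5, 0.5], [20.0, 12.0, 24.0])
        ann = pd.DataFrame({"gene_id": ["t0", "t1", "t2"], "term_id": ["GO:1"] * 3})
        out = comparison_summary(a, b, 0.001, annotation=ann)
        per_set = out["per_set"].set_index(["term_id", "split", "period_range"])["count"]
        assert per_set[("GO:1", "both_same", "daily")] == 1
        assert per_set[("GO:1", "excl_A", "ultradian")] == 1
        assert per_set.sum() == 2  # the nonrhythmic transcript is excluded
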