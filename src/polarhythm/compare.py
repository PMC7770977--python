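"""Cross-station rhythm-architecture taxonomy and multi-cutoff summaries.

Per station a transcript is ``daily`` (assigned period 20/24 h), ``ultradian``
(12/16 h) or ``none`` at a given adjusted-p cutoff; the pair of statuses
maps each transcript into one of seven categories (exclusive to either
station, shared with the same period range, shared with a range switch in
either direction, or non-rhythmic).  Stations are tested and BH-adjusted
independently — no cross-station multiplicity correction — and "same"
means same period *range*, not same exact period.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import DAILY_PERIODS_H, ULTRADIAN_PERIODS_H

STATUSES = ("none", "daily", "ultradian")
CATEGORIES = (
    "excl_A", "excl_B", "both_same_daily", "both_same_ultradian",
    "switch_daily_to_ultradian", "switch_ultradian_to_daily", "nonrhythmic",
)


def rhythm_status(assigned_adj_p: float, range_class: str, alpha: float) -> str:
    """``daily``/``ultradian`` when significant at ``alpha``, else ``none``."""
    if range_class not in ("daily", "ultradian"):
        raise ValueError(f"unknown period range {range_class!r}")
    return range_class if assigned_adj_p < alpha else "none"


def categorize(status_a: str, status_b: str) -> str:
    """Category of a (station A, station B) status pair."""
    for s in (status_a, status_b):
        if s not in STATUSES:
            raise ValueError(f"unknown status {s!r}")
    if status_a == "none" and status_b == "none":
        return "nonrhythmic"
    if status_b == "none":
        return "excl_A"
    if status_a == "none":
        return "excl_B"
    if status_a == status_b:
        return f"both_same_{status_a}"
    return f"switch_{status_a}_to_{status_b}"


def cutoff_summary(results: pd.DataFrame, alphas, n_total: int) -> pd.DataFrame:
    """Per-cutoff count (and fraction of the universe) tables.

    Each transcript is counted once, at its assigned period.  Rows are
    indexed by (alpha, key) where key is a period (``"24"``...), ``daily``,
    ``ultradian`` or ``all``; columns are ``count`` and ``pct`` (percentage
    of ``n_total``).
    """
    if n_total < len(results):
        raise ValueError("universe size smaller than the results table")
    periods = sorted(results["assigned_period_h"].unique(), reverse=True)
    rows = []
    for alpha in sorted(alphas):
        sig = results[results["assigned_adj_p"] < alpha]
        per_period = {p: int((sig["assigned_period_h"] == p).sum()) for p in periods}
        daily = sum(c for p, c in per_period.items() if p in DAILY_PERIODS_H)
        ultra = sum(c for p, c in per_period.items() if p in ULTRADIAN_PERIODS_H)
        for p in periods:
            rows.append((alpha, f"{p:g}", per_period[p]))
        rows.append((alpha, "daily", daily))
        rows.append((alpha, "ultradian", ultra))
        rows.append((alpha, "all", daily + ultra))
    out = pd.DataFrame(rows, columns=["alpha", "key", "count"])
    out["pct"] = 100.0 * out["count"] / n_total
    return out.set_index(["alpha", "key"])


def compare_stations(results_a: pd.DataFrame, results_b: pd.DataFrame,
                     alpha: float = 0.001) -> pd.DataFrame:
    """Per-transcript status pair and category across two stations.

    Both tables must cover the same transcript universe.
    """
    set_a, set_b = set(results_a.index), set(results_b.index)
    if set_a != set_b:
        diff = len(set_a.symmetric_difference(set_b))
        raise ValueError(
            f"transcript universes differ between stations ({diff} transcripts "
            "in one table only)"
        )
    b = results_b.loc[results_a.index]
    status_a = [
        rhythm_status(p, r, alpha)
        for p, r in zip(results_a["assigned_adj_p"], results_a["period_range"])
    ]
    status_b = [
        rhythm_status(p, r, alpha)
        for p, r in zip(b["assigned_adj_p"], b["period_range"])
    ]
    cat = [categorize(sa, sb) for sa, sb in zip(status_a, status_b)]
    return pd.DataFrame(
        {"status_A": status_a, "status_B": status_b, "category": cat},
        index=results_a.index,
    )


def comparison_summary(results_a: pd.DataFrame, results_b: pd.DataFrame,
                       alpha: float = 0.001,
                       annotation: pd.DataFrame | None = None) -> dict:
    """Category counts, plus per-functional-set breakdowns when annotated.

    Returns ``{"table": per-transcript table, "counts": category counts,
    "per_set": long table or None}``.  The per-set breakdown follows the
    field convention: for every term, the four-way split (excl A / excl B /
    both-same / both-switch) crossed with the daily/ultradian range, with
    switching transcripts classified by their range at station B.
    """
    table = compare_stations(results_a, results_b, alpha)
    counts = table["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    per_set = None
    if annotation is not None:
        b = results_b.loc[table.index]
        a = results_a.loc[table.index]
        four_way = table["category"].map({
            "excl_A": "excl_A", "excl_B": "excl_B",
            "both_same_daily": "both_same", "both_same_ultradian": "both_same",
            "switch_daily_to_ultradian": "both_switch",
            "switch_ultradian_to_daily": "both_switch",
        })
        # range shown: station of expression (A for excl_A, otherwise B)
        shown_range = np.where(table["category"] == "excl_A",
                               a["period_range"], b["period_range"])
        aux = pd.DataFrame({"split": four_way, "range": shown_range}, index=table.index)
        rows = []
        for term, genes in annotation.groupby("term_id")["gene_id"]:
            sub = aux.loc[aux.index.intersection(genes)]
            sub = sub[sub["split"].notna()]
            for (split, rng), n in sub.groupby(["split", "range"]).size().items():
                rows.append((term, split, rng, int(n)))
        per_set = pd.DataFrame(rows, columns=["term_id", "split", "period_range", "count"])
    return {"table": table, "counts": counts, "per_set": per_set}
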