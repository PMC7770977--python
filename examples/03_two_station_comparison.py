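"""Cross-station rhythm architecture on a planted two-station scenario.

Simulates paired matrices for a daily-dominated southern station and an
ultradian-enriched northern station, detects rhythms independently at each,
and crosses the per-station statuses into the seven-category taxonomy
(exclusive / shared-same-range / period-range switch / non-rhythmic).
"""

from polarhythm import ScenarioConfig, detect_rhythms, two_station_scenario
from polarhythm.compare import comparison_summary, cutoff_summary

config = ScenarioConfig(
    n_excl_a=60, n_excl_b=60, n_both_same_daily=40, n_both_same_ultradian=15,
    n_switch_daily_to_ultradian=15, n_switch_ultradian_to_daily=10, n_null=300,
)
sim = two_station_scenario(config, seed=7)
res_a = detect_rhythms(sim["A"][0], sim["design_A"])
res_b = detect_rhythms(sim["B"][0], sim["design_B"])

summary = comparison_summary(res_a, res_b, alpha=0.001)
print("recovered category counts (planted in parentheses):")
planted = sim["categories"].value_counts()
for cat, n in summary["counts"].items():
    print(f"  {cat:28s} {n:4d}  ({planted.get(cat, 0)})")

table = cutoff_summary(res_a, [0.001, 0.01, 0.05], n_total=len(res_a))
print("\nstation A rhythmic totals by cutoff (count, % of universe):")
for alpha in (0.001, 0.01, 0.05):
    row = table.loc[(alpha, "all")]
    print(f"  adj-p<{alpha:<6} {int(row['count']):4d}  ({row['pct']:.1f}%)")
# Counts recovered near the planted numbers show the taxonomy working;
# daily rhythms are recovered nearly completely, while 12 h rhythms are
# power-limited on a 3-position folded cycle (see docs/methods.md).
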