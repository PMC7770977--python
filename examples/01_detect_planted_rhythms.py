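"""Plant rhythms in a synthetic expression matrix and detect them.

Builds a small 7-timepoint x 3-replicate matrix (the 4 h / 24 h field
design) with 30 planted 24 h cosine rhythms and 270 arrhythmic rows, runs
the umbrella rank test at periods 24/20/16/12 h, and reports how many
planted rows are recovered at the strict adjusted-p cutoff.
"""

import numpy as np

from polarhythm import TimeSeriesDesign, TruthClass, detect_rhythms, generate_matrix

design = TimeSeriesDesign(station="South", clock_start_h=14.0)
classes = [
    TruthClass(30, period_h=24.0, amplitude=2.0, baseline=10.0, phase_mode="grid"),
    TruthClass(270, period_h=None, baseline=10.0),
]
matrix, samples, truth = generate_matrix(design, classes, seed=42, noise_sigma=0.1)
results = detect_rhythms(matrix, design)

planted = results.loc[truth.loc[truth["rhythmic"], "transcript_id"]]
null = results.loc[truth.loc[~truth["rhythmic"], "transcript_id"]]
hits = int((planted["assigned_adj_p"] < 0.001).sum())
false = int((null["assigned_adj_p"] < 0.05).sum())

print(f"planted 24h rhythms recovered at adj-p<0.001: {hits}/30")
print(f"arrhythmic rows called at adj-p<0.05:         {false}/270")
recovered_periods = sorted(
    float(p) for p in
    planted.loc[planted["assigned_adj_p"] < 0.001, "assigned_period_h"].unique()
)
print(f"assigned periods of recovered rows:           {recovered_periods}")
# A high hit count with the correct 24 h assignment and few false calls
# shows the rank test separating planted oscillations from noise.
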