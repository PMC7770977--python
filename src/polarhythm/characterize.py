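"""Phase, amplitude, normalization and environment-coincidence labelling.

Phase is the cycle position at which the folded per-position median profile
peaks (ordinal, not a cosinor fit — with 3–7 positions per cycle and
non-sinusoidal waveforms a rank treatment is the honest choice), reported
both as position-in-cycle hours and as local clock hour.  Amplitude is the
relative peak-to-trough statistic A = (max - min)/min of the same profile
(an amplitude of 0.5 means the max exceeds the min by half the min), binned
into the conventional ranges 0–0.5, 0.5–1.5, 1.5–5 and >5.  Both statistics
are invariant under per-transcript median normalization.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import TimeSeriesDesign
from .detect import CycleFold, fold_timepoints

AMPLITUDE_BINS = ("0-0.5", "0.5-1.5", "1.5-5", ">5")
COINCIDENCE_LABELS = ("solar_min", "solar_max", "high_tide", "low_tide", "none")


def summarize_profile(row, fold: CycleFold) -> np.ndarray:
    """Median of replicate values at each cycle position (one per position)."""
    values = np.asarray(row, dtype=float)
    return np.array([np.median(values[list(g)]) for g in fold.groups])


def estimate_phase(profile, fold: CycleFold,
                   design: TimeSeriesDesign | None = None) -> tuple[float, float | None]:
    """Cycle position of the profile maximum, plus its local clock hour.

    Ties are broken toward the earliest position.  The clock hour is the
    local time of the earliest sampled timepoint at that cycle position
    (``None`` when no design is given).
    """
    prof = np.asarray(profile, dtype=float)
    if prof.size != fold.n_groups:
        raise ValueError("profile length does not match the fold")
    if np.all(prof == prof[0]):
        raise ValueError("phase undefined: constant profile")
    k = int(np.argmax(prof))          # argmax returns the first maximum
    phase_h = fold.positions[k]
    if design is None:
        return phase_h, None
    times = design.sample_times()
    t0 = times[fold.groups[k][0]]
    return phase_h, design.clock_of(t0)


def estimate_amplitude(profile, pseudocount: float = 0.0) -> float:
    """Relative amplitude A = (max - min)/min after adding a pseudocount."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    prof = np.asarray(profile, dtype=float) + pseudocount
    lo, hi = float(prof.min()), float(prof.max())
    if lo <= 0:
        raise ValueError(
            "amplitude undefined: profile minimum plus pseudocount is not positive"
        )
    return (hi - lo) / lo


def amplitude_bin(a: float) -> str:
    """Bin label for an amplitude: [0,0.5), [0.5,1.5), [1.5,5], (5,inf)."""
    if a < 0:
        raise ValueError("amplitude must be non-negative")
    if a < 0.5:
        return "0-0.5"
    if a < 1.5:
        return "0.5-1.5"
    if a <= 5.0:
        return "1.5-5"
    return ">5"


def median_normalize(row):
    """Row divided by its median (so the normalized median is 1)."""
    values = np.asarray(row, dtype=float)
    med = float(np.median(values))
    if med <= 0:
        raise ValueError("median normalization undefined: median is not positive")
    return values / med


def coincidence_label(phase_clock_h: float, events, tolerance_h: float = 2.0,
                      range_class: str = "daily") -> str:
    """Nearest environmental event kind within a clock-hour tolerance.

    Distances are taken on the 24 h clock (wrap-around).  On an exact tie,
    tide events take precedence for ultradian transcripts and solar events
    for daily transcripts.
    """
    if tolerance_h <= 0:
        raise ValueError("tolerance must be positive")
    if not events:
        return "none"
    tide_first = range_class == "ultradian"

    def prio(kind: str) -> int:
        is_tide = kind in ("high_tide", "low_tide")
        return 0 if is_tide == tide_first else 1

    best: tuple[float, int, str] | None = None
    for ev in events:
        clock = ev.time_h % 24.0
        d = abs(clock - phase_clock_h % 24.0)
        d = min(d, 24.0 - d)
        cand = (d, prio(ev.kind), ev.kind)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None or best[0] > tolerance_h:
        return "none"
    return best[2]


def phase_histogram(phases_clock_h, design: TimeSeriesDesign) -> pd.Series:
    """Transcript counts peaking at each sampling clock time.

    The index is the design's sampled clock hours; counts sum to the number
    of transcripts with a defined phase.
    """
    clocks = sorted({design.clock_of(t) for t in design.timepoints_h})
    counts = pd.Series(0, index=pd.Index(clocks, name="clock_h"), dtype=int)
    for ph in phases_clock_h:
        if ph is None or (isinstance(ph, float) and np.isnan(ph)):
            continue
        key = min(clocks, key=lambda c: min(abs(c - ph % 24.0), 24.0 - abs(c - ph % 24.0)))
        counts[key] += 1
    return counts


def characterize(matrix: pd.DataFrame, results: pd.DataFrame,
                 design: TimeSeriesDesign, env_events=None,
                 pseudocount: float = 0.0, tolerance_h: float = 2.0) -> pd.DataFrame:
    """Attach phase/amplitude/coincidence columns to a detection table.

    Each transcript is profiled at its assigned period.  Transcripts with a
    constant profile get missing phase/amplitude-bin entries and amplitude 0.
    Without environmental events every coincidence label is ``"none"``.
    """
    folds = {p: fold_timepoints(design, p) for p in results["assigned_period_h"].unique()}
    out = results.copy()
    phase_pos = np.full(len(out), np.nan)
    phase_clock = np.full(len(out), np.nan)
    amp = np.full(len(out), np.nan)
    bins = np.full(len(out), "", dtype=object)
    labels = np.full(len(out), "none", dtype=object)
    for i, (tid, row) in enumerate(results.iterrows()):
        fold = folds[row["assigned_period_h"]]
        prof = summarize_profile(matrix.loc[tid].values, fold)
        try:
            a = estimate_amplitude(prof, pseudocount)
        except ValueError:
            continue
        amp[i] = a
        bins[i] = amplitude_bin(a)
        try:
            pos, clock = estimate_phase(prof, fold, design)
        except ValueError:
            continue
        phase_pos[i] = pos
        phase_clock[i] = clock
        if env_events:
            labels[i] = coincidence_label(clock, env_events, tolerance_h,
                                          range_class=row["period_range"])
    out["phase_h"] = phase_pos
    out["phase_clock_h"] = phase_clock
    out["amplitude"] = amp
    out["amplitude_bin"] = bins
    out["coincidence_label"] = labels
    return out
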