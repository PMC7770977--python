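"""Sampling design: the time grid a station was sampled on.

The field design this package targets is a short cross-sectional time
series: one 24 h cycle sampled every 4 h (7 timepoints, the first and last
clock hour coinciding one day apart), with a small number of independent
replicate pools of animals per timepoint.  Times are carried on two axes:
hours elapsed since the first sample (used for period folding) and local
clock hour (used to report phases, UTC+2 convention in the motivating
campaign).
"""

from __future__ import annotations

from dataclasses import dataclass, field


DEFAULT_TIMEPOINTS_H = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)
DEFAULT_PERIODS_H = (24.0, 20.0, 16.0, 12.0)
DAILY_PERIODS_H = frozenset({20.0, 24.0})
ULTRADIAN_PERIODS_H = frozenset({12.0, 16.0})


def period_range(period_h: float) -> str:
    """Classify a period length as ``daily`` (20/24 h) or ``ultradian`` (12/16 h)."""
    if period_h in DAILY_PERIODS_H:
        return "daily"
    if period_h in ULTRADIAN_PERIODS_H:
        return "ultradian"
    raise ValueError(f"period {period_h} h is neither daily (20/24) nor ultradian (12/16)")


@dataclass(frozen=True)
class TimeSeriesDesign:
    """Sampling grid for one station.

    Parameters
    ----------
    timepoints_h:
        Strictly increasing sampling times in hours since the first sample.
    replicates:
        Number of independent replicate pools per timepoint.
    station:
        Station label (e.g. ``"South"``, ``"North"``).
    clock_start_h:
        Local clock hour of the first sample; maps elapsed hours to local
        clock time (``clock = (clock_start_h + t) mod 24``).
    """

    timepoints_h: tuple[float, ...] = DEFAULT_TIMEPOINTS_H
    replicates: int = 3
    station: str = "South"
    clock_start_h: float = 0.0

    def __post_init__(self) -> None:
        tps = tuple(float(t) for t in self.timepoints_h)
        object.__setattr__(self, "timepoints_h", tps)
        if len(tps) < 3:
            raise ValueError("design needs at least 3 timepoints")
        if any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints_h must be strictly increasing")
        if tps[0] < 0:
            raise ValueError("timepoints_h must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be a positive integer")

    @property
    def n_samples(self) -> int:
        return len(self.timepoints_h) * self.replicates

    def clock_of(self, time_h: float) -> float:
        """Local clock hour of an elapsed time."""
        return (self.clock_start_h + time_h) % 24.0

    def sample_times(self) -> list[float]:
        """Elapsed time of every sample, replicate-major within timepoint."""
        return [t for t in self.timepoints_h for _ in range(self.replicates)]

    def sample_ids(self, prefix: str | None = None) -> list[str]:
        """Deterministic sample identifiers ``<station>_t<h>_r<rep>``."""
        prefix = prefix if prefix is not None else self.station
        return [
            f"{prefix}_t{_fmt_h(t)}_r{r}"
            for t in self.timepoints_h
            for r in range(1, self.replicates + 1)
        ]


def _fmt_h(t: float) -> str:
    return f"{t:g}".replace(".", "p")
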