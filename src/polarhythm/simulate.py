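"""Synthetic expression matrices with planted rhythms.

The generator emulates the statistical structure of the motivating field
design: per station, 7 sampling times at 4 h intervals over 24 h, 3
replicate pools per time, and a transcript universe mixing rhythmic rows
(planted 24/20/16/12 h cosine waveforms with chosen phases and amplitudes)
with arrhythmic background.  The planted waveform

    x(t) = b * (1 + (A/2) * (1 + cos(2*pi*(t - phi)/P)))

has maximum ``b*(1+A)`` at the peak phase and minimum ``b`` at antiphase, so
its (max - min)/min equals the amplitude statistic ``A`` used downstream.
Noise is multiplicative lognormal by default (the pipeline consumes
normalized expression and the detector is rank-based, so the noise family is
deliberately simple); a negative-binomial count mode is available for count
realism.  A single master seed drives everything; each transcript draws from
its own counter-derived substream, so partial regeneration is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import TimeSeriesDesign, period_range

DAILY_CHOICES = (24.0, 20.0)
ULTRADIAN_CHOICES = (16.0, 12.0)


def planted_waveform(t_h, baseline: float, amplitude: float,
                     period_h: float, phase_h: float):
    """Noise-free expected expression at time(s) ``t_h``."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if period_h <= 0:
        raise ValueError("period must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    t = np.asarray(t_h, dtype=float)
    x = baseline * (
        1.0 + (amplitude / 2.0) * (1.0 + np.cos(2.0 * np.pi * (t - phase_h) / period_h))
    )
    return float(x) if np.ndim(t_h) == 0 else x


@dataclass(frozen=True)
class TruthClass:
    """One block of transcripts sharing a planted-parameter recipe.

    ``period_h=None`` plants arrhythmic rows.  ``phase_mode`` is one of
    ``"grid"`` (uniform over sampled cycle positions), ``"uniform"``
    (continuous uniform over the cycle) or ``"von_mises"`` (circular cluster
    at ``phase_mu_h`` with concentration ``phase_kappa`` — emulates phase
    clustering around an environmental event).
    """

    n: int
    period_h: float | None = None
    amplitude: float = 2.0
    baseline: float = 10.0
    phase_mode: str = "grid"
    phase_mu_h: float = 0.0
    phase_kappa: float = 4.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("class size must be non-negative")
        if self.period_h is not None:
            period_range(self.period_h)  # must be one of the tested periods
            if self.amplitude < 0:
                raise ValueError("amplitude must be non-negative")
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.phase_mode not in ("grid", "uniform", "von_mises"):
            raise ValueError(f"unknown phase_mode {self.phase_mode!r}")


def _draw_phase(cls: TruthClass, design: TimeSeriesDesign, rng: np.random.Generator) -> float:
    period = float(cls.period_h)
    if cls.phase_mode == "grid":
        positions = sorted({round(t * 60) % round(period * 60) for t in design.timepoints_h})
        return float(rng.choice(positions)) / 60.0
    if cls.phase_mode == "uniform":
        return float(rng.uniform(0.0, period))
    ang = rng.vonmises(2.0 * np.pi * cls.phase_mu_h / period, cls.phase_kappa)
    return float((ang / (2.0 * np.pi) * period) % period)


def _rng_for(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def generate_matrix(
    design: TimeSeriesDesign,
    classes: list[TruthClass],
    seed: int,
    noise_sigma: float = 0.1,
    noise_model: str = "lognormal",
    nb_dispersion: float = 10.0,
    id_prefix: str = "tr",
    explicit_truth: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a matrix, its sample table and the planted-truth table.

    Returns ``(matrix, samples, truth)``: matrix is transcripts x samples,
    samples carries (sample_id, station, time_h, clock_local, replicate),
    truth one row per transcript aligned 1:1 with the matrix rows.

    ``explicit_truth`` bypasses the class recipes and realizes an existing
    truth table (used by :func:`two_station_scenario` to share transcript
    parameters across stations).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if noise_model not in ("lognormal", "nb"):
        raise ValueError(f"unknown noise model {noise_model!r}")

    if explicit_truth is not None:
        truth = explicit_truth.copy()
    else:
        if not classes or sum(c.n for c in classes) == 0:
            raise ValueError("no transcripts requested")
        rng0 = _rng_for(seed, 0)
        rows = []
        k = 0
        for cls in classes:
            for _ in range(cls.n):
                if cls.period_h is None:
                    rows.append((f"{id_prefix}{k:06d}", False, math.nan, math.nan,
                                 math.nan, cls.baseline))
                else:
                    rows.append((f"{id_prefix}{k:06d}", True, float(cls.period_h),
                                 _draw_phase(cls, design, rng0), float(cls.amplitude),
                                 cls.baseline))
                k += 1
        truth = pd.DataFrame(
            rows, columns=["transcript_id", "rhythmic", "period_h", "phase_h",
                           "amplitude", "baseline"],
        )
    truth["noise_sigma"] = noise_sigma

    t = np.array(design.sample_times())
    n_tr = len(truth)
    x = np.empty((n_tr, t.size))
    for i, row in enumerate(truth.itertuples(index=False)):
        if row.rhythmic:
            mu = planted_waveform(t, row.baseline, row.amplitude, row.period_h, row.phase_h)
        else:
            mu = np.full(t.size, float(row.baseline))
        rng = _rng_for(seed, i + 1)
        if noise_sigma == 0.0:
            x[i] = mu
        elif noise_model == "lognormal":
            x[i] = mu * np.exp(rng.normal(0.0, noise_sigma, t.size))
        else:
            # NB with mean mu and dispersion r: var = mu + mu^2/r
            r = nb_dispersion
            p = r / (r + mu)
            x[i] = rng.negative_binomial(r, p).astype(float)

    samples = pd.DataFrame({
        "sample_id": design.sample_ids(),
        "station": design.station,
        "time_h": t,
        "clock_local": [design.clock_of(ti) for ti in t],
        "replicate": [r for _ in design.timepoints_h for r in range(1, design.replicates + 1)],
    })
    matrix = pd.DataFrame(x, index=pd.Index(truth["transcript_id"], name="transcript_id"),
                          columns=samples["sample_id"].tolist())
    return matrix, samples, truth


# --------------------------------------------------------------------------
# two-station scenario
# --------------------------------------------------------------------------

CATEGORIES = (
    "excl_A", "excl_B", "both_same_daily", "both_same_ultradian",
    "switch_daily_to_ultradian", "switch_ultradian_to_daily", "nonrhythmic",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Planted cross-station rhythm architecture.

    Category counts follow the field taxonomy: transcripts rhythmic
    exclusively at station A or B, rhythmic at both with the same period
    range, or rhythmic at both with a range switch (direction A -> B).
    Defaults emulate a daily-dominated station A and an ultradian-enriched
    station B at desk scale.
    """

    n_excl_a: int = 200
    n_excl_b: int = 200
    n_both_same_daily: int = 120
    n_both_same_ultradian: int = 60
    n_switch_daily_to_ultradian: int = 50
    n_switch_ultradian_to_daily: int = 30
    n_null: int = 1340
    excl_a_daily_frac: float = 0.8
    excl_b_daily_frac: float = 0.4
    amplitude: float = 2.0
    baseline: float = 10.0
    noise_sigma: float = 0.1
    station_a: str = "South"
    station_b: str = "North"
    clock_start_a: float = 14.0
    clock_start_b: float = 10.0

    def __post_init__(self) -> None:
        for name in ("n_excl_a", "n_excl_b", "n_both_same_daily", "n_both_same_ultradian",
                     "n_switch_daily_to_ultradian", "n_switch_ultradian_to_daily", "n_null"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("excl_a_daily_frac", "excl_b_daily_frac"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def n_total(self) -> int:
        return (self.n_excl_a + self.n_excl_b + self.n_both_same_daily
                + self.n_both_same_ultradian + self.n_switch_daily_to_ultradian
                + self.n_switch_ultradian_to_daily + self.n_null)


def two_station_scenario(
    config: ScenarioConfig,
    seed: int,
    design: TimeSeriesDesign | None = None,
) -> dict:
    """Paired station matrices with a planted cross-station architecture.

    Returns a dict with keys ``"A"`` and ``"B"`` (each a
    ``(matrix, samples, truth)`` triple on the same transcript universe) and
    ``"categories"``: a Series mapping transcript_id to its planted category.
    """
    base = design or TimeSeriesDesign()
    design_a = replace(base, station=config.station_a, clock_start_h=config.clock_start_a)
    design_b = replace(base, station=config.station_b, clock_start_h=config.clock_start_b)
    rng = _rng_for(seed, 0)

    def pick(kind: str) -> float:
        choices = DAILY_CHOICES if kind == "daily" else ULTRADIAN_CHOICES
        return float(rng.choice(choices))

    recs_a, recs_b, cats = [], [], []

    def add(cat: str, kind_a: str | None, kind_b: str | None) -> None:
        cats.append(cat)
        for recs, kind, dsn in ((recs_a, kind_a, design_a), (recs_b, kind_b, design_b)):
            if kind is None:
                recs.append((False, math.nan, math.nan, math.nan, config.baseline))
            else:
                period = pick(kind)
                cls = TruthClass(1, period, config.amplitude, config.baseline)
                phase = _draw_phase(cls, dsn, rng)
                recs.append((True, period, phase, config.amplitude, config.baseline))

    for i in range(config.n_excl_a):
        kind = "daily" if rng.random() < config.excl_a_daily_frac else "ultradian"
        add("excl_A", kind, None)
    for i in range(config.n_excl_b):
        kind = "daily" if rng.random() < config.excl_b_daily_frac else "ultradian"
        add("excl_B", None, kind)
    for _ in range(config.n_both_same_daily):
        add("both_same_daily", "daily", "daily")
    for _ in range(config.n_both_same_ultradian):
        add("both_same_ultradian", "ultradian", "ultradian")
    for _ in range(config.n_switch_daily_to_ultradian):
        add("switch_daily_to_ultradian", "daily", "ultradian")
    for _ in range(config.n_switch_ultradian_to_daily):
        add("switch_ultradian_to_daily", "ultradian", "daily")
    for _ in range(config.n_null):
        add("nonrhythmic", None, None)

    ids = [f"tr{k:06d}" for k in range(len(cats))]
    cols = ["rhythmic", "period_h", "phase_h", "amplitude", "baseline"]
    truth_a = pd.DataFrame(recs_a, columns=cols)
    truth_a.insert(0, "transcript_id", ids)
    truth_b = pd.DataFrame(recs_b, columns=cols)
    truth_b.insert(0, "transcript_id", ids)

    out_a = generate_matrix(design_a, [], seed=seed * 2 + 1, noise_sigma=config.noise_sigma,
                            explicit_truth=truth_a)
    out_b = generate_matrix(design_b, [], seed=seed * 2 + 2, noise_sigma=config.noise_sigma,
                            explicit_truth=truth_b)
    return {
        "A": out_a,
        "B": out_b,
        "design_A": design_a,
        "design_B": design_b,
        "categories": pd.Series(cats, index=pd.Index(ids, name="transcript_id"),
                                name="category"),
    }
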