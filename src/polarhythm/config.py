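"""Run configuration and YAML loading for the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .design import TimeSeriesDesign, period_range
from .simulate import ScenarioConfig, TruthClass


@dataclass(frozen=True)
class RunConfig:
    """Analysis-stage parameters shared across the pipeline."""

    tested_periods_h: tuple[float, ...] = (24.0, 20.0, 16.0, 12.0)
    alpha_levels: tuple[float, ...] = (0.001, 0.01, 0.05)
    pseudocount: float = 0.0
    coincidence_tolerance_h: float = 2.0
    seed: int = 0
    normalize: str = "none"

    def __post_init__(self) -> None:
        for p in self.tested_periods_h:
            period_range(p)
        alphas = tuple(sorted(self.alpha_levels))
        if not alphas or any(not (0 < a < 1) for a in alphas):
            raise ValueError("alpha levels must lie in (0, 1)")
        if len(set(alphas)) != len(alphas):
            raise ValueError("alpha levels must be distinct")
        object.__setattr__(self, "alpha_levels", alphas)
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.coincidence_tolerance_h <= 0:
            raise ValueError("coincidence tolerance must be positive")
        if self.normalize not in ("none", "cpm"):
            raise ValueError("normalize must be 'none' or 'cpm'")


def load_sim_config(path) -> dict:
    """Parse a simulation YAML into design/classes/noise/seed pieces.

    Schema::

        design: {timepoints_h: [...], replicates: 3, station: South,
                 clock_start_h: 14}
        classes:
          - {n: 50, period_h: 24, amplitude: 2.0, baseline: 10.0,
             phase_mode: grid}
          - {n: 950, period_h: null}
        noise: {model: lognormal, sigma: 0.1}
        seed: 1
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    d = raw.get("design", {})
    design = TimeSeriesDesign(
        tuple(d.get("timepoints_h", TimeSeriesDesign().timepoints_h)),
        int(d.get("replicates", 3)),
        str(d.get("station", "South")),
        float(d.get("clock_start_h", 0.0)),
    )
    classes = [
        TruthClass(
            n=int(c["n"]),
            period_h=None if c.get("period_h") is None else float(c["period_h"]),
            amplitude=float(c.get("amplitude", 2.0)),
            baseline=float(c.get("baseline", 10.0)),
            phase_mode=str(c.get("phase_mode", "grid")),
            phase_mu_h=float(c.get("phase_mu_h", 0.0)),
            phase_kappa=float(c.get("phase_kappa", 4.0)),
        )
        for c in raw.get("classes", [])
    ]
    noise = raw.get("noise", {})
    return {
        "design": design,
        "classes": classes,
        "noise_model": str(noise.get("model", "lognormal")),
        "noise_sigma": float(noise.get("sigma", 0.1)),
        "seed": int(raw.get("seed", 0)),
    }


def load_scenario_config(path) -> tuple[ScenarioConfig, int]:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.pop("seed", 0))
    return ScenarioConfig(**raw), seed


def load_constituents(path) -> tuple[list, float]:
    """Tidal constituents YAML: list of {name, period_h, amplitude_m,
    phase_rad} entries plus a global ``z0_m`` datum offset."""
    from .environment import TidalConstituent

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    z0 = float(raw.get("z0_m", 0.0))
    cons = [
        TidalConstituent(
            str(c["name"]), float(c["period_h"]),
            float(c.get("amplitude_m", 1.0)), float(c.get("phase_rad", 0.0)),
        )
        for c in raw.get("constituents", [])
    ]
    if not cons:
        raise ValueError("constituents file lists no constituents")
    return cons, z0
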