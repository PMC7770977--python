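"""Readers and writers for the pipeline's tabular artifacts.

Everything is plain TSV: UTF-8, Unix newlines, tab separated, no quoting,
``.`` decimal separator.  Floats are written with 12 significant digits so
that a write/read round trip is lossless at that precision.  Output files
carry ``#``-prefixed comment header lines recording the producing stage and
configuration; all readers skip such lines.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .design import TimeSeriesDesign

NA = "NA"
_FLOAT_FMT = "%.12g"

RESULT_FIXED_COLUMNS = (
    "assigned_period_h", "assigned_adj_p", "period_range",
    "phase_h", "amplitude", "amplitude_bin", "coincidence_label",
)


@dataclass
class ExpressionMatrix:
    """Transcripts x samples expression values with sample annotations."""

    values: pd.DataFrame          # index transcript_id, columns sample_id
    samples: pd.DataFrame         # sample_id, station, time_h, clock_local, replicate

    @property
    def stations(self) -> list[str]:
        return sorted(self.samples["station"].unique())

    def design(self, station: str) -> TimeSeriesDesign:
        """Reconstruct the sampling design of one station."""
        sub = self.samples[self.samples["station"] == station]
        if sub.empty:
            raise KeyError(f"no samples for station {station!r}")
        tps = tuple(sorted(sub["time_h"].unique()))
        reps = int(sub.groupby("time_h")["replicate"].count().max())
        first = sub.loc[sub["time_h"].idxmin()]
        clock0 = (float(first["clock_local"]) - float(first["time_h"])) % 24.0
        return TimeSeriesDesign(tps, reps, station, clock0)

    def station_matrix(self, station: str) -> pd.DataFrame:
        """Columns of one station, ordered time-major then replicate."""
        sub = self.samples[self.samples["station"] == station]
        order = sub.sort_values(["time_h", "replicate"])["sample_id"]
        return self.values[list(order)]


def read_expression(matrix_path, samples_path) -> ExpressionMatrix:
    """Read an expression matrix TSV plus its sample-metadata TSV.

    The matrix has a header of sample ids and a first ``transcript_id``
    column; all values must be non-negative finite reals, every matrix
    column must be annotated, and transcript ids must be unique.
    """
    samples = pd.read_csv(samples_path, sep="\t", comment="#")
    required = {"sample_id", "station", "time_h", "clock_local", "replicate"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples table lacks columns: {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in samples table")
    key = samples[["station", "time_h", "replicate"]]
    if key.duplicated().any():
        raise ValueError("(station, time_h, replicate) must be unique in samples table")

    mat = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    mat.index.name = "transcript_id"
    if mat.index.duplicated().any():
        dup = mat.index[mat.index.duplicated()][0]
        raise ValueError(f"duplicate transcript_id {dup!r} in matrix")
    annotated = set(samples["sample_id"])
    for col in mat.columns:
        if col not in annotated:
            raise ValueError(f"unannotated sample {col}")
    vals = mat.to_numpy()
    bad = ~np.isfinite(vals) | (vals < 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid expression value {vals[r, c]!r} for transcript "
            f"{mat.index[r]!r}, sample {mat.columns[c]!r} "
            "(values must be finite and non-negative)"
        )
    return ExpressionMatrix(mat, samples)


def _comment_header(stage: str, **params) -> str:
    items = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# polarhythm {__version__} | {stage} | {items}\n" if items else \
        f"# polarhythm {__version__} | {stage}\n"


def _write_tsv(df: pd.DataFrame, path, stage: str, index: bool, **params) -> None:
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index, float_format=_FLOAT_FMT,
              na_rep=NA, lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_comment_header(stage, **params))
        fh.write(buf.getvalue())


def write_matrix(matrix: pd.DataFrame, path, **params) -> None:
    _write_tsv(matrix, path, "matrix", index=True, **params)


def write_samples(samples: pd.DataFrame, path, **params) -> None:
    _write_tsv(samples, path, "samples", index=False, **params)


def write_truth(truth: pd.DataFrame, path, **params) -> None:
    _write_tsv(truth, path, "truth", index=False, **params)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=[NA])
    df["rhythmic"] = df["rhythmic"].astype(bool)
    return df


def result_columns(periods) -> list[str]:
    cols = []
    for p in sorted({float(x) for x in periods}, reverse=True):
        cols += [f"raw_p_{p:g}", f"adj_p_{p:g}"]
    return cols + list(RESULT_FIXED_COLUMNS)


def write_results(results: pd.DataFrame, path, **params) -> None:
    """Write a detection/characterization table with the canonical schema.

    Columns: ``transcript_id``, per tested period ``raw_p_<P>`` and
    ``adj_p_<P>`` (periods descending), then assigned period, adjusted p,
    period range, phase, amplitude, amplitude bin and coincidence label.
    Characterization columns missing from ``results`` are written as
    ``NA`` (or ``none`` for the coincidence label).
    """
    periods = sorted(
        {float(c.split("_")[-1]) for c in results.columns if c.startswith("raw_p_")},
        reverse=True,
    )
    if not periods:
        raise ValueError("results table has no raw_p_<period> columns")
    out = results.copy()
    for col in RESULT_FIXED_COLUMNS:
        if col not in out.columns:
            out[col] = "none" if col == "coincidence_label" else np.nan
    out = out[result_columns(periods)]
    out.index.name = "transcript_id"
    _write_tsv(out, path, "results", index=True, **params)


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col="transcript_id",
                     na_values=[NA], keep_default_na=False)
    for col in ("period_range", "amplitude_bin", "coincidence_label"):
        if col in df.columns:
            df[col] = df[col].where(df[col].notna(), "")
    for col in df.columns:
        if col.startswith(("raw_p_", "adj_p_")) or col in (
            "assigned_period_h", "assigned_adj_p", "phase_h", "amplitude",
        ):
            df[col] = df[col].astype(float)
    return df


def read_annotation(path) -> pd.DataFrame:
    """Flat two-column gene -> term table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns[:2]) != ["gene_id", "term_id"]:
        if df.shape[1] < 2:
            raise ValueError("annotation must have two columns: gene_id, term_id")
        df = df.iloc[:, :2]
        df.columns = ["gene_id", "term_id"]
    return df


def read_id_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_env(env, path, utc_offset_h: float = 2.0, start_local=None, **params) -> None:
    """Environment series TSV: time_h, iso_time_local, solar_elev_deg, tide_m."""
    import datetime as dt

    iso = [
        (start_local + dt.timedelta(hours=float(t))).isoformat(timespec="minutes")
        if start_local is not None else NA
        for t in env.times_h
    ]
    df = pd.DataFrame({
        "time_h": env.times_h,
        "iso_time_local": iso,
        "solar_elev_deg": env.solar_elev_deg,
        "tide_m": env.tide_m,
    })
    _write_tsv(df, path, "environment", index=False, **params)


def write_events(env, path, **params) -> None:
    df = pd.DataFrame(
        [(e.time_h, e.kind) for e in env.events], columns=["time_h", "kind"]
    )
    _write_tsv(df, path, "events", index=False, **params)
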