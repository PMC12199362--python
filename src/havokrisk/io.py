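"""CSV schemas and configuration files.

Time-series schema (one file per patient):

    timestamp,iea_count,le_count,seizure_flag,visit_id

Timestamps are ISO-8601 on a strict hourly grid; missing hours are absent
rows (they become the gap mask on read); inter-visit blocks are inferred
from changes of ``visit_id``. Comment lines starting with ``#`` (e.g. the
generator seed) are ignored on read.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .timeseries import EventSeries, HourlyCountSeries

__all__ = [
    "PipelineConfig",
    "SchemaError",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "write_matrix_csv",
    "read_matrix_csv",
]

TIMESERIES_COLUMNS = ["timestamp", "iea_count", "le_count", "seizure_flag", "visit_id"]


class SchemaError(ValueError):
    """Malformed time-series file (duplicate/non-monotone/sub-hourly rows)."""


@dataclasses.dataclass
class PipelineConfig:
    """All tunable parameters of the end-to-end analysis."""

    d: int = 100                       # embedding depth (hours)
    k: int = 22                        # SVD truncation
    r: int = 11                        # forcing index for the single-model fit
    sweep_r: tuple[int, int] = (4, 22)  # forcing-index sweep bounds (inclusive)
    lowpass_cutoff_hours: float = 72.0
    fir_order: int = 100
    line_length_window_hours: int = 72
    trim_months: float = 5.0
    train_hours: int = 4380            # six months
    horizons: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6, 7)
    coordinates: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    resolution: str = "daily"
    models: tuple[str, ...] = ("bagged_trees",)
    repetitions: int = 50
    n_null: int = 50
    n_permutation: int = 100
    alpha: float = 0.05
    correction: str = "bonferroni"     # or "fdr"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.r <= self.k <= self.d:
            raise ValueError(f"require r <= k <= d, got r={self.r}, k={self.k}, d={self.d}")
        lo, hi = self.sweep_r
        if not 2 <= lo <= hi <= self.k:
            raise ValueError(f"sweep range {self.sweep_r} outside [2, k={self.k}]")
        if any(h < 0 or h > 7 for h in self.horizons):
            raise ValueError("horizons must lie in [0, 7] days")
        if self.correction not in ("bonferroni", "fdr"):
            raise ValueError(f"unknown correction {self.correction!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("sweep_r", "horizons", "coordinates", "models"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_timeseries_csv(
    path: str | Path,
    series: HourlyCountSeries,
    events: EventSeries | None = None,
    seed: int | None = None,
) -> None:
    n = series.n_hours
    le = events.le_counts if events is not None else np.zeros(n, dtype=int)
    sz = events.seizure_flags if events is not None else np.zeros(n, dtype=bool)
    visit_id = np.zeros(n, dtype=int)
    for b in series.visit_boundaries:
        visit_id[b:] += 1
    df = pd.DataFrame(
        {
            "timestamp": series.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
            "iea_count": series.values,
            "le_count": le,
            "seizure_flag": sz.astype(int),
            "visit_id": visit_id,
        }
    )
    df = df[~series.gap_mask]  # missing hours are absent rows
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if series.patient_id:
            fh.write(f"# patient_id={series.patient_id}\n")
        df.to_csv(fh, index=False)


def read_timeseries_csv(path: str | Path) -> tuple[HourlyCountSeries, EventSeries]:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TIMESERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    ts = pd.to_datetime(df["timestamp"])
    # line numbers are 1-based and account for the header row
    header_lines = 1 + _count_comment_lines(path)
    dup = ts.duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        raise SchemaError(f"{path}: duplicate timestamp at line {i + 1 + header_lines}")
    if not ts.is_monotonic_increasing:
        i = int(np.flatnonzero(np.diff(ts.values).astype("timedelta64[s]") < 0)[0]) + 1
        raise SchemaError(f"{path}: non-monotone timestamp at line {i + 1 + header_lines}")
    deltas = np.diff(ts.values).astype("timedelta64[s]").astype(int)
    bad = np.flatnonzero(deltas % 3600 != 0)
    if bad.size:
        i = int(bad[0]) + 1
        raise SchemaError(f"{path}: sub-hourly spacing at line {i + 1 + header_lines}")

    start, end = ts.iloc[0], ts.iloc[-1]
    grid = pd.date_range(start, end, freq="h")
    n = grid.size
    pos = ((ts - start).dt.total_seconds() // 3600).astype(int).to_numpy()
    values = np.zeros(n)
    le = np.zeros(n, dtype=int)
    sz = np.zeros(n, dtype=bool)
    visit = np.full(n, -1)
    gap = np.ones(n, dtype=bool)
    values[pos] = df["iea_count"].to_numpy(float)
    le[pos] = df["le_count"].to_numpy(int)
    sz[pos] = df["seizure_flag"].to_numpy(int) > 0
    visit[pos] = df["visit_id"].to_numpy()
    gap[pos] = False
    # carry visit ids through gaps, then find block starts
    for i in range(1, n):
        if visit[i] == -1:
            visit[i] = visit[i - 1]
    boundaries = np.flatnonzero(np.diff(visit) != 0) + 1
    series = HourlyCountSeries(values, start, gap, boundaries)
    return series, EventSeries(le, sz)


def _count_comment_lines(path: str | Path) -> int:
    count = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                count += 1
            else:
                break
    return count


def write_matrix_csv(path: str | Path, M: np.ndarray, meta: dict | None = None) -> None:
    """Matrix as plain CSV with an optional JSON sidecar (same stem)."""
    np.savetxt(path, np.atleast_2d(M), delimiter=",")
    if meta is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_matrix_csv(path: str | Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter=","))
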