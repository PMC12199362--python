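"""Containers for hourly count records.

The unit of analysis throughout the package is the hour index on a strict
uniform grid; wall-clock timestamps are carried only for serialization.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = ["HourlyCountSeries", "EventSeries", "check_aligned"]


@dataclasses.dataclass
class HourlyCountSeries:
    """Hourly counts on a uniform 1-hour grid.

    Parameters
    ----------
    values
        Count (or normalized) values, one per hour.
    start_time
        Timestamp of the first sample; hour ``i`` is ``start_time + i h``.
    gap_mask
        True where the hour is missing (telemetry gap). Missing samples keep
        a placeholder value but are excluded from normalization statistics.
    visit_boundaries
        Strictly increasing sample indices in ``(0, n)`` at which a new
        inter-visit block starts. Device detection parameters may be retuned
        at office visits, so each block is normalized independently.
    """

    values: np.ndarray
    start_time: pd.Timestamp = pd.Timestamp("2020-01-01 00:00")
    gap_mask: np.ndarray | None = None
    visit_boundaries: np.ndarray | None = None
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        n = self.values.size
        if self.gap_mask is None:
            self.gap_mask = np.zeros(n, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.size != n:
                raise ValueError("gap_mask length does not match values")
        if self.visit_boundaries is None:
            self.visit_boundaries = np.empty(0, dtype=int)
        else:
            vb = np.asarray(self.visit_boundaries, dtype=int)
            if vb.size and (np.any(np.diff(vb) <= 0) or vb[0] <= 0 or vb[-1] >= n):
                raise ValueError(
                    "visit_boundaries must be strictly increasing and inside (0, n)"
                )
            self.visit_boundaries = vb
        self.start_time = pd.Timestamp(self.start_time)

    @property
    def n_hours(self) -> int:
        return self.values.size

    def block_slices(self) -> list[slice]:
        """Inter-visit blocks as slices covering the whole series."""
        edges = [0, *self.visit_boundaries.tolist(), self.n_hours]
        return [slice(a, b) for a, b in zip(edges[:-1], edges[1:]) if b > a]

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=self.n_hours, freq="h")

    def copy(self) -> "HourlyCountSeries":
        return HourlyCountSeries(
            self.values.copy(),
            self.start_time,
            self.gap_mask.copy(),
            self.visit_boundaries.copy(),
            self.patient_id,
        )


@dataclasses.dataclass
class EventSeries:
    """Device-labeled long events (LEs) and sparse patient-labeled seizures.

    ``le_counts`` are non-negative integers on the same hourly grid as the
    companion :class:`HourlyCountSeries`; ``seizure_flags`` marks the subset
    of hours the patient additionally tagged (e.g., by magnet swipe).
    """

    le_counts: np.ndarray
    seizure_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.le_counts = np.asarray(self.le_counts)
        if np.any(self.le_counts < 0):
            raise ValueError("le_counts must be non-negative")
        self.le_counts = self.le_counts.astype(int)
        if self.seizure_flags is None:
            self.seizure_flags = np.zeros(self.le_counts.size, dtype=bool)
        else:
            self.seizure_flags = np.asarray(self.seizure_flags, dtype=bool)
            if self.seizure_flags.size != self.le_counts.size:
                raise ValueError("seizure_flags length does not match le_counts")

    @property
    def n_hours(self) -> int:
        return self.le_counts.size

    def copy(self) -> "EventSeries":
        return EventSeries(self.le_counts.copy(), self.seizure_flags.copy())


def check_aligned(series: HourlyCountSeries, events: EventSeries) -> None:
    if series.n_hours != events.n_hours:
        raise ValueError(
            f"series ({series.n_hours} h) and events ({events.n_hours} h) "
            "are not on the same grid"
        )
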