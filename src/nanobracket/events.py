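"""Translocation-event extraction from raw ion-current traces.

A nanopore channel reports an open-pore current Io (pA); a translocating
molecule occupies part of the lumen and drops the current to a residual
level Ir for the dwell time of the molecule.  At the platform's acquisition
rate of 3 points per millisecond a dwell of tau milliseconds spans
``3 * tau`` samples ("tps", time points).  An event is a maximal run of
consecutive samples whose residual ratio Ir/Io falls below a ceiling, and
events are kept only when they satisfy the published threshold filters:

* duration between 4 and 1200 tps (1.3-400 ms),
* lowest Ir/Io below 0.55,
* every sample's Ir/Io below 0.6 (automatic from the run definition).

Inequalities are strict.  Coordinates are 0-based and half-open,
``[start_index, start_index + duration_tps)``.  Adjacent sub-ceiling runs
separated by even a single at-baseline sample are distinct events; no
merging is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

#: Acquisition rate of the instrument's raw output.
DEFAULT_SAMPLING_PER_MS = 3.0

#: Canonical column order of the inter-stage event table.
EVENT_COLUMNS = ["channel", "start_tps", "duration_tps", "min_ratio", "max_ratio"]


@dataclass(frozen=True)
class FilterParams:
    """Published event-acceptance thresholds."""

    min_duration_tps: int = 4
    max_duration_tps: int = 1200
    min_ratio_ceiling: float = 0.55
    all_ratio_ceiling: float = 0.6

    def __post_init__(self) -> None:
        if self.min_duration_tps < 1 or self.min_duration_tps > self.max_duration_tps:
            raise ValueError("require 1 <= min_duration_tps <= max_duration_tps")
        if not (0 < self.min_ratio_ceiling <= self.all_ratio_ceiling < 1):
            raise ValueError("require 0 < min_ratio_ceiling <= all_ratio_ceiling < 1")


@dataclass
class RawTrace:
    """Per-channel current samples in pA.

    ``open_current`` may be left unset and estimated robustly with
    :func:`estimate_open_current`.
    """

    channel_id: int
    samples: np.ndarray
    sampling_per_ms: float = DEFAULT_SAMPLING_PER_MS
    open_current: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_per_ms <= 0:
            raise ValueError("sampling_per_ms must be positive")


@dataclass(frozen=True)
class TranslocationEvent:
    channel_id: int
    start_index: int
    duration_tps: int
    min_ratio: float
    max_ratio: float

    @property
    def duration_ms(self) -> float:
        return self.duration_tps / DEFAULT_SAMPLING_PER_MS


def estimate_open_current(trace: RawTrace) -> float:
    """Estimate the open-pore current Io of a trace.

    Io is taken as the median of the samples above 0.8x the trace's 95th
    percentile, which ignores dips as long as they occupy well under half
    of the samples.
    """
    x = trace.samples
    if x.size == 0:
        raise ValueError("empty trace")
    if np.max(x) <= 0:
        raise ValueError("trace has no positive samples; cannot estimate open current")
    p95 = np.percentile(x, 95)
    top = x[x > 0.8 * p95]
    io = float(np.median(top))
    if io <= 0:
        raise ValueError("open-current estimate is non-positive")
    return io


def extract_events(
    trace: RawTrace, params: FilterParams | None = None
) -> list[TranslocationEvent]:
    """Extract filtered translocation events, in ascending start order.

    The trace's ``open_current`` is used when set, otherwise estimated.
    """
    params = params or FilterParams()
    io = trace.open_current
    if io is None:
        io = estimate_open_current(trace)
    if io <= 0:
        raise ValueError("open_current must be positive")

    ratio = trace.samples / io
    below = ratio < params.all_ratio_ceiling
    if not below.any():
        return []

    flags = below.astype(np.int8)
    d = np.diff(flags)
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if below[0]:
        starts = np.concatenate(([0], starts))
    if below[-1]:
        ends = np.concatenate((ends, [below.size]))

    out: list[TranslocationEvent] = []
    for s, e in zip(starts, ends):
        dur = int(e - s)
        if dur < params.min_duration_tps or dur > params.max_duration_tps:
            continue
        seg = ratio[s:e]
        mn = float(seg.min())
        if mn >= params.min_ratio_ceiling:
            continue
        out.append(
            TranslocationEvent(
                channel_id=trace.channel_id,
                start_index=int(s),
                duration_tps=dur,
                min_ratio=mn,
                max_ratio=float(seg.max()),
            )
        )
    return out


def events_to_frame(events: Iterable[TranslocationEvent]) -> pd.DataFrame:
    """Convert events to the canonical inter-stage table."""
    rows = [
        (ev.channel_id, ev.start_index, ev.duration_tps, ev.min_ratio, ev.max_ratio)
        for ev in events
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS).astype(
        {"channel": int, "start_tps": int, "duration_tps": int}
    )


def filter_event_table(
    table: pd.DataFrame, params: FilterParams | None = None
) -> pd.DataFrame:
    """Apply the acceptance thresholds to a pre-extracted event table.

    Mirrors :func:`extract_events` for pipelines that start from event
    tables (simulator output or the detector's TSV) instead of raw signal.
    """
    params = params or FilterParams()
    keep = (
        (table["duration_tps"] >= params.min_duration_tps)
        & (table["duration_tps"] <= params.max_duration_tps)
        & (table["min_ratio"] < params.min_ratio_ceiling)
        & (table["max_ratio"] < params.all_ratio_ceiling)
    )
    return table.loc[keep].reset_index(drop=True)
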