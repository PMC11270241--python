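"""Residual-ratio histograms and the detection/silencing caller.

Filtered events are binned on their lowest residual ratio (min Ir/Io) into
0.05-wide, left-closed bins spanning [0.05, 0.55).  Typical runs show two
maxima: an early one near 0.15 (the probe population) and a late one near
0.30 (background).  Either maximum may drift by +/-0.05 with flow-cell
age, so each is sought as the highest-count bin whose centre lies within
0.15 +/- 0.05 and 0.30 +/- 0.05 respectively.  The R-factor is the ratio
of the late maximum's count to the early maximum's count.

A test is three runs on one flow cell: a buffer control followed by two
runs of the probe/RNA mixture.  Free probe adds early events, so R drops
relative to the control (detection); a fully hybridised probe shields the
pores, events are suppressed and R rises (silencing).  A change in R must
be statistically significant to count; the two directions may not be
mixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .events import TranslocationEvent, events_to_frame

HISTOGRAM_EDGES = np.round(np.arange(0.05, 0.551, 0.05), 10)  # 10 bins
EARLY_CENTER = 0.15
LATE_CENTER = 0.30
MAXIMUM_WOBBLE = 0.05

DETECTION = "DETECTION"
SILENCING = "SILENCING"
INCONCLUSIVE = "INCONCLUSIVE"

Call = Literal["DETECTION", "SILENCING", "INCONCLUSIVE"]


@dataclass
class RatioHistogram:
    """0.05-binned min-ratio histogram with its two maxima.

    ``total_events`` counts the events inside [0.05, 0.55), i.e. the sum
    of the bin counts.  ``early_max``/``late_max`` are ``(bin centre,
    count)`` pairs; a zero-count maximum is flagged.
    """

    counts: np.ndarray
    total_events: int
    early_max: tuple[float, int]
    late_max: tuple[float, int]
    r_factor: float
    early_window_count: int = 0  # all events with centres in 0.15 +/- 0.05
    late_window_count: int = 0  # all events with centres in 0.30 +/- 0.05
    flags: list[str] = field(default_factory=list)
    bin_edges: np.ndarray = field(default_factory=lambda: HISTOGRAM_EDGES.copy())

    @property
    def bin_centers(self) -> np.ndarray:
        return np.round((self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0, 3)


def _window_max(
    centers: np.ndarray, counts: np.ndarray, center: float
) -> tuple[tuple[float, int], int]:
    """(highest-count bin, total count) within ``center +/- 0.05``."""
    lo, hi = center - MAXIMUM_WOBBLE, center + MAXIMUM_WOBBLE
    in_win = (centers >= lo - 1e-9) & (centers <= hi + 1e-9)
    idx = np.flatnonzero(in_win)
    best = idx[np.argmax(counts[idx])]
    return (float(centers[best]), int(counts[best])), int(counts[idx].sum())


def build_histogram(
    events: pd.DataFrame | Sequence[TranslocationEvent],
) -> RatioHistogram:
    """Build the ratio histogram of an already-filtered event set."""
    if not isinstance(events, pd.DataFrame):
        events = events_to_frame(list(events))
    ratios = np.asarray(events["min_ratio"], dtype=float)
    lo, hi = HISTOGRAM_EDGES[0], HISTOGRAM_EDGES[-1]
    width = 0.05
    idx = np.floor((ratios - lo) / width).astype(int)
    in_range = (ratios >= lo) & (ratios < hi)
    counts = np.bincount(idx[in_range], minlength=len(HISTOGRAM_EDGES) - 1)[
        : len(HISTOGRAM_EDGES) - 1
    ]
    centers = np.round((HISTOGRAM_EDGES[:-1] + HISTOGRAM_EDGES[1:]) / 2.0, 3)
    early, early_win = _window_max(centers, counts, EARLY_CENTER)
    late, late_win = _window_max(centers, counts, LATE_CENTER)
    flags = []
    if early[1] == 0:
        flags.append("zero-count early maximum")
    if late[1] == 0:
        flags.append("zero-count late maximum")
    r = float(late[1]) / float(early[1]) if early[1] > 0 else float("nan")
    return RatioHistogram(
        counts=counts,
        total_events=int(counts.sum()),
        early_max=early,
        late_max=late,
        r_factor=r,
        early_window_count=early_win,
        late_window_count=late_win,
        flags=flags,
    )


@dataclass(frozen=True)
class CallConfig:
    """Significance settings of the triplet caller.

    An R change between a run and the control is judged by a two-sided
    two-proportion z-test on the late-vs-early window counts at level
    ``alpha``.  A test whose two sample runs both total fewer than
    ``severe_reduction_fraction`` of the control's events is called
    silencing outright (shielding).
    """

    alpha: float = 0.05
    severe_reduction_fraction: float = 0.25


@dataclass
class TripletCall:
    r_control: float
    r_run1: float
    r_run2: float
    totals: tuple[int, int, int]
    call: Call
    rationale: str
    directions: tuple[str, str] = ("none", "none")  # significant direction per run
    trends: tuple[str, str] = ("flat", "flat")  # raw direction of R, any size


def _run_direction(
    control: RatioHistogram, run: RatioHistogram, alpha: float
) -> str:
    """'increase' / 'decrease' / 'none' of R vs the control, with significance.

    The late-vs-early window counts are the sufficient statistic: the
    late-event share is compared between control and run with a two-sided
    two-proportion z-test.
    """
    ec, lc = control.early_window_count, control.late_window_count
    er, lr = run.early_window_count, run.late_window_count
    if ec + lc == 0 or er + lr == 0:
        return "none"
    stat, p = proportions_ztest([lc, lr], [ec + lc, er + lr])
    if not np.isfinite(p) or p >= alpha:
        return "none"
    p_c = lc / (ec + lc)
    p_r = lr / (er + lr)
    return "increase" if p_r > p_c else "decrease"


def _trend(r_control: float, r_run: float) -> str:
    if not (np.isfinite(r_control) and np.isfinite(r_run)):
        return "flat"
    if r_run > r_control:
        return "up"
    if r_run < r_control:
        return "down"
    return "flat"


def call_triplet(
    control: RatioHistogram,
    run1: RatioHistogram,
    run2: RatioHistogram,
    config: CallConfig | None = None,
) -> TripletCall:
    """Call a control/run1/run2 test as detection, silencing or inconclusive.

    Detection requires at least one significant R decrease and no
    significant increase; silencing the reverse.  Mixed directions are
    inconclusive (such a pattern may carry information about the copy
    number itself, but no rule is applied here).  Severely reduced totals
    in both runs indicate shielding and are called silencing regardless
    of R.
    """
    config = config or CallConfig()
    totals = (control.total_events, run1.total_events, run2.total_events)
    base = dict(
        r_control=control.r_factor,
        r_run1=run1.r_factor,
        r_run2=run2.r_factor,
        totals=totals,
        trends=(_trend(control.r_factor, run1.r_factor),
                _trend(control.r_factor, run2.r_factor)),
    )

    severe = (
        totals[0] > 0
        and totals[1] < config.severe_reduction_fraction * totals[0]
        and totals[2] < config.severe_reduction_fraction * totals[0]
    )
    if severe:
        return TripletCall(
            call=SILENCING,
            rationale=(
                "severely reduced events in both runs "
                f"(< {config.severe_reduction_fraction:.0%} of control)"
            ),
            directions=("none", "none"),
            **base,
        )

    if control.early_max[1] == 0 or control.late_max[1] == 0:
        return TripletCall(
            call=INCONCLUSIVE,
            rationale="zero-count maximum in control histogram",
            directions=("none", "none"),
            **base,
        )

    d1 = _run_direction(control, run1, config.alpha)
    d2 = _run_direction(control, run2, config.alpha)
    n_dec = (d1 == "decrease") + (d2 == "decrease")
    n_inc = (d1 == "increase") + (d2 == "increase")
    if n_dec and n_inc:
        call, why = INCONCLUSIVE, (
            "one run increased and one decreased R significantly; "
            "mixed directions are inconclusive"
        )
    elif n_dec:
        call, why = DETECTION, f"R decreased significantly in {n_dec} run(s)"
    elif n_inc:
        call, why = SILENCING, f"R increased significantly in {n_inc} run(s)"
    else:
        call, why = INCONCLUSIVE, "no statistically significant change in R"
    return TripletCall(call=call, rationale=why, directions=(d1, d2), **base)
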