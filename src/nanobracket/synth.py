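"""Seeded synthetic flow-cell runs and cohort-level HL tables.

The generator emulates the statistical structure the sensing platform
assumes, so that every downstream stage is testable without instrument
data:

* Two translocation populations.  Osmium-tagged probes dwell long enough
  to be sampled and translocate with a residual ratio Ir/Io near 0.15;
  background traffic (buffer impurities, the occasional intact nucleic
  acid caught by the detector) clusters near 0.30.  Min-ratio values are
  drawn from truncated normals centred at those maxima.
* 1:1 hybridisation.  With P probe copies loaded against T target copies
  per microlitre in a y-microlitre RNA aliquot, the free probe is
  ``F = max(0, P - T*y)`` and the expected probe-population event count is
  proportional to F.
* Pore inactivation.  The active fraction of the flow cell decays by a
  fixed factor every run, so totals shrink from control to run 1 to run 2.
* Shielding.  When the probe is fully hybridised (F = 0) the bulky
  probe/target hybrids crowd the pore entrances without translocating;
  totals drop by ``shielding_factor`` and the early (probe-like) window is
  suppressed more strongly, so the late/early ratio R rises relative to
  the control.

A run can be materialised either as a plain event table (the fast path,
mirroring the detector's TSV output) or as raw per-channel traces with the
dips planted in the signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .events import DEFAULT_SAMPLING_PER_MS, EVENT_COLUMNS, RawTrace

#: copies per (fM * uL); 600 reproduces the platform's printed bookkeeping.
COPIES_PER_FM_UL = 600.0

# Residual-ratio populations (min-ratio statistic), truncated to (0, 0.55).
PROBE_RATIO_MEAN = 0.15
PROBE_RATIO_SD = 0.03
BACKGROUND_RATIO_MEAN = 0.30
BACKGROUND_RATIO_SD = 0.05
RATIO_TRUNC = (0.0, 0.55)

#: accepted dwell window (tps); decoys are planted outside it.
DURATION_RANGE_TPS = (4, 1200)

RUN_MINUTES = 45.0
BIAS_VOLTAGE_MV = -180.0

# Cohort-level HL distributions: healthy markers sit at the healthy level
# by construction; validated cancer biomarkers are ~1.8-fold overexpressed
# with tight spread; miR-15b is cancer-independent.
HEALTHY_HL_MEAN = 1.0
HEALTHY_HL_RSD = 0.17
CANCER_HL_MEAN = 1.83
CANCER_HL_RSD = 0.09
MIR15B_HL_MEAN = 0.96
MIR15B_HL_RSD = 0.14

COHORT_MARKERS = ("miR-15b", "miR-21", "miR-375", "miR-141")
KNOWN_MARKERS = ("let-7b", "miR-15b", "miR-16", "miR-21", "miR-375", "miR-141")
CANCER_INDEPENDENT_MARKERS = frozenset({"miR-15b"})


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth and loading of one simulated experiment."""

    mirna_id: str
    true_copies_per_ul_rna: float
    rna_conc: float  # ng/uL
    probe_conc: float = 30.0  # fM
    probe_vol: float = 5.0  # uL
    rna_vol: float = 8.0  # uL

    def __post_init__(self) -> None:
        if min(self.rna_conc, self.probe_conc, self.probe_vol, self.rna_vol) <= 0:
            raise ValueError("volumes and concentrations must be positive")
        if self.true_copies_per_ul_rna < 0:
            raise ValueError("true_copies_per_ul_rna must be non-negative")

    @property
    def probe_copies(self) -> float:
        """P: probe copies loaded."""
        return COPIES_PER_FM_UL * self.probe_vol * self.probe_conc

    @property
    def target_copies(self) -> float:
        """T*y: target copies in the RNA aliquot."""
        return self.true_copies_per_ul_rna * self.rna_vol

    @property
    def free_probe(self) -> float:
        """F = max(0, P - T*y) under 1:1 hybridisation."""
        return max(0.0, self.probe_copies - self.target_copies)


@dataclass(frozen=True)
class FlowCellState:
    """Per-session flow-cell condition.

    ``active_fraction`` is the initial usable-channel fraction; it decays
    by ``per_run_decay`` with every run of the session.  ``shielding_factor``
    scales totals only when no free probe remains.
    """

    n_channels: int = 512
    active_fraction: float = 1.0
    per_run_decay: float = 0.15
    shielding_factor: float = 0.35
    early_shielding_factor: float = 0.5  # extra suppression of the early window

    def __post_init__(self) -> None:
        if not (0 < self.active_fraction <= 1):
            raise ValueError("active_fraction must be in (0, 1]")
        if not (0 <= self.per_run_decay < 1):
            raise ValueError("per_run_decay must be in [0, 1)")
        if not (0 < self.shielding_factor <= 1):
            raise ValueError("shielding_factor must be in (0, 1]")

    def active_at(self, run_index: int) -> float:
        return self.active_fraction * (1.0 - self.per_run_decay) ** run_index


@dataclass(frozen=True)
class SimulatorConfig:
    """Event-rate model of one 45-minute run.

    ``background_rate`` is the expected background event count at full
    channel activity; ``background_early_fraction`` of it falls in the
    early (0.15) window.  ``capture_efficiency`` converts free-probe copies
    into expected probe events.  ``decoy_fraction`` plants out-of-window
    durations to exercise the duration filter downstream.
    """

    background_rate: float = 800.0
    background_early_fraction: float = 0.35
    capture_efficiency: float = 0.05
    decoy_fraction: float = 0.05
    noise_sd_fraction: float = 0.02  # trace mode: additive noise, sd = 2% of Io
    open_current: float = 220.0  # pA


@dataclass
class SimulatedRun:
    """One 45-minute run: an event table and/or raw traces plus the truth."""

    truth: TruthSpec
    seed: int
    run_index: int  # 0 = buffer control, 1 and 2 = sample runs
    events: Optional[pd.DataFrame] = None
    traces: Optional[list[RawTrace]] = None


def _draw_ratios(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    lo, hi = RATIO_TRUNC
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _draw_durations(
    rng: np.random.Generator, n: int, decoy_fraction: float
) -> np.ndarray:
    lo, hi = DURATION_RANGE_TPS
    d = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    dur = np.clip(d.astype(int), lo, hi)
    n_decoy = rng.binomial(n, decoy_fraction) if n else 0
    if n_decoy:
        idx = rng.choice(n, size=n_decoy, replace=False)
        short = rng.random(n_decoy) < 0.5
        dur[idx] = np.where(short, rng.integers(1, lo, size=n_decoy),
                            rng.integers(hi + 1, 3 * hi, size=n_decoy))
    return dur


def _event_table(
    rng: np.random.Generator,
    n_early: int,
    n_late: int,
    flowcell: FlowCellState,
    config: SimulatorConfig,
) -> pd.DataFrame:
    n = n_early + n_late
    ratios = np.concatenate(
        [
            _draw_ratios(rng, n_early, PROBE_RATIO_MEAN, PROBE_RATIO_SD),
            _draw_ratios(rng, n_late, BACKGROUND_RATIO_MEAN, BACKGROUND_RATIO_SD),
        ]
    )
    dur = _draw_durations(rng, n, config.decoy_fraction)
    total_tps = int(RUN_MINUTES * 60 * 1000 * DEFAULT_SAMPLING_PER_MS)
    start = rng.integers(0, max(1, total_tps - DURATION_RANGE_TPS[1]), size=n)
    channel = rng.integers(1, flowcell.n_channels + 1, size=n)
    # max_ratio stays below the 0.6 run ceiling by construction
    max_ratio = ratios + rng.uniform(0.0, 1.0, size=n) * (0.595 - ratios)
    df = pd.DataFrame(
        {
            "channel": channel,
            "start_tps": start,
            "duration_tps": dur,
            "min_ratio": ratios,
            "max_ratio": max_ratio,
        }
    )[EVENT_COLUMNS]
    return df.sort_values(["channel", "start_tps"], kind="stable").reset_index(drop=True)


def _expected_counts(
    truth: TruthSpec, flowcell: FlowCellState, config: SimulatorConfig, run_index: int
) -> tuple[float, float]:
    """Expected (early, late) event counts for one run."""
    af = flowcell.active_at(run_index)
    bg = config.background_rate * af
    early = bg * config.background_early_fraction
    late = bg * (1.0 - config.background_early_fraction)
    if run_index == 0:
        return early, late
    free = truth.free_probe
    if free > 0:
        early += config.capture_efficiency * free * af
    else:
        early *= flowcell.shielding_factor * flowcell.early_shielding_factor
        late *= flowcell.shielding_factor
    return early, late


def simulate_run(
    truth: TruthSpec,
    flowcell: FlowCellState,
    run_index: int,
    rng: np.random.Generator,
    config: SimulatorConfig | None = None,
) -> pd.DataFrame:
    """Event table of a single run (control when ``run_index == 0``)."""
    config = config or SimulatorConfig()
    mu_early, mu_late = _expected_counts(truth, flowcell, config, run_index)
    n_early = int(rng.poisson(mu_early))
    n_late = int(rng.poisson(mu_late))
    return _event_table(rng, n_early, n_late, flowcell, config)


def simulate_experiment(
    truth: TruthSpec,
    flowcell: FlowCellState | None = None,
    seed: int = 0,
    config: SimulatorConfig | None = None,
) -> tuple[SimulatedRun, SimulatedRun, SimulatedRun]:
    """Simulate one test: a buffer control followed by two sample runs.

    The control contains background events only.  Identical
    ``(truth, flowcell, config, seed)`` reproduce the three event tables
    bit-for-bit.
    """
    flowcell = flowcell or FlowCellState()
    config = config or SimulatorConfig()
    rng = np.random.default_rng(seed)
    runs = []
    for run_index in range(3):
        table = simulate_run(truth, flowcell, run_index, rng, config)
        runs.append(
            SimulatedRun(truth=truth, seed=seed, run_index=run_index, events=table)
        )
    return tuple(runs)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# signal-level simulation


def simulate_trace(
    open_current: float,
    noise_sd: float,
    dips: Sequence[tuple[int, int, float]],
    n_samples: int,
    sampling_per_ms: float = DEFAULT_SAMPLING_PER_MS,
    channel_id: int = 1,
    rng: np.random.Generator | None = None,
) -> RawTrace:
    """Synthesize a raw trace with planted dips.

    ``dips`` are ``(start_index, duration_tps, residual_ratio)`` triples;
    each drops the current to ``ratio * open_current`` for its span.
    Overlapping or out-of-bounds dips are rejected.
    """
    if open_current <= 0:
        raise ValueError("open_current must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(0)
    x = np.full(n_samples, open_current, dtype=np.float64)
    prev_end = -1
    for start, dur, ratio in sorted(dips, key=lambda d: d[0]):
        if start < 0 or dur < 1 or start + dur > n_samples:
            raise ValueError(f"dip ({start}, {dur}) outside trace of {n_samples} samples")
        if start <= prev_end:
            raise ValueError(
                f"dip at {start} overlaps the previous dip ending at {prev_end}"
            )
        if not (0 < ratio < 1):
            raise ValueError("dip residual ratio must be in (0, 1)")
        x[start : start + dur] = ratio * open_current
        prev_end = start + dur - 1
    if noise_sd > 0:
        x += rng.normal(0.0, noise_sd, size=n_samples)
    return RawTrace(
        channel_id=channel_id,
        samples=x,
        sampling_per_ms=sampling_per_ms,
        open_current=None,
    )


def plant_events_in_traces(
    table: pd.DataFrame,
    n_channels: int,
    n_samples: int,
    config: SimulatorConfig,
    rng: np.random.Generator,
) -> list[RawTrace]:
    """Materialise an event table as raw traces, one per channel.

    Events are re-timed uniformly within the trace (non-overlapping per
    channel); events that cannot be placed without overlap are dropped,
    which only matters at densities far above the instrument's.
    """
    io = config.open_current
    noise_sd = config.noise_sd_fraction * io
    traces = []
    for ch in range(1, n_channels + 1):
        sub = table[table["channel"] == ch]
        dips: list[tuple[int, int, float]] = []
        occupied: list[tuple[int, int]] = []
        for _, row in sub.iterrows():
            dur = int(min(row["duration_tps"], max(1, n_samples // 4)))
            for _ in range(20):
                start = int(rng.integers(0, max(1, n_samples - dur)))
                if all(start + dur + 1 <= s or start >= e + 2 for s, e in occupied):
                    occupied.append((start, start + dur))
                    dips.append((start, dur, float(row["min_ratio"])))
                    break
        traces.append(
            simulate_trace(io, noise_sd, dips, n_samples, channel_id=ch, rng=rng)
        )
    return traces


# ---------------------------------------------------------------------------
# cohort generator


def generate_cohort(
    n_healthy: int,
    n_cancer: int,
    markers: Sequence[str] = COHORT_MARKERS,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a tidy HL table for a synthetic healthy/cancer cohort.

    Healthy marker values are drawn around the healthy level (mean 1.0,
    RSD 0.17); validated biomarkers in cancer samples around 1.83 with
    RSD 0.09; miR-15b is drawn cancer-independently around 0.96 with
    RSD 0.14.  All values are positive (truncated normals).
    """
    if n_healthy < 0 or n_cancer < 0 or n_healthy + n_cancer < 1:
        raise ValueError("need at least one subject")
    for m in markers:
        if m not in KNOWN_MARKERS:
            raise ValueError(f"unknown marker label: {m!r}")
    rng = np.random.default_rng(seed)
    rows = []

    def draw(mean: float, rsd: float) -> float:
        sd = mean * rsd
        a = (0.0 - mean) / sd
        return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))

    for i in range(n_healthy + n_cancer):
        condition = "healthy" if i < n_healthy else "cancer"
        sample_id = f"{'H' if condition == 'healthy' else 'C'}{i + 1:03d}"
        for m in markers:
            if m in CANCER_INDEPENDENT_MARKERS:
                hl = draw(MIR15B_HL_MEAN, MIR15B_HL_RSD)
            elif condition == "cancer":
                hl = draw(CANCER_HL_MEAN, CANCER_HL_RSD)
            else:
                hl = draw(HEALTHY_HL_MEAN, HEALTHY_HL_RSD)
            rows.append((sample_id, condition, m, hl))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "marker", "hl"])
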