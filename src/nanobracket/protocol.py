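"""The bracketing titration protocol, end to end.

A copy number is measured by running tests (control + two runs) at
different probe-to-RNA loadings and walking a geometric ladder of
``P/y`` values spaced by a factor 1.5: a silencing call puts the target
above the rung, a detection call below it.  Two adjacent rungs with
opposite calls bracket the target with relative accuracy exactly
``(1.5 - 1) / (1.5 + 1) = 0.20``.  Inconclusive tests are retried a
bounded number of times; if a rung between the bounds stays inconclusive
the bracket is wider than protocol accuracy and is flagged, never
silently tightened.

The driver is simulator-agnostic: it only needs a callable that runs one
test at a requested ``P/y`` and returns the triplet call.  A convenience
factory wires the synthetic flow-cell simulator, the event filter, the
histogram stage and the caller into such a callable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import calling, events, quantify, synth

LADDER_FACTOR = 1.5


@dataclass
class TitrationResult:
    """Outcome of one bracketing campaign."""

    estimate: Optional[quantify.BracketEstimate]
    bounds: list[quantify.BoundEstimate]
    calls: list[tuple[float, str]]  # (P/y, call) in execution order
    n_tests: int
    tight: bool  # bound pair sits on adjacent ladder rungs
    error: Optional[str] = None


TestRunner = Callable[[float, int], str]


def make_simulated_test_runner(
    true_copies_per_ul_rna: float,
    rna_conc: float = 16.0,
    rna_vol: float = 8.0,
    probe_conc: float = 30.0,
    flowcell: synth.FlowCellState | None = None,
    sim_config: synth.SimulatorConfig | None = None,
    filter_params: events.FilterParams | None = None,
    call_config: calling.CallConfig | None = None,
) -> TestRunner:
    """A test runner over the synthetic flow cell.

    Each invocation simulates a fresh three-run session at the requested
    ``P/y`` (probe volume adjusted, RNA aliquot fixed), filters the event
    tables, builds the ratio histograms and returns the triplet call.
    """
    flowcell = flowcell or synth.FlowCellState()
    filter_params = filter_params or events.FilterParams()

    def run_test(p_per_y: float, seed: int) -> str:
        probe_vol = p_per_y * rna_vol / (synth.COPIES_PER_FM_UL * probe_conc)
        truth = synth.TruthSpec(
            mirna_id="synthetic",
            true_copies_per_ul_rna=true_copies_per_ul_rna,
            rna_conc=rna_conc,
            probe_conc=probe_conc,
            probe_vol=probe_vol,
            rna_vol=rna_vol,
        )
        runs = synth.simulate_experiment(truth, flowcell, seed=seed, config=sim_config)
        hists = [
            calling.build_histogram(events.filter_event_table(r.events, filter_params))
            for r in runs
        ]
        return calling.call_triplet(*hists, config=call_config).call

    return run_test


def bracket_titration(
    run_test: TestRunner,
    start_p_per_y: float,
    seed: int = 0,
    max_tests: int = 14,
    max_retries: int = 2,
    ladder_factor: float = LADDER_FACTOR,
) -> TitrationResult:
    """Walk the titration ladder until a copy-number bracket is found.

    ``run_test(p_per_y, seed) -> call`` runs one full test.  The ladder is
    anchored at ``start_p_per_y``; rung k is ``start * factor**k``.
    """
    seeds = iter(np.random.SeedSequence(seed).generate_state(max_tests * 4) % (2**31))
    tested: dict[int, list[str]] = {}
    calls_log: list[tuple[float, str]] = []
    k_low: Optional[int] = None  # highest SIL rung
    k_high: Optional[int] = None  # lowest DET rung

    def rung(k: int) -> float:
        return start_p_per_y * ladder_factor**k

    def evaluate(k: int) -> str:
        call = run_test(rung(k), int(next(seeds)))
        tested.setdefault(k, []).append(call)
        calls_log.append((rung(k), call))
        return call

    def note(k: int, call: str) -> None:
        nonlocal k_low, k_high
        if call == calling.SILENCING and (k_low is None or k > k_low):
            k_low = k
        elif call == calling.DETECTION and (k_high is None or k < k_high):
            k_high = k

    # probe outward from the anchor until both bound directions exist
    n_tests = 0
    probe_order = [0]
    step = 1
    while len(probe_order) < max_tests:
        probe_order.extend([step, -step])
        step += 1

    def next_rung() -> Optional[int]:
        if k_low is None and k_high is None:
            for k in probe_order:
                if k not in tested or len(tested[k]) <= max_retries:
                    return k
            return None
        if k_high is None:
            k = (k_low + 1) if k_low is not None else 1
            while k in tested and len(tested[k]) > max_retries:
                k += 1
            return k
        if k_low is None:
            k = k_high - 1
            while k in tested and len(tested[k]) > max_retries:
                k -= 1
            return k
        if k_high - k_low > 1:
            for k in range(k_low + 1, k_high):
                if k not in tested or len(tested[k]) <= max_retries:
                    return k
        return None  # bracket settled

    while n_tests < max_tests:
        k = next_rung()
        if k is None:
            break
        call = evaluate(k)
        note(k, call)
        n_tests += 1
        if (
            k_low is not None
            and k_high is not None
            and k_high - k_low == 1
        ):
            break

    bounds = []
    for k, calls in tested.items():
        for call in calls:
            if call == calling.SILENCING:
                bounds.append(quantify.BoundEstimate(rung(k), "lower", source_id=f"rung{k}"))
            elif call == calling.DETECTION:
                bounds.append(quantify.BoundEstimate(rung(k), "upper", source_id=f"rung{k}"))

    if k_low is None or k_high is None:
        return TitrationResult(
            estimate=None, bounds=bounds, calls=calls_log, n_tests=n_tests,
            tight=False, error="no consistent detection/silencing bound pair found",
        )
    try:
        est = quantify.bracket(bounds)
    except quantify.InconsistentBoundsError as exc:
        return TitrationResult(
            estimate=None, bounds=bounds, calls=calls_log, n_tests=n_tests,
            tight=False, error=str(exc),
        )
    tight = k_high - k_low == 1
    return TitrationResult(
        estimate=est, bounds=bounds, calls=calls_log, n_tests=n_tests, tight=tight
    )
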