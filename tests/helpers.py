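"""Independent reference implementations used as test oracles."""

from __future__ import annotations

from nanobracket.events import FilterParams


def naive_event_scan(samples, open_current, params: FilterParams):
    """Sample-by-sample reference scan applying the three filter rules.

    Deliberately written as a plain loop, independent of the vectorised
    extraction path.
    """
    events = []
    run = []
    for i, v in enumerate(samples):
        r = v / open_current
        if r < params.all_ratio_ceiling:
            run.append((i, r))
        else:
            _flush(run, events, params)
            run = []
    _flush(run, events, params)
    return events


def _flush(run, events, params):
    if not run:
        return
    start = run[0][0]
    dur = len(run)
    ratios = [r for _, r in run]
    mn, mx = min(ratios), max(ratios)
    if (
        params.min_duration_tps <= dur <= params.max_duration_tps
        and mn < params.min_ratio_ceiling
        and all(r < params.all_ratio_ceiling for r in ratios)
    ):
        events.append((start, dur, mn, mx))


def count_dips_below(samples, open_current, ceiling=0.6):
    """Number of maximal sub-ceiling runs in a trace (brute force)."""
    below = [v / open_current < ceiling for v in samples]
    n = 0
    prev = False
    for b in below:
        if b and not prev:
            n += 1
        prev = b
    return n


def confusion_counts(truth, calls):
    """Direct 2x2 tabulation for cross-checking confusion_metrics."""
    tp = sum(1 for t, c in zip(truth, calls) if t and c)
    tn = sum(1 for t, c in zip(truth, calls) if not t and not c)
    fp = sum(1 for t, c in zip(truth, calls) if not t and c)
    fn = sum(1 for t, c in zip(truth, calls) if t and not c)
    return tp, tn, fp, fn


def random_trace(rng, n_samples, open_current=220.0, noise_sd=4.0, n_dips=None):
    """A random trace with non-overlapping planted dips and its dip list."""
    if n_dips is None:
        n_dips = int(rng.integers(0, 12))
    x = open_current + rng.normal(0.0, noise_sd, size=n_samples)
    dips = []
    cursor = int(rng.integers(0, 50))
    for _ in range(n_dips):
        dur = int(rng.integers(1, 40))
        if cursor + dur >= n_samples - 2:
            break
        ratio = float(rng.uniform(0.05, 0.7))
        x[cursor : cursor + dur] = ratio * open_current
        dips.append((cursor, dur, ratio))
        cursor += dur + int(rng.integers(2, 60))
    return x, dips
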