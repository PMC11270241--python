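"""File formats of the pipeline stages.

The event TSV is the canonical inter-stage format (the detector's native
output): tab-separated, '.' decimal, UTF-8, one header line with columns
``channel  start_tps  duration_tps  min_ratio  max_ratio``; ratios are
written with 4 decimals.  Raw traces travel in an HDF5 container with one
dataset per channel and run metadata in root attributes.  Experiment
manifests are YAML.  All writers are deterministic: identical inputs give
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .events import DEFAULT_SAMPLING_PER_MS, EVENT_COLUMNS, RawTrace
from .synth import BIAS_VOLTAGE_MV

MANIFEST_REQUIRED = ("test_id", "sample", "experiments")
EXPERIMENT_REQUIRED = ("mirna_id", "rna_vol", "probe_vol", "probe_conc")


class SchemaError(ValueError):
    """A file does not conform to its documented dialect."""


# ---------------------------------------------------------------------------
# event tables


def write_event_tsv(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"event table lacks column(s): {', '.join(missing)}")
    out = table[EVENT_COLUMNS].copy()
    for col in ("min_ratio", "max_ratio"):
        out[col] = out[col].map(lambda v: f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_event_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {', '.join(missing)} in header line 1"
        )
    return df[EVENT_COLUMNS].astype(
        {"channel": int, "start_tps": int, "duration_tps": int,
         "min_ratio": float, "max_ratio": float}
    )


# ---------------------------------------------------------------------------
# trace containers


def write_trace_container(
    path: str | Path,
    traces: Sequence[RawTrace],
    seed: int,
    duration_min: float,
    voltage_mv: float = BIAS_VOLTAGE_MV,
) -> None:
    """Write per-channel traces to an HDF5 container.

    One float32 dataset per channel named ``channel_<id>``; run metadata
    (sampling rate, duration, bias voltage, seed) in root attributes.
    """
    with h5py.File(path, "w") as h5:
        h5.attrs["sampling_rate_per_ms"] = float(
            traces[0].sampling_per_ms if traces else DEFAULT_SAMPLING_PER_MS
        )
        h5.attrs["duration_min"] = float(duration_min)
        h5.attrs["voltage_mV"] = float(voltage_mv)
        h5.attrs["seed"] = int(seed)
        for tr in traces:
            h5.create_dataset(
                f"channel_{tr.channel_id:03d}",
                data=tr.samples.astype(np.float32),
                compression="gzip",
            )


def read_trace_container(path: str | Path) -> tuple[list[RawTrace], dict[str, Any]]:
    traces = []
    with h5py.File(path, "r") as h5:
        attrs = {k: (v.item() if hasattr(v, "item") else v) for k, v in h5.attrs.items()}
        for name in sorted(h5.keys()):
            ch = int(name.split("_")[-1])
            traces.append(
                RawTrace(
                    channel_id=ch,
                    samples=h5[name][()].astype(np.float64),
                    sampling_per_ms=float(attrs.get("sampling_rate_per_ms", 3.0)),
                )
            )
    return traces, attrs


# ---------------------------------------------------------------------------
# manifests and reports


def read_manifest(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError(f"{path}: manifest must be a mapping")
    for key in MANIFEST_REQUIRED:
        if key not in doc:
            raise SchemaError(f"{path}: manifest missing required field {key!r}")
    sample = doc["sample"]
    for key in ("id", "rna_conc"):
        if key not in sample:
            raise SchemaError(f"{path}: sample block missing field {key!r}")
    for i, exp in enumerate(doc["experiments"]):
        for key in EXPERIMENT_REQUIRED:
            if key not in exp:
                raise SchemaError(
                    f"{path}: experiment {i + 1} missing field {key!r}"
                )
        if "call" not in exp and "events" not in exp:
            raise SchemaError(
                f"{path}: experiment {i + 1} needs either a 'call' or an "
                "'events' list of three TSV paths"
            )
    return dict(doc)


def write_manifest(doc: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(doc), fh, sort_keys=False)


def write_call_report(rows: Iterable[Mapping], path: str | Path) -> None:
    """Call report TSV: one row per test with R values, totals and call."""
    df = pd.DataFrame(list(rows))
    cols = [
        "test_id", "r_control", "r_run1", "r_run2",
        "total_control", "total_run1", "total_run2", "call", "rationale",
    ]
    df = df[cols]
    for col in ("r_control", "r_run1", "r_run2"):
        df[col] = df[col].map(lambda v: f"{v:.2f}" if pd.notna(v) else "NA")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_call_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_results_csv(rows: Iterable[Mapping], path: str | Path) -> None:
    df = pd.DataFrame(list(rows))
    cols = [
        "sample", "miRNA", "copies_per_ul_rna", "normalized_copies",
        "HL", "half_range", "flags",
    ]
    df[cols].to_csv(path, index=False, lineterminator="\n")


def read_results_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
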