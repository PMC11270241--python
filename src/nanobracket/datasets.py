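"""Bundled reference datasets of the let-7b validation study.

Small, printed-size tables used throughout the package and its tests:

* the reference panel - miRNA copies per microlitre of total RNA isolated
  from the combined-healthy-serum reference (first lot, 16.0 ng/uL), which
  defines the HL unit;
* the let-7b titration experiments - every nanopore experiment of the
  validation campaign (healthy urine/serum plus pancreatic, prostate and
  breast cancer samples) with its loading metadata, its detection or
  silencing call and the published arithmetic columns for cross-checking;
* the cohort HL table - the per-sample, per-marker HL values behind the
  healthy/cancer group statistics (28 cancer-biomarker values, 16
  miR-15b values, 22 healthy non-miR-15b values);
* the zero-overlap design table rows used to exercise the accuracy/fold
  calculus;
* the manufactured probe registry with sequences, concentrations and
  average osmylation extents, plus the mature target miRNA sequences.
"""

from __future__ import annotations

import pandas as pd

from .probes import ProbeSpec
from .quantify import DEFAULT_PANEL, ReferencePanel

__all__ = [
    "reference_panel",
    "let7b_experiments",
    "printed_brackets",
    "cohort_hl",
    "overlap_design_rows",
    "probe_registry",
    "TARGET_SEQUENCES",
]


def reference_panel() -> ReferencePanel:
    """The HL-defining reference panel (healthy combined serum, 1st lot)."""
    return DEFAULT_PANEL


_EXPERIMENT_COLUMNS = [
    "sample_id", "biospecimen", "condition", "rna_conc", "rna_vol", "probe_vol",
    "call", "starred", "printed_probe_copies", "printed_normalized", "printed_hl",
]

# One row per nanopore experiment targeting let-7b.  rna_conc is the
# RNA content of the isolate actually mixed with the probe; the H2 urine
# isolate (82.3 ng/uL) was diluted 1:3, i.e. 27.43 ng/uL (the published
# table prints 27.4 but its arithmetic uses the 2-decimal value).
# Probe concentration is 30 fM throughout.  INCONCLUSIVE rows are the
# mixed-direction experiments; they contribute no bound.
_LET7B_EXPERIMENTS = [
    # sample, specimen, condition, conc, y, x, call, starred, P/y, norm, HL
    ("H1", "urine", "healthy", 18.8, 9.5, 6.0, "SILENCING", True, 11368, 9675, 0.80),
    ("H1", "urine", "healthy", 18.8, 6.3, 6.0, "DETECTION", True, 17143, 14590, 1.20),
    ("H2", "urine", "healthy", 27.43, 6.0, 6.0, "INCONCLUSIVE", False, 18000, 10499, 0.86),
    ("H2", "urine", "healthy", 27.43, 4.0, 6.0, "DETECTION", True, 27000, 15749, 1.30),
    ("H2", "urine", "healthy", 27.43, 4.0, 6.0, "DETECTION", True, 27000, 15749, 1.30),
    ("H2", "urine", "healthy", 27.43, 8.5, 6.0, "SILENCING", True, 12706, 7411, 0.61),
    ("H6914-4th", "serum", "healthy", 14.3, 10.5, 5.0, "DETECTION", True, 8571, 9590, 0.79),
    ("H6914-4th", "serum", "healthy", 14.3, 6.8, 5.0, "DETECTION", False, 13235, 14809, 1.22),
    ("H6914-4th", "serum", "healthy", 14.3, 13.0, 5.0, "SILENCING", True, 6923, 7746, 0.64),
    ("SR16-690", "serum", "pancreatic", 16.4, 9.0, 5.0, "SILENCING", True, 10000, 9756, 0.80),
    ("SR16-690", "serum", "pancreatic", 16.4, 6.0, 5.0, "DETECTION", True, 15000, 14634, 1.20),
    ("SR16-690", "serum", "pancreatic", 14.3, 6.5, 5.0, "DETECTION", False, 13846, 15492, 1.28),
    ("SR16-690", "serum", "pancreatic", 14.3, 13.0, 5.0, "SILENCING", False, 6923, 7746, 0.64),
    ("SR17-248", "serum", "pancreatic", 21.0, 4.5, 5.0, "DETECTION", False, 20000, 15238, 1.25),
    ("SR17-248", "serum", "pancreatic", 21.0, 7.5, 5.0, "DETECTION", True, 12000, 9143, 0.75),
    ("SR17-248", "serum", "pancreatic", 21.0, 9.5, 5.0, "SILENCING", True, 9474, 7218, 0.59),
    ("SR23-6022", "urine", "prostate", 14.5, 4.0, 5.0, "DETECTION", True, 22500, 24828, 2.04),
    ("SR23-6022", "urine", "prostate", 14.5, 5.0, 4.0, "SILENCING", False, 14400, 15890, 1.31),
    ("SR23-6022", "urine", "prostate", 14.5, 8.0, 4.0, "SILENCING", False, 9000, 9931, 0.82),
    ("SR23-6022", "urine", "prostate", 14.5, 4.0, 4.0, "SILENCING", True, 18000, 19862, 1.63),
    ("SR23-6022", "urine", "prostate", 14.5, 5.3, 5.0, "INCONCLUSIVE", False, 16981, 18738, 1.54),
    ("SR23-6028", "urine", "prostate", 12.4, 10.0, 4.0, "SILENCING", False, 7200, 9290, 0.76),
    ("SR23-6028", "urine", "prostate", 12.4, 6.0, 4.0, "SILENCING", True, 12000, 15484, 1.27),
    ("SR23-6028", "urine", "prostate", 12.4, 4.7, 4.0, "DETECTION", True, 15319, 19767, 1.63),
    ("SR23-6016", "urine", "breast", 43.7, 4.0, 6.0, "SILENCING", False, 27000, 9886, 0.81),
    ("SR23-6016", "urine", "breast", 43.7, 2.7, 6.0, "INCONCLUSIVE", False, 40000, 14645, 1.21),
    ("SR23-6016", "urine", "breast", 21.8, 4.0, 7.5, "DETECTION", True, 33750, 24771, 2.04),
    ("SR23-6016", "urine", "breast", 21.8, 4.0, 6.0, "SILENCING", True, 27000, 19817, 1.63),
    ("SR23-6016", "urine", "breast", 21.8, 5.5, 7.5, "SILENCING", False, 24545, 18015, 1.48),
    ("101499", "serum", "breast", 17.1, 5.5, 6.0, "SILENCING", True, 19636, 18373, 1.51),
    ("101499", "serum", "breast", 17.1, 4.0, 6.0, "DETECTION", True, 27000, 25263, 2.08),
]

#: published per-sample bracket (HL midpoint, half-range); ``clean`` marks
#: the entries that equal the midpoint of their starred bounds under
#: half-up rounding (the other three are reported as computed and flagged).
_PRINTED_BRACKETS = {
    "H1": (1.00, 0.20, True),
    "H2": (1.07, 0.37, False),
    "H6914-4th": (0.72, 0.08, True),
    "SR16-690": (1.00, 0.20, True),
    "SR17-248": (0.67, 0.08, True),
    "SR23-6022": (1.82, 0.20, False),
    "SR23-6028": (1.45, 0.18, True),
    "SR23-6016": (1.77, 0.28, False),
    "101499": (1.80, 0.28, True),
}


def let7b_experiments() -> pd.DataFrame:
    """Experiment table of the let-7b validation campaign."""
    df = pd.DataFrame(_LET7B_EXPERIMENTS, columns=_EXPERIMENT_COLUMNS)
    df["mirna_id"] = "let-7b"
    df["probe_conc"] = 30.0
    return df


def printed_brackets() -> dict[str, tuple[float, float, bool]]:
    """Published per-sample HL bracket (midpoint, half-range, clean)."""
    return dict(_PRINTED_BRACKETS)


# ---------------------------------------------------------------------------
# cohort HL table

_CANCER_ROWS = [
    # sample, indication, specimen, marker, hl
    ("CAN7", "breast", "serum", "miR-15b", 0.79),
    ("CAN7", "breast", "serum", "miR-21", 1.60),
    ("CAN9", "breast", "serum", "miR-15b", 0.89),
    ("CAN9", "breast", "serum", "miR-21", 1.79),
    ("CAN9", "breast", "serum", "miR-141", 1.80),
    ("CAN4", "prostate", "serum", "miR-15b", 0.88),
    ("CAN4", "prostate", "serum", "miR-21", 1.79),
    ("CAN4", "prostate", "serum", "miR-141", 1.81),
    ("CAN6", "prostate", "serum", "miR-15b", 0.90),
    ("CAN6", "prostate", "serum", "miR-21", 1.87),
    ("CAN6", "prostate", "serum", "miR-141", 1.84),
    ("SR16-690", "pancreatic", "serum", "miR-15b", 1.01),
    ("SR16-690", "pancreatic", "serum", "miR-21", 1.63),
    ("SR16-690", "pancreatic", "serum", "miR-21", 1.88),
    ("SR17-248", "pancreatic", "serum", "miR-15b", 1.00),
    ("SR17-248", "pancreatic", "serum", "miR-141", 1.88),
    ("SR23-6016", "breast", "urine", "miR-15b", 1.34),
    ("SR23-6016", "breast", "urine", "miR-21", 1.75),
    ("SR23-6016", "breast", "urine", "miR-141", 1.76),
    ("SR23-6016", "breast", "urine", "miR-375+miR-141", 1.69),
    ("SR23-6017", "breast", "urine", "miR-15b", 1.12),
    ("SR23-6017", "breast", "urine", "miR-21", 2.13),
    ("SR23-6017", "breast", "urine", "miR-141", 1.73),
    ("SR23-6017", "breast", "urine", "miR-375+miR-141", 1.66),
    ("SR23-6017", "breast", "urine", "miR-375", 2.20),
    ("SR23-6018", "breast", "urine", "miR-141", 1.72),
    ("SR23-6018", "breast", "urine", "miR-375", 2.25),
    ("SR23-6022", "prostate", "urine", "miR-375", 1.81),
    ("SR23-6022", "prostate", "urine", "miR-141", 1.80),
    ("SR23-6028", "prostate", "urine", "miR-375", 1.81),
    ("SR23-6028", "prostate", "urine", "miR-141", 1.82),
    ("SR23-6023", "prostate", "urine", "miR-375", 1.82),
    ("SR23-6023", "prostate", "urine", "miR-141", 1.63),
    ("SR23-6023", "prostate", "urine", "miR-375", 2.00),
    ("SR23-6033", "pancreatic", "urine", "miR-375", 1.82),
    ("SR23-6033", "pancreatic", "urine", "miR-141", 1.82),
]

_HEALTHY_ROWS = [
    ("HU01", "healthy", "urine", "miR-15b", 0.97),
    ("HU01", "healthy", "urine", "miR-375", 1.04),
    ("HU02", "healthy", "urine", "miR-375", 0.97),
    ("HU03", "healthy", "urine", "miR-15b", 1.00),
    ("H2", "healthy", "urine", "miR-15b", 0.84),
    ("H2", "healthy", "urine", "miR-21", 0.90),
    ("H2", "healthy", "urine", "miR-141", 0.83),
    ("H2", "healthy", "urine", "miR-375+miR-141", 0.84),
    ("H2", "healthy", "urine", "miR-21", 1.19),
    ("HU04", "healthy", "urine", "miR-21", 1.01),
    ("HU05", "healthy", "urine", "miR-375+miR-141", 0.89),
    ("HU06", "healthy", "urine", "miR-15b", 1.00),
    ("HU07", "healthy", "urine", "miR-15b", 0.98),
    ("HU07", "healthy", "urine", "miR-375+miR-141", 0.80),
    ("HU08", "healthy", "urine", "miR-15b", 0.84),
    ("HU08", "healthy", "urine", "miR-141", 1.02),
    ("HU09", "healthy", "urine", "miR-375+miR-141", 0.96),
    ("HU10", "healthy", "urine", "miR-21", 1.03),
    ("HU10", "healthy", "urine", "miR-375+miR-141", 0.87),
    ("HU11", "healthy", "urine", "miR-375+miR-141", 0.92),
    ("HU12", "healthy", "urine", "miR-21", 1.17),
    ("HU12", "healthy", "urine", "miR-375+miR-141", 1.16),
    ("HU13", "healthy", "urine", "miR-15b", 0.79),
    ("HU13", "healthy", "urine", "miR-21", 1.17),
    ("HU13", "healthy", "urine", "miR-375+miR-141", 1.06),
    ("HU14", "healthy", "urine", "miR-15b", 1.02),
    ("HU14", "healthy", "urine", "miR-21", 1.42),
    ("HU14", "healthy", "urine", "miR-375+miR-141", 1.30),
    ("HU15", "healthy", "urine", "miR-21", 1.30),
    ("HU15", "healthy", "urine", "miR-375+miR-141", 1.31),
]

#: markers whose cancer-sample values constitute the validated-biomarker group
BIOMARKER_LABELS = ("miR-21", "miR-375", "miR-141", "miR-375+miR-141")


def cohort_hl() -> pd.DataFrame:
    """Tidy per-sample, per-marker HL table of the validation cohort."""
    df = pd.DataFrame(
        _CANCER_ROWS + _HEALTHY_ROWS,
        columns=["sample_id", "indication", "biospecimen", "marker", "hl"],
    )
    df["condition"] = (df["indication"] != "healthy").map(
        {True: "cancer", False: "healthy"}
    )
    return df


# ---------------------------------------------------------------------------
# zero-overlap design table

_OVERLAP_ROWS_OVER = [
    # accuracy, control lo, control hi, disease lo, disease hi, avg, fold
    (0.15, 0.85, 1.15, 1.15, 1.55, 1.35, 1.35),
    (0.20, 0.80, 1.20, 1.20, 1.80, 1.50, 1.50),
    (0.30, 0.70, 1.30, 1.30, 2.40, 1.85, 1.85),
    (0.40, 0.60, 1.40, 1.40, 3.20, 2.30, 2.30),
    (0.50, 0.50, 1.50, 1.50, 4.50, 3.00, 3.00),
    (0.75, 0.25, 1.75, 1.75, 12.25, 7.00, 7.00),
]

_OVERLAP_ROWS_UNDER = [
    (0.15, 0.85, 1.15, 0.63, 0.85, 0.74, 1.35),
    (0.20, 0.80, 1.20, 0.54, 0.80, 0.67, 1.50),
    (0.30, 0.70, 1.30, 0.40, 0.70, 0.55, 1.80),
    (0.40, 0.60, 1.40, 0.30, 0.60, 0.45, 2.20),
    (0.50, 0.50, 1.50, 0.18, 0.50, 0.34, 2.90),
    (0.75, 0.25, 1.75, 0.036, 0.25, 0.14, 7.10),
]


def overlap_design_rows(direction: str = "overexpressed") -> pd.DataFrame:
    """Published zero-overlap rows (accuracy vs ranges, average and fold)."""
    rows = _OVERLAP_ROWS_OVER if direction == "overexpressed" else _OVERLAP_ROWS_UNDER
    return pd.DataFrame(
        rows,
        columns=[
            "accuracy", "control_lo", "control_hi",
            "disease_lo", "disease_hi", "disease_avg", "min_fold",
        ],
    )


# ---------------------------------------------------------------------------
# probes

_PROBES = [
    # the miR-375 probe carries its extra tag site as a C between tail and
    # flank, so its token structure deviates from the canonical layout
    ("375T5", "(A)_5_dUCACGCGAGCCGAACGAACAAAC(T)_5_C(A)_5_", 42.0, 5.1, "miR-375"),
    ("m21T5", "(A)_5_mUCAACAmUCAGmUCmUGAmUAAGCmUA(T)_5_C(A)_6_", 27.1, 4.4, "miR-21"),
    ("m141T5", "(A)_4_CCAmUC(mU)_3_ACCAGACAGmUG(mU)_2_A(T)_5_(A)_5_", 33.5, 4.7, "miR-141"),
    ("15bT5", "(A)_6_dUGdUAAACCAdUGAdUGdUGCdUGCdUA(T)_5_(A)_6_", 35.0, 5.9, "miR-15b"),
    ("let7bT5", "(A)_6_CCACACAACCmUACmUACCmUCA(T)5(A)_5_", 30.0, 5.5, "let-7b"),
]

#: mature target sequences (miRBase mature strands)
TARGET_SEQUENCES = {
    "let-7b": "UGAGGUAGUAGGUUGUGUGGUU",
    "miR-15b": "UAGCAGCACAUCAUGGUUUACA",
    "miR-16": "UAGCAGCACGUAAAUAUUGGCG",
    "miR-21": "UAGCUUAUCAGACUGAUGUUGA",
    "miR-375": "UUUGUUCGUUCGGCUCGCGUGA",
    "miR-141": "UAACACUGUCUGGUAAAGAUGG",
}


def probe_registry() -> dict[str, ProbeSpec]:
    """Manufactured probes keyed by probe id."""
    return {
        pid: ProbeSpec(probe_id=pid, sequence=seq, conc_fm=conc, n_osbp=tags)
        for pid, seq, conc, tags, _target in _PROBES
    }


def probe_targets() -> dict[str, str]:
    """Probe id -> targeted miRNA id."""
    return {pid: target for pid, _seq, _c, _t, target in _PROBES}
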