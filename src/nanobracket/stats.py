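"""Zero-overlap calculus, cohort statistics and threshold classification.

The zero-overlap calculus links measurement accuracy to the smallest
disease/control fold change that keeps the two groups' data disjoint.
With fractional accuracy ``a``, a healthy marker normalised to 1.0 spans
``[1-a, 1+a]``.  For an overexpressed marker, zero overlap requires its
lower limit at ``1+a``; the same accuracy around the disease average ``m``
means ``m(1-a) = 1+a``, so ``m = (1+a)/(1-a)`` and the disease range is
``[(1+a), (1+a)^2/(1-a)]``.  Underexpression mirrors this below 1.  At
a = 0.20 the minimal fold is exactly 1.5.

Cohort statistics summarise HL tables (mean and RSD with the n-1 sample
standard deviation), classify samples against the 1.5 HL threshold
(optionally requiring elevation in 2 of 3 biomarkers), tabulate 2x2
screening metrics, and compare groups with the pooled two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .quantify import COPIES_PER_FM_UL, DEFAULT_PANEL, ReferencePanel

OVEREXPRESSED = "overexpressed"
UNDEREXPRESSED = "underexpressed"


@dataclass(frozen=True)
class AccuracySpec:
    accuracy: float  # fractional, e.g. 0.20
    direction: Literal["overexpressed", "underexpressed"] = OVEREXPRESSED

    def __post_init__(self) -> None:
        if not (0 < self.accuracy < 1):
            raise ValueError("accuracy must be in (0, 1)")
        if self.direction not in (OVEREXPRESSED, UNDEREXPRESSED):
            raise ValueError("direction must be 'overexpressed' or 'underexpressed'")


@dataclass
class OverlapDesign:
    control_range: tuple[float, float]
    disease_range: tuple[float, float]
    disease_average: float
    min_fold: float


def zero_overlap_design(spec: AccuracySpec) -> OverlapDesign:
    """Disease range/average and minimal fold change for zero data overlap."""
    a = spec.accuracy
    control = (1.0 - a, 1.0 + a)
    if spec.direction == OVEREXPRESSED:
        avg = (1.0 + a) / (1.0 - a)
        disease = (1.0 + a, (1.0 + a) ** 2 / (1.0 - a))
        fold = avg
    else:
        avg = (1.0 - a) / (1.0 + a)
        disease = ((1.0 - a) ** 2 / (1.0 + a), 1.0 - a)
        fold = (1.0 + a) / (1.0 - a)
    return OverlapDesign(
        control_range=control, disease_range=disease, disease_average=avg, min_fold=fold
    )


@dataclass
class GroupSummary:
    n: int
    mean: float
    rsd: float  # sample sd (n-1) / mean


def summarize_group(values: Sequence[float]) -> GroupSummary:
    """Mean and relative standard deviation of a group of HL values."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to summarise a group")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return GroupSummary(n=int(x.size), mean=mean, rsd=sd / mean)


@dataclass(frozen=True)
class ClassifierConfig:
    """Threshold rule of the screening test.

    A marker is elevated when its HL exceeds ``hl_threshold``; a sample is
    called positive when at least ``rule`` of the tested biomarkers are
    elevated (2 of 3 in the multiplexed screening design).
    """

    hl_threshold: float = 1.5
    markers: tuple[str, ...] = ("miR-21", "miR-375", "miR-141")
    rule: int = 2

    def __post_init__(self) -> None:
        if self.hl_threshold <= 1:
            raise ValueError("hl_threshold must exceed 1")
        if self.rule < 1:
            raise ValueError("rule must be >= 1")


def classify(
    values: Mapping[str, float], config: ClassifierConfig | None = None
) -> tuple[dict[str, bool], bool]:
    """Per-marker elevated flags and the overall call for one sample."""
    config = config or ClassifierConfig()
    if not values:
        raise ValueError("empty marker set")
    if any(v <= 0 for v in values.values()):
        raise ValueError("HL values must be positive")
    flags = {m: v > config.hl_threshold for m, v in values.items()}
    overall = sum(flags.values()) >= config.rule
    return flags, overall


def confusion_metrics(
    truth: Sequence[bool], calls: Sequence[bool]
) -> dict[str, Optional[float]]:
    """Sensitivity, specificity, PPV and NPV of binary calls vs truth.

    Ratios with an empty denominator are reported as ``None`` (not
    applicable), never as zero.
    """
    if len(truth) != len(calls):
        raise ValueError("truth and calls must have the same length")
    t = np.asarray(truth, dtype=bool)
    c = np.asarray(calls, dtype=bool)
    tp = int(np.sum(t & c))
    tn = int(np.sum(~t & ~c))
    fp = int(np.sum(~t & c))
    fn = int(np.sum(t & ~c))

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den else None

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def group_ttest(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided p of the pooled (equal-variance) two-sample t-test."""
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = ((a.size - 1) * np.var(a, ddof=1) + (b.size - 1) * np.var(b, ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.pvalue)


def plan_threshold_test(
    panel: ReferencePanel = DEFAULT_PANEL,
    sample_rna_conc: float = 16.0,
    mirna_id: str = "let-7b",
    threshold: float = 1.5,
    probe_conc: float = 30.0,
    volume_bounds: tuple[float, float] = (2.0, 15.0),
    volume_step: float = 0.1,
    tolerance: float = 0.01,
) -> tuple[float, float]:
    """Choose probe/RNA volumes that put P/y at a target HL threshold.

    Returns ``(probe_vol, rna_vol)`` in microlitres such that the loaded
    P/y, normalised to the reference RNA content, equals ``threshold``
    times the reference copy number within ``tolerance``; a sample too
    concentrated (or too dilute) to hit the target inside the volume
    bounds raises with a suggested dilution.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if mirna_id not in panel.ref_copies:
        raise KeyError(f"unknown miRNA: {mirna_id!r}")
    if sample_rna_conc <= 0 or probe_conc <= 0:
        raise ValueError("concentrations must be positive")
    # normalized P/y = (P/y) * ref_conc / conc  ==  threshold * ref_copies
    target_py = threshold * panel.ref_copies[mirna_id] * sample_rna_conc / panel.ref_rna_conc
    ratio = target_py / (COPIES_PER_FM_UL * probe_conc)  # required x / y
    lo, hi = volume_bounds
    best: Optional[tuple[float, float, float]] = None
    for y in np.arange(lo, hi + 1e-9, volume_step):
        x = round(ratio * y, 2)
        if x < lo or x > hi:
            continue
        achieved = COPIES_PER_FM_UL * x * probe_conc / y
        err = abs(achieved / target_py - 1.0)
        if err <= tolerance and (best is None or err < best[2]):
            best = (float(round(x, 2)), float(round(y, 1)), err)
    if best is None:
        if ratio > hi / lo:
            dilution = ratio * lo / hi
            raise ValueError(
                f"target P/y = {target_py:.0f} copies/uL is infeasible within "
                f"volumes {volume_bounds}; dilute the RNA isolate by at least "
                f"{dilution:.1f}-fold"
            )
        raise ValueError(
            f"target P/y = {target_py:.0f} copies/uL is infeasible within "
            f"volumes {volume_bounds}; use a more concentrated probe"
        )
    return best[0], best[1]
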