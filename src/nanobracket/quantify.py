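"""Copy-number bounds, bracketed estimates and healthy-level normalisation.

The quantification arithmetic of the platform.  An experiment loads
``P = 600 * probe_vol(uL) * probe_conc(fM)`` probe copies against a
``y``-microlitre aliquot of the RNA isolate.  A detection outcome means
free probe remained, so the target is below ``P/y`` copies per microlitre
of RNA (an upper bound); a silencing outcome means the probe was fully
hybridised, so the target exceeds ``P/y`` (a lower bound).  The copy
number is the midpoint of the tightest consistent (silencing, detection)
pair; half the bound spread is the protocol accuracy, and bounds spaced by
a factor 1.5 give exactly +/-20% by the identity ``(r-1)/(r+1)``.

Copy numbers from different isolates are made comparable by scaling to the
reference RNA content (16 ng/uL, the healthy-serum reference isolate) and
expressed as multiples of the reference miRNA's copy number (HL, healthy
level; 1.0 is the healthy reference).

The copies-per-(fM*uL) constant is fixed at 600 - the platform's printed
bookkeeping convention - with the exact Avogadro-derived 602.214 available
via ``exact=True``.  Copies round half-up to integers; HL half-up to two
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional, Sequence

from .util import round_copies, round_half_up

COPIES_PER_FM_UL = 600.0
COPIES_PER_FM_UL_EXACT = 602.214

#: a bound pair looser than this relative accuracy misses protocol accuracy
PROTOCOL_ACCURACY_LIMIT = 0.25

DETECTION = "DETECTION"
SILENCING = "SILENCING"
INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class ReferencePanel:
    """Reference RNA content and per-miRNA copy numbers defining HL units.

    Defaults are the combined-healthy-serum reference isolate (16 ng/uL;
    1 uL of its total RNA is equivalent to 2 uL of serum).
    """

    ref_rna_conc: float = 16.0
    ref_copies: Mapping[str, float] = field(
        default_factory=lambda: {
            "miR-16": 210_250,
            "miR-15b": 17_710,
            "let-7b": 12_150,
            "miR-21": 10_494,
            "miR-375": 9_240,
            "miR-141": 6_096,
        }
    )
    serum_ul_per_rna_ul: float = 2.0

    def __post_init__(self) -> None:
        if self.ref_rna_conc <= 0 or self.serum_ul_per_rna_ul <= 0:
            raise ValueError("reference constants must be positive")
        if any(v <= 0 for v in self.ref_copies.values()):
            raise ValueError("reference copy numbers must be positive")


DEFAULT_PANEL = ReferencePanel()


@dataclass(frozen=True)
class ExperimentRecord:
    """One nanopore experiment: loading metadata plus its DET/SIL call."""

    sample_id: str
    mirna_id: str
    rna_conc: float  # ng/uL
    rna_vol: float  # uL (y)
    probe_vol: float  # uL (x)
    probe_conc: float  # fM
    call: str = INCONCLUSIVE

    def __post_init__(self) -> None:
        if min(self.rna_conc, self.rna_vol, self.probe_vol, self.probe_conc) <= 0:
            raise ValueError("volumes and concentrations must be positive")


@dataclass(frozen=True)
class BoundEstimate:
    """A one-sided copy-number bound derived from a single experiment."""

    value: float
    direction: Literal["upper", "lower"]  # upper from DETECTION, lower from SILENCING
    source_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("bound must be positive")
        if self.direction not in ("upper", "lower"):
            raise ValueError("direction must be 'upper' or 'lower'")


@dataclass
class BracketEstimate:
    """Midpoint +/- half-range of the tightest consistent bound pair."""

    lower: float
    upper: float
    midpoint: float
    half_range: float
    relative_accuracy: float
    flags: list[str] = field(default_factory=list)


class InconsistentBoundsError(ValueError):
    """Raised when some detection upper bound sits at or below a silencing
    lower bound, which cannot happen for a fixed true copy number."""


def probe_copies_per_ul_rna(
    probe_vol: float,
    probe_conc: float,
    rna_vol: float,
    exact: bool = False,
    rounded: bool = True,
) -> float:
    """P/y: probe copies loaded per microlitre of the RNA aliquot.

    ``rounded=False`` returns the raw quotient; table arithmetic rounds
    half-up to integer copies.
    """
    if probe_vol <= 0 or probe_conc <= 0:
        raise ValueError("probe volume and concentration must be positive")
    if rna_vol <= 0:
        raise ValueError("rna_vol must be positive")
    k = COPIES_PER_FM_UL_EXACT if exact else COPIES_PER_FM_UL
    value = k * probe_vol * probe_conc / rna_vol
    return round_copies(value) if rounded else value


def normalize_to_reference(
    copies: float,
    rna_conc: float,
    panel: ReferencePanel = DEFAULT_PANEL,
    rounded: bool = True,
) -> float:
    """Scale a copy number to the reference RNA content.

    Copy numbers are directly proportional to the RNA content of the
    isolate, so ``copies * ref_conc / rna_conc`` expresses every sample at
    the same 16 ng/uL reference content.
    """
    if rna_conc <= 0:
        raise ValueError("rna_conc must be positive")
    value = copies * panel.ref_rna_conc / rna_conc
    return round_copies(value) if rounded else value


def to_hl(
    copies_normalized: float, mirna_id: str, panel: ReferencePanel = DEFAULT_PANEL
) -> float:
    """Express a content-normalised copy number in healthy-level units.

    HL = copies / reference copies for that miRNA, reported to 2 decimals.
    """
    if mirna_id not in panel.ref_copies:
        raise KeyError(f"unknown miRNA: {mirna_id!r}")
    return round_half_up(copies_normalized / panel.ref_copies[mirna_id], 2)


def serum_equivalent(
    copies_per_ul_rna: float, panel: ReferencePanel = DEFAULT_PANEL
) -> float:
    """Copies per microlitre of serum (1 uL RNA isolate = 2 uL serum)."""
    if copies_per_ul_rna < 0:
        raise ValueError("copies must be non-negative")
    return copies_per_ul_rna / panel.serum_ul_per_rna_ul


def bracket(bounds: Sequence[BoundEstimate]) -> BracketEstimate:
    """Bracket a copy number from a set of one-sided bounds.

    Selects the tightest consistent pair: the largest lower (silencing)
    bound and the smallest upper (detection) bound above it.  Any upper
    bound at or below the chosen lower bound contradicts a fixed true copy
    number and raises :class:`InconsistentBoundsError`.
    """
    lowers = [b for b in bounds if b.direction == "lower"]
    uppers = [b for b in bounds if b.direction == "upper"]
    if not lowers or not uppers:
        raise ValueError(
            "bracketing needs at least one silencing (lower) and one "
            "detection (upper) bound"
        )
    lo = max(lowers, key=lambda b: b.value)
    bad = [u for u in uppers if u.value <= lo.value]
    if bad:
        ids = ", ".join(str(u.source_id or u.value) for u in bad)
        raise InconsistentBoundsError(
            f"detection upper bound(s) at or below the silencing lower bound "
            f"{lo.value:g} ({lo.source_id or 'unnamed'}): {ids}"
        )
    up = min(uppers, key=lambda b: b.value)
    midpoint = (lo.value + up.value) / 2.0
    half = (up.value - lo.value) / 2.0
    rel = half / midpoint
    flags = []
    if rel > PROTOCOL_ACCURACY_LIMIT:
        flags.append(
            f"relative accuracy {rel:.2f} exceeds the protocol limit "
            f"{PROTOCOL_ACCURACY_LIMIT:.2f}"
        )
    return BracketEstimate(
        lower=lo.value,
        upper=up.value,
        midpoint=midpoint,
        half_range=half,
        relative_accuracy=rel,
        flags=flags,
    )


def quantify_experiment(
    record: ExperimentRecord, panel: ReferencePanel = DEFAULT_PANEL
) -> dict:
    """Per-experiment table arithmetic: P/y, normalised copies, HL, bound.

    The normalised column is computed from the unrounded P/y (rounding a
    quotient twice can shift the last integer digit) and then rounded.
    """
    raw = probe_copies_per_ul_rna(
        record.probe_vol, record.probe_conc, record.rna_vol, rounded=False
    )
    probe_copies = round_copies(raw)
    normalized = int(normalize_to_reference(raw, record.rna_conc, panel))
    hl = to_hl(normalized, record.mirna_id, panel)
    out = {
        "sample_id": record.sample_id,
        "mirna_id": record.mirna_id,
        "probe_copies_per_ul_rna": probe_copies,
        "normalized_copies": normalized,
        "hl": hl,
        "call": record.call,
    }
    if record.call == DETECTION:
        out["bound"] = BoundEstimate(hl, "upper", source_id=record.sample_id)
    elif record.call == SILENCING:
        out["bound"] = BoundEstimate(hl, "lower", source_id=record.sample_id)
    else:
        out["bound"] = None
    return out


def bounds_from_records(
    records: Iterable[ExperimentRecord], panel: ReferencePanel = DEFAULT_PANEL
) -> list[BoundEstimate]:
    """HL-unit bounds of every called (DET/SIL) experiment."""
    out = []
    for rec in records:
        q = quantify_experiment(rec, panel)
        if q["bound"] is not None:
            out.append(q["bound"])
    return out
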