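"""Probe bookkeeping: osmylation extent, aliquot copies and design checks.

Probes are DNA oligos complementary to a target miRNA, extended at one end
with a tail of 4-5 adjacent thymidines and flanked with short adenosine
runs that steer the molecule into the pore.  The tail thymidines carry the
osmium tetroxide/bipyridine (OsBp) tags that slow translocation enough for
the detector; thymidines inside the complementary core are substituted
with U, dU or 2'-OMe-U, whose osmylation kinetics are much slower, so the
core stays essentially untagged and hybridisation-competent.

The average number of tags per probe is read off the UV absorbance ratio
``R(312/272) = 2 * n_OsBp / total_nt`` - the osmate ester absorbs at
312 nm - and may be fractional (a population average).

Sequences are written with inline tokens: plain bases ``A C G T U``, the
modified bases ``mU`` (2'-OMe-U) and ``dU`` (2'-deoxy-U), and run-length
groups like ``(A)5`` or ``(A)_5_``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .quantify import COPIES_PER_FM_UL, COPIES_PER_FM_UL_EXACT

_TOKEN_RE = re.compile(
    r"\(([A-Za-z]{1,2})\)_?(\d+)_?|(mU|dU)(?:_?(\d+)_)?|([ACGTU])(?:_?(\d+)_)?"
)

#: tokens treated as uridine for pairing purposes
_U_LIKE = {"U", "mU", "dU", "T"}

_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A", "T": "A"}


def parse_sequence(sequence: str) -> list[str]:
    """Expand a probe sequence string into a token list.

    ``"(A)_2_mUC(T)3"`` -> ``['A', 'A', 'mU', 'C', 'T', 'T', 'T']``.
    Unknown characters raise ``ValueError``.
    """
    tokens: list[str] = []
    pos = 0
    s = sequence.strip().replace(" ", "")
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            raise ValueError(f"cannot parse sequence at {s[pos:pos + 8]!r}")
        if m.group(1) is not None:
            unit, count = m.group(1), int(m.group(2))
            if unit not in {"A", "C", "G", "T", "U", "mU", "dU"}:
                raise ValueError(f"unknown base group {unit!r}")
            tokens.extend([unit] * count)
        elif m.group(3) is not None:
            tokens.extend([m.group(3)] * int(m.group(4) or 1))
        else:
            tokens.extend([m.group(5)] * int(m.group(6) or 1))
        pos = m.end()
    return tokens


def base_class(token: str) -> str:
    """Collapse modified-base tokens to their pairing base (mU/dU/T -> U)."""
    return "U" if token in _U_LIKE else token


def reverse_complement(tokens: Sequence[str]) -> str:
    """RNA-alphabet reverse complement of a token list (U/T equivalent)."""
    return "".join(_COMPLEMENT[base_class(t)] for t in reversed(tokens))


def count_pyrimidines(tokens: Sequence[str]) -> int:
    return sum(1 for t in tokens if base_class(t) in {"U", "C"})


@dataclass
class ProbeSpec:
    """A characterised probe: sequence, concentration, average tag count."""

    probe_id: str
    sequence: str
    conc_fm: float
    n_osbp: float
    tokens: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.tokens = parse_sequence(self.sequence)
        if self.conc_fm <= 0:
            raise ValueError("conc_fm must be positive")
        if not (0 <= self.n_osbp <= count_pyrimidines(self.tokens)):
            raise ValueError("n_osbp must lie between 0 and the pyrimidine count")

    @property
    def total_nt(self) -> int:
        return len(self.tokens)

    @property
    def absorbance_ratio(self) -> float:
        return expected_absorbance_ratio(self.n_osbp, self.total_nt)


def osmylation_extent(absorbance_ratio: float, total_nt: int) -> float:
    """Average osmium tags per molecule from the 312/272 absorbance ratio.

    Inverts ``R(312/272) = 2 * n_OsBp / total_nt``; the result is a
    population average and may be fractional.
    """
    if absorbance_ratio < 0:
        raise ValueError("absorbance ratio must be non-negative")
    if total_nt <= 0:
        raise ValueError("total_nt must be positive")
    return absorbance_ratio * total_nt / 2.0


def expected_absorbance_ratio(n_osbp: float, total_nt: int) -> float:
    """Expected R(312/272) of a probe with ``n_osbp`` average tags."""
    if total_nt <= 0:
        raise ValueError("total_nt must be positive")
    if n_osbp < 0:
        raise ValueError("n_osbp must be non-negative")
    return 2.0 * n_osbp / total_nt


def copies_in_aliquot(vol: float, conc_fm: float, exact: bool = False) -> float:
    """Probe molecules in an aliquot: ``600 * uL * fM`` (exact: 602.214)."""
    if vol < 0 or conc_fm < 0:
        raise ValueError("volume and concentration must be non-negative")
    k = COPIES_PER_FM_UL_EXACT if exact else COPIES_PER_FM_UL
    return k * vol * conc_fm


@dataclass
class DesignReport:
    """Pass/fail per probe-design rule, with diagnostic detail."""

    core: str  # core tokens joined, 5'->3'
    tail_length: int
    flank_lengths: tuple[int, int]
    core_complementary: bool
    core_mismatches: int
    tail_ok: bool
    flanks_ok: bool
    core_t_substituted: bool

    @property
    def all_ok(self) -> bool:
        return (
            self.core_complementary
            and self.tail_ok
            and self.flanks_ok
            and self.core_t_substituted
        )


def _split_structure(tokens: list[str]) -> tuple[list[str], int, tuple[int, int]]:
    """Split flank(A) | core | tail(T) | flank(A).

    The osmylated tail is the longest run of plain T in the A-stripped
    segment; the core is the longer remainder beside it.  A stray tagged
    residue between tail and flank (some probes carry an extra C there)
    is tolerated and excluded from the core.
    """
    left = 0
    while left < len(tokens) and tokens[left] == "A":
        left += 1
    right = 0
    while right < len(tokens) - left and tokens[-(right + 1)] == "A":
        right += 1
    inner = tokens[left : len(tokens) - right or None]
    best_start, best_len = 0, 0
    i = 0
    while i < len(inner):
        if inner[i] == "T":
            j = i
            while j < len(inner) and inner[j] == "T":
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    if best_len == 0:
        return inner, 0, (left, right)
    before = inner[:best_start]
    after = inner[best_start + best_len :]
    core = before if len(before) >= len(after) else after
    return core, best_len, (left, right)


def check_probe_design(
    probe: ProbeSpec,
    target_sequence: str,
    max_flank: int = 6,
    tail_range: tuple[int, int] = (4, 5),
) -> DesignReport:
    """Check a probe against its target miRNA sequence.

    Rules: (i) the core is the reverse complement of a contiguous stretch
    of the target (U, dU and 2'-OMe-U all pair with A); (ii) an osmylated
    tail of 4-5 adjacent Ts exists; (iii) adenosine flanks do not exceed
    ``max_flank`` per end (the manufactured probes run to 6); (iv) no
    unsubstituted T remains in the core.
    """
    target = parse_sequence(target_sequence)
    target_str = "".join(base_class(t) for t in target)
    core, tail_len, flanks = _split_structure(list(probe.tokens))
    rc = reverse_complement(core)
    complementary = rc in target_str if core else False
    mismatches = _best_mismatches(rc, target_str)
    return DesignReport(
        core="".join(core),
        tail_length=tail_len,
        flank_lengths=flanks,
        core_complementary=complementary,
        core_mismatches=mismatches,
        tail_ok=tail_range[0] <= tail_len <= tail_range[1],
        flanks_ok=all(f <= max_flank for f in flanks),
        core_t_substituted=all(t != "T" for t in core),
    )


def _best_mismatches(query: str, target: str) -> int:
    """Minimal Hamming distance of ``query`` over all target windows.

    When the query is longer than the target the overhang counts as
    mismatched.  Useful for screening probes against paralogous miRNAs.
    """
    if not query:
        return 0
    if len(query) > len(target):
        overhang = len(query) - len(target)
        return overhang + _best_mismatches(query[:len(target)], target)
    best = len(query)
    for i in range(len(target) - len(query) + 1):
        d = sum(1 for a, b in zip(query, target[i : i + len(query)]) if a != b)
        best = min(best, d)
    return best
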