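"""Degenerate half-site patterns and repeat-element scanning.

Nuclear receptors of the NR1H/NR2B class bind DNA as dimers on two hexameric
half-sites arranged as an inverted (IR), direct (DR) or everted (ER) repeat
separated by a short spacer.  The farnesoid X receptor (FXR) element is the
IR1: two half-sites matching the degenerate consensus ``[GA]GGT[TC]A`` facing
each other across a single unconstrained base.

This module represents such consensi as ordered lists of allowed-base sets,
compiles a half-site plus a repeat geometry into a full-site pattern, and
scans nucleotide sequences for matches under a mismatch budget on either
strand.  A position whose allowed set is the full ``{A,C,G,T}`` alphabet
(a spacer, or an ``N`` in the consensus) is unconstrained and never counts a
mismatch; any character outside ``A/C/G/T`` in the subject counts as a
mismatch at every constrained position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IUPACPattern",
    "Arrangement",
    "RepeatGeometry",
    "ResponseElementPattern",
    "MotifHit",
    "PatternParseError",
    "parse_halfsite",
    "compile_element",
    "mismatches_at",
    "scan",
    "reverse_complement",
]

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_FULL_SET = frozenset(_BASES)

# base -> row index into the allowed-base matrix; anything else (N, gaps) -> 4
_BASE_INDEX = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case-insensitive)."""
    return seq.upper().translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


class PatternParseError(ValueError):
    """Raised for malformed bracket-form consensus text."""


@dataclass(frozen=True)
class IUPACPattern:
    """An ordered list of allowed-base sets, one per consensus position."""

    sets: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.sets) < 1:
            raise ValueError("pattern must have at least one position")
        for i, s in enumerate(self.sets):
            if not s or not s <= _FULL_SET:
                raise ValueError(f"position {i}: allowed set must be a nonempty subset of ACGT")

    @property
    def length(self) -> int:
        return len(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def reverse_complement(self) -> "IUPACPattern":
        rc = tuple(
            frozenset(_COMPLEMENT[b] for b in s) for s in reversed(self.sets)
        )
        return IUPACPattern(rc)

    def concat(self, other: "IUPACPattern") -> "IUPACPattern":
        return IUPACPattern(self.sets + other.sets)

    def is_constrained(self, i: int) -> bool:
        """True when position ``i`` restricts the base (set != {A,C,G,T})."""
        return self.sets[i] != _FULL_SET

    @property
    def n_constrained(self) -> int:
        return sum(1 for s in self.sets if s != _FULL_SET)

    @property
    def n_words(self) -> int:
        """Number of distinct exact words matching the pattern."""
        return math.prod(len(s) for s in self.sets)

    def to_bracket(self) -> str:
        """Canonical bracket text: singletons bare, full set as N, else [sorted]."""
        out = []
        for s in self.sets:
            if s == _FULL_SET:
                out.append("N")
            elif len(s) == 1:
                out.append(next(iter(s)))
            else:
                out.append("[" + "".join(sorted(s)) + "]")
        return "".join(out)

    def allowed_matrix(self) -> np.ndarray:
        """Boolean (length, 5) matrix; column 4 is the non-ACGT character class."""
        m = np.zeros((self.length, 5), dtype=bool)
        for i, s in enumerate(self.sets):
            for b in s:
                m[i, _BASES.index(b)] = True
            if s == _FULL_SET:  # unconstrained: anything, including N, matches
                m[i, 4] = True
        return m


def parse_halfsite(text: str) -> IUPACPattern:
    """Parse bracket-form consensus text such as ``"[GA]GGT[TC]A"``.

    ``N`` denotes the fully degenerate position {A,C,G,T}.  Raises
    :class:`PatternParseError` naming the offending position for malformed
    brackets, empty alternative sets, or illegal characters.
    """
    sets: list[frozenset[str]] = []
    i = 0
    n = len(text)
    while i < n:
        c = text[i].upper()
        if c == "[":
            j = text.find("]", i + 1)
            if j < 0:
                raise PatternParseError(f"position {len(sets)}: unclosed '[' at character {i}")
            alt = text[i + 1 : j].upper()
            if not alt:
                raise PatternParseError(f"position {len(sets)}: empty alternative set")
            bad = [b for b in alt if b not in _BASES]
            if bad:
                raise PatternParseError(
                    f"position {len(sets)}: illegal character {bad[0]!r} in brackets"
                )
            sets.append(frozenset(alt))
            i = j + 1
        elif c == "]":
            raise PatternParseError(f"position {len(sets)}: unmatched ']' at character {i}")
        elif c == "N":
            sets.append(_FULL_SET)
            i += 1
        elif c in _BASES:
            sets.append(frozenset(c))
            i += 1
        else:
            raise PatternParseError(
                f"position {len(sets)}: illegal character {text[i]!r} at character {i}"
            )
    if not sets:
        raise PatternParseError("empty pattern text")
    return IUPACPattern(tuple(sets))


class Arrangement(str, Enum):
    """Dimer half-site arrangement: inverted, direct, or everted repeat."""

    IR = "IR"
    DR = "DR"
    ER = "ER"


@dataclass(frozen=True)
class RepeatGeometry:
    arrangement: Arrangement
    spacer: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "arrangement", Arrangement(self.arrangement))
        if self.spacer < 0:
            raise ValueError("spacer must be >= 0")


IR1 = RepeatGeometry(Arrangement.IR, 1)


@dataclass(frozen=True)
class ResponseElementPattern:
    """A compiled full-site pattern: left half, spacer, right half.

    ``self_rc`` is true when the full allowed-set list equals its own
    reverse-complement mirror, in which case a match is the same physical
    site read on either strand (the IR1 consensus has this property).
    """

    left: IUPACPattern
    right: IUPACPattern
    spacer: int
    full: IUPACPattern
    self_rc: bool

    @property
    def length(self) -> int:
        return self.full.length


def compile_element(half: IUPACPattern, geometry: RepeatGeometry) -> ResponseElementPattern:
    """Assemble a full-site pattern from one half-site and a repeat geometry.

    IR places the reverse-complemented half on the right; DR repeats the half
    directly; ER everts the arrangement (reverse-complemented half on the
    left, direct half on the right).  Spacer positions are fully degenerate.
    """
    arr = geometry.arrangement
    if arr is Arrangement.IR:
        left, right = half, half.reverse_complement()
    elif arr is Arrangement.DR:
        left, right = half, half
    else:  # ER
        left, right = half.reverse_complement(), half
    mid = IUPACPattern(tuple([_FULL_SET] * geometry.spacer)) if geometry.spacer else None
    full = left.concat(mid).concat(right) if mid is not None else left.concat(right)
    self_rc = full.sets == full.reverse_complement().sets
    return ResponseElementPattern(
        left=left, right=right, spacer=geometry.spacer, full=full, self_rc=self_rc
    )


def ir1_pattern(halfsite: str = "[GA]GGT[TC]A") -> ResponseElementPattern:
    """The canonical FXR element: IR1 over the ``[GA]GGT[TC]A`` half-site."""
    return compile_element(parse_halfsite(halfsite), IR1)


@dataclass(frozen=True)
class MotifHit:
    """A located element match on a stored (plus-strand) sequence.

    ``start`` is the 0-based offset of the match on the stored strand;
    ``start1``/``end1`` give the 1-based inclusive interval for display.
    ``matched`` is the literal stored-strand substring.  ``gene_offset`` is
    filled in by the window machinery (+1 convention, no position 0).
    """

    seq_id: str
    start: int
    strand: str
    length: int
    mismatches: int
    matched: str
    gene_offset: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.start < 0 or self.mismatches < 0:
            raise ValueError("start and mismatches must be non-negative")
        if len(self.matched) != self.length:
            raise ValueError("matched text length disagrees with hit length")

    @property
    def start1(self) -> int:
        return self.start + 1

    @property
    def end1(self) -> int:
        return self.start + self.length

    def with_gene_offset(self, off: int) -> "MotifHit":
        return replace(self, gene_offset=off)


def _encode(seq: str) -> np.ndarray:
    return _BASE_INDEX[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def mismatches_at(seq: str, pos: int, pattern: ResponseElementPattern) -> int:
    """Count constrained-position mismatches of ``pattern`` at ``pos`` in ``seq``.

    Spacer/unconstrained positions never contribute; non-ACGT subject
    characters count as mismatches at every constrained position.
    """
    L = pattern.length
    if pos < 0 or pos + L > len(seq):
        raise ValueError(f"position {pos} out of range for pattern length {L} on sequence of length {len(seq)}")
    window = seq[pos : pos + L].upper()
    mm = 0
    for i, s in enumerate(pattern.full.sets):
        if s == _FULL_SET:
            continue
        if window[i] not in s:
            mm += 1
    return mm


def _mismatch_profile(enc: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    """Mismatch count for every start position, vectorised over the sequence."""
    L = allowed.shape[0]
    n = enc.size
    if n < L:
        return np.zeros(0, dtype=np.int32)
    counts = np.zeros(n - L + 1, dtype=np.int32)
    for j in range(L):
        counts += ~allowed[j, enc[j : j + n - L + 1]]
    return counts


def scan(
    seq: str,
    pattern: ResponseElementPattern,
    max_mm: int = 0,
    strands: str = "both",
    seq_id: str = "seq",
) -> list[MotifHit]:
    """Report every position matching ``pattern`` within the mismatch budget.

    ``strands`` is ``"plus"`` or ``"both"``.  For a self-reverse-complement
    pattern scanned on both strands, each physical site is reported once,
    canonicalised to strand '+'.  Hits are sorted by start (then strand).
    Overlapping hits are all reported.
    """
    if max_mm < 0:
        raise ValueError("max_mm must be >= 0")
    if strands not in ("plus", "both"):
        raise ValueError("strands must be 'plus' or 'both'")
    if not seq:
        return []
    enc = _encode(seq)
    L = pattern.length
    hits: list[MotifHit] = []

    profiles = [("+", pattern.full.allowed_matrix())]
    if strands == "both" and not pattern.self_rc:
        profiles.append(("-", pattern.full.reverse_complement().allowed_matrix()))

    for strand, allowed in profiles:
        counts = _mismatch_profile(enc, allowed)
        for pos in np.nonzero(counts <= max_mm)[0]:
            p = int(pos)
            hits.append(
                MotifHit(
                    seq_id=seq_id,
                    start=p,
                    strand=strand,
                    length=L,
                    mismatches=int(counts[p]),
                    matched=seq[p : p + L].upper(),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits
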