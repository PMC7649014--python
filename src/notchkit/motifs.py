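"""Motif grammar, scanners, EGF-repeat calling and the calcium signature.

The pattern grammar is PROSITE-flavoured: fixed residues (``C``), the
wildcard ``X`` (any residue, including the ambiguity character ``X`` of the
input), residue classes ``[FY]``, and bounded spacers ``x(2,14)``; ``-``
separators are cosmetic.  A *fixed* position, by contrast, is never
satisfied by an input ``X``.

Built-in patterns: the two conserved EGF-internal motifs

    A: CXNGGXC        (two invariant glycines between invariant cysteines)
    B: CXCXXG[FY]XG   (invariant Cys/Gly scaffold with an aromatic F/Y slot)

plus the LNR-core and NOD/NODP patterns C, D and E, which ship as
configurable defaults matched to this package's synthetic templates and are
flagged experimental.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from ._templates import (
    EGF_SPACING_PATTERN,
    MOTIF_A_PATTERN,
    MOTIF_B_PATTERN,
    MOTIF_C_PATTERN,
    MOTIF_D_PATTERN,
    MOTIF_E_PATTERN,
)
from .matrices import AMINO_ACIDS
from .records import SequenceRecord

logger = logging.getLogger(__name__)

_CB_FLANK_RE = re.compile(r"[DN].[DN][EQ]")
_CB_FLANK_WINDOW = 5

#: Disulfide pairing of the six cysteines of an EGF-like repeat (1-based).
EGF_DISULFIDE_PAIRING = ((1, 3), (2, 4), (5, 6))


class MotifSyntaxError(ValueError):
    """Malformed motif pattern; ``column`` is the 1-based offending position."""

    def __init__(self, message: str, column: int):
        super().__init__(f"{message} (column {column})")
        self.column = column


# ---------------------------------------------------------------------------
# pattern compilation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPattern:
    """A compiled wildcard-grammar pattern."""

    pattern: str
    elements: tuple
    label: str = "custom"

    @property
    def min_length(self) -> int:
        return sum(e[1] if e[0] == "range" else 1 for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e[2] if e[0] == "range" else 1 for e in self.elements)

    def fullmatch(self, residues: str) -> bool:
        return any(
            end == len(residues)
            for end, _ in _match_from(residues, 0, self.elements)
        )


def compile_motif(pattern_string: str, label: str = "custom") -> MotifPattern:
    """Parse a pattern string into a :class:`MotifPattern`.

    Raises :class:`MotifSyntaxError` with a column pointer on malformed
    classes or spacer ranges.
    """
    s = pattern_string.strip()
    if not s:
        raise MotifSyntaxError("empty motif pattern", 1)
    elements: list = []
    i = 0
    while i < len(s):
        c = s[i]
        col = i + 1
        if c == "-":
            i += 1
        elif c == "X":
            elements.append(("wild",))
            i += 1
        elif c == "x":
            if i + 1 < len(s) and s[i + 1] == "(":
                j = s.find(")", i + 2)
                if j < 0:
                    raise MotifSyntaxError("unclosed spacer range", col)
                body = s[i + 2 : j]
                m = re.fullmatch(r"(\d+)\s*,\s*(\d+)", body)
                if not m:
                    raise MotifSyntaxError(
                        f"spacer range must be x(min,max), got x({body})", col
                    )
                lo, hi = int(m.group(1)), int(m.group(2))
                if lo > hi:
                    raise MotifSyntaxError(
                        f"spacer range has min {lo} > max {hi}", col
                    )
                elements.append(("range", lo, hi))
                i = j + 1
            else:
                elements.append(("wild",))
                i += 1
        elif c == "[":
            j = s.find("]", i + 1)
            if j < 0:
                raise MotifSyntaxError("unclosed residue class", col)
            body = s[i + 1 : j]
            if not body:
                raise MotifSyntaxError("empty residue class", col)
            bad = [ch for ch in body if ch not in AMINO_ACIDS]
            if bad:
                raise MotifSyntaxError(
                    f"invalid residue {bad[0]!r} in class", col
                )
            elements.append(("class", frozenset(body)))
            i = j + 1
        elif c in AMINO_ACIDS:
            elements.append(("fixed", c))
            i += 1
        else:
            raise MotifSyntaxError(f"unexpected character {c!r}", col)
    if not elements:
        raise MotifSyntaxError("pattern has no matchable element", 1)
    return MotifPattern(pattern=s, elements=tuple(elements), label=label)


#: Built-in named patterns (C, D, E are configurable/experimental defaults).
BUILTIN_MOTIFS = {
    "A": compile_motif(MOTIF_A_PATTERN, label="A"),
    "B": compile_motif(MOTIF_B_PATTERN, label="B"),
    "C": compile_motif(MOTIF_C_PATTERN, label="C"),
    "D": compile_motif(MOTIF_D_PATTERN, label="D"),
    "E": compile_motif(MOTIF_E_PATTERN, label="E"),
}

EGF_SPACING = compile_motif(EGF_SPACING_PATTERN, label="EGF")


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def _match_from(seq: str, start: int, elements: tuple):
    """Yield ``(end, fixed_positions)`` for matches anchored at ``start``.

    Spacer lengths are explored in ascending order, so the first yielded
    match is the shortest.  ``fixed_positions`` are the sequence positions
    consumed by *fixed* elements (used to report cysteine anchors).
    """
    n = len(seq)

    def rec(pos: int, k: int, fixed: tuple):
        if k == len(elements):
            yield pos, fixed
            return
        el = elements[k]
        kind = el[0]
        if kind == "fixed":
            if pos < n and seq[pos] == el[1]:
                yield from rec(pos + 1, k + 1, fixed + (pos,))
        elif kind == "wild":
            if pos < n:
                yield from rec(pos + 1, k + 1, fixed)
        elif kind == "class":
            if pos < n and seq[pos] in el[1]:
                yield from rec(pos + 1, k + 1, fixed)
        else:  # range
            for length in range(el[1], el[2] + 1):
                if pos + length > n:
                    break
                yield from rec(pos + length, k + 1, fixed)

    yield from rec(start, 0, ())


@dataclass(frozen=True)
class MotifHit:
    """A located motif occurrence (0-based half-open coordinates)."""

    seq_id: str
    start: int
    end: int
    match: str
    label: str

    @property
    def start_1based(self) -> int:
        return self.start + 1

    @property
    def end_1based(self) -> int:
        return self.end


def scan_motif(
    record, pattern: MotifPattern, allow_overlaps: bool = True
) -> list:
    """All occurrences of a pattern, left to right.

    With ``allow_overlaps`` every distinct (start, end) occurrence is
    reported; otherwise matches are taken leftmost-first, shortest extent,
    and scanning resumes after each match (non-overlapping).
    """
    if isinstance(record, SequenceRecord):
        seq, seq_id = record.residues, record.id
    else:
        seq, seq_id = str(record), ""
    hits: list[MotifHit] = []
    pos = 0
    n = len(seq)
    while pos < n:
        matched_end = None
        seen_ends = set()
        for end, _ in _match_from(seq, pos, pattern.elements):
            if allow_overlaps:
                if end not in seen_ends:
                    seen_ends.add(end)
                    hits.append(
                        MotifHit(seq_id, pos, end, seq[pos:end], pattern.label)
                    )
            else:
                matched_end = end
                break
        if not allow_overlaps and matched_end is not None:
            hits.append(
                MotifHit(seq_id, pos, matched_end, seq[pos:matched_end],
                         pattern.label)
            )
            pos = matched_end
        else:
            pos += 1
    return hits


# ---------------------------------------------------------------------------
# EGF-like repeats and the calcium signature
# ---------------------------------------------------------------------------

@dataclass
class RepeatAnnotation:
    """One called repeat (EGF/LNR/NOD/ANK) with its cysteine anchors."""

    kind: str
    start: int
    end: int
    cysteine_positions: tuple = ()
    is_calcium_binding: Optional[bool] = None

    def __post_init__(self) -> None:
        for p in self.cysteine_positions:
            if not (self.start <= p < self.end):
                raise ValueError("cysteine position outside repeat interval")


def find_egf_repeats(record) -> list:
    """Call EGF-like repeats by their six-cysteine spacing grammar.

    Matches ``C-x(2,14)-C-x(1,10)-C-x(1,6)-C-x(2,14)-C-x(1,8)-C``
    non-overlapping, leftmost-first with shortest extent; the six anchored
    cysteines (disulfide-paired 1-3, 2-4, 5-6) are recorded per repeat.
    """
    if isinstance(record, SequenceRecord):
        seq = record.residues
    else:
        seq = str(record)
    repeats: list[RepeatAnnotation] = []
    pos = 0
    n = len(seq)
    elements = EGF_SPACING.elements
    while pos < n:
        if seq[pos] != "C":
            pos += 1
            continue
        found = None
        for end, fixed in _match_from(seq, pos, elements):
            found = (end, fixed)
            break
        if found is None:
            pos += 1
            continue
        end, fixed = found
        repeats.append(
            RepeatAnnotation(
                kind="EGF", start=pos, end=end, cysteine_positions=fixed
            )
        )
        pos = end
    return repeats


def classify_cbEGF(record, repeat: RepeatAnnotation) -> bool:
    """Calcium-binding classification of one EGF repeat.

    True iff the five residues immediately N-terminal of the repeat's first
    cysteine contain the Asp/Asn consensus ``[DN]-x-[DN]-[EQ]`` — a
    documented surrogate for the calcium-coordinating, hydroxylation-prone
    Asn/Asp flank of genuine cbEGF modules.
    """
    seq = record.residues if isinstance(record, SequenceRecord) else str(record)
    start = repeat.start
    window = seq[max(0, start - _CB_FLANK_WINDOW) : start]
    if len(window) < 4:
        logger.info(
            "repeat at %d has a %d-residue flank; classified non-cb",
            start, len(window),
        )
        return False
    return _CB_FLANK_RE.search(window) is not None


def digital_signature(record) -> str:
    """N-to-C bitstring over called EGF repeats: 1 = calcium-binding, 0 = not.

    This is the receptor's "digital format": each EGF hoop of the
    extracellular chain contributes one bit according to its ability to bind
    a calcium ion.
    """
    bits = []
    for rep in find_egf_repeats(record):
        rep.is_calcium_binding = classify_cbEGF(record, rep)
        bits.append("1" if rep.is_calcium_binding else "0")
    return "".join(bits)


# ---------------------------------------------------------------------------
# conservation-window motif discovery
# ---------------------------------------------------------------------------

def discover_conserved_motifs(
    msa,
    invariant_tau: float = 0.95,
    class_tau: float = 0.95,
    min_len: int = 7,
    max_wildcard_run: int = 2,
    gap_tau: float = 0.5,
) -> list:
    """Derive motif patterns from the conservation profile of an alignment.

    Per column: a fixed residue if the modal gap-excluded frequency reaches
    ``invariant_tau``; else a two-residue class if the top-2 cumulative
    frequency reaches ``class_tau``; else a wildcard.  Columns gapped in
    more than ``gap_tau`` of rows are wildcards.  Maximal windows of length
    >= ``min_len`` that start and end on non-wildcard columns and contain no
    wildcard run longer than ``max_wildcard_run`` are reported as patterns.
    """
    from .align import conservation_profile

    for name, tau in (("invariant_tau", invariant_tau), ("class_tau", class_tau)):
        if not (0.5 < tau <= 1.0):
            raise ValueError(f"{name} must lie in (0.5, 1], got {tau}")
    profile = conservation_profile(msa)
    symbols: list = []
    for stats in profile.columns:
        if stats.gap_fraction > gap_tau or stats.modal_residue is None:
            symbols.append(("wild",))
        elif stats.modal_freq >= invariant_tau and stats.modal_residue != "X":
            symbols.append(("fixed", stats.modal_residue))
        elif (
            len(stats.top2_residues) == 2
            and stats.top2_freq >= class_tau
            and "X" not in stats.top2_residues
        ):
            symbols.append(("class", stats.top2_residues))
        else:
            symbols.append(("wild",))

    # split at wildcard runs longer than max_wildcard_run
    segments: list[tuple] = []
    start = 0
    run = 0
    for j, sym in enumerate(symbols):
        if sym[0] == "wild":
            run += 1
            if run == max_wildcard_run + 1:
                segments.append((start, j - max_wildcard_run))
                start = j + 1
            elif run > max_wildcard_run + 1:
                start = j + 1
        else:
            run = 0
    segments.append((start, len(symbols)))

    patterns: list[MotifPattern] = []
    for lo, hi in segments:
        while lo < hi and symbols[lo][0] == "wild":
            lo += 1
        while hi > lo and symbols[hi - 1][0] == "wild":
            hi -= 1
        if hi - lo < min_len:
            continue
        parts = []
        for sym in symbols[lo:hi]:
            if sym[0] == "fixed":
                parts.append(sym[1])
            elif sym[0] == "class":
                parts.append("[" + "".join(sorted(sym[1])) + "]")
            else:
                parts.append("X")
        patterns.append(compile_motif("".join(parts), label="discovered"))
    return patterns
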