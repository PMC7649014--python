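"""Sequence records and NCBI-style defline parsing.

The defline dialect follows NCBI protein FASTA: the first whitespace token is
the accession, the *last* square-bracketed group (when present) names the
source organism, and everything in between is free-text description.  The
description is kept verbatim — including markers such as ``PREDICTED:`` or
``partial`` — because the curation stage filters on it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .matrices import AMINO_ACIDS

#: Noise markers a record may carry after keyword screening.
KNOWN_FLAGS = frozenset(
    {"hypothetical", "partial", "predicted", "low_quality", "synthetic", "unrelated"}
)

_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
_ORGANISM_RE = re.compile(r"\[([^\[\]]*)\]\s*$")


@dataclass
class Defline:
    """Parsed FASTA header (without the leading ``>``)."""

    raw: str
    accession: str
    description: str
    organism: str = ""

    def serialize(self) -> str:
        parts = [self.accession]
        if self.description:
            parts.append(self.description)
        if self.organism:
            parts.append(f"[{self.organism}]")
        return " ".join(parts)


def parse_defline(raw: str) -> Defline:
    """Split a header into accession / description / trailing [organism]."""
    raw = raw.strip()
    if not raw:
        raise ValueError("empty FASTA header")
    head = raw.split(None, 1)
    accession = head[0]
    rest = head[1] if len(head) > 1 else ""
    organism = ""
    m = _ORGANISM_RE.search(rest)
    if m:
        organism = m.group(1).strip()
        rest = rest[: m.start()].rstrip()
    return Defline(raw=raw, accession=accession, description=rest, organism=organism)


@dataclass
class SequenceRecord:
    """One protein sequence plus its parsed defline metadata."""

    id: str
    residues: str
    description: str = ""
    organism: str = ""
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record must have a non-empty id")
        self.residues = self.residues.upper()
        for pos, ch in enumerate(self.residues):
            if ch not in _VALID_RESIDUES:
                raise ValueError(
                    f"record {self.id!r}: invalid residue {ch!r} at position {pos + 1}"
                )
        bad = self.flags - KNOWN_FLAGS
        if bad:
            raise ValueError(f"unknown flags: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def defline(self) -> str:
        return Defline(
            raw="", accession=self.id, description=self.description,
            organism=self.organism,
        ).serialize()

    @classmethod
    def from_defline(cls, header: str, residues: str) -> "SequenceRecord":
        d = parse_defline(header)
        return cls(
            id=d.accession,
            residues=residues,
            description=d.description,
            organism=d.organism,
        )
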