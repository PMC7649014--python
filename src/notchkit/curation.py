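"""Three-stage curation of a noisy protein family dataset.

The pipeline order is fixed: (1) keyword/regex screening of deflines removes
obviously irrelevant or degraded entries (strawberry-notch homologs,
hypothetical / partial / predicted / low-quality / synthetic records);
(2) a local-alignment reference screen removes sequences with no credible
similarity to curated family exemplars; (3) near-duplicate removal collapses
records sharing at least 95% global-alignment identity, keeping the longest
representative.  Every removed record carries exactly one rejection reason —
the first failing stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _engine
from .matrices import AMINO_ACIDS, encode, get_matrix
from .records import SequenceRecord

#: Defline markers excluded by default, mirroring the noise classes of NCBI
#: keyword searches ("strawberry notch" is a different protein entirely).
DEFAULT_EXCLUDE_PATTERNS = (
    "strawberry notch",
    "hypothetical",
    "partial",
    "low quality",
    "predicted",
    "synthetic construct",
)

DEFAULT_IDENTITY_THRESHOLD = 0.95
DEFAULT_MIN_NORM_SCORE = 0.3


@dataclass
class Rejection:
    record_id: str
    stage: str  # keyword | reference | duplicate
    reason: str


@dataclass
class CurationReport:
    """Stage-by-stage accounting of a curation run."""

    n_input: int = 0
    n_removed_by_keyword: int = 0
    n_removed_by_reference_screen: int = 0
    n_removed_as_duplicates: int = 0
    n_retained: int = 0
    rejections: list = field(default_factory=list)

    def validate(self) -> None:
        removed = (
            self.n_removed_by_keyword
            + self.n_removed_by_reference_screen
            + self.n_removed_as_duplicates
        )
        if self.n_input != self.n_retained + removed:
            raise ValueError("curation report counts do not reconcile")
        if len(self.rejections) != removed:
            raise ValueError("rejection list does not match removal counts")
        ids = [r.record_id for r in self.rejections]
        if len(set(ids)) != len(ids):
            raise ValueError("a record was rejected more than once")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tstage\treason\n")
            for r in self.rejections:
                fh.write(f"{r.record_id}\t{r.stage}\t{r.reason}\n")


# ---------------------------------------------------------------------------
# stage 1: keyword screen
# ---------------------------------------------------------------------------

def _compile_patterns(patterns):
    compiled = []
    for p in patterns:
        try:
            compiled.append((p, re.compile(p, re.IGNORECASE)))
        except re.error as exc:
            raise ValueError(f"invalid pattern {p!r}: {exc}") from None
    return compiled


def filter_by_keywords(
    records: Sequence[SequenceRecord],
    exclude_patterns=DEFAULT_EXCLUDE_PATTERNS,
    flag_patterns: Optional[dict] = None,
):
    """Reject records whose description matches any exclude pattern.

    ``flag_patterns`` maps flag names to patterns; matches are recorded on
    kept records' ``flags`` without rejecting them.  Patterns are
    case-insensitive regular expressions; an invalid one raises, naming it.
    """
    excludes = _compile_patterns(exclude_patterns)
    flags = [
        (name, rx)
        for name, rx in (
            (n, _compile_patterns([p])[0][1]) for n, p in (flag_patterns or {}).items()
        )
    ]
    kept: list[SequenceRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        text = rec.description
        hit = next((p for p, rx in excludes if rx.search(text)), None)
        if hit is not None:
            rejected.append(
                Rejection(rec.id, "keyword", f"description matches {hit!r}")
            )
            continue
        for name, rx in flags:
            if rx.search(text):
                rec.flags.add(name)
        kept.append(rec)
    return kept, rejected


# ---------------------------------------------------------------------------
# stage 2: reference screen
# ---------------------------------------------------------------------------

def _normalized_local_score(codes_rec, codes_ref, M, gap_open, gap_extend) -> float:
    """Smith-Waterman score divided by the self-score of the aligned
    reference segment."""
    score, _, b_idx, _ = _engine.align_encoded(
        codes_rec, codes_ref, M, gap_open, gap_extend, local=True
    )
    ref_cols = b_idx[b_idx >= 0]
    if ref_cols.size == 0 or score <= 0:
        return 0.0
    self_score = float(np.sum(np.diagonal(M)[codes_ref[ref_cols]]))
    if self_score <= 0:
        return 0.0
    return score / self_score


def reference_screen(
    records: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    min_norm_score: float = DEFAULT_MIN_NORM_SCORE,
    matrix="gonnet250",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
):
    """Keep records locally similar to at least one reference exemplar.

    Each record is Smith-Waterman-aligned against the references; it is kept
    iff its best score, normalised by the self-score of the aligned
    reference segment, reaches ``min_norm_score``.
    """
    if not references:
        raise ValueError("reference screen requires a non-empty reference set")
    if not (0 < min_norm_score <= 1):
        raise ValueError("min_norm_score must lie in (0, 1]")
    M = get_matrix(matrix)
    ref_codes = [encode(r.residues) for r in references]
    kept: list[SequenceRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        codes = encode(rec.residues)
        best = 0.0
        for rc in ref_codes:
            best = max(
                best, _normalized_local_score(codes, rc, M, gap_open, gap_extend)
            )
            if best >= min_norm_score:
                break
        if best >= min_norm_score:
            kept.append(rec)
        else:
            rejected.append(
                Rejection(
                    rec.id,
                    "reference",
                    f"best normalized local score {best:.3f} < {min_norm_score}",
                )
            )
    return kept, rejected


# ---------------------------------------------------------------------------
# stage 3: near-duplicate removal
# ---------------------------------------------------------------------------

def global_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix="gonnet250",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Global-alignment identity: matches over aligned columns.

    The denominator counts every alignment column (a pairwise alignment has
    no dual-gap column), which deliberately penalises length-discordant
    partial sequences.
    """
    M = get_matrix(matrix)
    ca, cb = encode(a.residues), encode(b.residues)
    _, ai, bj, _ = _engine.align_encoded(ca, cb, M, gap_open, gap_extend)
    both = (ai >= 0) & (bj >= 0)
    matches = int(np.count_nonzero(ca[ai[both]] == cb[bj[both]]))
    return matches / len(ai)


def dedup_by_identity(
    records: Sequence[SequenceRecord],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    within_species: bool = True,
    matrix="gonnet250",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
):
    """Greedy near-duplicate sweep keeping the longest representative.

    Records are visited in descending length (ties: lexicographic id); a
    record is removed if its identity to any already-kept record (of the
    same organism when ``within_species``) reaches ``threshold``.  Because
    identity over alignment columns is bounded by the length ratio, pairs
    whose lengths differ by more than the threshold are skipped unaligned.
    """
    if not (0 < threshold <= 1):
        raise ValueError("identity threshold must lie in (0, 1]")
    order = sorted(records, key=lambda r: (-r.length, r.id))
    kept: list[SequenceRecord] = []
    removed_pairs: list[tuple] = []
    for rec in order:
        duplicate_of = None
        for other in kept:
            if within_species and other.organism != rec.organism:
                continue
            if rec.length / other.length < threshold:  # other is >= rec in length
                continue
            ident = global_identity(rec, other, matrix, gap_open, gap_extend)
            if ident >= threshold:
                duplicate_of = (other, ident)
                break
        if duplicate_of is None:
            kept.append(rec)
        else:
            removed_pairs.append((rec.id, duplicate_of[0].id, duplicate_of[1]))
    input_order = {r.id: k for k, r in enumerate(records)}
    kept.sort(key=lambda r: input_order[r.id])
    return kept, removed_pairs


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def curate(
    records: Sequence[SequenceRecord],
    references: Sequence[SequenceRecord],
    exclude_patterns=DEFAULT_EXCLUDE_PATTERNS,
    flag_patterns: Optional[dict] = None,
    min_norm_score: float = DEFAULT_MIN_NORM_SCORE,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    within_species: bool = True,
    matrix="gonnet250",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
):
    """Run keywords -> reference screen -> dedup; return (kept, report)."""
    report = CurationReport(n_input=len(records))
    kept, rej_kw = filter_by_keywords(records, exclude_patterns, flag_patterns)
    report.n_removed_by_keyword = len(rej_kw)
    report.rejections.extend(rej_kw)

    kept, rej_ref = reference_screen(
        kept, references, min_norm_score, matrix, gap_open, gap_extend
    )
    report.n_removed_by_reference_screen = len(rej_ref)
    report.rejections.extend(rej_ref)

    kept, removed_pairs = dedup_by_identity(
        kept, identity_threshold, within_species, matrix, gap_open, gap_extend
    )
    for rec_id, keeper_id, ident in removed_pairs:
        report.rejections.append(
            Rejection(rec_id, "duplicate", f"identity {ident:.3f} to {keeper_id}")
        )
    report.n_removed_as_duplicates = len(removed_pairs)
    report.n_retained = len(kept)
    report.validate()
    return kept, report
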