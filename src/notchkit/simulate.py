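"""Synthetic Notch-family benchmark generator with planted ground truth.

Every record the generator emits is annotated in a truth table: which clade
it belongs to, which positions are motif-invariant ("protected"), where each
planted domain lies, which EGF repeats are calcium-binding, which records
are noise and which are near-duplicates.  That truth table is the oracle
against which curation, clustering, consensus phylogeny and motif discovery
are tested without any database download.

Sequence evolution uses the 20-state Jukes-Cantor substitution process
(uniform replacement over the 19 alternative residues), so that corrected
distances recover planted branch lengths in expectation and all test
expectations stay analytic.  Substitutions hit only unprotected positions;
indels are restricted to linker segments, keeping planted domain
coordinates exact.

Clade ancestors descend from one family master along a planted ultrametric
divergence ladder: the Notch2/Notch3 pair splits last among the vertebrate
paralogs (their planted distance is the shortest), Notch4 splits before
Notch1, the two C. elegans-style outgroup homologs (GLP-1-like, LIN-12-like)
attach outside the four paralog clades, and the invertebrate, protist, plant
and bacterial clades branch progressively earlier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._templates import (
    ANK_TEMPLATE,
    CB_FLANK,
    EGF_UNIT_LAYOUT,
    FLANK_LENGTH,
    LNR_TEMPLATE,
    NLS_TEMPLATE,
    NOD_MOTIF_D,
    NOD_TEMPLATE,
    NONCB_FLANK,
    PEST_TEMPLATE,
    RAM_TEMPLATE,
    TM_TEMPLATE,
)
from .matrices import AMINO_ACIDS
from .records import SequenceRecord

#: Linker residues exclude cysteine so repeat grammars never fire in linkers.
LINKER_ALPHABET = AMINO_ACIDS.replace("C", "")

#: Deterministic calcium-binding plan: every fourth EGF repeat is
#: calcium-free, the rest bind calcium (clade plans are prefixes of this).
def _cb_plan(n_egf: int) -> str:
    return "".join("0" if i % 4 == 3 else "1" for i in range(n_egf))


_EGF_PROTECTED = tuple(
    i for i, el in enumerate(EGF_UNIT_LAYOUT) if el is not None
)

_TEMPLATES = {
    "lnr": LNR_TEMPLATE,
    "tm": TM_TEMPLATE,
    "ram": RAM_TEMPLATE,
    "nls": NLS_TEMPLATE,
    "ank": ANK_TEMPLATE,
    "pest": PEST_TEMPLATE,
    "nod": NOD_TEMPLATE,
    "motifd": NOD_MOTIF_D,
}


# ---------------------------------------------------------------------------
# architecture specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchitectureSpec:
    """Domain architecture and length target of one clade's receptor."""

    name: str
    target_length: int
    n_egf: int
    cb_bits: str
    n_lnr: int = 0
    nod: str = "none"  # none | d_only | full
    n_ank: int = 0
    description: str = "notch receptor"
    organisms: tuple = ()

    def __post_init__(self) -> None:
        if len(self.cb_bits) != self.n_egf:
            raise ValueError("cb bit plan length must equal EGF count")
        if self.nod not in {"none", "d_only", "full"}:
            raise ValueError(f"unknown nod mode {self.nod!r}")


def canonical_roster() -> list:
    """The eight default clade architectures of the family benchmark.

    Lengths follow the family's reported receptor sizes (Notch1 2,627 aa
    down to Notch4 2,059 aa, with the invertebrate receptor longest and the
    bacterial Notch-like protein a single EGF-unit miniature); the three
    long paralogs carry the canonical 36 EGF repeats, 3 LNRs and 7 ANKs,
    Notch4 a reduced EGF array.
    """
    return [
        ArchitectureSpec(
            "Notch_Bacteria", 110, 1, _cb_plan(1), nod="d_only",
            description="notch-like protein",
            organisms=("Bacillus subtilis", "Escherichia coli",
                       "Pseudomonas putida", "Streptomyces griseus",
                       "Synechocystis sp.", "Myxococcus xanthus"),
        ),
        ArchitectureSpec(
            "Notch_Plants", 400, 4, _cb_plan(4), nod="full",
            description="notch homolog",
            organisms=("Arabidopsis thaliana", "Oryza sativa", "Zea mays",
                       "Solanum lycopersicum", "Physcomitrella patens",
                       "Selaginella moellendorffii"),
        ),
        ArchitectureSpec(
            "Notch_Protist", 600, 8, _cb_plan(8), n_lnr=1, nod="full",
            description="notch-like receptor",
            organisms=("Dictyostelium discoideum", "Tetrahymena thermophila",
                       "Paramecium tetraurelia", "Plasmodium falciparum",
                       "Perkinsus marinus", "Monosiga brevicollis"),
        ),
        ArchitectureSpec(
            "Notch_Invertebrates", 2700, 36, _cb_plan(36), n_lnr=3,
            nod="full", n_ank=7, description="notch protein",
            organisms=("Drosophila melanogaster", "Aedes aegypti",
                       "Hydra vulgaris", "Schmidtea mediterranea",
                       "Strongylocentrotus purpuratus", "Apis mellifera"),
        ),
        ArchitectureSpec(
            "Notch1", 2627, 36, _cb_plan(36), n_lnr=3, nod="full", n_ank=7,
            description="notch receptor 1",
            organisms=("Homo sapiens", "Mus musculus", "Bos taurus",
                       "Gallus gallus", "Danio rerio", "Xenopus laevis"),
        ),
        ArchitectureSpec(
            "Notch2", 2471, 36, _cb_plan(36), n_lnr=3, nod="full", n_ank=7,
            description="notch receptor 2",
            organisms=("Homo sapiens", "Mus musculus", "Rattus norvegicus",
                       "Canis lupus", "Danio rerio", "Pan troglodytes"),
        ),
        ArchitectureSpec(
            "Notch3", 2321, 36, _cb_plan(36), n_lnr=3, nod="full", n_ank=7,
            description="notch receptor 3",
            organisms=("Homo sapiens", "Mus musculus", "Sus scrofa",
                       "Equus caballus", "Danio rerio", "Felis catus"),
        ),
        ArchitectureSpec(
            "Notch4", 2059, 29, _cb_plan(29), n_lnr=3, nod="full", n_ank=7,
            description="notch receptor 4",
            organisms=("Homo sapiens", "Mus musculus", "Bos taurus",
                       "Rattus norvegicus", "Canis lupus", "Ovis aries"),
        ),
    ]


OUTGROUP_SPECS = (
    ArchitectureSpec(
        "GLP1_like", 1295, 10, _cb_plan(10), n_lnr=3, nod="full", n_ank=7,
        description="glp-1 notch family homolog",
        organisms=("Caenorhabditis elegans",),
    ),
    ArchitectureSpec(
        "LIN12_like", 1429, 13, _cb_plan(13), n_lnr=3, nod="full", n_ank=7,
        description="lin-12 notch family homolog",
        organisms=("Caenorhabditis elegans",),
    ),
)

_MASTER_SPEC = ArchitectureSpec(
    "_master", 2700, 36, _cb_plan(36), n_lnr=3, nod="full", n_ank=7,
)


# ---------------------------------------------------------------------------
# segment-level proteins
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    kind: str
    text: str
    cb: Optional[bool] = None  # flank segments only

    def protected_local(self) -> tuple:
        if self.kind == "linker":
            return ()
        if self.kind == "egf":
            return _EGF_PROTECTED
        return tuple(range(len(self.text)))


@dataclass
class SyntheticProtein:
    """A planted-architecture protein as an ordered list of segments."""

    name: str
    spec: ArchitectureSpec
    segments: list

    def sequence(self) -> str:
        return "".join(s.text for s in self.segments)

    @property
    def length(self) -> int:
        return sum(len(s.text) for s in self.segments)

    def domains(self) -> list:
        """(kind, start, end, cb) intervals of all non-linker segments."""
        out = []
        pos = 0
        for seg in self.segments:
            if seg.kind != "linker":
                out.append((seg.kind, pos, pos + len(seg.text), seg.cb))
            pos += len(seg.text)
        return out

    def egf_intervals(self) -> list:
        return [(s, e) for k, s, e, _ in self.domains() if k == "egf"]

    def cb_bits(self) -> str:
        return "".join(
            "1" if cb else "0" for k, _, _, cb in self.domains() if k == "flank"
        )

    def protected_positions(self) -> np.ndarray:
        out = []
        pos = 0
        for seg in self.segments:
            out.extend(pos + i for i in seg.protected_local())
            pos += len(seg.text)
        return np.asarray(out, dtype=np.int64)

    def necd_span(self) -> tuple:
        """Extracellular span: sequence start up to the TM segment."""
        pos = 0
        for seg in self.segments:
            if seg.kind == "tm":
                return (0, pos)
            pos += len(seg.text)
        return (0, pos)

    def to_record(self, rec_id: str, description: str = "",
                  organism: str = "") -> SequenceRecord:
        return SequenceRecord(
            id=rec_id,
            residues=self.sequence(),
            description=description or self.spec.description,
            organism=organism,
        )


def _rand_linker(rng, n: int) -> str:
    return "".join(rng.choice(list(LINKER_ALPHABET), size=n)) if n else ""


def _instantiate_egf_unit(rng) -> str:
    out = []
    for el in EGF_UNIT_LAYOUT:
        if el is None:
            out.append(str(rng.choice(list(LINKER_ALPHABET))))
        elif el == "FY":
            out.append(str(rng.choice(["F", "Y"])))
        else:
            out.append(el)
    return "".join(out)


def _fixed_length(spec: ArchitectureSpec) -> tuple:
    """(total template length, number of linker slots) of an architecture."""
    fixed = spec.n_egf * (FLANK_LENGTH + len(EGF_UNIT_LAYOUT))
    slots = 1 + spec.n_egf  # N-terminal linker + one after each EGF block
    fixed += spec.n_lnr * len(LNR_TEMPLATE)
    slots += spec.n_lnr
    if spec.nod == "full":
        fixed += len(NOD_TEMPLATE)
        slots += 1
    elif spec.nod == "d_only":
        fixed += len(NOD_MOTIF_D)
        slots += 1
    if spec.n_ank:
        fixed += (
            len(TM_TEMPLATE) + len(RAM_TEMPLATE) + len(NLS_TEMPLATE)
            + spec.n_ank * len(ANK_TEMPLATE) + len(PEST_TEMPLATE)
        )
        slots += 2 + spec.n_ank
    slots += 1  # C-terminal tail
    return fixed, slots


def _slot_lengths(spec: ArchitectureSpec) -> list:
    fixed, slots = _fixed_length(spec)
    budget = spec.target_length - fixed
    if budget < 3 * slots:
        raise ValueError(
            f"impossible spec {spec.name!r}: target length {spec.target_length} "
            f"too small for {fixed} residues of domains plus {slots} linkers"
        )
    base, rem = divmod(budget, slots)
    return [base + (1 if k < rem else 0) for k in range(slots)]


def make_protein(spec: ArchitectureSpec, rng) -> SyntheticProtein:
    """Instantiate an architecture: domains from templates, linkers random."""
    lengths = _slot_lengths(spec)
    slot = iter(lengths)
    segments: list[Segment] = [Segment("linker", _rand_linker(rng, next(slot)))]
    for i in range(spec.n_egf):
        cb = spec.cb_bits[i] == "1"
        segments.append(Segment("flank", CB_FLANK if cb else NONCB_FLANK, cb=cb))
        segments.append(Segment("egf", _instantiate_egf_unit(rng)))
        segments.append(Segment("linker", _rand_linker(rng, next(slot))))
    for _ in range(spec.n_lnr):
        segments.append(Segment("lnr", LNR_TEMPLATE))
        segments.append(Segment("linker", _rand_linker(rng, next(slot))))
    if spec.nod == "full":
        segments.append(Segment("nod", NOD_TEMPLATE))
        segments.append(Segment("linker", _rand_linker(rng, next(slot))))
    elif spec.nod == "d_only":
        segments.append(Segment("motifd", NOD_MOTIF_D))
        segments.append(Segment("linker", _rand_linker(rng, next(slot))))
    if spec.n_ank:
        segments.append(Segment("tm", TM_TEMPLATE))
        segments.append(Segment("linker", _rand_linker(rng, next(slot))))
        segments.append(Segment("ram", RAM_TEMPLATE))
        segments.append(Segment("nls", NLS_TEMPLATE))
        segments.append(Segment("linker", _rand_linker(rng, next(slot))))
        for _ in range(spec.n_ank):
            segments.append(Segment("ank", ANK_TEMPLATE))
            segments.append(Segment("linker", _rand_linker(rng, next(slot))))
        segments.append(Segment("pest", PEST_TEMPLATE))
    segments.append(Segment("linker", _rand_linker(rng, next(slot))))
    protein = SyntheticProtein(spec.name, spec, segments)
    assert protein.length == spec.target_length
    return protein


def make_ancestor(spec: ArchitectureSpec, seed: int) -> tuple:
    """Deterministic clade ancestor: (SequenceRecord, SyntheticProtein)."""
    rng = np.random.default_rng(seed)
    protein = make_protein(spec, rng)
    record = protein.to_record(f"{spec.name}_anc")
    return record, protein


# ---------------------------------------------------------------------------
# evolution
# ---------------------------------------------------------------------------

def _jc_sub_probability(branch: float) -> float:
    """Expected difference fraction after a JC branch of given length."""
    return (19.0 / 20.0) * (1.0 - math.exp(-20.0 * branch / 19.0))


_AA_LIST = np.array(list(AMINO_ACIDS))
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _mutate_text(
    text: str, p_sub: float, protected_local, rng, alphabet: str = AMINO_ACIDS
) -> str:
    if not text or p_sub <= 0:
        return text
    chars = list(text)
    editable = np.ones(len(text), dtype=bool)
    for i in protected_local:
        editable[i] = False
    hit = editable & (rng.random(len(text)) < p_sub)
    for i in np.nonzero(hit)[0]:
        choices = [a for a in alphabet if a != chars[i]]
        chars[i] = str(rng.choice(choices))
    return "".join(chars)


def _indel_text(text: str, indel_rate: float, rng, max_len: int = 8) -> str:
    if not text or indel_rate <= 0:
        return text
    out = []
    i = 0
    while i < len(text):
        if rng.random() < indel_rate:
            length = min(int(rng.geometric(0.5)), max_len)
            if rng.random() < 0.5:
                out.append(_rand_linker(rng, length))  # insertion
                out.append(text[i])
                i += 1
            else:
                i += length  # deletion
        else:
            out.append(text[i])
            i += 1
    return "".join(out) or text[:1]


def _evolve_protein(
    protein: SyntheticProtein, branch: float, rng, indel_rate: float = 0.0
) -> SyntheticProtein:
    """One descendant: substitutions at unprotected sites, linker indels.

    Per-site substitution probability follows the Jukes-Cantor expectation
    for the branch length; replacements are drawn from the cysteine-free
    alphabet so planted cysteine architectures (EGF spacing, LNR pairs)
    stay exact in every descendant.
    """
    p_sub = _jc_sub_probability(branch)
    segments = []
    for seg in protein.segments:
        text = _mutate_text(
            seg.text, p_sub, seg.protected_local(), rng, alphabet=LINKER_ALPHABET
        )
        if seg.kind == "linker":
            text = _indel_text(text, indel_rate, rng)
        segments.append(Segment(seg.kind, text, cb=seg.cb))
    return SyntheticProtein(protein.name, protein.spec, segments)


def evolve_clade(
    ancestor: SequenceRecord,
    n_members: int,
    sub_rate: float = 0.02,
    indel_rate: float = 0.0,
    protected_columns: Sequence[int] = (),
    seed: int = 0,
):
    """Independent descendants of a flat ancestor sequence.

    Each unprotected position substitutes independently with probability
    ``sub_rate`` (replacement uniform over the 19 other residues), so two
    members differ at an unprotected site with probability
    ``2*sub_rate*(1 - sub_rate) + (sub_rate**2)*(18/19)``, approximately
    ``2*sub_rate`` for small rates.  Indels (geometric lengths) occur at
    unprotected positions with probability ``indel_rate`` per site.  Returns
    ``(records, truths)`` where each truth lists the edits applied.
    """
    if not (0 <= sub_rate < 0.5 and 0 <= indel_rate < 0.5):
        raise ValueError("rates must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    protected = set(int(p) for p in protected_columns)
    bad = [p for p in protected if not (0 <= p < ancestor.length)]
    if bad:
        raise ValueError(f"protected column {bad[0]} outside ancestor")
    records = []
    truths = []
    for k in range(n_members):
        chars = []
        subs = []
        indels = []
        i = 0
        seq = ancestor.residues
        while i < len(seq):
            if i not in protected and rng.random() < indel_rate:
                length = min(int(rng.geometric(0.5)), 8)
                if rng.random() < 0.5:
                    ins = _rand_linker(rng, length)
                    indels.append(("ins", i, ins))
                    chars.append(ins)
                else:
                    end = i
                    while end < min(i + length, len(seq)) and end not in protected:
                        end += 1
                    indels.append(("del", i, seq[i:end]))
                    i = end
                    continue
            c = seq[i]
            if i not in protected and c in _AA_INDEX and rng.random() < sub_rate:
                new = str(rng.choice([a for a in AMINO_ACIDS if a != c]))
                subs.append((i, c, new))
                chars.append(new)
            else:
                chars.append(c)
            i += 1
        rec = SequenceRecord(
            id=f"{ancestor.id}_m{k}",
            residues="".join(chars),
            description=ancestor.description,
            organism=ancestor.organism,
        )
        records.append(rec)
        truths.append({"substitutions": subs, "indels": indels})
    return records, truths


# ---------------------------------------------------------------------------
# family ladder and restructuring
# ---------------------------------------------------------------------------

#: Planted divergence ladder (heights in expected substitutions per
#: unprotected site).  Leaves are clade names; internal nodes carry the
#: join height.  Notch2/Notch3 are the closest pair; the outgroup homologs
#: join outside the four vertebrate paralog clades.
FAMILY_LADDER = (
    0.70,
    "Notch_Bacteria",
    (
        0.65,
        "Notch_Plants",
        (
            0.60,
            "Notch_Protist",
            (
                0.55,
                "Notch_Invertebrates",
                (
                    0.50,
                    (0.30, "GLP1_like", "LIN12_like"),
                    (
                        0.42,
                        "Notch4",
                        (0.36, "Notch1", (0.30, "Notch2", "Notch3")),
                    ),
                ),
            ),
        ),
    ),
)


def _restructure(master: SyntheticProtein, spec: ArchitectureSpec,
                 rng) -> SyntheticProtein:
    """Carve a clade architecture out of an evolved family master.

    Keeps the first ``n_egf`` EGF blocks (flank + unit), the first
    ``n_lnr`` LNRs and the intracellular segments the architecture asks for, and
    trims (or, rarely, pads) each inherited linker to the clade's own
    length budget, so clade sequences stay column-homologous wherever their
    architectures overlap.
    """
    lengths = _slot_lengths(spec)
    slot = iter(lengths)

    by_kind: dict[str, list] = {}
    linkers: list[str] = []
    for seg in master.segments:
        if seg.kind == "linker":
            linkers.append(seg.text)
        else:
            by_kind.setdefault(seg.kind, []).append(seg)

    # master linker slot indices (master architecture is _MASTER_SPEC)
    m = _MASTER_SPEC
    m_egf0 = 1
    m_lnr0 = m_egf0 + m.n_egf
    m_nod = m_lnr0 + m.n_lnr
    m_tm = m_nod + 1
    m_ram = m_tm + 1
    m_ank0 = m_ram + 1
    m_cterm = m_ank0 + m.n_ank

    def fit(text: str, n: int) -> str:
        if len(text) >= n:
            return text[:n]
        return text + _rand_linker(rng, n - len(text))

    out: list[Segment] = []
    out.append(Segment("linker", fit(linkers[0], next(slot))))
    for i in range(spec.n_egf):
        cb = spec.cb_bits[i] == "1"
        out.append(Segment("flank", by_kind["flank"][i].text, cb=cb))
        out.append(Segment("egf", by_kind["egf"][i].text))
        out.append(Segment("linker", fit(linkers[m_egf0 + i], next(slot))))
    for j in range(spec.n_lnr):
        out.append(Segment("lnr", by_kind["lnr"][j].text))
        out.append(Segment("linker", fit(linkers[m_lnr0 + j], next(slot))))
    nod_seg = by_kind["nod"][0]
    if spec.nod == "full":
        out.append(Segment("nod", nod_seg.text))
        out.append(Segment("linker", fit(linkers[m_nod], next(slot))))
    elif spec.nod == "d_only":
        d0 = NOD_TEMPLATE.index(NOD_MOTIF_D)
        out.append(Segment("motifd", nod_seg.text[d0 : d0 + len(NOD_MOTIF_D)]))
        out.append(Segment("linker", fit(linkers[m_nod], next(slot))))
    if spec.n_ank:
        out.append(Segment("tm", by_kind["tm"][0].text))
        out.append(Segment("linker", fit(linkers[m_tm], next(slot))))
        out.append(Segment("ram", by_kind["ram"][0].text))
        out.append(Segment("nls", by_kind["nls"][0].text))
        out.append(Segment("linker", fit(linkers[m_ram], next(slot))))
        for a in range(spec.n_ank):
            out.append(Segment("ank", by_kind["ank"][a].text))
            out.append(Segment("linker", fit(linkers[m_ank0 + a], next(slot))))
        out.append(Segment("pest", by_kind["pest"][0].text))
    out.append(Segment("linker", fit(linkers[m_cterm], next(slot))))
    protein = SyntheticProtein(spec.name, spec, out)
    assert protein.length == spec.target_length
    return protein


def _descend_ladder(master: SyntheticProtein, rng) -> dict:
    """Evolve the family master down the planted ladder to clade ancestors."""
    ancestors: dict[str, SyntheticProtein] = {}

    def walk(node, protein: SyntheticProtein, parent_height: float) -> None:
        if isinstance(node, str):
            ancestors[node] = _evolve_protein(protein, parent_height, rng)
            return
        height = node[0]
        evolved = _evolve_protein(protein, parent_height - height, rng)
        for child in node[1:]:
            walk(child, evolved, height)

    root_height = FAMILY_LADDER[0]
    for child in FAMILY_LADDER[1:]:
        walk(child, master, root_height)
    return ancestors


# ---------------------------------------------------------------------------
# truth table and benchmark
# ---------------------------------------------------------------------------

@dataclass
class TruthRecord:
    record_id: str
    clade: str
    kind: str  # clean | outgroup | noise:<flavor> | duplicate
    duplicate_of: Optional[str] = None
    domains: tuple = ()
    cb_bits: str = ""
    unprotected_positions: Optional[np.ndarray] = None

    @property
    def is_noise(self) -> bool:
        return self.kind.startswith("noise")


@dataclass
class TruthTable:
    rows: dict = field(default_factory=dict)

    def add(self, row: TruthRecord) -> None:
        if row.record_id in self.rows:
            raise ValueError(f"duplicate truth id {row.record_id!r}")
        if row.duplicate_of is not None and row.duplicate_of not in self.rows:
            raise ValueError(f"duplicate-of refers to unknown id {row.duplicate_of!r}")
        self.rows[row.record_id] = row

    def __getitem__(self, rec_id: str) -> TruthRecord:
        return self.rows[rec_id]

    def __len__(self) -> int:
        return len(self.rows)

    def ids_of_kind(self, *kinds: str) -> list:
        return [
            r.record_id
            for r in self.rows.values()
            if any(r.kind == k or r.kind.startswith(k + ":") for k in kinds)
        ]

    def clean_partition(self) -> dict:
        """clade -> sorted clean member ids (the planted clustering truth)."""
        part: dict[str, list] = {}
        for r in self.rows.values():
            if r.kind == "clean":
                part.setdefault(r.clade, []).append(r.record_id)
        return {k: sorted(v) for k, v in part.items()}

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tclade\tkind\tduplicate_of\tcb_bits\tdomains\n")
            for r in self.rows.values():
                doms = ";".join(f"{k}:{s}-{e}" for k, s, e, _ in r.domains)
                fh.write(
                    f"{r.record_id}\t{r.clade}\t{r.kind}\t"
                    f"{r.duplicate_of or ''}\t{r.cb_bits}\t{doms}\n"
                )


@dataclass
class Benchmark:
    records: list
    truth: TruthTable
    ancestors: dict  # clade name -> SequenceRecord (curation references)
    ancestor_proteins: dict
    roster: list
    seed: int

    @property
    def reference_records(self) -> list:
        return list(self.ancestors.values())

    def write(self, fasta_path, truth_path=None) -> None:
        from .io import write_fasta

        write_fasta(self.records, fasta_path)
        if truth_path is not None:
            self.truth.to_tsv(truth_path)


_NOISE_FLAVORS = (
    "strawberry", "hypothetical", "partial", "low_quality",
    "predicted", "synthetic", "unrelated",
)


def _noise_record(flavor: str, idx: int, clean: list, truth: TruthTable,
                  rng) -> tuple:
    organisms = ("Homo sapiens", "Mus musculus", "Danio rerio",
                 "Drosophila melanogaster", "Arabidopsis thaliana")
    org = str(rng.choice(list(organisms)))
    src = clean[int(rng.integers(0, len(clean)))]
    shuffled = "".join(rng.permutation(list(src.residues)))
    rand_len = int(rng.integers(250, 450))
    random_seq = "".join(rng.choice(list(LINKER_ALPHABET), size=rand_len))
    if flavor == "strawberry":
        return shuffled, "strawberry notch homolog 1", org
    if flavor == "hypothetical":
        return random_seq, "hypothetical protein", org
    if flavor == "partial":
        cut = max(30, int(0.4 * src.length))
        return src.residues[:cut], f"{src.description}, partial", src.organism
    if flavor == "low_quality":
        return shuffled, "LOW QUALITY PROTEIN: notch receptor-like", org
    if flavor == "predicted":
        return shuffled, "PREDICTED: notch-like protein", org
    if flavor == "synthetic":
        return random_seq, "synthetic construct notch protein", org
    return random_seq, "putative membrane protein", org  # unrelated


def make_benchmark(
    roster: Optional[Sequence[ArchitectureSpec]] = None,
    members_per_clade: int = 6,
    noise_fraction: float = 0.25,
    duplicate_fraction: float = 0.125,
    seed: int = 1,
    within_branch: float = 0.02,
    indel_rate: float = 0.005,
    include_outgroups: bool = True,
) -> Benchmark:
    """Full synthetic family benchmark with NCBI-style deflines.

    Emits, per clade of the roster, ``members_per_clade`` clean members
    (between-clade divergence several-fold the within-clade divergence, per
    the planted ladder), plus the two outgroup homolog records, noise
    records of all flavors (``noise_fraction`` of the clean count) and
    near-duplicate copies (``duplicate_fraction``), each annotated in the
    truth table.
    """
    if not (0 <= noise_fraction < 1 and 0 <= duplicate_fraction < 1):
        raise ValueError("fractions must lie in [0, 1)")
    roster = list(roster) if roster is not None else canonical_roster()
    rng = np.random.default_rng(seed)
    specs = {s.name: s for s in roster}
    if include_outgroups:
        specs.update({s.name: s for s in OUTGROUP_SPECS})

    master = make_protein(_MASTER_SPEC, rng)
    evolved = _descend_ladder(master, rng)

    truth = TruthTable()
    records: list[SequenceRecord] = []
    ancestors: dict[str, SequenceRecord] = {}
    ancestor_proteins: dict[str, SyntheticProtein] = {}
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"SYN{counter:04d}"

    clean_records: list[SequenceRecord] = []
    for spec in roster:
        clade_protein = _restructure(evolved[spec.name], specs[spec.name], rng)
        ancestor_proteins[spec.name] = clade_protein
        ancestors[spec.name] = clade_protein.to_record(f"{spec.name}_anc")
        for k in range(members_per_clade):
            member = _evolve_protein(
                clade_protein, within_branch, rng, indel_rate=indel_rate
            )
            org = (
                spec.organisms[k] if k < len(spec.organisms)
                else f"{spec.name} sp. {k}"
            )
            rec = member.to_record(next_id(), spec.description, org)
            records.append(rec)
            clean_records.append(rec)
            prot = member.protected_positions()
            mask = np.ones(member.length, dtype=bool)
            mask[prot] = False
            truth.add(
                TruthRecord(
                    rec.id, spec.name, "clean",
                    domains=tuple(member.domains()),
                    cb_bits=member.cb_bits(),
                    unprotected_positions=np.nonzero(mask)[0],
                )
            )

    if include_outgroups:
        for spec in OUTGROUP_SPECS:
            protein = _restructure(evolved[spec.name], spec, rng)
            ancestor_proteins[spec.name] = protein
            ancestors[spec.name] = protein.to_record(f"{spec.name}_anc")
            rec = protein.to_record(next_id(), spec.description, spec.organisms[0])
            records.append(rec)
            truth.add(
                TruthRecord(
                    rec.id, spec.name, "outgroup",
                    domains=tuple(protein.domains()),
                    cb_bits=protein.cb_bits(),
                )
            )

    n_noise = round(noise_fraction * len(clean_records))
    for i in range(n_noise):
        flavor = _NOISE_FLAVORS[i % len(_NOISE_FLAVORS)]
        residues, desc, org = _noise_record(flavor, i, clean_records, truth, rng)
        rec = SequenceRecord(
            id=next_id(), residues=residues, description=desc, organism=org
        )
        records.append(rec)
        truth.add(TruthRecord(rec.id, "", f"noise:{flavor}"))

    n_dup = round(duplicate_fraction * len(clean_records))
    dup_sources = rng.choice(len(clean_records), size=n_dup, replace=False)
    for si in sorted(int(x) for x in dup_sources):
        src = clean_records[si]
        seq = list(src.residues)
        n_sub = max(1, int(0.015 * len(seq)))
        for pos in rng.choice(len(seq), size=n_sub, replace=False):
            orig = seq[pos]
            if orig in _AA_INDEX:
                seq[pos] = str(rng.choice([a for a in AMINO_ACIDS if a != orig]))
        cut = max(3, int(0.01 * len(seq)))
        residues = "".join(seq[:-cut])
        rec = SequenceRecord(
            id=f"{src.id}d", residues=residues,
            description=src.description, organism=src.organism,
        )
        records.append(rec)
        truth.add(
            TruthRecord(rec.id, truth[src.id].clade, "duplicate",
                        duplicate_of=src.id)
        )

    return Benchmark(
        records=records, truth=truth, ancestors=ancestors,
        ancestor_proteins=ancestor_proteins, roster=roster, seed=seed,
    )


# ---------------------------------------------------------------------------
# focused desk-scale generators
# ---------------------------------------------------------------------------

def compact_roster() -> list:
    """A four-clade miniature of the canonical roster for quick studies.

    Same clade names (so the planted divergence ladder applies) with
    shrunken architectures; useful where the full-length receptors would
    dominate runtime without changing what is being exercised.
    """
    base = {s.name: s for s in canonical_roster()}
    return [
        replace(base["Notch_Plants"], target_length=300),
        replace(
            base["Notch_Protist"], target_length=450, n_egf=6,
            cb_bits=_cb_plan(6),
        ),
        replace(
            base["Notch_Invertebrates"], target_length=800, n_egf=10,
            cb_bits=_cb_plan(10), n_lnr=2, n_ank=2,
        ),
        replace(
            base["Notch2"], target_length=700, n_egf=8, cb_bits=_cb_plan(8),
            n_lnr=1, n_ank=2,
        ),
        replace(
            base["Notch4"], target_length=700, n_egf=8, cb_bits=_cb_plan(8),
            n_lnr=1, n_ank=2,
        ),
    ]


def make_motif_panel(n_rows: int = 24, n_units: int = 2, seed: int = 0):
    """Pre-aligned panel for conservation-based motif discovery.

    Each row instantiates the EGF unit layout independently: grammar
    positions (cysteines, the invariant Asn/Gly scaffold) are identical in
    every row, the aromatic column alternates F/Y, and all other positions
    are independently random — so the discovered patterns should be exactly
    the two conserved EGF-internal motifs.
    """
    from .align import MultipleAlignment

    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_rows):
        parts = [_rand_linker(rng, 6)]
        for _ in range(n_units):
            unit = []
            for el in EGF_UNIT_LAYOUT:
                if el is None:
                    unit.append(str(rng.choice(list(LINKER_ALPHABET))))
                elif el == "FY":
                    unit.append("F" if r % 2 == 0 else "Y")
                else:
                    unit.append(el)
            parts.append("".join(unit))
            parts.append(_rand_linker(rng, 5))
        rows.append("".join(parts))
    return MultipleAlignment([f"panel{r}" for r in range(n_rows)], rows)


def make_partition_benchmark(
    n_clades: int,
    members_per_clade: int = 6,
    length: int = 400,
    within: float = 0.04,
    between: float = 0.16,
    seed: int = 0,
):
    """Equal-length clades for clustering parameter-recovery studies.

    No indels, so the records are mutually aligned as emitted.  Expected
    pairwise distance is ``within`` inside a clade and ``between`` across
    clades (the planted separation is ``between/within``-fold).  Returns
    ``(records, labels)`` with ``labels`` mapping record id to clade index.
    """
    if n_clades < 2:
        raise ValueError("need at least 2 clades")
    if between < within:
        raise ValueError("between-clade divergence must exceed within-clade")
    rng = np.random.default_rng(seed)
    master = rng.integers(0, 20, size=length)

    def jc_branch(codes: np.ndarray, branch: float) -> np.ndarray:
        p = _jc_sub_probability(branch)
        out = codes.copy()
        hit = rng.random(length) < p
        idx = np.nonzero(hit)[0]
        draw = rng.integers(0, 19, size=idx.size)
        out[idx] = draw + (draw >= out[idx])
        return out

    records = []
    labels = {}
    for c in range(n_clades):
        anc = jc_branch(master, (between - within) / 2.0)
        for k in range(members_per_clade):
            member = jc_branch(anc, within / 2.0)
            rid = f"K{c}_{k}"
            records.append(
                SequenceRecord(
                    id=rid,
                    residues="".join(_AA_LIST[member]),
                    description=f"planted clade {c}",
                )
            )
            labels[rid] = c
    return records, labels
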