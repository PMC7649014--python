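"""Synthetic domain templates shared by the motif module and the data generator.

All templates are synthetic stand-ins: they reproduce the *grammar-level*
features of the real domains (cysteine spacing of EGF-like repeats, the
conserved motif scaffolds, cysteine-rich LNR cores) without copying any real
protein sequence.  Cysteines appear only where a domain grammar requires them,
so that the cysteine-spacing EGF caller never fires inside a non-EGF domain.
"""

from __future__ import annotations

#: 27-residue EGF-like unit layout.  Fixed positions carry the six grammar
#: cysteines plus the invariant residues of the two conserved EGF-internal
#: motifs (CXNGGXC spanning columns 0-6, CXCXXG[FY]XG spanning columns 10-18).
#: ``None`` marks variable positions, ``"FY"`` the aromatic two-residue column.
EGF_UNIT_LAYOUT: tuple = (
    "C", None, "N", "G", "G", None, "C",        # motif A block
    None, None, None,                           # spacer
    "C", None, "C", None, None, "G", "FY", None, "G",  # motif B block
    None, None, None,                           # spacer
    "C", None, None, None, "C",                 # closing disulfide pair
)

EGF_UNIT_LENGTH = len(EGF_UNIT_LAYOUT)  # 27

#: One concrete instantiation of the layout, used as the canonical worked
#: example (26 aa variant with a tighter final spacer, equally grammar-valid).
CANONICAL_EGF_UNIT = "CANGGECIDSCRCPPGFTGARCEVNC"

#: Five-residue flank immediately N-terminal of an EGF repeat's first cysteine.
#: The calcium-binding flank carries the Asp/Asn consensus [DN]-x-[DN]-[EQ];
#: the neutral flank is built from residues that cannot satisfy it.
CB_FLANK = "DIDEG"
NONCB_FLANK = "GSSTG"
FLANK_LENGTH = 5

#: Synthetic LNR (LIN-12/Notch repeat) core, 32 aa.  Its cysteines sit in
#: adjacent pairs (positions 6,7 and 13,14) so no six-cysteine EGF spacing
#: chain can start or continue inside an LNR block.
LNR_TEMPLATE = "NRGSLTCCDSHGRCCNEAHSLPAWLSDGSVTE"

#: Synthetic NOD/NODP domain, cysteine-free, embedding the two conserved
#: NOD-internal motif scaffolds (motifs D and E of the pipeline's reports).
NOD_MOTIF_D = "FDNHGTWD"
NOD_MOTIF_E = "QPLEHPYQ"
NOD_TEMPLATE = (
    "GSAVT" + NOD_MOTIF_D + "ALKEHGSVRT" + NOD_MOTIF_E + "SLTPGKAVE"
)

#: Synthetic transmembrane, RAM, ankyrin, NLS and PEST stand-ins (all
#: cysteine-free so they are inert to the EGF caller).
TM_TEMPLATE = "LLVILGAVLLLIAGFVLLWF"
RAM_TEMPLATE = "MRKRRHGSLAEVQAMDTSGLKPMEHPWTGS"
NLS_TEMPLATE = "KRKRRPS"
ANK_TEMPLATE = "GHLDIVKLLLEAGADVNAQDKFGKTPLHVAAES"
PEST_TEMPLATE = "PESTSPESMTPSQITPESTLSPETSVPES"

#: PROSITE-style cysteine spacing grammar of an EGF-like repeat: six
#: cysteines forming three disulfide bonds (paired 1-3, 2-4, 5-6).
EGF_SPACING_PATTERN = "C-x(2,14)-C-x(1,10)-C-x(1,6)-C-x(2,14)-C-x(1,8)-C"

#: Built-in motif pattern strings.  A and B are the conserved EGF-internal
#: motifs; C (LNR core), D and E (NOD/NODP) ship as configurable patterns
#: matched to the synthetic templates above and are flagged experimental.
MOTIF_A_PATTERN = "CXNGGXC"
MOTIF_B_PATTERN = "CXCXXG[FY]XG"
MOTIF_C_PATTERN = "CCXXXGXCC"
MOTIF_D_PATTERN = "FDNHGXWD"
MOTIF_E_PATTERN = "QPXEHPXQ"
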