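"""Residue alphabet, integer encoding and substitution matrices.

The 20 canonical residues are indexed 0..19 in the order of the Gonnet matrix
alphabet; the ambiguity character ``X`` is code 20 and the gap ``-`` code 21.
Substitution scores involving ``X`` or a gap are zero, so ambiguous positions
neither reward nor penalise an alignment column.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
X_CODE = 20
GAP_CODE = 21
ALPHABET = AMINO_ACIDS + "X-"
N_SYMBOLS = len(ALPHABET)  # 22

_CODE_OF = {aa: i for i, aa in enumerate(ALPHABET)}


def encode(residues: str) -> np.ndarray:
    """Encode a residue (or gapped alignment row) string as uint8 codes."""
    try:
        return np.array([_CODE_OF[c] for c in residues], dtype=np.uint8)
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


def decode(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


@lru_cache(maxsize=None)
def gonnet_matrix() -> np.ndarray:
    """Gonnet-250 family substitution matrix as a 22x22 float32 array.

    Loaded from Biopython's GONNET1992 table (whose alphabet is exactly
    ``AMINO_ACIDS`` in our order) and padded with zero rows/columns for the
    ``X`` and gap codes.
    """
    from Bio.Align import substitution_matrices

    raw = substitution_matrices.load("GONNET1992")
    if str(raw.alphabet) != AMINO_ACIDS:  # pragma: no cover - library contract
        raise RuntimeError("unexpected GONNET1992 alphabet")
    full = np.zeros((N_SYMBOLS, N_SYMBOLS), dtype=np.float32)
    full[:20, :20] = np.asarray(raw, dtype=np.float32)
    return full


def get_matrix(name_or_matrix="gonnet250") -> np.ndarray:
    """Resolve a substitution matrix argument to a 22x22 float32 array."""
    if isinstance(name_or_matrix, np.ndarray):
        m = np.asarray(name_or_matrix, dtype=np.float32)
        if m.shape != (N_SYMBOLS, N_SYMBOLS):
            raise ValueError(f"substitution matrix must be {N_SYMBOLS}x{N_SYMBOLS}")
        return m
    name = str(name_or_matrix).lower()
    if name in {"gonnet", "gonnet250", "gonnet1992"}:
        return gonnet_matrix()
    from Bio.Align import substitution_matrices

    try:
        raw = substitution_matrices.load(str(name_or_matrix).upper())
    except Exception:
        raise ValueError(f"unknown substitution matrix {name_or_matrix!r}") from None
    order = str(raw.alphabet)
    full = np.zeros((N_SYMBOLS, N_SYMBOLS), dtype=np.float32)
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            if a in _CODE_OF and b in _CODE_OF:
                ia, ib = _CODE_OF[a], _CODE_OF[b]
                if ia < 20 and ib < 20:
                    full[ia, ib] = raw[i, j]
    return full
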