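"""FASTA / Clustal / Newick input and output."""

from __future__ import annotations

import os
from typing import Iterable, Optional

from Bio import SeqIO

from .records import SequenceRecord
from .tree import TreeNode

FASTA_WRAP = 60


def read_fasta(path) -> list[SequenceRecord]:
    """Read a protein FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and a single terminal stop ``*`` is stripped.
    Raises on an empty file, on duplicate ids (naming the id) and on
    non-amino-acid characters (with position).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(os.fspath(path), "fasta"):
        residues = str(entry.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        rec = SequenceRecord.from_defline(entry.description, residues)
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(rec)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, wrap: int = FASTA_WRAP) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.defline()}\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i : i + wrap] + "\n")


def read_alignment(path):
    """Read a gapped FASTA alignment into a MultipleAlignment."""
    from .align import MultipleAlignment

    ids: list[str] = []
    rows: list[str] = []
    for entry in SeqIO.parse(os.fspath(path), "fasta"):
        ids.append(entry.id)
        rows.append(str(entry.seq).upper())
    if not ids:
        raise ValueError(f"no alignment rows found in {path}")
    return MultipleAlignment(ids, rows)


def write_alignment_fasta(msa, path, wrap: int = FASTA_WRAP) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.ids, msa.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), wrap):
                fh.write(row[i : i + wrap] + "\n")


def write_clustal(msa, path, block: int = 60) -> None:
    """Clustal-style block layout for human inspection (no score line)."""
    width = max(len(i) for i in msa.ids) + 3
    with open(path, "w") as fh:
        fh.write("CLUSTAL-style alignment (notchkit)\n\n")
        for start in range(0, msa.n_columns, block):
            for rid, row in zip(msa.ids, msa.rows):
                fh.write(f"{rid:<{width}}{row[start : start + block]}\n")
            fh.write("\n")


def newick_string(tree: TreeNode, with_supports: bool = False) -> str:
    if tree.n_leaves() < 2:
        raise ValueError("Newick export requires a tree with at least 2 leaves")
    names = tree.leaf_names()
    if len(set(names)) != len(names):
        raise ValueError("Newick export requires unique leaf labels")
    return tree.newick(with_supports=with_supports)


def write_newick(tree: TreeNode, path, with_supports: bool = False) -> None:
    """Serialize a tree to Newick.

    Ultrametric trees get branch lengths ``parent height - child height``
    (raising if a child sits above its parent); guide trees use their stored
    branch lengths.  With ``with_supports``, bootstrap supports are written
    as internal-node labels.
    """
    with open(path, "w") as fh:
        fh.write(newick_string(tree, with_supports=with_supports) + "\n")
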