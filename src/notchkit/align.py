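"""Progressive multiple sequence alignment.

The recipe mirrors the classic progressive scheme: Gonnet-scored pairwise
global alignments give raw difference fractions (p-distances), a
neighbor-joining guide tree orders the merges, and profiles are aligned
profile-to-profile with frequency-weighted average substitution scores.
Gaps, once inserted, are never removed, and there is no iterative
refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from . import _engine
from .distmat import DistanceMatrix
from .matrices import GAP_CODE, N_SYMBOLS, decode, encode, get_matrix
from .records import SequenceRecord
from .tree import TreeNode, leaf

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5


def _residues_of(x) -> str:
    return x.residues if isinstance(x, SequenceRecord) else str(x)


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

@dataclass
class PairwiseAlignment:
    """A gapped pair of sequences with its affine-gap score."""

    aligned_a: str
    aligned_b: str
    score: float
    mode: str = "global"
    a_start: int = 0
    b_start: int = 0

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def identity(self) -> float:
        """Matched residues over aligned columns (no column is gap-gap)."""
        if not self.aligned_a:
            return 0.0
        matches = sum(
            a == b and a != "-" for a, b in zip(self.aligned_a, self.aligned_b)
        )
        return matches / len(self.aligned_a)


def pairwise_align(
    a,
    b,
    matrix="gonnet250",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    mode: str = "global",
) -> PairwiseAlignment:
    """Optimal affine-gap alignment of two sequences.

    ``mode`` is ``"global"`` (Needleman-Wunsch, end gaps penalised) or
    ``"local"`` (Smith-Waterman).  Traceback ties resolve diagonal > up >
    left, so the result is deterministic.
    """
    ra, rb = _residues_of(a), _residues_of(b)
    if not ra or not rb:
        raise ValueError("cannot align an empty sequence")
    if mode not in {"global", "local"}:
        raise ValueError(f"unknown alignment mode {mode!r}")
    M = get_matrix(matrix)
    ca, cb = encode(ra), encode(rb)
    score, a_idx, b_idx, (sa, sb) = _engine.align_encoded(
        ca, cb, M, gap_open, gap_extend, local=(mode == "local")
    )
    row_a = "".join(ra[i] if i >= 0 else "-" for i in a_idx)
    row_b = "".join(rb[j] if j >= 0 else "-" for j in b_idx)
    return PairwiseAlignment(row_a, row_b, score, mode=mode, a_start=sa, b_start=sb)


def pairwise_distance(
    a,
    b,
    matrix="gonnet250",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Raw difference fraction after global alignment.

    Counts mismatches over columns where neither sequence is gapped; raises
    if the optimal alignment leaves no comparable column.
    """
    aln = pairwise_align(a, b, matrix, gap_open, gap_extend, mode="global")
    comparable = 0
    mismatches = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != "-" and y != "-":
            comparable += 1
            if x != y:
                mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable (ungapped) columns between sequences")
    return mismatches / comparable


def p_distance_matrix(
    records: Sequence[SequenceRecord],
    matrix="gonnet250",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> DistanceMatrix:
    """All-pairs alignment-based p-distances (guide-tree input)."""
    M = get_matrix(matrix)
    codes = [encode(r.residues) for r in records]
    n = len(records)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, ai, bj, _ = _engine.align_encoded(
                codes[i], codes[j], M, gap_open, gap_extend
            )
            both = (ai >= 0) & (bj >= 0)
            if not np.any(both):
                raise ValueError(
                    f"no comparable columns between {records[i].id!r} "
                    f"and {records[j].id!r}"
                )
            mism = np.count_nonzero(
                codes[i][ai[both]] != codes[j][bj[both]]
            )
            D[i, j] = D[j, i] = mism / np.count_nonzero(both)
    return DistanceMatrix([r.id for r in records], D, kind="p_distance")


# ---------------------------------------------------------------------------
# neighbor-joining guide tree
# ---------------------------------------------------------------------------

def nj_guide_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree, midpoint-rooted for progressive ordering.

    Standard Q-criterion NJ with negative branch lengths clamped to zero;
    the unrooted result is rooted at the midpoint of the longest leaf-to-leaf
    path so profile merges proceed from the most similar sequences outward.
    """
    if dm.n < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    D = dm.values.astype(float).copy()
    if dm.n == 2:
        d = D[0, 1]
        for nd in nodes:
            nd.length = d / 2
        return TreeNode(children=nodes)

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        du = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        du = np.maximum(du, 0.0)
        D[i, :] = du
        D[:, i] = du
        D[i, i] = 0.0
        keep = [k for k in range(n) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    # join the last three around an unrooted central node
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    nodes[0].length = max(0.5 * (d01 + d02 - d12), 0.0)
    nodes[1].length = max(0.5 * (d01 + d12 - d02), 0.0)
    nodes[2].length = max(0.5 * (d02 + d12 - d01), 0.0)
    center = TreeNode(children=list(nodes))
    return _midpoint_root(center)


def _adjacency(root: TreeNode):
    adj: dict[int, list] = {}
    info: dict[int, TreeNode] = {}

    def walk(node: TreeNode) -> None:
        info[id(node)] = node
        adj.setdefault(id(node), [])
        for child in node.children:
            info[id(child)] = child
            adj.setdefault(id(child), [])
            w = child.length if child.length is not None else 0.0
            adj[id(node)].append((id(child), w))
            adj[id(child)].append((id(node), w))
            walk(child)

    walk(root)
    return adj, info


def _midpoint_root(root: TreeNode) -> TreeNode:
    """Reroot an unrooted (trifurcating) tree at its path midpoint."""
    adj, info = _adjacency(root)
    leaves = [nid for nid, node in info.items() if node.is_leaf]

    def paths_from(src: int):
        dist = {src: 0.0}
        prev: dict[int, int] = {src: src}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    prev[v] = u
                    stack.append(v)
        return dist, prev

    best = (-1.0, None, None, None)
    for a in leaves:
        dist, prev = paths_from(a)
        for b in leaves:
            if b != a and dist[b] > best[0]:
                best = (dist[b], a, b, prev)
    total, a, b, prev = best
    # walk from b back to a, finding the edge containing total/2 from a's side
    path = [b]
    while path[-1] != a:
        path.append(prev[path[-1]])
    path.reverse()  # a ... b
    half = total / 2
    acc = 0.0
    edge_w = {frozenset((u, v)): w for u in adj for v, w in adj[u]}
    u = path[0]
    for v in path[1:]:
        w = edge_w[frozenset((u, v))]
        if acc + w >= half - 1e-12:
            break
        acc += w
        u = v
    # midpoint sits on edge (u, v) at offset (half - acc) from u
    offset = min(max(half - acc, 0.0), edge_w[frozenset((u, v))])

    def build(nid: int, parent: Optional[int], length: float) -> TreeNode:
        src = info[nid]
        node = TreeNode(label=src.label, length=length)
        for v, w in adj[nid]:
            if v != parent:
                node.children.append(build(v, nid, w))
        return node

    w_uv = edge_w[frozenset((u, v))]
    new_root = TreeNode(
        children=[build(u, v, offset), build(v, u, w_uv - offset)]
    )
    return new_root


# ---------------------------------------------------------------------------
# multiple alignment container
# ---------------------------------------------------------------------------

class MultipleAlignment:
    """An aligned character matrix with row ids."""

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        self.ids = list(ids)
        self.rows = [r.upper() for r in rows]
        if not self.ids:
            raise ValueError("alignment must have at least one row")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("alignment row ids must be unique")
        ncols = len(self.rows[0])
        if any(len(r) != ncols for r in self.rows):
            raise ValueError("alignment rows must have equal length")
        self._codes: Optional[np.ndarray] = None

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def encoded(self) -> np.ndarray:
        if self._codes is None:
            self._codes = np.vstack([encode(r) for r in self.rows])
        return self._codes

    def degapped(self, row_id: str) -> str:
        return self.rows[self.ids.index(row_id)].replace("-", "")

    def subset(self, keep_ids: Iterable[str], drop_all_gap: bool = True):
        keep = list(keep_ids)
        idx = [self.ids.index(i) for i in keep]
        rows = [self.rows[i] for i in idx]
        sub = MultipleAlignment(keep, rows)
        if drop_all_gap:
            codes = sub.encoded()
            keep_cols = ~np.all(codes == GAP_CODE, axis=0)
            rows = ["".join(np.array(list(r))[keep_cols]) for r in sub.rows]
            sub = MultipleAlignment(keep, rows)
        return sub

    def project_pair(self, id_a: str, id_b: str) -> tuple:
        """The two rows with their mutual all-gap columns removed."""
        a = self.rows[self.ids.index(id_a)]
        b = self.rows[self.ids.index(id_b)]
        pairs = [(x, y) for x, y in zip(a, b) if not (x == "-" and y == "-")]
        return "".join(x for x, _ in pairs), "".join(y for _, y in pairs)

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


# ---------------------------------------------------------------------------
# progressive profile alignment
# ---------------------------------------------------------------------------

def _profile(block: np.ndarray) -> np.ndarray:
    """Column frequency profile (n_columns x 22) of an encoded row block."""
    ncols = block.shape[1]
    prof = np.zeros((ncols, N_SYMBOLS), dtype=np.float32)
    for row in block:
        prof[np.arange(ncols), row] += 1.0
    prof /= np.float32(block.shape[0])
    return prof


def _merge_blocks(block_a, block_b, M, gap_open, gap_extend):
    Pa = _profile(block_a)
    Pb = _profile(block_b)
    S = (Pa @ M) @ Pb.T
    _, a_idx, b_idx, _ = _engine.align_score_matrix(S, gap_open, gap_extend)
    ncols = len(a_idx)
    out_a = np.full((block_a.shape[0], ncols), GAP_CODE, dtype=np.uint8)
    out_b = np.full((block_b.shape[0], ncols), GAP_CODE, dtype=np.uint8)
    mask_a = a_idx >= 0
    mask_b = b_idx >= 0
    out_a[:, mask_a] = block_a[:, a_idx[mask_a]]
    out_b[:, mask_b] = block_b[:, b_idx[mask_b]]
    return np.vstack([out_a, out_b])


def progressive_msa(
    records: Sequence[SequenceRecord],
    guide_tree: Optional[TreeNode] = None,
    matrix="gonnet250",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MultipleAlignment:
    """Guide-tree-ordered progressive profile alignment.

    Without an explicit guide tree, all-pairs p-distances feed a
    neighbor-joining tree first.  Profile columns are scored by the
    frequency-weighted average substitution score; row order of the result
    equals the input order.
    """
    records = list(records)
    if not records:
        raise ValueError("no sequences to align")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    if len(records) == 1:
        return MultipleAlignment(ids, [records[0].residues])
    by_id = {r.id: r for r in records}

    if guide_tree is None:
        dm = p_distance_matrix(records, matrix, gap_open, gap_extend)
        guide_tree = nj_guide_tree(dm)
    tree_ids = set(guide_tree.leaf_names())
    if tree_ids != set(ids):
        raise ValueError("guide tree leaves do not match record ids")

    M = get_matrix(matrix)

    def merge(node: TreeNode):
        if node.is_leaf:
            rec = by_id[node.label]
            if not rec.residues:
                raise ValueError(f"empty sequence {rec.id!r}")
            return [node.label], encode(rec.residues)[None, :]
        child_results = [merge(c) for c in node.children]
        ids_acc, block_acc = child_results[0]
        for ids_next, block_next in child_results[1:]:
            block_acc = _merge_blocks(block_acc, block_next, M, gap_open, gap_extend)
            ids_acc = ids_acc + ids_next
        return ids_acc, block_acc

    out_ids, block = merge(guide_tree)
    order = [out_ids.index(i) for i in ids]
    rows = [decode(block[k]) for k in order]
    msa = MultipleAlignment(ids, rows)
    for rec in records:  # degap identity safety net
        if msa.degapped(rec.id) != rec.residues:
            raise AssertionError("progressive alignment corrupted a sequence")
    return msa


# ---------------------------------------------------------------------------
# consensus and conservation
# ---------------------------------------------------------------------------

@dataclass
class ColumnStats:
    modal_residue: Optional[str]
    modal_freq: float
    top2_residues: str
    top2_freq: float
    gap_fraction: float


@dataclass
class ConservationProfile:
    """Per-column modal residue / top-2 bookkeeping of an alignment.

    Frequencies are gap-excluded; an all-gap column has modal residue
    ``None`` and gap fraction 1.0.
    """

    columns: list

    def __len__(self) -> int:
        return len(self.columns)

    def __getitem__(self, j: int) -> ColumnStats:
        return self.columns[j]


def conservation_profile(msa: MultipleAlignment) -> ConservationProfile:
    codes = msa.encoded()
    n_rows = codes.shape[0]
    cols: list[ColumnStats] = []
    from .matrices import ALPHABET

    for j in range(msa.n_columns):
        col = codes[:, j]
        gaps = int(np.count_nonzero(col == GAP_CODE))
        gap_fraction = gaps / n_rows
        residues = col[col != GAP_CODE]
        if residues.size == 0:
            cols.append(ColumnStats(None, 0.0, "", 0.0, 1.0))
            continue
        counts = np.bincount(residues, minlength=N_SYMBOLS)[: GAP_CODE]
        total = residues.size
        # order residues by descending count, ties alphabetical
        present = np.nonzero(counts)[0]
        ranked = sorted(present, key=lambda c: (-counts[c], ALPHABET[c]))
        modal = ranked[0]
        top2 = ranked[:2]
        cols.append(
            ColumnStats(
                modal_residue=ALPHABET[modal],
                modal_freq=counts[modal] / total,
                top2_residues="".join(sorted(ALPHABET[c] for c in top2)),
                top2_freq=sum(counts[c] for c in top2) / total,
                gap_fraction=gap_fraction,
            )
        )
    return ConservationProfile(cols)


def consensus(msa: MultipleAlignment, gap_rule_threshold: float = 0.5) -> str:
    """Majority-residue consensus.

    Columns whose gap fraction exceeds ``gap_rule_threshold`` are omitted;
    elsewhere the modal gap-excluded residue wins, ties alphabetical.
    """
    profile = conservation_profile(msa)
    out = []
    for stats in profile.columns:
        if stats.gap_fraction > gap_rule_threshold or stats.modal_residue is None:
            continue
        out.append(stats.modal_residue)
    return "".join(out)
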