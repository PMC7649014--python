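"""Distance phylogenetics: protein Jukes-Cantor distances, UPGMA trees,
threshold clustering and bootstrap clade supports.

Two distance recipes coexist in the pipeline, mirroring their different
roles: the guide tree of the aligner uses raw p-distances, while the family
phylogeny and clustering use the 20-state ("protein-adapted") Jukes-Cantor
multiple-hit correction

    d = -(19/20) * ln(1 - 20 p / 19),

which diverges as p approaches its saturation bound 19/20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .align import MultipleAlignment, consensus as _consensus, progressive_msa
from .distmat import DistanceMatrix
from .matrices import GAP_CODE
from .records import SequenceRecord
from .tree import TreeNode, leaf

logger = logging.getLogger(__name__)

JC_SATURATION = 19.0 / 20.0


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def jc_protein_distance(p):
    """20-state Jukes-Cantor correction of a difference fraction.

    Accepts a scalar or array with 0 <= p < 19/20; raises on saturated
    values where the corrected distance is undefined.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(arr < 0):
        raise ValueError("p-distance cannot be negative")
    if np.any(arr >= JC_SATURATION):
        raise ValueError(
            "p-distance at or beyond 19/20: Jukes-Cantor distance is undefined "
            "(saturated pair)"
        )
    d = -JC_SATURATION * np.log1p(-arr / JC_SATURATION)
    return float(d) if np.isscalar(p) else d


def msa_distance_matrix(
    msa: MultipleAlignment,
    kind: str = "jc_protein",
    clamp_saturated: bool = False,
) -> DistanceMatrix:
    """Pairwise distances over the shared alignment (pairwise deletion).

    For each pair, p = mismatches / columns where neither row is gapped.
    ``kind="jc_protein"`` applies the 20-state correction entrywise; with
    ``clamp_saturated`` saturated pairs receive the largest finite corrected
    distance in the matrix (logged) instead of raising.
    """
    if msa.n_rows < 2:
        raise ValueError("distance matrix needs at least 2 rows")
    if kind not in {"p_distance", "jc_protein"}:
        raise ValueError(f"unknown distance kind {kind!r}")
    codes = msa.encoded()
    present = codes != GAP_CODE
    n = msa.n_rows
    P = np.zeros((n, n))
    for i in range(n):
        both = present[i] & present[i + 1 :]
        comparable = both.sum(axis=1)
        if np.any(comparable == 0):
            j = int(np.nonzero(comparable == 0)[0][0]) + i + 1
            raise ValueError(
                f"rows {msa.ids[i]!r} and {msa.ids[j]!r} share no comparable columns"
            )
        mism = np.count_nonzero((codes[i] != codes[i + 1 :]) & both, axis=1)
        P[i, i + 1 :] = mism / comparable
    P = P + P.T
    if kind == "p_distance":
        return DistanceMatrix(list(msa.ids), P, kind=kind)
    saturated = P >= JC_SATURATION
    if saturated.any():
        if not clamp_saturated:
            i, j = map(int, np.argwhere(saturated)[0])
            raise ValueError(
                f"saturated pair {msa.ids[i]!r}/{msa.ids[j]!r} (p={P[i, j]:.4f} "
                ">= 19/20); rerun with clamp_saturated=True to cap it"
            )
        finite = jc_protein_distance(P[~saturated])
        cap = float(finite.max()) if finite.size else 0.0
        D = np.zeros_like(P)
        D[~saturated] = finite
        D[saturated] = cap
        np.fill_diagonal(D, 0.0)
        logger.warning(
            "clamped %d saturated pairs to %.4f", int(saturated.sum() // 2), cap
        )
    else:
        D = jc_protein_distance(P)
    return DistanceMatrix(list(msa.ids), D, kind="jc_protein")


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> TreeNode:
    """Unweighted pair-group (arithmetic mean) agglomeration.

    Iteratively merges the closest pair of clusters at height d/2; distances
    to the merged cluster are size-weighted averages, which equals the plain
    average over all member leaves of the original matrix.  Ties resolve to
    the smallest (i, j) in the current cluster ordering, and the merged
    cluster takes position i.
    """
    if dm.n < 2:
        raise ValueError("UPGMA needs at least 2 taxa")
    nodes: list[TreeNode] = [leaf(l) for l in dm.labels]
    sizes = [1] * dm.n
    D = dm.values.astype(float).copy()
    while len(nodes) > 1:
        n = len(nodes)
        work = D.copy()
        work[np.tril_indices(n)] = np.inf
        i, j = np.unravel_index(int(np.argmin(work)), work.shape)
        height = D[i, j] / 2.0
        parent = TreeNode(children=[nodes[i], nodes[j]], height=height)
        ni, nj = sizes[i], sizes[j]
        merged = (ni * D[i, :] + nj * D[j, :]) / (ni + nj)
        D[i, :] = merged
        D[:, i] = merged
        D[i, i] = 0.0
        keep = [k for k in range(n) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        sizes[i] = ni + nj
        del nodes[j]
        del sizes[j]
    return nodes[0]


# ---------------------------------------------------------------------------
# threshold clustering
# ---------------------------------------------------------------------------

@dataclass
class Clustering:
    """A cut of an ultrametric tree into clusters of leaves."""

    assignments: dict
    threshold: float
    clusters: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.clusters:
            groups: dict[int, list] = {}
            for label, cid in self.assignments.items():
                groups.setdefault(cid, []).append(label)
            self.clusters = [sorted(groups[c]) for c in sorted(groups)]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cut_tree(tree: TreeNode, height: float) -> Clustering:
    """Clusters = maximal subtrees whose root height is strictly below ``height``.

    A leaf not contained in any such subtree (including every leaf when the
    threshold is 0) forms a singleton cluster.
    """
    if height < 0:
        raise ValueError("cut height must be non-negative")
    clusters: list[list] = []

    def walk(node: TreeNode) -> None:
        h = node.height if node.height is not None else 0.0
        if h < height:
            clusters.append(sorted(node.leaf_names()))
            return
        if node.is_leaf:  # only reachable when height <= leaf height (0)
            clusters.append([node.label])
            return
        for child in node.children:
            walk(child)

    walk(tree)
    assignments = {
        label: cid for cid, members in enumerate(clusters) for label in members
    }
    return Clustering(assignments=assignments, threshold=height, clusters=clusters)


def merge_heights(tree: TreeNode) -> np.ndarray:
    """Sorted heights of the internal (merge) nodes."""
    hs = sorted(n.height for n in tree.postorder() if not n.is_leaf)
    return np.asarray(hs, dtype=float)


def auto_threshold(tree: TreeNode) -> float:
    """Midpoint of the largest gap between consecutive sorted merge heights.

    Deterministic: on ties the lowest gap wins.  Requires at least 3 leaves
    (two merges) for a gap to exist.
    """
    if tree.n_leaves() < 3:
        raise ValueError("auto threshold needs at least 3 leaves")
    hs = merge_heights(tree)
    gaps = np.diff(hs)
    k = int(np.argmax(gaps))  # argmax returns the first (lowest) maximal gap
    return float((hs[k] + hs[k + 1]) / 2.0)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _default_builder(kind: str = "jc_protein") -> Callable:
    def build(msa: MultipleAlignment) -> TreeNode:
        return upgma(msa_distance_matrix(msa, kind=kind))

    return build


def bootstrap_support(
    msa: MultipleAlignment,
    n_replicates: int = 100,
    seed: int = 0,
    tree_builder: Optional[Callable] = None,
    max_retries: int = 10,
) -> TreeNode:
    """Column-resampling bootstrap supports on the reference UPGMA tree.

    Support of each internal node is the percentage of replicates whose tree
    contains a clade with the same leaf set (rooted-clade comparison, which
    matches UPGMA's rooted output).  Replicate r draws from a generator
    seeded ``seed + r``; a replicate whose resampled columns leave some pair
    with no comparable column is redrawn (up to ``max_retries`` times).
    """
    if n_replicates < 1:
        raise ValueError("need at least one bootstrap replicate")
    builder = tree_builder or _default_builder()
    reference = builder(msa)
    clades = [n for n in reference.postorder() if not n.is_leaf]
    clade_sets = [n.leaf_set() for n in clades]
    hits = np.zeros(len(clades))
    ncols = msa.n_columns
    for r in range(n_replicates):
        rng = np.random.default_rng(seed + r)
        tree = None
        for attempt in range(max_retries):
            cols = rng.integers(0, ncols, size=ncols)
            rows = ["".join(row[c] for c in cols) for row in msa.rows]
            try:
                tree = builder(MultipleAlignment(list(msa.ids), rows))
                break
            except ValueError as exc:
                logger.info("replicate %d redrawn (%s)", r, exc)
        else:
            raise ValueError(
                f"bootstrap replicate {r} failed after {max_retries} redraws"
            )
        rep_sets = {n.leaf_set() for n in tree.postorder() if not n.is_leaf}
        for k, cs in enumerate(clade_sets):
            if cs in rep_sets:
                hits[k] += 1
    for node, h in zip(clades, hits):
        node.support = 100.0 * h / n_replicates
    return reference


# ---------------------------------------------------------------------------
# consensus-level ("specialized") phylogeny
# ---------------------------------------------------------------------------

def specialized_phylogeny(
    cluster_msas: dict,
    extra_sequences: Sequence[SequenceRecord] = (),
    n_replicates: int = 100,
    seed: int = 0,
    gap_rule_threshold: float = 0.5,
    matrix="gonnet250",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> TreeNode:
    """Bootstrapped UPGMA tree over per-cluster consensus sequences.

    Each cluster contributes the consensus of its member alignment; the
    consensus records plus any extra homolog records are re-aligned, JC
    distances computed, and UPGMA with bootstrap supports run on the
    consensus-level alignment.
    """
    if len(cluster_msas) < 2:
        raise ValueError("specialized phylogeny needs at least 2 clusters")
    reps: list[SequenceRecord] = []
    for name, msa in cluster_msas.items():
        if msa.n_rows < 1:
            raise ValueError(f"cluster {name!r} has no members")
        cons = _consensus(msa, gap_rule_threshold)
        if not cons:
            raise ValueError(f"cluster {name!r} has an empty consensus")
        reps.append(SequenceRecord(id=name, residues=cons,
                                   description="cluster consensus"))
    reps.extend(extra_sequences)
    cons_msa = progressive_msa(reps, matrix=matrix, gap_open=gap_open,
                               gap_extend=gap_extend)
    return bootstrap_support(cons_msa, n_replicates=n_replicates, seed=seed)
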