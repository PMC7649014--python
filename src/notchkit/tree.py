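"""Rooted tree structure shared by the guide-tree and phylogeny code.

Two flavours live in the same node type: guide trees built by
neighbor-joining carry explicit branch ``length``s, while UPGMA trees are
ultrametric and carry node ``height``s (leaves at height 0); branch lengths
of an ultrametric tree are derived as parent height minus child height.
"""

from __future__ import annotations

from typing import Iterator, Optional


class TreeNode:
    __slots__ = ("children", "label", "height", "length", "support")

    def __init__(
        self,
        children: Optional[list] = None,
        label: Optional[str] = None,
        height: Optional[float] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ):
        self.children: list[TreeNode] = children or []
        self.label = label
        self.height = height
        self.length = length
        self.support = support

    # -- traversal -------------------------------------------------------
    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self) -> Iterator["TreeNode"]:
        for node in self.postorder():
            if node.is_leaf:
                yield node

    def leaf_names(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def leaf_set(self) -> frozenset:
        return frozenset(self.leaf_names())

    def n_leaves(self) -> int:
        return sum(1 for _ in self.leaves())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<TreeNode {self.newick()}>"

    # -- geometry --------------------------------------------------------
    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        """True if node heights are consistent (leaves 0, parents above children)."""
        for node in self.postorder():
            if node.height is None:
                return False
            if node.is_leaf and abs(node.height) > tol:
                return False
            for child in node.children:
                if child.height is None or child.height > node.height + tol:
                    return False
        return True

    def branch_length_to(self, child: "TreeNode") -> float:
        """Branch length of the edge down to ``child``."""
        if self.height is not None and child.height is not None:
            length = self.height - child.height
            if length < -1e-9:
                raise ValueError(
                    f"non-ultrametric heights: child at {child.height} above "
                    f"parent at {self.height}"
                )
            return max(length, 0.0)
        if child.length is None:
            raise ValueError("tree has neither heights nor branch lengths")
        return child.length

    def leaf_depths(self) -> dict:
        """Map leaf label -> path length from this node (root)."""
        depths: dict[str, float] = {}

        def walk(node: TreeNode, acc: float) -> None:
            if node.is_leaf:
                depths[node.label] = acc
            for child in node.children:
                walk(child, acc + node.branch_length_to(child))

        walk(self, 0.0)
        return depths

    def tip_distances(self) -> dict:
        """All leaf-pair path lengths as {(a, b): distance} with a < b."""
        dist: dict[tuple, float] = {}

        def walk(node: TreeNode) -> dict:
            if node.is_leaf:
                return {node.label: 0.0}
            below: list[dict] = []
            for child in node.children:
                sub = walk(child)
                edge = node.branch_length_to(child)
                below.append({k: v + edge for k, v in sub.items()})
            merged: dict[str, float] = {}
            for i, di in enumerate(below):
                for j in range(i + 1, len(below)):
                    for a, da in di.items():
                        for b, db in below[j].items():
                            key = (a, b) if a < b else (b, a)
                            dist[key] = da + db
                merged.update(di)
            return merged

        walk(self)
        return dist

    # -- serialisation ---------------------------------------------------
    def newick(self, with_supports: bool = False, fmt: str = ".17g") -> str:
        """Newick string; labels containing whitespace are single-quoted."""

        def quote(label: str) -> str:
            if label is None:
                return ""
            if any(c in label for c in " \t(),:;[]'"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def render(node: TreeNode, parent: Optional[TreeNode]) -> str:
            if node.is_leaf:
                body = quote(node.label)
            else:
                inner = ",".join(render(c, node) for c in node.children)
                tag = ""
                if with_supports and node.support is not None:
                    tag = format(node.support, "g")
                elif node.label:
                    tag = quote(node.label)
                body = f"({inner}){tag}"
            if parent is None:
                return body
            return f"{body}:{format(parent.branch_length_to(node), fmt)}"

        return render(self, None) + ";"


def leaf(label: str, height: float = 0.0) -> TreeNode:
    return TreeNode(label=label, height=height)
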