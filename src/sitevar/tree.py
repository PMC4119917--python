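"""Lightweight phylogenetic tree type plus Newick I/O.

The tree is a plain recursive node structure carrying names and branch
lengths in expected substitutions per site. Newick parsing is delegated to
dendropy; writing is a direct recursive serialization. Tree *construction*
(NJ, UPGMA) lives in :mod:`sitevar.phylo`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to the parent; 0 at the root
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0  # distance above the leaves for ultrametric trees

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]


@dataclass
class PhyloTree:
    root: TreeNode

    def __post_init__(self) -> None:
        for node in self.root.postorder():
            if node.length < 0 or node.length != node.length:
                raise ValueError(
                    f"negative or non-finite branch length at {node.name!r}"
                )

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.root.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def total_length(self) -> float:
        return sum(n.length for n in self.root.postorder() if n is not self.root)

    def leaf_depths(self) -> dict[str, float]:
        """Root-to-leaf path lengths."""
        depths = {}

        def walk(node: TreeNode, d: float) -> None:
            d += node.length
            if node.is_leaf:
                depths[node.name] = d
            for c in node.children:
                walk(c, d)

        walk(self.root, -self.root.length)
        return depths

    def scale(self, factor: float) -> "PhyloTree":
        """Return a copy with every branch length multiplied by ``factor``."""

        def copy(node: TreeNode) -> TreeNode:
            return TreeNode(
                node.name, node.length * factor,
                [copy(c) for c in node.children], node.height * factor,
            )

        return PhyloTree(copy(self.root))


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string with branch lengths.

    Unbalanced parentheses raise a ``ValueError`` reporting the character
    position of the mismatch.
    """
    stack = []
    for pos, c in enumerate(text):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced parentheses at position {pos}")
            stack.pop()
    if stack:
        raise ValueError(f"unbalanced parentheses at position {stack[-1]}")
    dtree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )

    def convert(dnode) -> TreeNode:
        name = dnode.taxon.label if dnode.taxon else (dnode.label or None)
        length = dnode.edge.length if dnode.edge.length is not None else 0.0
        return TreeNode(name, float(length), [convert(c) for c in dnode.child_nodes()])

    return PhyloTree(convert(dtree.seed_node))


def write_newick(tree: PhyloTree) -> str:
    """Serialize to Newick with branch lengths at 10 significant digits."""

    def render(node: TreeNode, top: bool) -> str:
        if node.is_leaf:
            body = node.name or ""
        else:
            body = "(" + ",".join(render(c, False) for c in node.children) + ")"
            if node.name:
                body += node.name
        if top:
            return body
        return f"{body}:{node.length:.10g}"

    return render(tree.root, True) + ";"
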