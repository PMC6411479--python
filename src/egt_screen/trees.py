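"""Phylogenetic tree container and Newick round-trip.

The tree structure is deliberately small: nodes with parent links, branch
lengths, and integer bootstrap supports stored on the child node of the edge
they annotate (the standard Newick convention, which keeps support/bipartition
pairing unambiguous under re-rooting).  Leaves optionally carry the taxon and
taxon-role metadata used by the provenance classifier.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

__all__ = ["Node", "PhyloTree", "read_newick", "write_newick", "NewickError"]


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset when known."""


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None
    # leaf metadata, populated by callers that know the proteome context
    taxon: str | None = None
    role: str | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class PhyloTree:
    """Rooted or unrooted tree. Unrooted trees use a (typically trifurcating)
    placeholder root node; ``rooted`` records which interpretation applies."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = [lf.name for lf in self.leaves()]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf names in tree: {dup}")

    # -- traversal -----------------------------------------------------------

    def postorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    # -- bipartitions --------------------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions as the smaller-side-canonicalized leaf set
        of each internal edge (root edge excluded)."""
        all_leaves = frozenset(self.leaf_names())
        parts: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf():
                below[id(node)] = frozenset([node.name])
            else:
                s = frozenset().union(*(below[id(c)] for c in node.children))
                below[id(node)] = s
                if node.parent is not None and 1 < len(s) < len(all_leaves) - 1:
                    other = all_leaves - s
                    parts.add(min(s, other, key=lambda x: (len(x), sorted(x))))
        return parts

    def clade_leafset(self, node: Node) -> frozenset[str]:
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf():
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def copy(self) -> "PhyloTree":
        def rec(n: Node) -> Node:
            m = Node(n.name, n.length, n.support, taxon=n.taxon, role=n.role)
            for c in n.children:
                m.add(rec(c))
            return m

        return PhyloTree(rec(self.root), rooted=self.rooted)

    def __repr__(self):
        return f"PhyloTree({len(self.leaves())} leaves, rooted={self.rooted})"


def _check_balanced(text: str) -> None:
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickError(f"unbalanced ')' at character offset {i}")
    if depth != 0:
        raise NewickError(
            f"unbalanced parentheses: {depth} unclosed '(' at end of input"
        )


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string.  Integer internal-node labels in [0, 100] are
    interpreted as bootstrap supports on the subtending edge; missing branch
    lengths default to 0."""
    _check_balanced(text)
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(name=name)
        else:
            node = Node()
            label = dnode.label
            if label is not None:
                try:
                    val = int(label)
                except ValueError:
                    val = None
                if val is not None and 0 <= val <= 100:
                    node.support = val
                else:
                    node.name = label
        node.length = dnode.edge.length if dnode.edge.length is not None else 0.0
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    root = convert(dtree.seed_node)
    rooted = len(root.children) == 2
    return PhyloTree(root, rooted=rooted)


def write_newick(tree: PhyloTree, lengths: bool = True) -> str:
    buf = io.StringIO()

    def rec(node: Node) -> None:
        if node.is_leaf():
            buf.write(node.name or "")
        else:
            buf.write("(")
            for i, c in enumerate(node.children):
                if i:
                    buf.write(",")
                rec(c)
            buf.write(")")
            if node.support is not None:
                buf.write(str(node.support))
            elif node.name:
                buf.write(node.name)
        if node.parent is not None and lengths:
            buf.write(f":{node.length:.10g}")

    rec(tree.root)
    buf.write(";")
    return buf.getvalue()
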