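"""Lightweight rooted trees for dynamic-programming algorithms.

The phylogenetic algorithms in this package (Sankoff parsimony, pruning
likelihoods, branch-event painting) all walk a rooted tree in postorder and
index per-node arrays.  This module provides a minimal node structure tuned
for that access pattern.  Newick text is parsed with dendropy and converted;
writing is done directly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy

__all__ = ["Node", "Tree"]


@dataclass
class Node:
    name: str | None = None
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Tree:
    """A rooted (not necessarily binary) tree with uniquely named nodes."""

    def __init__(self, root: Node):
        self.root = root
        self.root.parent = None
        for node in self.postorder():
            for child in node.children:
                child.parent = node
        self._autoname()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dt = dendropy.Tree.get(data=text, schema="newick",
                               preserve_underscores=True,
                               suppress_internal_node_taxa=False)

        def convert(dn) -> Node:
            label = None
            if dn.taxon is not None:
                label = dn.taxon.label
            elif dn.label:
                label = dn.label
            node = Node(name=label,
                        length=dn.edge.length if dn.edge.length else 0.0)
            for c in dn.child_nodes():
                node.add(convert(c))
            return node

        return cls(convert(dt.seed_node))

    def _autoname(self) -> None:
        seen = set()
        counter = itertools.count()
        for node in self.postorder():
            if node.name is None or node.name in seen:
                name = f"nd{next(counter)}"
                while name in seen:
                    name = f"nd{next(counter)}"
                node.name = name
            seen.add(node.name)

    # -- traversal ----------------------------------------------------------

    def postorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def preorder(self) -> list[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def node(self, name: str) -> Node:
        for n in self.postorder():
            if n.name == name:
                return n
        raise KeyError(f"no node named {name!r}")

    def has_node(self, name: str) -> bool:
        return any(n.name == name for n in self.postorder())

    def leaves_under(self, name: str) -> list[str]:
        return [n.name for n in self._subtree_postorder(self.node(name))
                if n.is_leaf]

    @staticmethod
    def _subtree_postorder(node: Node) -> list[Node]:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(n.children)
        out.reverse()
        return out

    def mrca(self, names: set[str]) -> Node:
        """Deepest node whose descendant leaves include all of *names*."""
        best = self.root
        for node in self.preorder():
            under = {l.name for l in self._subtree_postorder(node)
                     if l.is_leaf}
            if names <= under:
                best = node
        return best

    # -- output -------------------------------------------------------------

    def newick(self, lengths: bool = True, internal_labels: bool = True,
               fmt: str = "%.6g") -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                body = _quote(node.name)
            else:
                body = "(" + ",".join(rec(c) for c in node.children) + ")"
                if internal_labels:
                    body += _quote(node.name)
            if lengths and node.parent is not None:
                body += ":" + (fmt % node.length)
            return body

        return rec(self.root) + ";"

    def copy(self) -> "Tree":
        return Tree.from_newick(self.newick())

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Tree {len(self.leaves())} leaves>"


_UNSAFE = set(" ,():;[]'")


def _quote(name: str) -> str:
    if any(ch in _UNSAFE for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name
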