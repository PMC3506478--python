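"""Rooted-representation phylogenetic trees with Newick I/O (dendropy-backed).

Trees are stored with parent pointers and per-node branch lengths; a basal
multifurcation at the root carries unrooted semantics.  Internal node labels
hold support values when present.
"""

from __future__ import annotations

import io

import dendropy


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("name", "length", "children", "parent", "support")

    def __init__(self, name=None, length=None, support=None):
        self.name = name
        self.length = length
        self.children: list["Node"] = []
        self.parent: "Node | None" = None
        self.support = support

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Leaf-labelled tree with branch lengths and optional support values."""

    def __init__(self, root: Node):
        self.root = root
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise TreeError("duplicate leaf labels")
        for node in self.postorder():
            if node is not self.root and node.length is not None and node.length < 0:
                raise TreeError(f"negative branch length on {node.name or 'internal node'}")

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out[::-1]

    def preorder(self):
        return list(reversed(self.postorder()))

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self):
        return [n.name for n in self.leaves()]

    def branches(self):
        """All non-root nodes (each owns the branch to its parent)."""
        return [n for n in self.postorder() if n.parent is not None]

    def copy(self) -> "PhyloTree":
        def clone(node):
            c = Node(node.name, node.length, node.support)
            for ch in node.children:
                c.add_child(clone(ch))
            return c
        return PhyloTree(clone(self.root))

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.branches())

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the frozenset of leaf names on the
        child side, canonicalized to the smaller-by-sorted-order side."""
        all_leaves = frozenset(self.leaf_names())
        splits = set()
        for node in self.postorder():
            if node.parent is None or node.is_leaf:
                continue
            side = frozenset(l.name for l in _subtree_leaves(node))
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            splits.add(min(side, other, key=lambda s: tuple(sorted(s))))
        return splits

    # -- newick ------------------------------------------------------------
    def to_newick(self, support_as_labels: bool = True) -> str:
        def fmt(node):
            if node.is_leaf:
                s = node.name or ""
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = ""
                if support_as_labels and node.support is not None:
                    label = f"{node.support:g}"
                elif node.name:
                    label = node.name
                s = f"({inner}){label}"
            if node.length is not None:
                s += f":{node.length:.10g}"
            return s
        return fmt(self.root) + ";"

    def __str__(self) -> str:
        return self.to_newick()


def _subtree_leaves(node: Node):
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    def convert(dnode) -> Node:
        if dnode.is_leaf():
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = Node(name=name, length=dnode.edge.length)
        else:
            support = None
            label = dnode.label
            if label is not None:
                try:
                    support = float(label)
                    label = None
                except ValueError:
                    pass
            node = Node(name=label, length=dnode.edge.length, support=support)
        for ch in dnode.child_nodes():
            node.add_child(convert(ch))
        return node

    return PhyloTree(convert(dtree.seed_node))


def parse_newick(text: str) -> PhyloTree:
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"invalid Newick: {exc}") from exc
    return _from_dendropy(dtree)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
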