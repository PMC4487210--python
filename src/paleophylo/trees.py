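"""Lightweight phylogenetic tree structure shared by all analysis modules.

A :class:`Tree` is a rooted data structure; unrooted semantics are obtained
by treating the root as an unlabeled hub (degree >= 3) and ignoring its
placement.  Edges are identified with the node below them, which gives every
branch of the unrooted topology a stable handle for placement scans.

Newick parsing is delegated to dendropy (quoted labels, comments, the usual
dialect corner cases); writing is done directly so that branch lengths
round-trip at full precision.
"""

from __future__ import annotations

import io as _io
from typing import Iterator, Sequence

import dendropy

__all__ = ["Node", "Tree", "TreeSample"]


class Node:
    """Tree node; ``length`` is the branch above, ``None`` for the root."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def remove_child(self, node: "Node") -> None:
        self.children.remove(node)
        node.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} len={self.length}>"


class Tree:
    """Rooted container; a degree-2 root marks an explicitly rooted tree,
    a root of degree >= 3 an unrooted one."""

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=False,
        )
        return cls.from_dendropy(dtree)

    @classmethod
    def from_dendropy(cls, dtree: "dendropy.Tree") -> "Tree":
        def build(dnode) -> Node:
            label = None
            if dnode.taxon is not None:
                label = dnode.taxon.label
            elif dnode.label:
                label = dnode.label
            node = Node(label=label, length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(build(child))
            return node

        root = build(dtree.seed_node)
        root.length = None
        return cls(root)

    def to_dendropy(
        self, taxon_namespace: "dendropy.TaxonNamespace | None" = None
    ) -> "dendropy.Tree":
        ns = taxon_namespace or dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=ns)

        def build(node: Node, dnode) -> None:
            for child in node.children:
                dchild = dnode.new_child(edge_length=child.length)
                if child.is_leaf:
                    dchild.taxon = ns.require_taxon(label=child.label)
                elif child.label:
                    dchild.label = child.label
                build(child, dchild)

        if self.root.label and self.root.is_leaf:
            dtree.seed_node.taxon = ns.require_taxon(label=self.root.label)
        build(self.root, dtree.seed_node)
        dtree.is_rooted = self.is_rooted
        return dtree

    def to_newick(self, precision: int = 12) -> str:
        out = _io.StringIO()

        def needs_quotes(label: str) -> bool:
            return any(c in label for c in " ()[]{}:;,'\t\n")

        def fmt_label(label: str) -> str:
            if needs_quotes(label):
                return "'" + label.replace("'", "''") + "'"
            return label

        def write(node: Node) -> None:
            if node.children:
                out.write("(")
                for i, child in enumerate(node.children):
                    if i:
                        out.write(",")
                    write(child)
                out.write(")")
                if node.label:
                    out.write(fmt_label(node.label))
            else:
                out.write(fmt_label(node.label or ""))
            if node.length is not None:
                out.write(f":{node.length:.{precision}g}")

        write(self.root)
        out.write(";")
        return out.getvalue()

    # ---------------------------------------------------------- traversal
    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def edges(self) -> list[Node]:
        """All branches of the unrooted topology, as the nodes below them.

        For a rooted (degree-2 root) tree the two root-adjacent branches
        form a single unrooted edge; only the first root child is reported
        for that edge.
        """
        nodes = [n for n in self.postorder() if n is not self.root]
        if self.is_rooted and len(self.root.children) == 2:
            nodes.remove(self.root.children[1])
        return nodes

    def internal_edges(self) -> list[Node]:
        return [n for n in self.edges() if not n.is_leaf]

    # ---------------------------------------------------------- predicates
    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    @property
    def n_leaves(self) -> int:
        return sum(1 for n in self.postorder() if n.is_leaf)

    def is_binary(self) -> bool:
        limit = 2 if self.is_rooted else 3
        if len(self.root.children) > limit:
            return False
        return all(
            len(n.children) in (0, 2)
            for n in self.postorder()
            if n is not self.root
        )

    def find(self, label: str) -> Node:
        for node in self.postorder():
            if node.label == label:
                return node
        raise KeyError(f"no node labelled {label!r}")

    # ---------------------------------------------------------- mutation
    def copy(self) -> "Tree":
        def dup(node: Node) -> Node:
            clone = Node(label=node.label, length=node.length)
            for child in node.children:
                clone.add_child(dup(child))
            return clone

        return Tree(dup(self.root))

    def unroot(self) -> "Tree":
        """Collapse a degree-2 root in place (lengths of the two root edges
        are summed onto the retained child); returns self."""
        root = self.root
        if len(root.children) != 2:
            return self
        a, b = root.children
        keep, merge = (a, b) if not a.is_leaf else (b, a)
        if keep.is_leaf:  # two-leaf tree: keep the rooted form
            return self
        root.remove_child(keep)
        root.remove_child(merge)
        merge.length = (merge.length or 0.0) + (keep.length or 0.0)
        keep.add_child(merge)
        keep.length = None
        keep.parent = None
        self.root = keep
        return self

    def reroot_on_edge(self, edge: Node, fraction: float = 0.5) -> "Tree":
        """Reroot in place on the branch above ``edge``; returns self."""
        self.unroot()
        if edge.parent is None:
            raise ValueError("cannot reroot on the root node")
        old_len = edge.length if edge.length is not None else 0.0
        parent = edge.parent
        # path from the attachment parent up to the old root, with the
        # length of the branch above each path node, recorded before surgery
        path = [parent]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        lens = [n.length for n in path]
        new_root = Node()
        parent.remove_child(edge)
        new_root.add_child(edge)
        edge.length = old_len * fraction
        for lower, upper in zip(path, path[1:]):
            upper.remove_child(lower)
        new_root.add_child(parent)
        parent.length = old_len * (1.0 - fraction)
        for i in range(len(path) - 1):
            path[i].add_child(path[i + 1])
            path[i + 1].length = lens[i]
        old_root = path[-1]
        if len(old_root.children) == 1 and old_root.parent is not None:
            only = old_root.children[0]
            gp = old_root.parent
            gp.remove_child(old_root)
            only.length = (only.length or 0.0) + (old_root.length or 0.0)
            gp.add_child(only)
        self.root = new_root
        return self

    def attach(
        self,
        label: str,
        edge: Node,
        pendant_length: float = 0.0,
        fraction: float = 0.5,
    ) -> tuple[Node, Node]:
        """Subdivide the branch above ``edge`` and hang a new pendant leaf.

        Returns ``(attachment_node, query_leaf)``; undo with :meth:`detach`.
        """
        if edge.parent is None:
            raise ValueError("cannot attach above the root")
        parent = edge.parent
        old_len = edge.length if edge.length is not None else 0.0
        knot = Node(length=old_len * (1.0 - fraction))
        idx = parent.children.index(edge)
        parent.children[idx] = knot
        knot.parent = parent
        knot.add_child(edge)
        edge.length = old_len * fraction
        leaf = knot.add_child(Node(label=label, length=pendant_length))
        return knot, leaf

    def detach(self, knot: Node) -> None:
        """Reverse :meth:`attach`: remove the pendant and splice the edge."""
        parent = knot.parent
        assert parent is not None
        edge = knot.children[0]
        knot.remove_child(edge)
        edge.length = (edge.length or 0.0) + (knot.length or 0.0)
        idx = parent.children.index(knot)
        parent.children[idx] = edge
        edge.parent = parent
        knot.parent = None

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n.length)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree n={self.n_leaves} rooted={self.is_rooted}>"


class TreeSample:
    """A collection of trees over a shared taxon set, with provenance.

    Bootstrap replicate samples and MCMC posterior samples both arrive in
    this form; split frequencies over the sample give BS / PP support.
    """

    def __init__(self, trees: Sequence[Tree], provenance: dict | None = None):
        self.trees = list(trees)
        self.provenance = dict(provenance or {})
        if self.trees:
            ref = sorted(self.trees[0].leaf_labels())
            for i, t in enumerate(self.trees[1:], start=1):
                if sorted(t.leaf_labels()) != ref:
                    raise ValueError(
                        f"tree {i} has a different taxon set than tree 0"
                    )

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self) -> Iterator[Tree]:
        return iter(self.trees)

    def __getitem__(self, i: int) -> Tree:
        return self.trees[i]

    def taxa(self) -> list[str]:
        return sorted(self.trees[0].leaf_labels()) if self.trees else []
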