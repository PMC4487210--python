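"""Fitch parsimony: step counting, character fit, and insertion scans.

Characters are unordered; polymorphic leaf cells enter generalized Fitch
as their state set, missing cells as the full alphabet.  Multifurcations
are folded pairwise (equivalent to an arbitrary binary resolution), which
is exact for the binary trees used throughout.  Fitch scores depend only
on the unrooted topology, so rootings never change a step count — which
is why alternative rooting scenarios of one unrooted backbone always
optimize to the same tree length.

The insertion scan attaches a query taxon to every branch of a fixed
backbone in turn and records the incremental increase in steps, giving
the full parsimony landscape of possible placements; ties are reported,
never broken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import DataMatrix
from .trees import Node, Tree

__all__ = [
    "fitch_steps",
    "min_steps",
    "consistency_index",
    "insertion_scan",
    "InsertionScan",
]


def _per_character_steps(tree: Tree, m: DataMatrix) -> np.ndarray:
    """Generalized Fitch step counts, one entry per character."""
    steps = np.zeros(m.n_characters, dtype=np.int64)
    state: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            try:
                i = m.taxon_index(node.label)
            except KeyError:
                raise ValueError(
                    f"leaf {node.label!r} missing from matrix"
                ) from None
            state[node] = m.masks[i]
        else:
            acc: np.ndarray | None = None
            for child in node.children:
                s = state.pop(child)
                if acc is None:
                    acc = s.copy()
                else:
                    inter = acc & s
                    empty = inter == 0
                    steps += empty
                    acc = np.where(empty, acc | s, inter)
            state[node] = acc
    return steps


def fitch_steps(
    tree: Tree, m: DataMatrix, weights: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Weighted Fitch tree length.

    Returns ``(total, per_character)`` where ``total`` is the
    weight-weighted sum of per-character step counts.  The result is
    invariant under re-rooting.
    """
    w = m.weights if weights is None else np.asarray(weights, dtype=float)
    per_char = _per_character_steps(tree, m)
    return float(np.dot(w, per_char)), per_char


def min_steps(m: DataMatrix, char: int) -> int:
    """Lower bound on a character's steps on any tree.

    Counts the states that *must* be present — those observed in scored,
    non-polymorphic cells — minus one, floored at zero.  Polymorphic cells
    never force a state, so they are excluded from the count.
    """
    observed: set[int] = set()
    for i in range(m.n_taxa):
        if not m.scored[i, char]:
            continue
        mask = int(m.masks[i, char])
        if mask & (mask - 1) == 0:  # single state
            observed.add(mask)
    return max(0, len(observed) - 1)


def consistency_index(
    tree: Tree, m: DataMatrix
) -> np.ndarray:
    """Per-character consistency index on a tree.

    CI = minimum possible steps / observed steps; a character that needs
    no steps (and could need none) scores 1.0 — homoplasy-free.
    """
    _, obs = fitch_steps(tree, m)
    ci = np.ones(m.n_characters)
    for c in range(m.n_characters):
        lo = min_steps(m, c)
        if obs[c] > 0:
            ci[c] = lo / obs[c]
        # obs == 0: nothing to explain, CI 1 regardless of lo (lo <= obs)
    return ci


@dataclass
class InsertionScan:
    """Result of scanning a query over every branch of a backbone.

    ``branch_labels[b]`` is the leaf set below branch ``b`` (its split
    side), ``added_steps[b]`` the extra weighted steps incurred when the
    query attaches there, and ``minimal_branches`` every branch attaining
    the minimum (ties preserved).
    """

    query: str
    backbone_steps: float
    branch_labels: list[frozenset[str]]
    added_steps: np.ndarray
    per_character: list[np.ndarray]

    @property
    def minimal_branches(self) -> list[int]:
        lo = self.added_steps.min()
        return [int(b) for b in np.flatnonzero(self.added_steps == lo)]

    @property
    def min_added(self) -> float:
        return float(self.added_steps.min())

    def ranking(self) -> list[tuple[int, float]]:
        order = np.argsort(self.added_steps, kind="stable")
        return [(int(b), float(self.added_steps[b])) for b in order]


def insertion_scan(
    backbone: Tree,
    m: DataMatrix,
    query: str,
    weights: np.ndarray | None = None,
) -> InsertionScan:
    """Exhaustive parsimony placement of ``query`` on a fixed backbone.

    For every branch (pendant branches included) the query is attached
    there, the tree re-scored, and the step increase over the bare
    backbone recorded.  Branch lengths play no role: parsimony sees only
    the topology.
    """
    if query in backbone.leaf_labels():
        raise ValueError(f"query {query!r} already a backbone leaf")
    m.taxon_index(query)  # raises if the query row is absent
    tree = backbone.copy()
    base_total, _ = fitch_steps(tree, m, weights)
    edges = tree.edges()
    labels: list[frozenset[str]] = []
    added = np.zeros(len(edges))
    per_char: list[np.ndarray] = []
    for b, edge in enumerate(edges):
        labels.append(frozenset(
            n.label for n in _subtree_leaves(edge)
        ))
        knot, _ = tree.attach(query, edge)
        total, chars = fitch_steps(tree, m, weights)
        tree.detach(knot)
        added[b] = total - base_total
        per_char.append(chars)
    return InsertionScan(query, base_total, labels, added, per_char)


def _subtree_leaves(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        else:
            stack.extend(n.children)
    return out
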