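"""Split systems: bipartitions, neighbour-nets, and support overlays.

A *split* (bipartition) is a two-block partition of the taxon set; internal
branches of unrooted trees induce splits, and support values (bootstrap
percentages, posterior probabilities) attach to splits rather than to any
particular tree.  The neighbour-net algorithm generalizes neighbor joining:
an agglomerative pass produces a circular ordering of the taxa, and
non-negative least squares assigns weights to the ordering-compatible
splits so that split-path distances approximate the input distances.
Conflicting signal then shows up as boxes in the resulting splits graph
instead of being forced into a single tree.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from .matrix import DistanceMatrix
from .trees import Tree, TreeSample

__all__ = [
    "Bipartition",
    "SplitSystem",
    "neighbor_net",
    "nnls_split_weights",
    "bipartition_frequencies",
    "support_overlay",
    "tree_splits",
    "NeighborNet",
    "NeighborNetResults",
]


class Bipartition:
    """A canonical taxon bipartition over ``n`` taxa.

    The stored side is the one *not* containing taxon 0, so each split has
    exactly one representation.  ``support`` maps method labels (e.g.
    ``"BS_NJ"``, ``"PP"``) to values: BS in percent, PP in [0, 1].
    """

    __slots__ = ("bits", "n", "support")

    def __init__(self, bits: int, n: int, support: dict | None = None):
        if bits & 1:
            raise ValueError("canonical side must not contain taxon 0")
        full = (1 << n) - 1
        if bits == 0 or bits == full:
            raise ValueError("neither side of a split may be empty")
        self.bits = bits
        self.n = n
        self.support: dict[str, float] = dict(support or {})

    @classmethod
    def from_side(cls, bits: int, n: int) -> "Bipartition":
        full = (1 << n) - 1
        if bits & 1:
            bits = ~bits & full
        return cls(bits, n)

    def side_indices(self) -> list[int]:
        return [i for i in range(self.n) if self.bits >> i & 1]

    def other_side_indices(self) -> list[int]:
        return [i for i in range(self.n) if not self.bits >> i & 1]

    @property
    def size(self) -> int:
        """Size of the smaller side."""
        k = bin(self.bits).count("1")
        return min(k, self.n - k)

    @property
    def is_trivial(self) -> bool:
        return self.size == 1

    def separates(self, i: int, j: int) -> bool:
        return (self.bits >> i & 1) != (self.bits >> j & 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return self.bits == other.bits and self.n == other.n

    def __hash__(self) -> int:
        return hash((self.bits, self.n))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Bipartition {self.side_indices()} | n={self.n}>"


class SplitSystem:
    """Weighted splits over a labelled taxon set, optionally circular."""

    def __init__(
        self,
        labels: list[str],
        splits: list[tuple[Bipartition, float]],
        ordering: list[str] | None = None,
    ):
        self.labels = list(labels)
        self.splits = list(splits)
        self.ordering = list(ordering) if ordering is not None else None
        for bip, w in self.splits:
            if bip.n != len(self.labels):
                raise ValueError("bipartition size does not match labels")
            if w < 0:
                raise ValueError("split weights must be non-negative")
        if self.ordering is not None:
            if sorted(self.ordering) != sorted(self.labels):
                raise ValueError("ordering must be a permutation of labels")
            for bip, _ in self.splits:
                if not self._is_arc(bip):
                    raise ValueError(
                        f"split {bip!r} is not an arc of the circular ordering"
                    )

    def _is_arc(self, bip: Bipartition) -> bool:
        # a side is an arc of the circular ordering iff its positions have
        # exactly one circular gap (counting the wrap-around step)
        n = len(self.labels)
        pos = {self.labels.index(t): k for k, t in enumerate(self.ordering)}
        side = sorted(pos[i] for i in bip.side_indices())
        steps = [b - a for a, b in zip(side, side[1:])]
        steps.append(side[0] + n - side[-1])
        breaks = sum(1 for s in steps if s != 1)
        return breaks <= 1

    def __len__(self) -> int:
        return len(self.splits)

    def weight_of(self, bip: Bipartition) -> float:
        for b, w in self.splits:
            if b == bip:
                return w
        return 0.0

    def split_distance(self, i: int, j: int) -> float:
        """Path-sum distance induced by the weighted splits."""
        return sum(w for bip, w in self.splits if bip.separates(i, j))

    def induced_distances(self) -> np.ndarray:
        n = len(self.labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = self.split_distance(i, j)
        return d

    def label_sides(self, bip: Bipartition) -> tuple[list[str], list[str]]:
        return (
            [self.labels[i] for i in bip.side_indices()],
            [self.labels[i] for i in bip.other_side_indices()],
        )


# ---------------------------------------------------------------------------
# neighbour-net ordering (agglomerative)


def _reduce_chain(d: np.ndarray, x: int, y: int, z: int) -> None:
    """Replace the 3-chain x-y-z by two nodes living in slots x and z.

    The new end nodes mix the old distances 2:1 in favour of the outer
    node, and the new internal distance averages the three old ones; slot
    y dies.
    """
    u = (2.0 / 3.0) * d[x, :] + d[y, :] / 3.0
    v = (2.0 / 3.0) * d[z, :] + d[y, :] / 3.0
    uv = (d[x, y] + d[x, z] + d[y, z]) / 3.0
    d[x, :] = u
    d[:, x] = u
    d[z, :] = v
    d[:, z] = v
    d[y, :] = 0.0
    d[:, y] = 0.0
    d[x, z] = d[z, x] = uv
    d[x, x] = d[z, z] = 0.0


def neighbor_net_ordering(D: np.ndarray) -> list[int]:
    """Circular taxon ordering by neighbour-net agglomeration.

    Clusters hold one or two active nodes (the ends of a partially ordered
    chain).  Cluster pairs are selected by the neighbor-joining adjusted
    distance on cluster-mean distances; the joining node pair within the
    winning clusters is selected by the same criterion with those clusters'
    nodes promoted to singletons; chains longer than two nodes are reduced
    end-inward.  Ties break to the lowest index pair.
    """
    n = D.shape[0]
    if n <= 3:
        return list(range(n))
    d = np.array(D, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(n)]  # live node slots
    orders: list[list[int]] = [[i] for i in range(n)]  # accumulated taxa
    while len(clusters) > 1:
        l = len(clusters)
        if l > 2:
            DM = np.zeros((l, l))
            for a in range(l):
                for b in range(a + 1, l):
                    DM[a, b] = DM[b, a] = d[
                        np.ix_(clusters[a], clusters[b])
                    ].mean()
            r = DM.sum(axis=1) / (l - 2)
            Q = DM - r[:, None] - r[None, :]
            Q[np.diag_indices(l)] = np.inf
            e1, e2 = divmod(int(np.argmin(Q)), l)
            if e1 > e2:
                e1, e2 = e2, e1
        else:
            e1, e2 = 0, 1
        c1, c2 = clusters[e1], clusters[e2]
        o1, o2 = orders[e1], orders[e2]
        n1, n2 = len(c1), len(c2)
        if n1 == 1 and n2 == 1:
            new_cluster = c1 + c2
            new_order = o1 + o2
        else:
            nodes = c1 + c2
            others = [clusters[k] for k in range(l) if k not in (e1, e2)]
            m_eff = len(nodes) + len(others)
            rt = np.zeros(len(nodes))
            for a, x in enumerate(nodes):
                s = sum(d[x, y] for y in nodes if y != x)
                s += sum(d[x, grp].mean() for grp in map(list, others))
                rt[a] = s
            if m_eff > 2:
                rt /= m_eff - 2
            Dn = d[np.ix_(nodes, nodes)] - rt[:, None] - rt[None, :]
            sub = Dn[:n1, n1:]
            bi, bj = divmod(int(np.argmin(sub)), n2)
            # orient so the joined nodes meet: c1's chosen node at the
            # tail, c2's chosen node at the head
            if n1 == 2 and bi == 0:
                c1 = c1[::-1]
                o1 = o1[::-1]
            if n2 == 2 and bj == 1:
                c2 = c2[::-1]
                o2 = o2[::-1]
            chain = c1 + c2
            new_order = o1 + o2
            while len(chain) > 2:
                x, y, z = chain[0], chain[1], chain[2]
                _reduce_chain(d, x, y, z)
                chain = [x, z] + chain[3:]
            new_cluster = chain
        clusters[e1] = new_cluster
        orders[e1] = new_order
        del clusters[e2]
        del orders[e2]
    return orders[0]


def circular_splits(ordering: list[int], n: int) -> list[Bipartition]:
    """All n(n-1)/2 splits whose one side is an arc of the ordering that
    excludes the ordering's first taxon."""
    out = []
    for i in range(1, n):
        for j in range(i, n):
            bits = 0
            for k in range(i, j + 1):
                bits |= 1 << ordering[k]
            out.append(Bipartition.from_side(bits, n))
    return out


def nnls_split_weights(
    D: np.ndarray, ordering: list[int]
) -> tuple[list[Bipartition], np.ndarray, float]:
    """Non-negative least-squares split weights for a circular ordering.

    Minimizes sum over pairs of (d_ij - sum_s w_s * delta_s(i,j))^2 with
    w_s >= 0 over all ordering-compatible splits.  Returns the splits,
    their weights, and the residual norm.
    """
    n = len(ordering)
    splits = circular_splits(ordering, n)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = np.zeros((len(pairs), len(splits)))
    y = np.zeros(len(pairs))
    for p, (i, j) in enumerate(pairs):
        y[p] = D[i, j]
        for s, bip in enumerate(splits):
            if bip.separates(i, j):
                A[p, s] = 1.0
    weights, residual = _scipy_nnls(A, y)
    return splits, weights, float(residual)


def neighbor_net(
    D: DistanceMatrix, threshold: float = 1e-8
) -> SplitSystem:
    """Neighbour-net: circular ordering plus NNLS-weighted circular splits.

    Splits with weight <= ``threshold`` are suppressed as numerical noise.
    Undefined (NaN) distances abort with an error: with no shared scored
    characters between a pair there is nothing principled to fit.
    """
    if not np.all(np.isfinite(D.d)):
        raise ValueError(
            f"undefined distances for pairs {D.undefined_pairs}; "
            "cannot build a neighbour-net"
        )
    ordering_idx = neighbor_net_ordering(D.d)
    splits, weights, _ = nnls_split_weights(D.d, ordering_idx)
    kept = [
        (bip, float(w))
        for bip, w in zip(splits, weights)
        if w > threshold
    ]
    ordering = [D.labels[i] for i in ordering_idx]
    return SplitSystem(D.labels, kept, ordering=ordering)


# ---------------------------------------------------------------------------
# split support from tree samples


def tree_splits(
    tree: Tree, labels: list[str], include_trivial: bool = False
) -> set[Bipartition]:
    """The splits induced by a tree's branches, treated unrooted."""
    index = {t: i for i, t in enumerate(labels)}
    n = len(labels)
    full = (1 << n) - 1
    out: set[Bipartition] = set()
    below: dict = {}
    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in index:
                raise ValueError(f"taxon {node.label!r} not in label set")
            below[node] = 1 << index[node.label]
        else:
            bits = 0
            for child in node.children:
                bits |= below[child]
            below[node] = bits
            if node is tree.root:
                continue
            k = bin(bits).count("1")
            if k == 0 or bits == full:
                continue
            if not include_trivial and (k < 2 or k > n - 2):
                continue
            out.add(Bipartition.from_side(bits, n))
    if include_trivial:
        for t in labels:
            out.add(Bipartition.from_side(1 << index[t], n))
    return out


def bipartition_frequencies(
    sample: TreeSample, labels: list[str] | None = None
) -> dict[Bipartition, float]:
    """Frequency of each non-trivial split across a tree sample.

    Rooted trees are implicitly unrooted; the two branches meeting at a
    degree-2 root induce the same split and are counted once.
    """
    if len(sample) == 0:
        raise ValueError("empty tree sample")
    labels = labels if labels is not None else sample.taxa()
    counts: dict[Bipartition, int] = {}
    for tree in sample:
        if sorted(tree.leaf_labels()) != sorted(labels):
            raise ValueError("tree taxon set does not match labels")
        for bip in tree_splits(tree, labels):
            counts[bip] = counts.get(bip, 0) + 1
    m = len(sample)
    return {bip: c / m for bip, c in counts.items()}


def support_overlay(
    net: SplitSystem,
    freqs_per_method: dict[str, dict[Bipartition, float]],
    as_percent: set[str] | None = None,
) -> tuple[SplitSystem, dict[str, dict[Bipartition, float]]]:
    """Annotate network splits with per-method support frequencies.

    Methods named in ``as_percent`` are scaled to [0, 100] (bootstrap
    convention); others stay as probabilities (posterior convention).
    Splits present in a sample but absent from the network are returned
    separately rather than silently dropped.
    """
    as_percent = as_percent or set()
    annotated = []
    net_bips = set()
    for bip, w in net.splits:
        new = Bipartition(bip.bits, bip.n, support=bip.support)
        for method, freqs in freqs_per_method.items():
            value = freqs.get(bip, 0.0)
            if method in as_percent:
                value *= 100.0
            new.support[method] = value
        annotated.append((new, w))
        net_bips.add(bip)
    leftover = {
        method: {
            bip: f for bip, f in freqs.items() if bip not in net_bips
        }
        for method, freqs in freqs_per_method.items()
    }
    out = SplitSystem(net.labels, annotated, ordering=net.ordering)
    return out, leftover


# ---------------------------------------------------------------------------
# model / results surface


class NeighborNetResults:
    """Fitted neighbour-net: ordering, weighted splits, fit diagnostics."""

    def __init__(
        self,
        model: "NeighborNet",
        split_system: SplitSystem,
        residual: float,
        all_weights: np.ndarray,
    ):
        self.model = model
        self.split_system = split_system
        self.ordering = split_system.ordering
        self.residual = residual
        self._all_weights = all_weights

    @property
    def n_splits(self) -> int:
        return len(self.split_system)

    def fitted_distances(self) -> np.ndarray:
        return self.split_system.induced_distances()

    def max_abs_error(self) -> float:
        return float(
            np.nanmax(np.abs(self.fitted_distances() - self.model.dist.d))
        )

    def annotate(
        self,
        freqs_per_method: dict[str, dict[Bipartition, float]],
        as_percent: set[str] | None = None,
    ) -> tuple[SplitSystem, dict]:
        return support_overlay(self.split_system, freqs_per_method, as_percent)

    def to_splits_nexus(self) -> str:
        from .iolib import write_splits_nexus

        return write_splits_nexus(self.split_system)

    def summary(self) -> str:
        lines = [
            "Neighbour-net".center(60),
            "=" * 60,
            f"Taxa:            {len(self.split_system.labels)}",
            f"Splits kept:     {self.n_splits}"
            f" (of {len(self._all_weights)} circular)",
            f"LS residual:     {self.residual:.6g}",
            f"Max |d - fit|:   {self.max_abs_error():.6g}",
            f"Circular order:  {', '.join(self.ordering)}",
            "-" * 60,
            f"{'weight':>10}  {'size':>4}  split (smaller side)",
        ]
        ordered = sorted(
            self.split_system.splits, key=lambda t: -t[1]
        )
        for bip, w in ordered:
            side, other = self.split_system.label_sides(bip)
            small = side if len(side) <= len(other) else other
            extras = "".join(
                f"  {m}={v:.2f}" for m, v in sorted(bip.support.items())
            )
            lines.append(
                f"{w:>10.5f}  {bip.size:>4}  {{{', '.join(sorted(small))}}}{extras}"
            )
        return "\n".join(lines)


class NeighborNet:
    """Neighbour-net model over a distance matrix.

    ``fit`` runs the agglomerative ordering and the constrained
    least-squares weight estimation, returning a
    :class:`NeighborNetResults`.
    """

    def __init__(self, dist: DistanceMatrix):
        self.dist = dist

    def fit(self, threshold: float = 1e-8) -> NeighborNetResults:
        if not np.all(np.isfinite(self.dist.d)):
            raise ValueError(
                f"undefined distances for pairs {self.dist.undefined_pairs}"
            )
        ordering_idx = neighbor_net_ordering(self.dist.d)
        splits, weights, residual = nnls_split_weights(
            self.dist.d, ordering_idx
        )
        kept = [
            (bip, float(w))
            for bip, w in zip(splits, weights)
            if w > threshold
        ]
        system = SplitSystem(
            self.dist.labels,
            kept,
            ordering=[self.dist.labels[i] for i in ordering_idx],
        )
        return NeighborNetResults(self, system, residual, weights)
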