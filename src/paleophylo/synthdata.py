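"""Synthetic data generators carrying the statistical structure the
analyses assume.

Defaults mirror the scale of the royal-fern study's data: a morphological
matrix of ~30 taxa x 23 multistate rhizome-anatomy-like characters
(states 2-4, ~15 % missing) and a partitioned plastid-like DNA alignment
whose coding partitions carry one root signal and whose spacer partitions
carry another.  Every generator is seed-deterministic and returns truth
records sufficient to score the downstream stages (true trees, true
attachment branches, per-partition generating root branches).

Engineered conflict: the conflicting partitions are simulated with the
outgroup attached at *different* ingroup branches — assignment of the
generating branch, not simulated convergence — which is the simplest
structure that exercises the root-placement scan.  The ``outgroup_stem``
length makes the outgroup branch long, emulating the long-branch
attraction risk of distant outgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import SubstModel
from .matrix import Character, DataMatrix, PartitionScheme
from .trees import Node, Tree

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_mk_matrix",
    "simulate_dna_conflict",
    "make_fossil_query",
]


@dataclass
class SimulationConfig:
    """Knobs for the generators; defaults are the study-scale conditions."""

    seed: int = 0
    # tree
    n_taxa: int = 30
    tree_depth: float = 1.0
    # morphology
    n_characters: int = 23
    state_counts: tuple[int, ...] = (2, 3, 4)
    char_rate: float = 1.0
    missing_fraction: float = 0.15
    # DNA
    partition_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "coding1": 300, "coding2": 300, "spacer1": 250, "spacer2": 250,
        }
    )
    partition_flags: dict[str, str] = field(
        default_factory=lambda: {
            "coding1": "coding", "coding2": "coding",
            "spacer1": "spacer", "spacer2": "spacer",
        }
    )
    dna_rate: float = 1.0
    gamma_alpha: float | None = None
    outgroup_stem: float = 0.5
    # query construction
    query_pendant: float = 0.05
    query_depth_fraction: float = 0.5

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_tree(
    n_taxa: int,
    depth: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> Tree:
    """Yule (pure-birth) tree with the requested leaf count, rescaled so
    the mean root-to-tip path equals ``depth``."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if n_taxa < 2:
        raise ValueError("need >= 2 taxa")
    root = Node()
    active = [root.add_child(Node(length=0.0)), root.add_child(Node(length=0.0))]
    while len(active) < n_taxa:
        wait = rng.exponential(1.0 / len(active))
        for node in active:
            node.length += wait
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        active.append(parent.add_child(Node(length=0.0)))
        active.append(parent.add_child(Node(length=0.0)))
    wait = rng.exponential(1.0 / len(active))
    for node in active:
        node.length += wait
    for i, node in enumerate(active):
        node.label = f"t{i + 1}"
    tree = Tree(root)
    depths = []
    for leaf in tree.leaves():
        d, nd = 0.0, leaf
        while nd.parent is not None:
            d += nd.length or 0.0
            nd = nd.parent
        depths.append(d)
    factor = depth / float(np.mean(depths))
    for node in tree.postorder():
        if node.length is not None:
            node.length *= factor
    return tree


def _evolve_states(
    tree: Tree,
    model: SubstModel,
    rate: float,
    rng: np.random.Generator,
    root_state: int | None = None,
) -> dict[str, int]:
    """One character down the tree; returns leaf-label -> state index."""
    k = model.k
    states: dict[Node, int] = {}
    out: dict[str, int] = {}
    for node in tree.preorder():
        if node.parent is None:
            states[node] = (
                int(rng.choice(k, p=model.pi))
                if root_state is None
                else root_state
            )
        else:
            P = model.transition((node.length or 0.0) * rate)
            states[node] = int(rng.choice(k, p=P[states[node.parent]]))
        if node.is_leaf:
            out[node.label] = states[node]
    return out


def simulate_mk_matrix(
    tree: Tree,
    config: SimulationConfig | None = None,
    rng: np.random.Generator | None = None,
) -> DataMatrix:
    """Categorical matrix evolved under per-character Mk chains.

    Each character draws its state count from ``config.state_counts``,
    starts from a uniform root state, and evolves at ``config.char_rate``;
    cells are then masked missing independently at
    ``config.missing_fraction``.
    """
    config = config or SimulationConfig()
    rng = rng if rng is not None else config.rng()
    taxa = tree.leaf_labels()
    characters = []
    cells: list[list] = [[] for _ in taxa]
    for c in range(config.n_characters):
        k = int(rng.choice(config.state_counts))
        symbols = tuple(str(s) for s in range(k))
        characters.append(Character(name=f"c{c + 1}", symbols=symbols))
        model = SubstModel("Mk", k)
        leaf_states = _evolve_states(tree, model, config.char_rate, rng)
        for i, t in enumerate(taxa):
            cells[i].append({symbols[leaf_states[t]]})
    m = DataMatrix(taxa, characters, cells)
    if config.missing_fraction > 0:
        mask = rng.random(m.shape) < config.missing_fraction
        for i in range(m.n_taxa):
            for j in range(m.n_characters):
                if mask[i, j]:
                    m.masks[i, j] = m.characters[j].full_mask
                    m.scored[i, j] = False
    return m


_DNA = ("A", "C", "G", "T")


def _simulate_dna_columns(
    tree: Tree,
    n_columns: int,
    model: SubstModel,
    rate: float,
    rng: np.random.Generator,
) -> dict[str, list[set]]:
    out: dict[str, list[set]] = {t: [] for t in tree.leaf_labels()}
    for _ in range(n_columns):
        leaf_states = _evolve_states(tree, model, rate, rng)
        for t, s in leaf_states.items():
            out[t].append({_DNA[s]})
    return out


def simulate_dna_conflict(
    ingroup_tree: Tree,
    root_branches: dict[str, frozenset[str]],
    config: SimulationConfig | None = None,
    outgroups: tuple[str, ...] = ("out1",),
    model: SubstModel | None = None,
) -> tuple[DataMatrix, PartitionScheme, dict]:
    """Partitioned alignment with engineered root-signal conflict.

    ``root_branches`` maps each partition name to the ingroup branch (a
    leaf set identifying the branch by the taxa below it) where the
    outgroup attaches *for that partition's simulation*.  Coding and
    spacer partitions pointed at different branches produce exactly the
    conflicting outgroup-inferred root signal the scan is built to
    expose.  Returns ``(matrix, scheme, truth)`` where truth records the
    generating branch per partition.
    """
    config = config or SimulationConfig()
    model = model or SubstModel("DNA-GTR")
    rng = config.rng()
    names = list(config.partition_lengths)
    for name in names:
        if name not in root_branches:
            raise ValueError(f"no generating branch for partition {name!r}")
    ingroup_taxa = ingroup_tree.leaf_labels()
    all_taxa = ingroup_taxa + list(outgroups)
    columns: dict[str, list[set]] = {t: [] for t in all_taxa}
    scheme_cols: dict[str, np.ndarray] = {}
    offset = 0
    for name in names:
        length = config.partition_lengths[name]
        target = root_branches[name]
        tree = ingroup_tree.copy()
        edge = _find_edge(tree, target)
        knot, leaf = tree.attach(
            next(iter(outgroups)), edge, pendant_length=config.outgroup_stem
        )
        if len(outgroups) > 1:
            # pre-resolved outgroup subtree on a shared stem
            stem = leaf
            stem.label = None
            for og in outgroups:
                stem.add_child(Node(label=og, length=0.05))
        cols = _simulate_dna_columns(
            tree, length, model, config.dna_rate, rng
        )
        for t in all_taxa:
            columns[t].extend(cols[t])
        scheme_cols[name] = np.arange(offset, offset + length)
        offset += length
    characters = [
        Character(name=str(j + 1), symbols=_DNA, kind="nucleotide")
        for j in range(offset)
    ]
    matrix = DataMatrix(all_taxa, characters, [columns[t] for t in all_taxa])
    scheme = PartitionScheme(scheme_cols, dict(config.partition_flags))
    truth = {
        "root_branches": {k: frozenset(v) for k, v in root_branches.items()},
        "outgroups": tuple(outgroups),
        "seed": config.seed,
    }
    return matrix, scheme, truth


def _find_edge(tree: Tree, side: frozenset[str]) -> Node:
    """The branch whose subtree leaf set equals ``side`` (either rooted
    orientation accepted)."""
    all_taxa = frozenset(tree.leaf_labels())
    want = frozenset(side)
    for edge in tree.edges():
        below = frozenset(n.label for n in _leaves(edge))
        if below == want or all_taxa - below == want:
            return edge
    raise KeyError(f"no branch with side {sorted(side)}")


def _leaves(node: Node) -> list[Node]:
    out, stack = [], [node]
    while stack:
        nd = stack.pop()
        if nd.is_leaf:
            out.append(nd)
        else:
            stack.extend(nd.children)
    return out


def conflict_demo(
    seed: int = 0,
    outgroup_stem: float = 0.5,
    dna_rate: float = 1.0,
    partition_lengths: dict[str, int] | None = None,
) -> dict:
    """A ready-made conflicting-root scenario.

    An 8-taxon balanced ingroup with four two-taxon clades A, B, C, D;
    the two "coding" partitions evolve with the outgroup attached at the
    A-clade stem (hypothesis H1), the two "spacer" partitions at the
    B-clade stem (hypothesis H2); H3 is the C-clade stem.  Returns a dict
    with the ingroup tree, matrix, partition scheme, outgroups, clade
    definitions, and the truth record.
    """
    ingroup = Tree.from_newick(
        "(((A1:0.05,A2:0.05):0.08,(B1:0.05,B2:0.05):0.08):0.06,"
        "((C1:0.05,C2:0.05):0.08,(D1:0.05,D2:0.05):0.08):0.06);"
    )
    clades = {
        "H1": {"A1", "A2"},
        "H2": {"B1", "B2"},
        "H3": {"C1", "C2"},
    }
    config = SimulationConfig(
        seed=seed, outgroup_stem=outgroup_stem, dna_rate=dna_rate
    )
    if partition_lengths is not None:
        config.partition_lengths = dict(partition_lengths)
        config.partition_flags = {
            k: config.partition_flags.get(k, "") for k in partition_lengths
        }
    root_branches = {
        name: frozenset(clades["H1" if flag == "coding" else "H2"])
        for name, flag in config.partition_flags.items()
    }
    matrix, scheme, truth = simulate_dna_conflict(
        ingroup, root_branches, config, outgroups=("out1",)
    )
    return {
        "ingroup_tree": ingroup,
        "matrix": matrix,
        "scheme": scheme,
        "outgroups": ["out1"],
        "clades": clades,
        "truth": truth,
        "config": config,
    }


def make_fossil_query(
    tree: Tree,
    branch: frozenset[str],
    config: SimulationConfig | None = None,
    query_label: str = "fossil",
    mosaic: tuple[frozenset[str], frozenset[str], float] | None = None,
) -> tuple[DataMatrix, frozenset[str]]:
    """Morphological matrix with a query taxon of known true attachment.

    Default mode: the query evolves from a point partway down ``branch``
    (at ``config.query_depth_fraction``) on a short pendant of length
    ``config.query_pendant``, so its true attachment branch is recorded
    ground truth.  Mosaic mode instead overwrites the query row with a
    mix of two clades' consensus states at the given ratio — an
    artificial morphologically intermediate taxon with no single true
    branch, emulating the character suites of ancestral-grade fossils.

    Returns ``(matrix including the query row, true branch leaf set)``.
    """
    config = config or SimulationConfig()
    rng = config.rng()
    full = tree.copy()
    edge = _find_edge(full, branch)
    full.attach(
        query_label,
        edge,
        pendant_length=config.query_pendant,
        fraction=config.query_depth_fraction,
    )
    m = simulate_mk_matrix(full, config, rng)
    qi = m.taxon_index(query_label)
    # the fossil row keeps its scores even under heavy random masking
    if not m.scored[qi].any():
        m.scored[qi, :] = True
        for j, char in enumerate(m.characters):
            if m.masks[qi, j] == char.full_mask:
                m.masks[qi, j] = 1
    if mosaic is not None:
        clade_a, clade_b, ratio = mosaic
        for j, char in enumerate(m.characters):
            donor = clade_a if rng.random() < ratio else clade_b
            rows = [m.taxon_index(t) for t in donor]
            scored = [r for r in rows if m.scored[r, j]]
            if not scored:
                continue
            counts: dict[int, int] = {}
            for r in scored:
                mk = int(m.masks[r, j])
                counts[mk] = counts.get(mk, 0) + 1
            consensus = max(sorted(counts), key=counts.get)
            m.masks[qi, j] = consensus
            m.scored[qi, j] = True
    return m, frozenset(branch)
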