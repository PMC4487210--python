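"""Tree estimation and resampling.

* :func:`bionj` — distance agglomeration with variance-weighted reduction,
  the least-squares criterion used for distance bootstraps.
* :func:`nni_search` — hill climbing over nearest-neighbour interchanges
  under parsimony or likelihood.
* :func:`bootstrap` — nonparametric character resampling with re-inference
  per replicate (NJ / MP / ML), the source of BS support values.
* :func:`mcmc_mk` — a single-chain Metropolis-Hastings sampler over
  (topology, branch lengths) under the Mk model, the source of posterior
  probabilities.  Priors: uniform on topologies, iid exponential branch
  lengths.  This sampler deliberately targets small matrices (tens of
  taxa); there are no heated chains.

Every stochastic routine takes an integer seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings

import numpy as np

from .matrix import DataMatrix, DistanceMatrix, mean_distance_matrix
from .parsimony import fitch_steps
from .likelihood import SubstModel, optimize_branch_lengths, tree_loglik
from .splits import Bipartition, bipartition_frequencies
from .trees import Node, Tree, TreeSample

__all__ = [
    "bionj",
    "nni_search",
    "bootstrap",
    "mcmc_mk",
    "Bootstrap",
    "BootstrapResults",
    "MkMCMC",
    "MCMCResults",
]


# ---------------------------------------------------------------------------
# BioNJ


def bionj(D: DistanceMatrix) -> Tree:
    """BioNJ tree from a distance matrix.

    Standard neighbor-joining selection with the variance-weighted
    reduction of distances (variances initialized to the distances
    themselves); negative branch-length estimates are clamped to zero.
    The returned tree is unrooted (degree-3 root) for n >= 3.
    """
    n = D.n
    if not np.all(np.isfinite(D.d)):
        raise ValueError(f"undefined distances: {D.undefined_pairs}")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[Node] = [Node(label=t) for t in D.labels]
    if n == 2:
        root = Node()
        half = D.d[0, 1] / 2
        for nd in nodes:
            nd.length = half
            root.add_child(nd)
        return Tree(root)
    d = D.d.copy()
    v = D.d.copy()
    active = list(range(n))
    d_full = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    v_full = {(i, j): v[i, j] for i in range(n) for j in range(n)}

    def dist(i, j):
        return d_full[(i, j)] if i <= j else d_full[(j, i)]

    def var(i, j):
        return v_full[(i, j)] if i <= j else v_full[(j, i)]

    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1:]:
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        dij = dist(i, j)
        bi = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        bj = dij - bi
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        parent = Node()
        nodes[i].length = bi
        nodes[j].length = bj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        vij = var(i, j)
        if vij > 1e-12 and m > 2:
            lam = 0.5 + sum(
                var(j, k) - var(i, k) for k in active if k not in (i, j)
            ) / (2 * (m - 2) * vij)
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        u = next_id
        next_id += 1
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            duk = lam * dist(i, k) + (1 - lam) * dist(j, k) - lam * bi - (1 - lam) * bj
            vuk = lam * var(i, k) + (1 - lam) * var(j, k) - lam * (1 - lam) * vij
            d_full[(min(u, k), max(u, k))] = max(duk, 0.0)
            v_full[(min(u, k), max(u, k))] = max(vuk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]
    # three-point finish
    i, j, k = active
    root = Node()
    bi = (dist(i, j) + dist(i, k) - dist(j, k)) / 2
    bj = (dist(i, j) + dist(j, k) - dist(i, k)) / 2
    bk = (dist(i, k) + dist(j, k) - dist(i, j)) / 2
    for idx, b in zip((i, j, k), (bi, bj, bk)):
        nodes[idx].length = max(b, 0.0)
        root.add_child(nodes[idx])
    return Tree(root)


# ---------------------------------------------------------------------------
# NNI hill climbing


def _swap_subtrees(a: Node, b: Node) -> None:
    """Exchange two subtrees (branch lengths travel with them)."""
    pa, pb = a.parent, b.parent
    ia, ib = pa.children.index(a), pb.children.index(b)
    pa.children[ia], pb.children[ib] = b, a
    a.parent, b.parent = pb, pa


def _nni_alternatives(edge: Node) -> list[tuple[Node, Node]]:
    """The two subtree swaps across the internal branch above ``edge``."""
    v = edge.parent
    others = [c for c in v.children if c is not edge]
    sibling = others[0]
    a, b = edge.children[0], edge.children[1]
    return [(b, sibling), (a, sibling)]


def nni_search(
    start: Tree,
    m: DataMatrix,
    objective: str = "MP",
    model: SubstModel | None = None,
    weights: np.ndarray | None = None,
    max_rounds: int = 50,
    ml_sweeps: int = 3,
) -> tuple[Tree, float]:
    """Greedy NNI hill climbing under parsimony or likelihood.

    Sweeps over all internal edges, evaluating both NNI alternatives per
    edge and accepting strict improvements; terminates when a full sweep
    yields none.  MP score is weighted Fitch steps (lower is better);
    ML score is the log-likelihood after branch-length re-optimization
    (higher is better).  Returns ``(best_tree, best_score)`` with the MP
    score negated so that *higher is always better* for the caller.
    """
    if objective not in ("MP", "ML"):
        raise ValueError("objective must be 'MP' or 'ML'")
    if objective == "ML" and model is None:
        raise ValueError("ML objective needs a model")
    tree = start.copy().unroot()
    if not tree.is_binary():
        raise ValueError("NNI search requires a binary start tree")

    def score(t: Tree) -> float:
        if objective == "MP":
            total, _ = fitch_steps(t, m, weights)
            return -total
        opt, value, _ = optimize_branch_lengths(
            t, m, model, weights, max_sweeps=ml_sweeps
        )
        # copy optimized lengths back (same topology, same traversal order)
        for nd, nd_opt in zip(t.postorder(), opt.postorder()):
            nd.length = nd_opt.length
        return value

    current = score(tree)
    for _ in range(max_rounds):
        improved = False
        for edge in list(tree.internal_edges()):
            if edge.parent is None or len(edge.children) != 2:
                continue
            for a, b in _nni_alternatives(edge):
                _swap_subtrees(a, b)
                candidate = score(tree)
                if candidate > current + 1e-10:
                    current = candidate
                    improved = True
                else:
                    _swap_subtrees(a, b)  # revert
        if not improved:
            break
    return tree, current


# ---------------------------------------------------------------------------
# nonparametric bootstrap


def _resample_columns(m: DataMatrix, rng: np.random.Generator) -> DataMatrix:
    p = m.weights / m.weights.sum()
    cols = rng.choice(m.n_characters, size=m.n_characters, replace=True, p=p)
    out = m.subset_columns(np.sort(cols))
    out.weights = np.ones(m.n_characters)
    return out


def _distances_imputed(m: DataMatrix) -> DistanceMatrix:
    D = mean_distance_matrix(m)
    if not np.all(np.isfinite(D.d)):
        finite = D.d[np.isfinite(D.d)]
        fill = finite.max() if finite.size else 1.0
        d = np.where(np.isfinite(D.d), D.d, fill)
        np.fill_diagonal(d, 0.0)
        D = DistanceMatrix(D.labels, d, D.comparable)
    return D


def _infer_one(
    m: DataMatrix, method: str, model: SubstModel | None
) -> Tree:
    D = _distances_imputed(m)
    start = bionj(D)
    if method == "NJ":
        return start
    tree, _ = nni_search(start, m, objective=method, model=model)
    return tree


def bootstrap(
    m: DataMatrix,
    replicates: int = 1000,
    method: str = "NJ",
    seed: int = 0,
    model: SubstModel | None = None,
) -> TreeSample:
    """Nonparametric bootstrap: resample characters with replacement
    (per-character weights act as sampling multiplicities), re-infer each
    replicate by ``method``, and collect the replicate trees.

    MP and ML replicates start from the replicate's BioNJ tree and hill
    climb by NNI — the fast-bootstrap economy.  Fixed seeds give
    bit-identical samples.
    """
    if method not in ("NJ", "MP", "ML"):
        raise ValueError("method must be NJ, MP or ML")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(replicates):
        rep = _resample_columns(m, rng)
        trees.append(_infer_one(rep, method, model))
    return TreeSample(
        trees,
        provenance={
            "bootstrap": method,
            "replicates": replicates,
            "seed": seed,
        },
    )


class BootstrapResults:
    """Replicate tree sample plus split-support accessors."""

    def __init__(self, sample: TreeSample, labels: list[str]):
        self.sample = sample
        self.labels = labels
        self._freqs: dict[Bipartition, float] | None = None

    def split_frequencies(self) -> dict[Bipartition, float]:
        if self._freqs is None:
            self._freqs = bipartition_frequencies(self.sample, self.labels)
        return self._freqs

    def support_percent(self, side: set[str]) -> float:
        """BS (percent) of the split separating ``side`` from the rest."""
        bits = 0
        for t in side:
            bits |= 1 << self.labels.index(t)
        bip = Bipartition.from_side(bits, len(self.labels))
        return 100.0 * self.split_frequencies().get(bip, 0.0)

    def summary(self) -> str:
        prov = self.sample.provenance
        lines = [
            "Nonparametric bootstrap".center(56),
            "=" * 56,
            f"Method:      {prov.get('bootstrap')}",
            f"Replicates:  {prov.get('replicates')}",
            f"Seed:        {prov.get('seed')}",
            "-" * 56,
            f"{'BS %':>7}  split (smaller side)",
        ]
        for bip, f in sorted(
            self.split_frequencies().items(), key=lambda kv: -kv[1]
        ):
            side = [self.labels[i] for i in bip.side_indices()]
            other = [self.labels[i] for i in bip.other_side_indices()]
            small = side if len(side) <= len(other) else other
            lines.append(f"{100 * f:>7.1f}  {{{', '.join(sorted(small))}}}")
        return "\n".join(lines)


class Bootstrap:
    """Bootstrap support model over a character matrix."""

    def __init__(
        self,
        m: DataMatrix,
        method: str = "NJ",
        model: SubstModel | None = None,
    ):
        self.m = m
        self.method = method
        self.model = model

    def fit(self, replicates: int = 1000, seed: int = 0) -> BootstrapResults:
        sample = bootstrap(
            self.m, replicates, self.method, seed, self.model
        )
        return BootstrapResults(sample, list(self.m.taxa))


# ---------------------------------------------------------------------------
# Mk MCMC


def _random_binary_tree(
    labels: list[str], rng: np.random.Generator, mean_length: float
) -> Tree:
    """Uniform random unrooted binary topology with exponential lengths."""
    labels = list(labels)
    order = rng.permutation(len(labels))
    root = Node()
    first = [Node(label=labels[i]) for i in order[:3]]
    for nd in first:
        root.add_child(nd)
    tree = Tree(root)
    for i in order[3:]:
        edges = tree.edges()
        edge = edges[int(rng.integers(len(edges)))]
        tree.attach(labels[i], edge, pendant_length=0.0)
    for nd in tree.postorder():
        if nd is not tree.root:
            nd.length = float(rng.exponential(mean_length))
    return tree


def mcmc_mk(
    m: DataMatrix,
    model: SubstModel | None = None,
    chain_length: int = 20000,
    burnin_fraction: float = 0.25,
    thinning: int = 20,
    seed: int = 0,
    prior_mean_length: float = 0.1,
) -> TreeSample:
    """Metropolis-Hastings over (topology, branch lengths) under Mk.

    Proposals: random NNI (probability 0.5) and a single-branch log-uniform
    multiplier in [e^-0.5, e^0.5] (probability 0.5).  Priors: uniform on
    unrooted binary topologies, iid Exponential(mean
    ``prior_mean_length``) branch lengths.  Posterior split frequencies
    over the post-burn-in thinned sample are PP values.  The acceptance
    rate is recorded in the sample's provenance.
    """
    if m.n_taxa < 4:
        raise ValueError("MCMC needs >= 4 taxa")
    if chain_length < 10 * thinning:
        raise ValueError("chain length must be at least 10x thinning")
    model = model or SubstModel("Mk")
    rng = np.random.default_rng(seed)
    tree = _random_binary_tree(list(m.taxa), rng, prior_mean_length)
    rate = 1.0 / prior_mean_length

    def log_posterior(t: Tree) -> float:
        ll, _ = tree_loglik(t, m, model)
        prior = sum(
            -rate * (nd.length or 0.0)
            for nd in t.postorder()
            if nd is not t.root
        )
        return ll + prior

    current = log_posterior(tree)
    accepted = 0
    sample: list[Tree] = []
    burnin = int(chain_length * burnin_fraction)
    for step in range(chain_length):
        use_nni = rng.random() < 0.5
        if use_nni:
            internals = [
                e for e in tree.internal_edges()
                if e.parent is not None and len(e.children) == 2
            ]
            if internals:
                edge = internals[int(rng.integers(len(internals)))]
                a, b = _nni_alternatives(edge)[int(rng.integers(2))]
                _swap_subtrees(a, b)
                proposed = log_posterior(tree)
                if np.log(rng.random()) < proposed - current:
                    current = proposed
                    accepted += 1
                else:
                    _swap_subtrees(a, b)
        else:
            branches = [nd for nd in tree.postorder() if nd is not tree.root]
            node = branches[int(rng.integers(len(branches)))]
            factor = float(np.exp(rng.uniform(-0.5, 0.5)))
            old = node.length or 1e-9
            node.length = old * factor
            proposed = log_posterior(tree)
            # log-uniform multiplier: Hastings ratio is the factor itself
            if np.log(rng.random()) < proposed - current + np.log(factor):
                current = proposed
                accepted += 1
            else:
                node.length = old
        if step >= burnin and (step - burnin) % thinning == 0:
            sample.append(tree.copy())
    return TreeSample(
        sample,
        provenance={
            "MCMC": "Mk Metropolis-Hastings",
            "chain_length": chain_length,
            "burn_in": burnin,
            "thinning": thinning,
            "seed": seed,
            "acceptance_rate": accepted / chain_length,
        },
    )


class MCMCResults:
    """Posterior tree sample with split-probability accessors."""

    def __init__(self, sample: TreeSample, labels: list[str]):
        self.sample = sample
        self.labels = labels
        self._freqs: dict[Bipartition, float] | None = None

    @property
    def acceptance_rate(self) -> float:
        return self.sample.provenance["acceptance_rate"]

    def split_probabilities(self) -> dict[Bipartition, float]:
        if self._freqs is None:
            self._freqs = bipartition_frequencies(self.sample, self.labels)
        return self._freqs

    def posterior_probability(self, side: set[str]) -> float:
        bits = 0
        for t in side:
            bits |= 1 << self.labels.index(t)
        bip = Bipartition.from_side(bits, len(self.labels))
        return self.split_probabilities().get(bip, 0.0)

    def summary(self) -> str:
        prov = self.sample.provenance
        lines = [
            "Mk MCMC posterior".center(56),
            "=" * 56,
            f"Chain length:    {prov['chain_length']}",
            f"Burn-in:         {prov['burn_in']}",
            f"Thinning:        {prov['thinning']}",
            f"Samples:         {len(self.sample)}",
            f"Acceptance rate: {prov['acceptance_rate']:.3f}",
            "-" * 56,
            f"{'PP':>6}  split (smaller side)",
        ]
        for bip, f in sorted(
            self.split_probabilities().items(), key=lambda kv: -kv[1]
        ):
            side = [self.labels[i] for i in bip.side_indices()]
            other = [self.labels[i] for i in bip.other_side_indices()]
            small = side if len(side) <= len(other) else other
            lines.append(f"{f:>6.2f}  {{{', '.join(sorted(small))}}}")
        return "\n".join(lines)


class MkMCMC:
    """Bayesian Mk model over a categorical matrix; ``fit`` runs the chain."""

    def __init__(self, m: DataMatrix, model: SubstModel | None = None):
        self.m = m
        self.model = model or SubstModel("Mk")

    def fit(
        self,
        chain_length: int = 20000,
        burnin_fraction: float = 0.25,
        thinning: int = 20,
        seed: int = 0,
        prior_mean_length: float = 0.1,
    ) -> MCMCResults:
        sample = mcmc_mk(
            self.m, self.model, chain_length, burnin_fraction, thinning,
            seed, prior_mean_length,
        )
        rate = sample.provenance["acceptance_rate"]
        if not 0.0 < rate < 1.0:
            warnings.warn(
                f"degenerate MCMC acceptance rate {rate:.3f}", stacklevel=2
            )
        return MCMCResults(sample, list(self.m.taxa))
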