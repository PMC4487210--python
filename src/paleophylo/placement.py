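"""Evolutionary placement of query taxa (fossils) onto a fixed backbone.

The query — typically a fossil scored for morphological characters — is
attached to every branch of a reference topology in turn and scored, per
one of three character-weighting schemes:

* ``MP`` — weighted parsimony: characters weighted by their consistency
  index on the backbone, score = weighted step increase.
* ``ML_MK`` — likelihood under Lewis' Mk model with characters weighted by
  their normalized per-character log-likelihood on the backbone.
* ``ML_GTR`` — as ``ML_MK`` but with empirical state frequencies
  (the multistate-GTR parameterization).

ML placements attach at the branch midpoint and optimize the pendant
branch only (the usual EPA economy; full re-optimization is available
behind a flag) and report softmax likelihood weights over branches, the
placement-probability semantics of the evolutionary placement algorithm.
Queries whose character suites mix the diagnostic states of distant
clades — the situation for anatomically intermediate fossils — may
resolve to different branches under different schemes; such scheme
dependence is exactly what the swap report records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import (
    SubstModel,
    optimize_branch_lengths,
    optimize_single_branch,
    tree_loglik,
)
from .matrix import DataMatrix
from .parsimony import consistency_index, insertion_scan
from .trees import Tree

__all__ = [
    "SCHEMES",
    "calibrate_character_weights",
    "place_query",
    "compare_schemes",
    "PlacementTable",
    "SwapReport",
    "EvolutionaryPlacement",
    "PlacementResults",
]

SCHEMES = ("MP", "ML_MK", "ML_GTR")

_MIN_WEIGHT = 1e-3  # keeps every character in play even at CI == 0


def _scheme_model(scheme: str) -> SubstModel | None:
    if scheme == "ML_MK":
        return SubstModel("Mk")
    if scheme == "ML_GTR":
        return SubstModel("multistate-GTR")
    return None


def calibrate_character_weights(
    backbone: Tree,
    m: DataMatrix,
    scheme: str,
    opt_sweeps: int = 5,
) -> np.ndarray:
    """Per-character weights calibrated against the backbone.

    MP: the character's consistency index on the backbone (floored at a
    small positive value).  ML schemes: ``exp(l_c - max_c' l_c')`` from
    per-character log-likelihoods on the backbone with optimized branch
    lengths, rescaled to mean 1.  All weights are strictly positive.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; use one of {SCHEMES}")
    sub = m.subset_taxa(backbone.leaf_labels())
    if scheme == "MP":
        ci = consistency_index(backbone, sub)
        return np.maximum(ci, _MIN_WEIGHT)
    model = _scheme_model(scheme)
    opt, _, _ = optimize_branch_lengths(
        backbone, sub, model, np.ones(sub.n_characters), max_sweeps=opt_sweeps
    )
    _, per_char = tree_loglik(opt, sub, model, np.ones(sub.n_characters))
    w = np.exp(per_char - per_char.max())
    w = np.maximum(w, _MIN_WEIGHT)
    return w / w.mean()


@dataclass
class PlacementTable:
    """Per-branch placement scores for one query under one scheme.

    ``branch_labels[b]`` identifies branch ``b`` by the leaf set on its
    far (subtree) side; ``raw_scores`` are weighted log-likelihoods (ML)
    or weighted added steps (MP); ``likelihood_weights`` are the softmax
    placement probabilities (ML) or inverse-rank weights (MP, reported
    for completeness, not probabilities).
    """

    query: str
    scheme: str
    branch_labels: list[frozenset[str]]
    raw_scores: np.ndarray
    likelihood_weights: np.ndarray
    pendant_lengths: np.ndarray | None = None
    ranks: np.ndarray | None = None

    @property
    def best_branch(self) -> int:
        return int(np.argmax(self.likelihood_weights))

    @property
    def best_branch_labels(self) -> frozenset[str]:
        return self.branch_labels[self.best_branch]

    @property
    def tie_set(self) -> list[int]:
        if self.scheme == "MP":
            lo = self.raw_scores.min()
            return [int(b) for b in np.flatnonzero(self.raw_scores == lo)]
        hi = self.raw_scores.max()
        return [
            int(b)
            for b in np.flatnonzero(self.raw_scores >= hi - 1e-9)
        ]

    def to_frame(self) -> pd.DataFrame:
        def short(labels: frozenset[str]) -> str:
            return "{" + ",".join(sorted(labels)) + "}"

        data = {
            "branch": [short(s) for s in self.branch_labels],
            "raw_score": self.raw_scores,
            "likelihood_weight": self.likelihood_weights,
        }
        if self.pendant_lengths is not None:
            data["pendant_length"] = self.pendant_lengths
        if self.ranks is not None:
            data["rank"] = self.ranks
        frame = pd.DataFrame(data)
        frame.insert(0, "scheme", self.scheme)
        frame.insert(0, "query", self.query)
        order = (
            frame["raw_score"].rank(ascending=self.scheme == "MP")
        )
        return frame.assign(_o=order).sort_values("_o").drop(columns="_o")


@dataclass
class SwapReport:
    """Best branches per scheme for each query; the swap flag marks
    queries whose best placement depends on the weighting scheme."""

    entries: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    def add(self, query: str, per_scheme: dict[str, frozenset[str]]) -> None:
        self.entries[query] = dict(per_scheme)

    def swapped(self, query: str) -> bool:
        return len(set(self.entries[query].values())) >= 2

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for query, per_scheme in self.entries.items():
            row: dict = {"query": query, "swap": self.swapped(query)}
            for scheme, labels in per_scheme.items():
                row[scheme] = "{" + ",".join(sorted(labels)) + "}"
            rows.append(row)
        return pd.DataFrame(rows)


def place_query(
    backbone: Tree,
    m: DataMatrix,
    query: str,
    weights: np.ndarray | None = None,
    scheme: str = "ML_MK",
    model: SubstModel | None = None,
    pendant_init: float = 0.05,
    full_reoptimize: bool = False,
) -> PlacementTable:
    """Score the attachment of ``query`` on every branch of the backbone.

    ML schemes attach at the branch midpoint, optimize the pendant branch
    (or, with ``full_reoptimize``, all branch lengths) and report softmax
    likelihood weights that sum to one.  The MP scheme scores weighted
    step increases via the parsimony insertion scan.  An all-missing
    query yields uniform weights with a warning.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    qi = m.taxon_index(query)
    if not m.scored[qi].any():
        warnings.warn(
            f"query {query!r} has no scored characters; placement is "
            "uninformative",
            stacklevel=2,
        )
    if weights is None:
        weights = np.ones(m.n_characters)
    if scheme == "MP":
        scan = insertion_scan(backbone, m, query, weights)
        scores = scan.added_steps
        ranks = np.argsort(np.argsort(scores, kind="stable"), kind="stable") + 1
        inv = 1.0 / ranks
        return PlacementTable(
            query=query,
            scheme=scheme,
            branch_labels=list(scan.branch_labels),
            raw_scores=scores.astype(float),
            likelihood_weights=inv / inv.sum(),
            ranks=ranks,
        )
    model = model or _scheme_model(scheme)
    tree = backbone.copy()
    edges = tree.edges()
    labels = []
    logliks = np.zeros(len(edges))
    pendants = np.zeros(len(edges))
    for b, edge in enumerate(edges):
        labels.append(frozenset(
            leaf.label for leaf in _leaves_below(edge)
        ))
        knot, leaf = tree.attach(query, edge, pendant_length=pendant_init)
        if full_reoptimize:
            opt, value, _ = optimize_branch_lengths(
                tree, m, model, weights, max_sweeps=3
            )
            pendants[b] = [
                nd.length for nd in opt.postorder() if nd.label == query
            ][0]
            logliks[b] = value
        else:
            logliks[b] = optimize_single_branch(tree, leaf, m, model, weights)
            pendants[b] = leaf.length
        tree.detach(knot)
    if m.scored[qi].any():
        shifted = logliks - logliks.max()
        lw = np.exp(shifted)
    else:
        lw = np.ones(len(edges))
    return PlacementTable(
        query=query,
        scheme=scheme,
        branch_labels=labels,
        raw_scores=logliks,
        likelihood_weights=lw / lw.sum(),
        pendant_lengths=pendants,
    )


def _leaves_below(node) -> list:
    out = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if nd.is_leaf:
            out.append(nd)
        else:
            stack.extend(nd.children)
    return out


def compare_schemes(tables: dict[str, PlacementTable]) -> dict:
    """Summarize one query's best branch per scheme and flag swaps."""
    queries = {t.query for t in tables.values()}
    if len(queries) != 1:
        raise ValueError("tables must all describe the same query")
    best = {
        scheme: table.best_branch_labels for scheme, table in tables.items()
    }
    best_weight = {
        scheme: float(table.likelihood_weights[table.best_branch])
        for scheme, table in tables.items()
    }
    return {
        "query": queries.pop(),
        "best_branch": best,
        "best_weight": best_weight,
        "swap": len(set(best.values())) >= 2,
    }


# ---------------------------------------------------------------------------
# model / results surface


class PlacementResults:
    """Placement tables for one or more queries across weighting schemes."""

    def __init__(
        self,
        model: "EvolutionaryPlacement",
        tables: dict[str, dict[str, PlacementTable]],
    ):
        self.model = model
        self.tables = tables
        self.swap_report = SwapReport()
        for query, per_scheme in tables.items():
            self.swap_report.add(
                query,
                {s: t.best_branch_labels for s, t in per_scheme.items()},
            )

    def table(self, query: str, scheme: str) -> PlacementTable:
        return self.tables[query][scheme]

    def to_frame(self) -> pd.DataFrame:
        frames = [
            t.to_frame()
            for per_scheme in self.tables.values()
            for t in per_scheme.values()
        ]
        return pd.concat(frames, ignore_index=True)

    def to_jplace(self) -> dict:
        """A jplace-style record: edge-numbered tree plus placements."""
        tree = self.model.backbone.copy()
        edges = tree.edges()
        numbers = {id(e): i for i, e in enumerate(edges)}
        for e in edges:
            e.label = (e.label or "") + "{" + str(numbers[id(e)]) + "}"
        placements = []
        for query, per_scheme in self.tables.items():
            for scheme, t in per_scheme.items():
                placements.append(
                    {
                        "n": [query],
                        "scheme": scheme,
                        "p": [
                            [
                                b,
                                float(t.raw_scores[b]),
                                float(t.likelihood_weights[b]),
                            ]
                            for b in np.argsort(-t.likelihood_weights)
                        ],
                    }
                )
        return {
            "tree": tree.to_newick(),
            "placements": placements,
            "fields": ["edge_num", "score", "likelihood_weight"],
            "version": 3,
        }

    def summary(self) -> str:
        lines = [
            "Evolutionary placement".center(60),
            "=" * 60,
            f"Backbone taxa: {self.model.backbone.n_leaves}",
            f"Schemes:       {', '.join(self.model.schemes)}",
            "-" * 60,
        ]
        frame = self.swap_report.to_frame()
        lines.append(frame.to_string(index=False))
        return "\n".join(lines)


class EvolutionaryPlacement:
    """Placement model: fixed backbone + character matrix + schemes.

    ``fit`` calibrates per-character weights per scheme against the
    backbone's extant taxa, places each query on every branch, and
    reports scheme-dependent position swaps.
    """

    def __init__(
        self,
        backbone: Tree,
        m: DataMatrix,
        schemes: tuple[str, ...] = SCHEMES,
    ):
        for s in schemes:
            if s not in SCHEMES:
                raise ValueError(f"unknown scheme {s!r}")
        self.backbone = backbone
        self.m = m
        self.schemes = tuple(schemes)

    def fit(
        self,
        queries: list[str] | str,
        full_reoptimize: bool = False,
    ) -> PlacementResults:
        if isinstance(queries, str):
            queries = [queries]
        weights = {
            s: calibrate_character_weights(self.backbone, self.m, s)
            for s in self.schemes
        }
        # ML backbones carry optimized lengths for the attachment scans
        opt_backbones: dict[str, Tree] = {}
        for s in self.schemes:
            if s == "MP":
                opt_backbones[s] = self.backbone
            else:
                sub = self.m.subset_taxa(self.backbone.leaf_labels())
                opt, _, _ = optimize_branch_lengths(
                    self.backbone, sub, _scheme_model(s), weights[s],
                    max_sweeps=5,
                )
                opt_backbones[s] = opt
        tables: dict[str, dict[str, PlacementTable]] = {}
        for query in queries:
            tables[query] = {}
            for s in self.schemes:
                tables[query][s] = place_query(
                    opt_backbones[s],
                    self.m,
                    query,
                    weights[s],
                    scheme=s,
                    full_reoptimize=full_reoptimize,
                )
        return PlacementResults(self, tables)
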