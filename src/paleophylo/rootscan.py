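"""Outgroup-inferred root placement per gene partition, and gene jackknifing.

Where an outgroup attaches to an ingroup-only topology determines the
ingroup root.  Placing each outgroup taxon as a likelihood query on every
ingroup branch (per partition, with per-partition branch lengths) turns
root placement into an evolutionary-placement problem, and per-branch
likelihood weights aggregate into support for competing *root
hypotheses*: each hypothesis is defined by the ingroup clade that the
root would split off.  For the royal-fern case these are

* H1 ("paraphyletic" scenario) — root on the branch separating
  *Osmundastrum* from the remainder of the family;
* H2 ("monophyletic" scenario) — root on the *Leptopteris* + *Todea* stem,
  leaving *Osmunda s.l.* as a clade;
* H3 — root isolating *Osmunda s.str.*, implying an
  *Osmundastrum*-*Leptopteris*-*Todea* clade.

Clade membership arrives as plain taxon lists, so the machinery
generalizes to any rooting controversy.  Gene jackknifing repeats the
scan on the concatenation, on each partition alone, and on each
leave-one-out concatenation, exposing which partitions drive a contested
root.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .likelihood import SubstModel, optimize_branch_lengths
from .matrix import DataMatrix, PartitionScheme
from .placement import place_query
from .inference import Bootstrap
from .trees import Tree

__all__ = [
    "classify_branch",
    "outgroup_root_scan",
    "gene_jackknife",
    "split_support_scan",
    "RootPlacementScan",
    "RootScanResults",
]


def classify_branch(
    tree: Tree,
    branch_labels: frozenset[str],
    clades: dict[str, set[str]],
) -> str:
    """Map an ingroup branch to the root hypothesis it would realize.

    ``branch_labels`` is the leaf set on one side of the branch;
    ``clades`` maps hypothesis labels (e.g. ``"H1"``) to taxon sets.  The
    branch realizes a hypothesis iff it separates exactly that clade from
    everything else; otherwise ``"other"``.
    """
    all_taxa = frozenset(tree.leaf_labels())
    side = frozenset(branch_labels)
    complement = all_taxa - side
    for label, clade in clades.items():
        want = frozenset(clade)
        if side == want or complement == want:
            return label
    return "other"


def _scan_one_subset(
    ingroup_tree: Tree,
    m: DataMatrix,
    columns: np.ndarray,
    outgroups: list[str],
    clades: dict[str, set[str]],
    model: SubstModel,
    opt_sweeps: int,
) -> dict:
    """Root scan of one column subset: re-optimize ingroup branch lengths,
    place each outgroup taxon, average branch weights, aggregate."""
    sub = m.subset_columns(columns)
    ingroup_taxa = ingroup_tree.leaf_labels()
    sub_ingroup = sub.subset_taxa(ingroup_taxa)
    variable = 0
    for c in range(sub_ingroup.n_characters):
        masks = [
            int(sub_ingroup.masks[i, c])
            for i in range(sub_ingroup.n_taxa)
            if sub_ingroup.scored[i, c]
        ]
        inter = ~0
        for mk in masks:
            inter &= mk
        if masks and inter == 0:
            variable += 1
    opt, _, model = optimize_branch_lengths(
        ingroup_tree, sub_ingroup, model,
        np.ones(sub_ingroup.n_characters), max_sweeps=opt_sweeps,
        optimize_alpha=model.alpha is not None,
    )
    branch_weights: np.ndarray | None = None
    branch_labels: list[frozenset[str]] | None = None
    for og in outgroups:
        table = place_query(
            opt, sub.subset_taxa(ingroup_taxa + [og]), og,
            np.ones(sub.n_characters), scheme="ML_GTR", model=model,
        )
        if branch_weights is None:
            branch_weights = table.likelihood_weights.copy()
            branch_labels = list(table.branch_labels)
        else:
            branch_weights += table.likelihood_weights
    branch_weights /= len(outgroups)
    support: dict[str, float] = {}
    for labels, w in zip(branch_labels, branch_weights):
        h = classify_branch(ingroup_tree, labels, clades)
        support[h] = support.get(h, 0.0) + float(w)
    top = int(np.argmax(branch_weights))
    hyps = {h: support.get(h, 0.0) for h in clades}
    hyps["other"] = support.get("other", 0.0)
    best_h = max(hyps, key=hyps.get)
    return {
        "support": hyps,
        "top_hypothesis": best_h,
        "top_branch": branch_labels[top],
        "branch_weights": dict(zip(branch_labels, branch_weights)),
        "n_columns": int(len(columns)),
        "n_variable": variable,
        "low_information": variable < 4,
    }


def outgroup_root_scan(
    ingroup_tree: Tree,
    m: DataMatrix,
    scheme: PartitionScheme,
    outgroups: list[str],
    clades: dict[str, set[str]],
    model: SubstModel | None = None,
    opt_sweeps: int = 3,
) -> pd.DataFrame:
    """Per-partition outgroup placement aggregated to root hypotheses.

    For each partition, ingroup branch lengths (and the gamma shape, when
    enabled) are re-optimized on that partition's columns, each outgroup
    taxon is placed as a likelihood query on every ingroup branch, and
    the averaged per-branch likelihood weights are pooled by
    :func:`classify_branch`.  Partitions with fewer than 4 variable
    columns are flagged low-information but still reported.  The result
    is invariant to the order of the outgroup taxa.
    """
    for og in outgroups:
        m.taxon_index(og)
        if og in ingroup_tree.leaf_labels():
            raise ValueError(f"outgroup {og!r} present in the ingroup tree")
    model = model or SubstModel("DNA-GTR", alpha=1.0, ncat=4)
    rows = []
    for name in scheme.names:
        res = _scan_one_subset(
            ingroup_tree, m, scheme.partitions[name], sorted(outgroups),
            clades, model, opt_sweeps,
        )
        row = {
            "subset": name,
            "flag": scheme.flags.get(name, ""),
            **res["support"],
            "top_hypothesis": res["top_hypothesis"],
            "top_branch": "{" + ",".join(sorted(res["top_branch"])) + "}",
            "n_columns": res["n_columns"],
            "n_variable": res["n_variable"],
            "low_information": res["low_information"],
        }
        rows.append(row)
    return pd.DataFrame(rows)


def gene_jackknife(
    ingroup_tree: Tree,
    m: DataMatrix,
    scheme: PartitionScheme,
    outgroups: list[str],
    clades: dict[str, set[str]],
    model: SubstModel | None = None,
    opt_sweeps: int = 3,
) -> pd.DataFrame:
    """Root scans over the concatenation, each single partition, and each
    leave-one-out concatenation (1 + P + P subsets for P partitions)."""
    model = model or SubstModel("DNA-GTR", alpha=1.0, ncat=4)
    names = scheme.names
    subsets: list[tuple[str, str, np.ndarray]] = [
        ("concatenated", "all", scheme.all_columns())
    ]
    for name in names:
        subsets.append((f"single:{name}", "single", scheme.partitions[name]))
    if len(names) > 1:  # leave-one-out is empty for a single partition
        for name in names:
            rest = [p for p in names if p != name]
            subsets.append(
                (f"without:{name}", "leave-one-out", scheme.columns(rest))
            )
    rows = []
    for label, mode, columns in subsets:
        res = _scan_one_subset(
            ingroup_tree, m, columns, sorted(outgroups), clades, model,
            opt_sweeps,
        )
        rows.append(
            {
                "subset": label,
                "mode": mode,
                **res["support"],
                "top_hypothesis": res["top_hypothesis"],
                "top_branch": "{" + ",".join(sorted(res["top_branch"])) + "}",
                "n_columns": res["n_columns"],
                "low_information": res["low_information"],
            }
        )
    return pd.DataFrame(rows)


def split_support_scan(
    subsets: dict[str, DataMatrix],
    focal_splits: dict[str, set[str]],
    replicates: int = 200,
    method: str = "NJ",
    seed: int = 0,
    model: SubstModel | None = None,
) -> pd.DataFrame:
    """Bootstrap support for named splits across data subsets.

    ``focal_splits`` maps split names to one side's taxon set; values are
    BS percentages in [0, 100].
    """
    rows = []
    for subset_name, sub in subsets.items():
        res = Bootstrap(sub, method=method, model=model).fit(
            replicates=replicates, seed=seed
        )
        row: dict = {"subset": subset_name}
        for split_name, side in focal_splits.items():
            row[split_name] = res.support_percent(set(side))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# model / results surface


class RootScanResults:
    """Per-subset root-hypothesis support tables."""

    def __init__(
        self,
        model: "RootPlacementScan",
        per_partition: pd.DataFrame,
        jackknife: pd.DataFrame | None,
    ):
        self.model = model
        self.per_partition = per_partition
        self.jackknife = jackknife

    def top_hypothesis(self, subset: str) -> str:
        frame = self.per_partition
        if subset not in set(frame["subset"]) and self.jackknife is not None:
            frame = self.jackknife
        row = frame[frame["subset"] == subset]
        if row.empty:
            raise KeyError(f"unknown subset {subset!r}")
        return str(row["top_hypothesis"].iloc[0])

    def hypothesis_columns(self) -> list[str]:
        return list(self.model.clades) + ["other"]

    def summary(self) -> str:
        cols = ["subset"] + self.hypothesis_columns() + ["top_hypothesis"]
        lines = [
            "Outgroup root-placement scan".center(64),
            "=" * 64,
            f"Outgroups: {', '.join(sorted(self.model.outgroups))}",
            "Per-partition support:",
            self.per_partition[cols].round(3).to_string(index=False),
        ]
        if self.jackknife is not None:
            lines += [
                "-" * 64,
                "Gene jackknife:",
                self.jackknife[["mode"] + cols].round(3).to_string(index=False),
            ]
        return "\n".join(lines)


class RootPlacementScan:
    """Root-placement scan model: ingroup tree, partitioned alignment,
    outgroup taxa and root-hypothesis clade definitions."""

    def __init__(
        self,
        ingroup_tree: Tree,
        m: DataMatrix,
        scheme: PartitionScheme,
        outgroups: list[str],
        clades: dict[str, set[str]],
        model: SubstModel | None = None,
    ):
        self.ingroup_tree = ingroup_tree
        self.m = m
        self.scheme = scheme
        self.outgroups = list(outgroups)
        self.clades = dict(clades)
        self.model = model or SubstModel("DNA-GTR", alpha=1.0, ncat=4)

    def fit(
        self, jackknife: bool = False, opt_sweeps: int = 3
    ) -> RootScanResults:
        per_partition = outgroup_root_scan(
            self.ingroup_tree, self.m, self.scheme, self.outgroups,
            self.clades, self.model, opt_sweeps,
        )
        jk = None
        if jackknife:
            jk = gene_jackknife(
                self.ingroup_tree, self.m, self.scheme, self.outgroups,
                self.clades, self.model, opt_sweeps,
            )
        return RootScanResults(self, per_partition, jk)
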