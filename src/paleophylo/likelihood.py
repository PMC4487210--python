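"""Pruning-algorithm likelihoods for categorical and nucleotide data.

Three reversible substitution models are provided:

* ``Mk`` — Lewis' k-state symmetric model: uniform stationary frequencies,
  equal exchangeabilities.  The transition probability has the closed form
  ``P_same(t) = 1/k + ((k-1)/k) exp(-k t / (k-1))`` under the rate
  normalization used throughout (one expected substitution per unit branch
  length).
* ``multistate-GTR`` — Mk with unequal stationary frequencies (equal
  exchangeabilities, empirical state frequencies).  This is the package's
  reconstruction of "GTR for multistate characters": full multistate
  exchangeability estimation is deliberately not implemented.
* ``DNA-GTR`` — the general time-reversible nucleotide model, optionally
  with discrete-gamma rate variation (default 4 categories).

Morphological characters get a per-character alphabet: the states observed
for that character (minimum 2), the standard morphological-likelihood
convention.  Likelihoods are computed by Felsenstein pruning over
compressed patterns with per-pattern rescaling; missing cells contribute
all-ones partials and polymorphic cells the indicator of their state set.
Under reversibility the likelihood is invariant to root placement.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .matrix import DataMatrix
from .trees import Node, Tree

__all__ = [
    "SubstModel",
    "transition_matrix",
    "tree_loglik",
    "optimize_branch_lengths",
    "ascertainment_correct",
    "discrete_gamma_rates",
]


def discrete_gamma_rates(alpha: float, ncat: int) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability discrete-gamma categories
    (shape = scale mean 1), the standard rate-heterogeneity discretization."""
    if ncat == 1:
        return np.ones(1)
    edges = _gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=alpha, scale=1 / alpha)
    # mean of a gamma(alpha, 1/alpha) over [lo, hi], times ncat
    cdf_ap1 = gammainc(alpha + 1, edges * alpha)
    rates = ncat * np.diff(cdf_ap1)
    return rates / rates.mean() * 1.0


class SubstModel:
    """A reversible substitution model with unit expected rate.

    Parameters
    ----------
    kind : {"Mk", "multistate-GTR", "DNA-GTR"}
    k : int
        State count (4 and fixed for DNA).
    pi : array-like, optional
        Stationary frequencies; uniform for Mk, required (or empirical)
        for the others.
    exchangeabilities : array-like, optional
        Symmetric rate multipliers (DNA-GTR); the 6 upper-triangle values
        in order AC, AG, AT, CG, CT, GT, or a full k x k matrix.  Equal
        for the categorical models.
    alpha : float, optional
        Discrete-gamma shape (DNA only); ``None`` disables rate variation.
    ncat : int
        Gamma category count (default 4).
    """

    def __init__(
        self,
        kind: str = "Mk",
        k: int = 2,
        pi=None,
        exchangeabilities=None,
        alpha: float | None = None,
        ncat: int = 4,
    ):
        if kind not in ("Mk", "multistate-GTR", "DNA-GTR"):
            raise ValueError(f"unknown model kind {kind!r}")
        self.kind = kind
        if kind == "DNA-GTR":
            k = 4
        self.k = int(k)
        if kind == "Mk":
            self.pi = np.full(self.k, 1.0 / self.k)
        else:
            if pi is None:
                self.pi = np.full(self.k, 1.0 / self.k)
            else:
                self.pi = np.asarray(pi, dtype=float)
                if self.pi.shape != (self.k,) or (self.pi <= 0).any():
                    raise ValueError("pi must be k positive frequencies")
                self.pi = self.pi / self.pi.sum()
        if exchangeabilities is None or kind != "DNA-GTR":
            self.s = np.ones((self.k, self.k))
        else:
            s = np.asarray(exchangeabilities, dtype=float)
            if s.shape == (6,) and self.k == 4:
                full = np.zeros((4, 4))
                full[np.triu_indices(4, 1)] = s
                s = full + full.T
            if s.shape != (self.k, self.k):
                raise ValueError("exchangeabilities must be 6-vector or k x k")
            self.s = s
        np.fill_diagonal(self.s, 0.0)
        self.alpha = alpha if kind == "DNA-GTR" else None
        self.ncat = int(ncat) if self.alpha is not None else 1
        self._build()

    def _build(self) -> None:
        Q = self.s * self.pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.dot(self.pi, np.diag(Q))
        if rate <= 0:
            raise ValueError("degenerate rate matrix")
        Q /= rate
        self.Q = Q
        # detailed balance makes diag(sqrt(pi)) Q diag(1/sqrt(pi)) symmetric
        sq = np.sqrt(self.pi)
        B = (sq[:, None] * Q) / sq[None, :]
        eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
        self._eigval = eigval
        self._left = eigvec / sq[:, None]      # D^{-1/2} U
        self._right = (eigvec * sq[:, None]).T  # U' D^{1/2}

    def rates(self) -> np.ndarray:
        """Per-category relative rates (length ``ncat``)."""
        if self.alpha is None:
            return np.ones(1)
        return discrete_gamma_rates(self.alpha, self.ncat)

    def with_alpha(self, alpha: float) -> "SubstModel":
        return SubstModel(
            self.kind, self.k, self.pi, self.s, alpha=alpha, ncat=self.ncat
        )

    def transition(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t) for one rate category, via the eigendecomposition."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        P = (self._left * np.exp(self._eigval * t * rate)) @ self._right
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        g = f"+G{self.ncat}(a={self.alpha})" if self.alpha else ""
        return f"<SubstModel {self.kind} k={self.k}{g}>"


def transition_matrix(model: SubstModel, t: float) -> np.ndarray:
    """Transition matrix at branch length ``t`` (gamma categories averaged)."""
    rates = model.rates()
    P = np.zeros((model.k, model.k))
    for r in rates:
        P += model.transition(t, r)
    return P / len(rates)


# ---------------------------------------------------------------------------
# pruning


def _char_submodel(
    model: SubstModel, m: DataMatrix, char: int, alphabet: str = "observed"
):
    """Per-character alphabet projection for categorical models.

    With ``alphabet="observed"`` (the standard morphological convention)
    the submodel lives on the states observed for this character (at
    least 2); ``"declared"`` keeps the character's full declared alphabet.
    Column masks are re-encoded on the local alphabet; missing cells map
    to the full local state set.
    """
    nstates = len(m.characters[char].symbols)
    if alphabet == "declared":
        state_ids = list(range(nstates))
    else:
        observed = 0
        for i in range(m.n_taxa):
            if m.scored[i, char]:
                observed |= int(m.masks[i, char])
        state_ids = [s for s in range(nstates) if observed >> s & 1]
        if len(state_ids) < 2:
            state_ids = (
                state_ids + [s for s in range(nstates) if s not in state_ids]
            )[:2]
    k = len(state_ids)
    if model.kind == "multistate-GTR":
        counts = np.zeros(k)
        for i in range(m.n_taxa):
            if not m.scored[i, char]:
                continue
            mask = int(m.masks[i, char])
            hits = [j for j, s in enumerate(state_ids) if mask >> s & 1]
            for j in hits:
                counts[j] += 1.0 / len(hits)
        counts += 1.0  # +1 smoothing keeps frequencies strictly positive
        sub = SubstModel("multistate-GTR", k, pi=counts / counts.sum())
    else:
        sub = SubstModel("Mk", k)
    cols = np.zeros(m.n_taxa, dtype=np.int64)
    full = (1 << k) - 1
    for i in range(m.n_taxa):
        mask = int(m.masks[i, char])
        local = 0
        for j, s in enumerate(state_ids):
            if mask >> s & 1:
                local |= 1 << j
        cols[i] = local if (local and m.scored[i, char]) else full
    return sub, cols


def _mask_to_partial(mask: int, k: int) -> np.ndarray:
    return np.array([(mask >> s) & 1 for s in range(k)], dtype=float)


# ---------------------------------------------------------------------------
# cached likelihood workspace
#
# Building per-character submodels and leaf partials is much more expensive
# than one pruning pass, and the branch-length optimizers evaluate the same
# (matrix, model) pair thousands of times.  A workspace precomputes, per
# matrix object, characters grouped by their local state count with stacked
# eigendecompositions, so each evaluation is a handful of vectorized passes.
# Matrices are treated as immutable once they enter likelihood code.


class _Group:
    """Characters sharing a state count, with stacked model spectra.

    ``eigval``/``left``/``right`` have shape (c, k)/(c, k, k)/(c, k, k);
    when every character shares one model the arrays are squeezed to a
    single spectrum and transitions become one matrix per branch.
    """

    __slots__ = (
        "chars", "k", "eigval", "left", "right", "pi", "leaf", "shared"
    )

    def __init__(self, chars, k, eigval, left, right, pi, leaf, shared):
        self.chars = chars
        self.k = k
        self.eigval = eigval
        self.left = left
        self.right = right
        self.pi = pi
        self.leaf = leaf
        self.shared = shared


class _Workspace:
    __slots__ = ("groups", "rates", "char_map")

    def __init__(self, groups, rates, char_map):
        self.groups = groups
        self.rates = rates
        self.char_map = char_map


_WORKSPACES: "weakref.WeakKeyDictionary" = None  # initialized below
import weakref  # noqa: E402

_WORKSPACES = weakref.WeakKeyDictionary()


def _model_key(model: SubstModel, alphabet: str) -> tuple:
    return (
        model.kind,
        model.k,
        model.pi.tobytes(),
        model.s.tobytes(),
        model.alpha,
        model.ncat,
        alphabet,
    )


def _get_workspace(
    m: DataMatrix, model: SubstModel, alphabet: str
) -> _Workspace:
    per_matrix = _WORKSPACES.get(m)
    if per_matrix is None:
        per_matrix = {}
        _WORKSPACES[m] = per_matrix
    key = _model_key(model, alphabet)
    ws = per_matrix.get(key)
    if ws is None:
        ws = _build_workspace(m, model, alphabet)
        per_matrix[key] = ws
    return ws


def _build_workspace(
    m: DataMatrix, model: SubstModel, alphabet: str
) -> _Workspace:
    if model.kind == "DNA-GTR":
        from .matrix import compress_patterns

        reps, _, inverse = compress_patterns(m)
        k = 4
        leaf = {}
        for i, name in enumerate(m.taxa):
            rows = np.zeros((len(reps), k))
            for p, j in enumerate(reps):
                rows[p] = _mask_to_partial(int(m.masks[i, j]), k)
            leaf[name] = rows
        group = _Group(
            chars=np.arange(len(reps)),
            k=k,
            eigval=model._eigval,
            left=model._left,
            right=model._right,
            pi=model.pi,
            leaf=leaf,
            shared=True,
        )
        return _Workspace([group], model.rates(), inverse)
    # categorical: build per-character submodels, group by state count
    subs = []
    cols = []
    for c in range(m.n_characters):
        sub, col = _char_submodel(model, m, c, alphabet)
        subs.append(sub)
        cols.append(col)
    groups = []
    for k in sorted({sub.k for sub in subs}):
        chars = np.array([c for c in range(m.n_characters) if subs[c].k == k])
        eigval = np.stack([subs[c]._eigval for c in chars])
        left = np.stack([subs[c]._left for c in chars])
        right = np.stack([subs[c]._right for c in chars])
        pi = np.stack([subs[c].pi for c in chars])
        leaf = {}
        for i, name in enumerate(m.taxa):
            rows = np.zeros((len(chars), k))
            for ci, c in enumerate(chars):
                rows[ci] = _mask_to_partial(int(cols[c][i]), k)
            leaf[name] = rows
        groups.append(_Group(chars, k, eigval, left, right, pi, leaf, False))
    return _Workspace(groups, np.ones(1), None)


def _group_loglik(
    tree: Tree, group: _Group, rates: np.ndarray,
    lengths: dict | None = None,
) -> np.ndarray:
    """Per-entry log-likelihood for one workspace group (vectorized)."""
    c = len(group.chars)
    total = np.zeros((c, len(rates)))
    for ri, rate in enumerate(rates):
        partials: dict[Node, np.ndarray] = {}
        scale = np.zeros(c)
        for node in tree.postorder():
            if node.is_leaf:
                partials[node] = group.leaf[node.label]
            else:
                acc = None
                for child in node.children:
                    t = (
                        lengths[child]
                        if lengths is not None
                        else (child.length or 0.0)
                    )
                    part = partials.pop(child)
                    if group.shared:
                        P = (
                            group.left * np.exp(group.eigval * t * rate)
                        ) @ group.right
                        np.clip(P, 0.0, None, out=P)
                        down = part @ P.T
                    else:
                        P = np.einsum(
                            "cij,cj,cjk->cik",
                            group.left,
                            np.exp(group.eigval * t * rate),
                            group.right,
                        )
                        np.clip(P, 0.0, None, out=P)
                        down = np.einsum("cik,ck->ci", P, part)
                    acc = down if acc is None else acc * down
                mx = acc.max(axis=1)
                safe = np.where(mx > 0, mx, 1.0)
                acc = acc / safe[:, None]
                scale += np.log(safe)
                partials[node] = acc
        root = partials[tree.root]
        if group.pi.ndim == 1:
            site = root @ group.pi
        else:
            site = (root * group.pi).sum(axis=1)
        with np.errstate(divide="ignore"):
            total[:, ri] = np.log(site) + scale
    mx = total.max(axis=1, keepdims=True)
    return mx[:, 0] + np.log(np.exp(total - mx).mean(axis=1))


def _prune_loglik(
    tree: Tree,
    leaf_partials: dict[str, np.ndarray],
    model: SubstModel,
    lengths: dict[Node, float] | None = None,
) -> np.ndarray:
    """Log-likelihood per pattern; ``leaf_partials[label]`` has shape
    (npatterns, k).  Gamma categories are averaged at the root."""
    rates = model.rates()
    some = next(iter(leaf_partials.values()))
    npat = some.shape[0]
    total = np.zeros((npat, len(rates)))
    for ci, r in enumerate(rates):
        partials: dict[Node, np.ndarray] = {}
        scale = np.zeros(npat)
        for node in tree.postorder():
            if node.is_leaf:
                partials[node] = leaf_partials[node.label]
            else:
                acc = None
                for child in node.children:
                    t = (
                        lengths[child]
                        if lengths is not None
                        else (child.length or 0.0)
                    )
                    P = model.transition(t, r)
                    down = partials.pop(child) @ P.T
                    acc = down if acc is None else acc * down
                mx = acc.max(axis=1)
                bad = mx <= 0
                if bad.any():
                    mx = np.where(bad, 1.0, mx)
                acc = acc / mx[:, None]
                scale += np.log(np.where(mx > 0, mx, 1.0))
                partials[node] = acc
        root_part = partials[tree.root]
        site = root_part @ model.pi
        with np.errstate(divide="ignore"):
            total[:, ci] = np.log(site) + scale
    # average likelihood over equal-probability categories, stably
    mx = total.max(axis=1, keepdims=True)
    out = mx[:, 0] + np.log(
        np.exp(total - mx).mean(axis=1)
    )
    return out


def tree_loglik(
    tree: Tree,
    m: DataMatrix,
    model: SubstModel,
    weights: np.ndarray | None = None,
    ascertainment: str = "none",
    alphabet: str = "observed",
) -> tuple[float, np.ndarray]:
    """Felsenstein-pruning log-likelihood of a matrix on a tree.

    Returns ``(L, per_character)`` with ``L`` the character-weight-weighted
    sum of per-character log-likelihoods.  ``ascertainment="variable-only"``
    applies the variable-characters conditioning of Lewis' Mkv model;
    ``alphabet`` controls the per-character state space of categorical
    models (observed states by default).
    """
    w = m.weights if weights is None else np.asarray(weights, dtype=float)
    leaf_names = tree.leaf_labels()
    for name in leaf_names:
        m.taxon_index(name)
    ws = _get_workspace(m, model, alphabet)
    per_char = np.zeros(m.n_characters)
    if model.kind == "DNA-GTR":
        per_pattern = _group_loglik(tree, ws.groups[0], ws.rates)
        per_char = per_pattern[ws.char_map]
        if ascertainment == "variable-only":
            per_char = per_char - _log_prob_variable(tree, model, leaf_names)
    else:
        for group in ws.groups:
            per_char[group.chars] = _group_loglik(tree, group, ws.rates)
        if ascertainment == "variable-only":
            for c in range(m.n_characters):
                sub, _ = _char_submodel(model, m, c, alphabet)
                per_char[c] -= _log_prob_variable(tree, sub, leaf_names)
    if not np.all(np.isfinite(per_char)):
        warnings.warn(
            "zero-probability characters (conflicts at zero-length "
            "branches); log-likelihood is -inf",
            stacklevel=2,
        )
    return float(np.dot(w, per_char)), per_char


def _log_prob_variable(
    tree: Tree, model: SubstModel, leaf_names: list[str]
) -> float:
    """log(1 - P(constant pattern)) on the tree, for Mkv conditioning."""
    k = model.k
    p_const = 0.0
    for s in range(k):
        leaf_partials = {
            name: _mask_to_partial(1 << s, k)[None, :] for name in leaf_names
        }
        p_const += float(np.exp(_prune_loglik(tree, leaf_partials, model)[0]))
    p_const = min(p_const, 1.0 - 1e-300)
    return float(np.log1p(-p_const))


def ascertainment_correct(
    per_char_loglik: np.ndarray,
    model: SubstModel,
    tree: Tree,
    m: DataMatrix,
    mode: str = "none",
) -> np.ndarray:
    """Condition per-character likelihoods on being variable (Mkv).

    ``mode="none"`` is the identity; ``mode="variable-only"`` divides each
    character's likelihood by (1 - P(constant)) computed on the same tree,
    which strictly decreases the log-likelihood of variable data.
    """
    if mode == "none":
        return np.asarray(per_char_loglik, dtype=float).copy()
    if mode != "variable-only":
        raise ValueError(f"unknown ascertainment mode {mode!r}")
    leaf_names = tree.leaf_labels()
    out = np.asarray(per_char_loglik, dtype=float).copy()
    if model.kind == "DNA-GTR":
        out -= _log_prob_variable(tree, model, leaf_names)
        return out
    for c in range(out.shape[0]):
        sub, _ = _char_submodel(model, m, c)
        out[c] -= _log_prob_variable(tree, sub, leaf_names)
    return out


# ---------------------------------------------------------------------------
# branch-length optimization

_GRID = np.array(
    [1e-8, 1e-4, 1e-3, 5e-3, 0.02, 0.05, 0.1, 0.2, 0.4, 0.8, 1.5, 3.0,
     6.0, 12.0, 25.0, 50.0, 100.0]
)


def _minimize_branch(
    neg: Callable[[float], float],
    bounds: tuple[float, float],
    tol: float,
    seed_t: float | None = None,
) -> tuple[float, float]:
    """Bracket on a log-spaced grid, then refine with bounded Brent.

    Likelihood surfaces in t are unimodal but extremely flat for long
    branches, so a naive bounded search over [1e-8, 100] can converge to
    the plateau; the grid pins down the basin first.  Returns
    ``(argmin, min)``.
    """
    lo, hi = bounds
    grid = [t for t in _GRID if lo <= t <= hi]
    if seed_t is not None and lo <= seed_t <= hi:
        grid.append(seed_t)
    grid = sorted(set(grid))
    values = [neg(t) for t in grid]
    b = int(np.argmin(values))
    left = grid[b - 1] if b > 0 else lo
    right = grid[b + 1] if b < len(grid) - 1 else hi
    res = minimize_scalar(
        neg, bounds=(left, right), method="bounded", options={"xatol": tol}
    )
    if res.fun <= values[b]:
        return float(res.x), float(res.fun)
    return float(grid[b]), float(values[b])


def optimize_branch_lengths(
    tree: Tree,
    m: DataMatrix,
    model: SubstModel,
    weights: np.ndarray | None = None,
    max_sweeps: int = 20,
    tol: float = 1e-6,
    bounds: tuple[float, float] = (1e-8, 100.0),
    optimize_alpha: bool = False,
) -> tuple[Tree, float, "SubstModel"]:
    """Coordinate-wise branch-length optimization (in place on a copy).

    Each sweep optimizes every branch with bounded scalar search; sweeps
    stop when the log-likelihood improves by less than ``tol``.  The
    log-likelihood never decreases across sweeps.  With
    ``optimize_alpha`` the gamma shape is optimized once per sweep by the
    same scalar routine.  Returns ``(tree, best_loglik, model)``.
    """
    work = tree.copy()
    for node in work.postorder():
        if node is not work.root and (node.length is None or node.length <= 0):
            node.length = max(bounds[0], 1e-4)
    current, _ = tree_loglik(work, m, model, weights)
    for _ in range(max_sweeps):
        previous = current
        for node in work.postorder():
            if node is work.root:
                continue

            saved = node.length

            def neg(t: float, node=node) -> float:
                node.length = t
                value, _ = tree_loglik(work, m, model, weights)
                return -value

            best_t, best_neg = _minimize_branch(neg, bounds, tol, saved)
            if -best_neg >= current:
                node.length = best_t
                current = -best_neg
            else:
                node.length = saved
        if optimize_alpha and model.alpha is not None:

            def neg_alpha(a: float) -> float:
                value, _ = tree_loglik(work, m, model.with_alpha(a), weights)
                return -value

            res = minimize_scalar(
                neg_alpha, bounds=(0.05, 50.0), method="bounded",
                options={"xatol": 1e-3},
            )
            if -res.fun >= current:
                model = model.with_alpha(float(res.x))
                current = -res.fun
        if current - previous < tol:
            break
    return work, current, model


def optimize_single_branch(
    tree: Tree,
    node: Node,
    m: DataMatrix,
    model: SubstModel,
    weights: np.ndarray | None = None,
    bounds: tuple[float, float] = (1e-8, 100.0),
    tol: float = 1e-6,
) -> float:
    """Optimize one branch length in place; returns the new log-likelihood."""

    def neg(t: float) -> float:
        node.length = t
        value, _ = tree_loglik(tree, m, model, weights)
        return -value

    best_t, best_neg = _minimize_branch(neg, bounds, tol, node.length)
    node.length = best_t
    return -best_neg
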