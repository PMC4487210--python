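import itertools
import math

import numpy as np
import pytest

from paleophylo.iolib import FormatDialect, read_alignment
from paleophylo.likelihood import (
    SubstModel,
    ascertainment_correct,
    discrete_gamma_rates,
    optimize_branch_lengths,
    transition_matrix,
    tree_loglik,
)
from paleophylo.matrix import Character, DataMatrix
from paleophylo.trees import Tree

from conftest import random_binary_tree, random_matrix


def _binary_two_taxon(n, x):
    """Two taxa differing at x of n binary characters."""
    chars = [Character(str(j), tuple("01")) for j in range(n)]
    row_a = [{"0"} for _ in range(n)]
    row_b = [{"1"} if j < x else {"0"} for j in range(n)]
    return DataMatrix(["A", "B"], chars, [row_a, row_b])


class TestSubstModel:
    def test_mk_two_state_closed_form(self):
        model = SubstModel("Mk", 2)
        P = transition_matrix(model, 0.5)
        assert P[0, 0] == pytest.approx(0.5 * (1 + math.exp(-1)), abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    @pytest.mark.parametrize("t", [0.0, 0.1, 0.7, 3.0])
    def test_mk_general_closed_form(self, k, t):
        model = SubstModel("Mk", k)
        P = transition_matrix(model, t)
        expect = 1 / k + ((k - 1) / k) * math.exp(-k * t / (k - 1))
        assert P[0, 0] == pytest.approx(expect, abs=1e-12)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_stationarity_at_long_branches(self):
        model = SubstModel("Mk", 4)
        P = transition_matrix(model, 200.0)
        assert np.allclose(P, 0.25, atol=1e-10)

    def test_identity_at_zero(self):
        model = SubstModel("DNA-GTR", pi=[0.3, 0.2, 0.3, 0.2],
                           exchangeabilities=[1, 2, 1, 1, 4, 1])
        assert np.allclose(transition_matrix(model, 0.0), np.eye(4),
                           atol=1e-12)

    def test_gtr_matches_series_expansion(self):
        rng = np.random.default_rng(3)
        pi = rng.dirichlet(np.ones(4))
        ex = rng.gamma(2, 1, 6)
        model = SubstModel("DNA-GTR", pi=pi, exchangeabilities=ex)
        t = 0.37
        # independent route: scaling-and-squaring series expansion of Qt
        from scipy.linalg import expm

        P_ref = expm(model.Q * t)
        assert np.allclose(model.transition(t), P_ref, atol=1e-10)

    def test_detailed_balance(self):
        rng = np.random.default_rng(4)
        pi = rng.dirichlet(np.ones(4))
        model = SubstModel("DNA-GTR", pi=pi,
                           exchangeabilities=rng.gamma(2, 1, 6))
        flux = pi[:, None] * model.Q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_unit_expected_rate(self):
        model = SubstModel("multistate-GTR", 3, pi=[0.5, 0.3, 0.2])
        assert -np.dot(model.pi, np.diag(model.Q)) == pytest.approx(1.0)

    def test_gamma_rates_mean_one(self):
        rates = discrete_gamma_rates(0.5, 4)
        assert rates.mean() == pytest.approx(1.0)
        assert (np.diff(rates) > 0).all()


class TestTreeLoglik:
    def test_single_character_two_taxa_closed_form(self):
        m = _binary_two_taxon(1, 1)
        tree = Tree.from_newick("(A:0.3,B:0.4);")
        L, per_char = tree_loglik(tree, m, SubstModel("Mk", 2))
        expect = math.log(0.5 * 0.5 * (1 - math.exp(-2 * 0.7)))
        assert L == pytest.approx(expect, abs=1e-12)

    def test_brute_force_sum_over_internal_states(self):
        rng = np.random.default_rng(5)
        tree = Tree.from_newick(
            "((A:0.2,B:0.4):0.3,(C:0.5,D:0.1):0.2,E:0.6);"
        )
        m = random_matrix(rng, 5, 3, state_counts=(3,), missing=0.2)
        m.taxa[:] = ["A", "B", "C", "D", "E"]
        model = SubstModel("Mk", 3)
        L, per_char = tree_loglik(tree, m, model, alphabet="declared")
        internal = [n for n in tree.postorder() if not n.is_leaf]
        for c in range(3):
            total = 0.0
            for combo in itertools.product(range(3), repeat=len(internal)):
                assign = dict(zip([id(n) for n in internal], combo))
                p = 1.0 / 3.0
                for node in tree.postorder():
                    if node is tree.root:
                        continue
                    P = model.transition(node.length)
                    parent_state = assign[id(node.parent)]
                    if node.is_leaf:
                        mask = int(m.masks[m.taxon_index(node.label), c])
                        p_leaf = sum(
                            P[parent_state, s]
                            for s in range(3)
                            if (mask >> s) & 1
                        )
                        p *= p_leaf
                    else:
                        p *= P[parent_state, assign[id(node)]]
                total += p
            assert per_char[c] == pytest.approx(math.log(total), abs=1e-9)

    def test_root_invariance_under_reversibility(self):
        rng = np.random.default_rng(6)
        labels = [f"t{i}" for i in range(6)]
        tree = random_binary_tree(rng, labels)
        m = random_matrix(rng, 6, 8, missing=0.1, poly=0.1)
        model = SubstModel("multistate-GTR")
        L, _ = tree_loglik(tree, m, model)
        for label in labels[:4]:
            rerooted = tree.copy()
            rerooted.reroot_on_edge(rerooted.find(label), 0.3)
            L2, _ = tree_loglik(rerooted, m, model)
            assert L2 == pytest.approx(L, abs=1e-9)

    def test_pattern_compression_does_not_change_dna_likelihood(self):
        text = ">A\nACGTACGTAA\n>B\nACGAACGTAA\n>C\nGCGTTCGTAT\n"
        m = read_alignment(text, FormatDialect("fasta"))
        tree = Tree.from_newick("(A:0.1,B:0.2,C:0.3);")
        model = SubstModel("DNA-GTR")
        _, per_char = tree_loglik(tree, m, model)
        # duplicated columns (identical patterns) share likelihoods
        assert per_char[0] == pytest.approx(per_char[4])  # A,A,G == A,A,G ?
        cols = [tuple(m.cell(i, j) for i in range(3)) for j in range(10)]
        for j1 in range(10):
            for j2 in range(10):
                if cols[j1] == cols[j2]:
                    assert per_char[j1] == pytest.approx(per_char[j2])
        # and the total equals the sum over raw columns computed one by one
        singles = sum(
            tree_loglik(tree, m.subset_columns([j]), model)[0]
            for j in range(10)
        )
        assert sum(per_char) == pytest.approx(singles, abs=1e-9)

    def test_long_branch_independence_limit(self):
        m = _binary_two_taxon(4, 2)
        tree = Tree.from_newick("(A:50,B:50);")
        _, per_char = tree_loglik(tree, m, SubstModel("Mk", 2))
        # every character's likelihood approaches prod(pi) = 1/4
        assert np.allclose(per_char, math.log(0.25), atol=1e-6)

    def test_missing_row_is_uninformative(self):
        chars = [Character("c", tuple("01"))]
        m = DataMatrix(["A", "B", "C"], chars, [[{"0"}], [{"1"}], [None]])
        tree3 = Tree.from_newick("(A:0.3,B:0.4,C:0.5);")
        tree2 = Tree.from_newick("(A:0.3,B:0.4);")
        m2 = DataMatrix(["A", "B"], chars, [[{"0"}], [{"1"}]])
        L3, _ = tree_loglik(tree3, m, SubstModel("Mk", 2))
        L2, _ = tree_loglik(tree2, m2, SubstModel("Mk", 2))
        assert L3 == pytest.approx(L2, abs=1e-9)


class TestOptimizeBranchLengths:
    def test_two_taxon_mle_closed_form(self):
        n, x = 50, 10
        m = _binary_two_taxon(n, x)
        tree = Tree.from_newick("(A:0.1,B:0.1);")
        opt, L, _ = optimize_branch_lengths(tree, m, SubstModel("Mk", 2))
        path = sum(nd.length for nd in opt.postorder() if nd.length)
        expect = -0.5 * math.log(1 - 2 * x / n)
        assert path == pytest.approx(expect, abs=1e-4)

    def test_already_optimal_unchanged(self):
        n, x = 40, 8
        m = _binary_two_taxon(n, x)
        t_hat = -0.5 * math.log(1 - 2 * x / n)
        tree = Tree.from_newick(f"(A:{t_hat / 2},B:{t_hat / 2});")
        L0, _ = tree_loglik(tree, m, SubstModel("Mk", 2))
        opt, L, _ = optimize_branch_lengths(tree, m, SubstModel("Mk", 2))
        assert L == pytest.approx(L0, abs=1e-6)

    def test_loglik_never_decreases(self):
        rng = np.random.default_rng(7)
        labels = [f"t{i}" for i in range(5)]
        tree = random_binary_tree(rng, labels)
        m = random_matrix(rng, 5, 12, missing=0.1)
        model = SubstModel("Mk")
        L0, _ = tree_loglik(tree, m, model)
        values = [L0]
        work = tree
        for _ in range(3):
            work, L, _ = optimize_branch_lengths(
                work, m, model, max_sweeps=1
            )
            values.append(L)
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))


class TestAscertainment:
    def test_none_is_identity(self, quartet_tree):
        rng = np.random.default_rng(8)
        m = random_matrix(rng, 4, 6)
        m.taxa[:] = ["A", "B", "C", "D"]
        model = SubstModel("Mk")
        _, per_char = tree_loglik(quartet_tree, m, model)
        out = ascertainment_correct(per_char, model, quartet_tree, m, "none")
        assert np.allclose(out, per_char)

    def test_two_taxon_hand_formula(self):
        m = _binary_two_taxon(1, 1)
        t = 0.6
        tree = Tree.from_newick(f"(A:{t / 2},B:{t / 2});")
        model = SubstModel("Mk", 2)
        _, per_char = tree_loglik(tree, m, model)
        out = ascertainment_correct(
            per_char, model, tree, m, "variable-only"
        )
        p_same = 0.5 * (1 + math.exp(-2 * t))
        p_const = 2 * 0.5 * p_same
        expect = per_char[0] - math.log1p(-p_const)
        assert out[0] == pytest.approx(expect, abs=1e-10)

    def test_conditioning_raises_loglik_of_variable_data(self):
        # dividing each character's likelihood by P(variable) < 1 strictly
        # increases it: conditioning re-normalizes onto the variable
        # patterns actually observable
        rng = np.random.default_rng(9)
        labels = [f"t{i}" for i in range(5)]
        tree = random_binary_tree(rng, labels)
        m = random_matrix(rng, 5, 8, state_counts=(2,))
        model = SubstModel("Mk")
        L, per_char = tree_loglik(tree, m, model)
        out = ascertainment_correct(
            per_char, model, tree, m, "variable-only"
        )
        assert (out > per_char).all()

    def test_matches_tree_loglik_flag(self, quartet_tree):
        rng = np.random.default_rng(10)
        m = random_matrix(rng, 4, 5)
        m.taxa[:] = ["A", "B", "C", "D"]
        model = SubstModel("Mk")
        _, plain = tree_loglik(quartet_tree, m, model)
        _, flagged = tree_loglik(
            quartet_tree, m, model, ascertainment="variable-only"
        )
        manual = ascertainment_correct(
            plain, model, quartet_tree, m, "variable-only"
        )
        assert np.allclose(flagged, manual)
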