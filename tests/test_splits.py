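import subprocess

import numpy as np
import pytest

from paleophylo.matrix import DistanceMatrix
from paleophylo.splits import (
    Bipartition,
    NeighborNet,
    SplitSystem,
    bipartition_frequencies,
    circular_splits,
    neighbor_net,
    neighbor_net_ordering,
    nnls_split_weights,
    support_overlay,
)
from paleophylo.trees import Tree, TreeSample

from conftest import random_binary_tree


def _dm(d, labels=None):
    d = np.asarray(d, dtype=float)
    labels = labels or [chr(65 + i) for i in range(d.shape[0])]
    return DistanceMatrix(labels, d)


def _circular_metric(rng, n):
    """Random non-negative combination of one circular ordering's splits."""
    perm = rng.permutation(n).tolist()
    splits = circular_splits(perm, n)
    w = np.where(rng.random(len(splits)) < 0.4, rng.random(len(splits)), 0.0)
    D = np.zeros((n, n))
    for bip, wt in zip(splits, w):
        if wt > 0:
            for i in range(n):
                for j in range(i + 1, n):
                    if bip.separates(i, j):
                        D[i, j] += wt
                        D[j, i] += wt
    return D


class TestBipartition:
    def test_canonical_orientation(self):
        a = Bipartition.from_side(0b0110, 4)
        b = Bipartition.from_side(0b1001, 4)
        assert a == b and hash(a) == hash(b)
        assert not a.bits & 1

    def test_empty_sides_rejected(self):
        with pytest.raises(ValueError):
            Bipartition.from_side(0, 4)

    def test_separates(self):
        bip = Bipartition.from_side(0b0110, 4)
        assert bip.separates(0, 1) and not bip.separates(1, 2)


class TestNNLSWeights:
    def test_three_taxon_closed_form(self):
        # trivial split weight for A is (d_AB + d_AC - d_BC) / 2
        d = np.array([[0, 0.6, 0.8], [0.6, 0, 0.9], [0.8, 0.9, 0]])
        splits, w, _ = nnls_split_weights(d, [0, 1, 2])
        by_side = {
            frozenset(b.side_indices() if not b.bits & 1 else []): wt
            for b, wt in zip(splits, w)
        }
        weights = {b.bits: wt for b, wt in zip(splits, w)}
        wA = (0.6 + 0.8 - 0.9) / 2
        wB = (0.6 + 0.9 - 0.8) / 2
        wC = (0.8 + 0.9 - 0.6) / 2
        got = {
            tuple(sorted(b.other_side_indices()))
            if len(b.other_side_indices()) == 1
            else tuple(sorted(b.side_indices())): wt
            for b, wt in zip(splits, w)
        }
        assert got[(0,)] == pytest.approx(wA)
        assert got[(1,)] == pytest.approx(wB)
        assert got[(2,)] == pytest.approx(wC)

    def test_tree_additive_recovers_branch_lengths(self):
        # ((A:1,B:2):3,(C:4,D:5)) path distances
        d = np.array(
            [
                [0, 3, 8, 9],
                [3, 0, 9, 10],
                [8, 9, 0, 9],
                [9, 10, 9, 0],
            ],
            dtype=float,
        )
        splits, w, resid = nnls_split_weights(d, [0, 1, 2, 3])
        assert resid < 1e-9
        weights = {}
        for b, wt in zip(splits, w):
            small = min(
                (tuple(sorted(b.side_indices())),
                 tuple(sorted(b.other_side_indices()))),
                key=len,
            )
            weights[small] = weights.get(small, 0) + wt
        assert weights[(0,)] == pytest.approx(1)
        assert weights[(1,)] == pytest.approx(2)
        assert weights[(2,)] == pytest.approx(4)
        assert weights[(3,)] == pytest.approx(5)
        assert weights[(2, 3)] == pytest.approx(3)

    def test_objective_not_worse_than_clipped_unconstrained(self):
        rng = np.random.default_rng(9)
        n = 6
        D = _circular_metric(rng, n) + rng.normal(0, 0.05, (n, n))
        D = np.abs((D + D.T) / 2)
        np.fill_diagonal(D, 0)
        order = list(range(n))
        splits, w, resid = nnls_split_weights(D, order)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        A = np.array(
            [[1.0 if s.separates(i, j) else 0.0 for s in splits]
             for i, j in pairs]
        )
        y = np.array([D[i, j] for i, j in pairs])
        w_unc, *_ = np.linalg.lstsq(A, y, rcond=None)
        clipped = np.clip(w_unc, 0, None)
        assert resid <= np.linalg.norm(A @ clipped - y) + 1e-12


class TestNeighborNet:
    def test_additive_quartet_exact(self):
        d = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]],
            dtype=float,
        )
        res = NeighborNet(_dm(d)).fit()
        assert res.n_splits == 5
        assert res.residual < 1e-9
        nontrivial = [b for b, w in res.split_system.splits if not b.is_trivial]
        assert len(nontrivial) == 1
        side = {res.split_system.labels[i] for i in nontrivial[0].side_indices()}
        assert side in ({"A", "B"}, {"C", "D"})
        assert res.split_system.weight_of(nontrivial[0]) == pytest.approx(1.0)

    def test_all_zero_distances_give_no_splits(self):
        res = NeighborNet(_dm(np.zeros((5, 5)))).fit()
        assert res.n_splits == 0

    def test_circular_metrics_reproduced_exactly(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 11))
            D = _circular_metric(rng, n)
            res = NeighborNet(_dm(D, [f"t{i}" for i in range(n)])).fit()
            assert np.abs(res.fitted_distances() - D).max() < 1e-6

    def test_all_splits_are_arcs_of_ordering(self):
        rng = np.random.default_rng(8)
        D = _circular_metric(rng, 8) + np.abs(rng.normal(0, 0.02, (8, 8)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        # SplitSystem validates the arc invariant on construction
        res = NeighborNet(_dm(D, [f"t{i}" for i in range(8)])).fit()
        assert res.ordering is not None

    def test_permutation_equivariance_up_to_rotation_reversal(self):
        rng = np.random.default_rng(10)
        D = _circular_metric(rng, 7)
        labels = [f"t{i}" for i in range(7)]
        res = NeighborNet(_dm(D, labels)).fit()
        perm = rng.permutation(7)
        D2 = D[np.ix_(perm, perm)]
        res2 = NeighborNet(_dm(D2, [labels[i] for i in perm])).fit()
        splits1 = {
            (min(map(frozenset, res.split_system.label_sides(b)),
                 key=lambda s: (len(s), sorted(s))), round(w, 9))
            for b, w in res.split_system.splits
        }
        splits2 = {
            (min(map(frozenset, res2.split_system.label_sides(b)),
                 key=lambda s: (len(s), sorted(s))), round(w, 9))
            for b, w in res2.split_system.splits
        }
        assert splits1 == splits2

    def test_undefined_distances_abort(self):
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            neighbor_net(DistanceMatrix(list("ABCD"), d))

    def test_small_n_trivial_systems(self):
        d = np.array([[0, 0.4, 0.6], [0.4, 0, 0.8], [0.6, 0.8, 0]])
        system = neighbor_net(_dm(d))
        assert len(system) == 3
        assert all(b.is_trivial for b, _ in system.splits)


class TestReferenceImplementation:
    def test_ordering_matches_phangorn(self, tmp_path):
        """Independent oracle: phangorn's neighbour-net ordering."""
        rng = np.random.default_rng(2)
        pts = rng.random((7, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        D += rng.random((7, 7)) * 0.05
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        path = tmp_path / "D.txt"
        np.savetxt(path, D)
        out = subprocess.run(
            [
                "Rscript", "-e",
                'suppressMessages(library(phangorn));'
                f'D<-as.matrix(read.table("{path}"));'
                "rownames(D)<-colnames(D)<-NULL;"
                'cat(phangorn:::getOrderingNN(D),sep=",")',
            ],
            capture_output=True, text=True, timeout=120,
        )
        assert out.returncode == 0, out.stderr
        theirs = [int(x) - 1 for x in out.stdout.strip().split(",")]
        mine = neighbor_net_ordering(D)

        def canon(order):
            i = order.index(0)
            fwd = order[i:] + order[:i]
            rev = fwd[::-1]
            rev = rev[-1:] + rev[:-1]
            return min(tuple(fwd), tuple(rev))

        assert canon(mine) == canon(theirs)


class TestBipartitionFrequencies:
    def test_single_topology_all_splits_certain(self):
        t = Tree.from_newick("((A,B),(C,D),E);")
        sample = TreeSample([t.copy() for _ in range(100)])
        freqs = bipartition_frequencies(sample)
        assert len(freqs) == 2
        assert all(f == 1.0 for f in freqs.values())

    def test_mixed_sample_frequency(self):
        t1 = Tree.from_newick("((A,B),(C,D));")
        t2 = Tree.from_newick("((A,C),(B,D));")
        sample = TreeSample([t1.copy() for _ in range(70)]
                            + [t2.copy() for _ in range(30)])
        freqs = bipartition_frequencies(sample)
        labels = sample.taxa()
        bits = (1 << labels.index("A")) | (1 << labels.index("B"))
        ab = Bipartition.from_side(bits, 4)
        assert freqs[ab] == pytest.approx(0.70)

    def test_rooted_trees_are_unrooted_first(self):
        rooted = Tree.from_newick("((A,B),((C,D),E));")
        unrooted = Tree.from_newick("(A,B,((C,D),E));")
        f1 = bipartition_frequencies(TreeSample([rooted]))
        f2 = bipartition_frequencies(TreeSample([unrooted]))
        assert f1 == f2

    def test_matches_dendropy_oracle(self):
        """Cross-check frequencies against dendropy's bipartition encoding
        on 50 random 6-taxon trees."""
        import dendropy

        rng = np.random.default_rng(12)
        labels = [f"t{i}" for i in range(6)]
        trees = [random_binary_tree(rng, labels) for _ in range(50)]
        sample = TreeSample(trees)
        mine = bipartition_frequencies(sample, labels)

        ns = dendropy.TaxonNamespace(labels)
        dlist = dendropy.TreeList(taxon_namespace=ns)
        for t in trees:
            dlist.append(
                dendropy.Tree.get(
                    data=t.to_newick(), schema="newick",
                    taxon_namespace=ns, preserve_underscores=True,
                )
            )
        counts: dict[frozenset, int] = {}
        for dt in dlist:
            dt.encode_bipartitions()
            seen = set()
            for bp in dt.bipartition_encoding:
                if bp.is_trivial():
                    continue
                taxa = frozenset(
                    str(t.label) for t in
                    ns.bitmask_taxa_list(bp.split_bitmask)
                )
                if 2 <= len(taxa) <= 4:
                    key = min(
                        taxa, frozenset(labels) - taxa,
                        key=lambda s: (len(s), sorted(s)),
                    )
                    seen.add(key)
            for key in seen:
                counts[key] = counts.get(key, 0) + 1
        theirs = {k: v / 50 for k, v in counts.items()}
        mine_by_side = {}
        for bip, f in mine.items():
            taxa = frozenset(labels[i] for i in bip.side_indices())
            key = min(
                taxa, frozenset(labels) - taxa,
                key=lambda s: (len(s), sorted(s)),
            )
            mine_by_side[key] = f
        assert mine_by_side == theirs

    def test_taxon_set_mismatch_rejected(self):
        t = Tree.from_newick("((A,B),(C,D));")
        with pytest.raises(ValueError):
            bipartition_frequencies(TreeSample([t]), ["A", "B", "C", "E"])


class TestSupportOverlay:
    def test_absent_split_gets_zero(self):
        labels = list("ABCD")
        bip = Bipartition.from_side(0b0110, 4)
        net = SplitSystem(labels, [(bip, 1.0)])
        out, leftover = support_overlay(net, {"BS": {}}, as_percent={"BS"})
        assert out.splits[0][0].support["BS"] == 0.0

    def test_frequencies_transferred_and_scaled(self):
        t1 = Tree.from_newick("((A,B),(C,D));")
        t2 = Tree.from_newick("((A,C),(B,D));")
        sample = TreeSample([t1.copy() for _ in range(70)]
                            + [t2.copy() for _ in range(30)])
        labels = sample.taxa()
        freqs = bipartition_frequencies(sample, labels)
        bits = (1 << labels.index("A")) | (1 << labels.index("B"))
        ab = Bipartition.from_side(bits, 4)
        net = SplitSystem(labels, [(ab, 0.5)])
        out, leftover = support_overlay(
            net, {"BS": freqs, "PP": freqs}, as_percent={"BS"}
        )
        annotated = out.splits[0][0]
        assert annotated.support["BS"] == pytest.approx(70.0)
        assert annotated.support["PP"] == pytest.approx(0.70)
        # the AC|BD split is in the sample but not the network
        assert len(leftover["BS"]) == 1

    def test_bounds(self):
        rng = np.random.default_rng(1)
        trees = [random_binary_tree(rng, list("ABCDE")) for _ in range(20)]
        sample = TreeSample(trees)
        freqs = bipartition_frequencies(sample)
        assert all(0 <= f <= 1 for f in freqs.values())
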