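import itertools

import networkx as nx
import numpy as np
import pytest

from commphylo import (
    NewickParseError,
    Phylogeny,
    TreeSample,
    ValidationError,
    mcc_tree,
    parse_newick,
    patristic_matrix,
    phylo_covariance,
    prune_to,
    simulate_yule_tree,
    write_newick,
)
from commphylo.treeio import clade_credibility_score


def tree_to_graph(tree):
    """Independent oracle helper: the tree as a weighted undirected graph."""
    g = nx.Graph()
    for node in range(tree.n_nodes):
        p = tree.parent[node]
        if p >= 0:
            g.add_edge(int(node), int(p), weight=float(tree.lengths[node]))
    return g


class TestParse:
    def test_basic(self, small_tree):
        assert small_tree.n_tips == 3
        assert small_tree.total_length() == pytest.approx(5.0)
        assert sorted(small_tree.tip_labels) == ["A", "B", "C"]

    def test_round_trip(self):
        for seed in range(5):
            t = simulate_yule_tree(12, seed=seed)
            t2 = parse_newick(write_newick(t))
            assert sorted(t2.tip_labels) == sorted(t.tip_labels)
            d1 = patristic_matrix(t).to_dataframe().sort_index(axis=0).sort_index(axis=1)
            d2 = patristic_matrix(t2).to_dataframe().sort_index(axis=0).sort_index(axis=1)
            np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), rtol=1e-9)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValidationError, match="duplicate tip"):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_malformed_input(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:1:1,C:2);")

    def test_quoted_labels_and_comments(self):
        t = parse_newick("(('sp one':1e0,[a comment]B:1):1,C:2.0e0);")
        assert "sp one" in t.tip_labels
        assert t.total_length() == pytest.approx(5.0)

    def test_negative_length_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            parse_newick("((A:1,B:-1):1,C:2);")


class TestPrune:
    def test_prune_to_all_is_identity(self, yule20):
        pruned = prune_to(yule20, yule20.tip_labels)
        assert pruned.total_length() == pytest.approx(yule20.total_length())
        d1 = patristic_matrix(yule20).to_dataframe()
        d2 = patristic_matrix(pruned).to_dataframe()
        np.testing.assert_allclose(
            d1.loc[d2.index, d2.columns].to_numpy(), d2.to_numpy(), rtol=1e-9
        )

    def test_hand_case(self, small_tree):
        p = prune_to(small_tree, {"A", "C"})
        depths = dict(zip([p.labels[t] for t in p.tips], p.depths()[p.tips]))
        assert depths == {"A": pytest.approx(2.0), "C": pytest.approx(2.0)}

    def test_empty_set_rejected(self, small_tree):
        with pytest.raises(ValidationError, match="empty"):
            prune_to(small_tree, set())

    def test_unknown_label_listed(self, small_tree):
        with pytest.raises(ValidationError, match="X"):
            prune_to(small_tree, {"A", "X"})

    def test_total_length_monotone(self, yule20):
        rng = np.random.default_rng(0)
        labels = yule20.tip_labels
        for _ in range(10):
            k = rng.integers(1, len(labels))
            subset = list(rng.choice(labels, size=k, replace=False))
            pruned = prune_to(yule20, subset)
            assert pruned.total_length() <= yule20.total_length() + 1e-9
        assert prune_to(yule20, labels).total_length() == pytest.approx(
            yule20.total_length()
        )

    def test_pruned_distances_preserved(self, yule20):
        """Patristic distances among the retained tips must be unchanged."""
        d_full = patristic_matrix(yule20).to_dataframe()
        subset = yule20.tip_labels[::3]
        d_sub = patristic_matrix(prune_to(yule20, subset)).to_dataframe()
        np.testing.assert_allclose(
            d_full.loc[d_sub.index, d_sub.columns].to_numpy(),
            d_sub.to_numpy(), rtol=1e-9,
        )


class TestPatristic:
    def test_hand_case(self, small_tree):
        d = patristic_matrix(small_tree).to_dataframe()
        assert d.loc["A", "B"] == pytest.approx(2.0)
        assert d.loc["A", "C"] == pytest.approx(4.0)
        assert d.loc["B", "C"] == pytest.approx(4.0)

    def test_ultrametric_tip_depths(self):
        t = simulate_yule_tree(15, seed=3)
        assert t.is_ultrametric(1e-9)
        d = patristic_matrix(t).values
        depth = t.depths()[t.tips][0] - t.lengths[t.root]
        # tip-to-tip distance through the root equals twice the crown depth
        i, j = 0, np.argmax(d[0])
        assert d[i, j] <= 2 * depth + 1e-9

    def test_matches_graph_shortest_paths(self):
        for seed in range(8):
            t = simulate_yule_tree(8, seed=seed)
            d = patristic_matrix(t)
            g = tree_to_graph(t)
            sp = dict(nx.all_pairs_dijkstra_path_length(g))
            tipnode = t.tip_index()
            for a, b in itertools.combinations(d.labels, 2):
                expect = sp[tipnode[a]][tipnode[b]]
                i, j = d.index_of([a, b])
                assert d.values[i, j] == pytest.approx(expect, rel=1e-9)

    def test_four_point_condition(self):
        t = simulate_yule_tree(8, seed=11)
        d = patristic_matrix(t).values
        n = d.shape[0]
        for q in itertools.combinations(range(n), 4):
            i, j, k, l = q
            sums = sorted([d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]])
            assert sums[1] == pytest.approx(sums[2], abs=1e-8)

    def test_covariance_consistent_with_depths(self, yule20):
        labels, C = phylo_covariance(yule20)
        depths = yule20.depths()[yule20.tips]
        np.testing.assert_allclose(np.diag(C), depths, rtol=1e-9)
        d = patristic_matrix(yule20).values
        # d(i,j) = depth_i + depth_j - 2 * C_ij
        np.testing.assert_allclose(
            d, depths[:, None] + depths[None, :] - 2 * C, atol=1e-9
        )


def _clade_sets(tree):
    """Test-local clade extraction (independent of mcc internals)."""
    out = []
    store = {}
    for node in tree.postorder():
        if not tree.children[node]:
            store[node] = frozenset([tree.labels[node]])
        else:
            s = frozenset().union(*(store.pop(c) for c in tree.children[node]))
            store[node] = s
            out.append(s)
    return out


class TestMCC:
    def test_identical_sample(self, yule20):
        sample = TreeSample([yule20.copy() for _ in range(4)])
        out = mcc_tree(sample)
        np.testing.assert_allclose(
            patristic_matrix(out).values, patristic_matrix(yule20).values, rtol=1e-9
        )

    def test_majority_topology_selected(self):
        t1 = parse_newick("((A:1,B:1):1,C:2);")
        t1b = parse_newick("((A:1.5,B:1.5):0.5,C:2);")
        t2 = parse_newick("((A:1,C:1):1,B:2);")
        out = mcc_tree(TreeSample([t1, t2, t1b]))
        # clade {A,B} appears twice, {A,C} once -> t1's topology wins
        assert frozenset(["A", "B"]) in _clade_sets(out)

    def test_score_maximal_over_sample(self):
        rng = np.random.default_rng(5)
        trees = [simulate_yule_tree(6, seed=int(s)) for s in rng.integers(0, 4, size=12)]
        # relabel so all share a tip set
        sample = TreeSample(trees)
        out = mcc_tree(sample)
        best = max(clade_credibility_score(t, sample) for t in sample)
        assert clade_credibility_score(out, sample) >= best - 1e-9

    def test_order_invariance(self):
        trees = [simulate_yule_tree(6, seed=s) for s in (0, 0, 1, 2)]
        a = mcc_tree(TreeSample(trees))
        b = mcc_tree(TreeSample(trees[::-1]))
        assert set(_clade_sets(a)) == set(_clade_sets(b))
        np.testing.assert_allclose(
            patristic_matrix(a).to_dataframe().sort_index().sort_index(axis=1).to_numpy(),
            patristic_matrix(b).to_dataframe().sort_index().sort_index(axis=1).to_numpy(),
            rtol=1e-9,
        )

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError, match="non-empty"):
            TreeSample([])

    def test_mean_heights(self):
        a = parse_newick("((A:1,B:1):1,C:2);")
        b = parse_newick("((A:3,B:3):1,C:4);")
        out = mcc_tree(TreeSample([a, b]))
        d = patristic_matrix(out).to_dataframe()
        # clade {A,B} age averages (1+3)/2 = 2 -> d(A,B) = 4
        assert d.loc["A", "B"] == pytest.approx(4.0)


class TestInvariants:
    def test_single_root_enforced(self):
        with pytest.raises(ValidationError, match="root"):
            Phylogeny([-1, -1], [0.0, 0.0], ["A", "B"])

    def test_tip_label_required(self):
        with pytest.raises(ValidationError, match="label"):
            Phylogeny([-1, 0, 0], [0.0, 1.0, 1.0], [None, "A", None])
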