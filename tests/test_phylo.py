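"""Trees, pruning likelihoods, empirical-Bayes rates, evolutionary trace."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from sitevar.io import MSAlignment
from sitevar.phylo import (
    build_nj_tree,
    build_upgma_tree,
    compute_cs,
    compute_et,
    pairwise_distances,
    site_likelihood,
)
from sitevar.substitution import discrete_gamma, jtt_model
from sitevar.synth import generate_tree, simulate_msa
from sitevar.tree import PhyloTree, TreeNode


def bipartitions(tree: PhyloTree) -> set[frozenset]:
    all_leaves = frozenset(tree.leaf_names)
    parts = set()
    for node in tree.root.postorder():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(leaf.name for leaf in node.leaves())
        parts.add(min(side, all_leaves - side, key=sorted))
    return parts


class TestDistances:
    def test_identical_sequences_zero(self):
        msa = MSAlignment(names=["a", "b"], rows=["ACDE", "ACDE"], query_index=0)
        D, _ = pairwise_distances(msa)
        assert D[0, 1] == 0.0

    def test_poisson_correction_hand_value(self):
        # 1 mismatch in 10 comparable columns: p = 0.1
        msa = MSAlignment(
            names=["a", "b"],
            rows=["ACDEFGHIKL", "ACDEFGHIKV"],
            query_index=0,
        )
        D, _ = pairwise_distances(msa)
        assert D[0, 1] == pytest.approx(-np.log(0.9), abs=1e-10)
        assert D[0, 1] == pytest.approx(0.10536, abs=1e-5)

    def test_saturation_capped(self):
        msa = MSAlignment(names=["a", "b"], rows=["AAAA", "VVVV"], query_index=0)
        D, _ = pairwise_distances(msa)
        assert D[0, 1] == 3.0

    def test_symmetric_zero_diagonal(self, rng):
        from sitevar.io import AMINO_ACIDS

        rows = ["".join(rng.choice(list(AMINO_ACIDS), size=30)) for _ in range(5)]
        msa = MSAlignment(names=list("abcde"), rows=rows, query_index=0)
        D, _ = pairwise_distances(msa)
        np.testing.assert_allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_no_comparable_columns_error(self):
        msa = MSAlignment(names=["a", "b"], rows=["A-", "-A"], query_index=0)
        with pytest.raises(ValueError, match="comparable"):
            pairwise_distances(msa)


class TestNeighborJoining:
    def test_additive_four_taxon_matrix_recovered_exactly(self):
        # AB|CD: a,b at 1 from their node; c,d at 1; internal edge 4
        D = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
        )
        t = build_nj_tree(D, ["A", "B", "C", "D"])
        assert bipartitions(t) == {frozenset({"A", "B"})}
        got = {}
        for node in t.root.postorder():
            if node.is_leaf:
                got[node.name] = node.length
            elif node is not t.root:
                got["internal"] = node.length
        assert got == pytest.approx(
            {"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0, "internal": 4.0}
        )

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 5], [3, 0, 4], [5, 4, 0]], float)
        t = build_nj_tree(D, ["a", "b", "c"])
        lengths = {leaf.name: leaf.length for leaf in t.root.leaves()}
        assert lengths == pytest.approx({"a": 2.0, "b": 1.0, "c": 3.0})

    def test_fewer_than_three_taxa_error(self):
        with pytest.raises(ValueError):
            build_nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_ultrametric_input_agrees_with_upgma(self):
        D = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float
        )
        names = list("abcd")
        assert bipartitions(build_nj_tree(D, names)) == bipartitions(
            build_upgma_tree(D, names)
        )

    def test_matches_independent_nj_on_random_matrix(self, rng):
        # scikit-bio's neighbor joining as the independent oracle
        from skbio import DistanceMatrix
        from skbio.tree import nj

        n = 7
        names = [f"t{i}" for i in range(n)]
        X = rng.random((n, 4)) * 5
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(D, 0.0)
        mine = build_nj_tree(D, names)
        ref = nj(DistanceMatrix(D, names))
        ref_parts = set()
        all_leaves = frozenset(names)
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < n:
                ref_parts.add(min(side, all_leaves - side, key=sorted))
        assert bipartitions(mine) == ref_parts


class TestUpgma:
    def test_two_taxa_split_evenly(self):
        t = build_upgma_tree(np.array([[0, 2], [2, 0]], float), ["a", "b"])
        assert all(leaf.length == 1.0 for leaf in t.root.leaves())

    def test_ultrametric_leaf_depths(self):
        D = np.array(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]], float
        )
        t = build_upgma_tree(D, list("abcd"))
        depths = t.leaf_depths()
        assert all(d == pytest.approx(4.0) for d in depths.values())

    def test_merge_heights_match_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        n = 8
        X = rng.random((n, 3))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(D, 0.0)
        t = build_upgma_tree(D, [f"t{i}" for i in range(n)])
        mine = sorted(
            node.height * 2 for node in t.root.postorder() if not node.is_leaf
        )
        ref = sorted(average(squareform(D))[:, 2])
        np.testing.assert_allclose(mine, ref, rtol=1e-10)


class TestLikelihood:
    def test_single_leaf_gives_stationary_frequency(self):
        model = jtt_model()
        tree = PhyloTree(TreeNode("x", 0.0))
        from sitevar.substitution import AA_INDEX

        for aa in "AWC":
            lik = site_likelihood({"x": aa}, tree, model)
            assert lik == pytest.approx(model.frequencies[AA_INDEX[aa]])

    def test_two_leaves_match_direct_summation(self):
        model = jtt_model()
        tree = PhyloTree(
            TreeNode(children=[TreeNode("x", 0.2), TreeNode("y", 0.5)])
        )
        rate = 1.3
        P1 = model.transition_matrix(rate * 0.2)
        P2 = model.transition_matrix(rate * 0.5)
        from sitevar.substitution import AA_INDEX

        a, c = AA_INDEX["A"], AA_INDEX["C"]
        direct = sum(
            model.frequencies[b] * P1[b, a] * P2[b, c] for b in range(20)
        )
        got = site_likelihood({"x": "A", "y": "C"}, tree, model, rate=rate)
        assert got == pytest.approx(direct, rel=1e-12)

    def test_rerooting_invariance_pulley_principle(self):
        model = jtt_model()
        t1 = PhyloTree(TreeNode(children=[TreeNode("x", 0.3), TreeNode("y", 0.4)]))
        t2 = PhyloTree(TreeNode(children=[TreeNode("x", 0.0), TreeNode("y", 0.7)]))
        col = {"x": "W", "y": "F"}
        assert site_likelihood(col, t1, model) == pytest.approx(
            site_likelihood(col, t2, model), rel=1e-10
        )

    def test_gap_is_missing_data(self):
        model = jtt_model()
        tree = PhyloTree(
            TreeNode(children=[TreeNode("x", 0.2), TreeNode("y", 0.5)])
        )
        from sitevar.substitution import AA_INDEX

        got = site_likelihood({"x": "A", "y": "-"}, tree, model)
        assert got == pytest.approx(model.frequencies[AA_INDEX["A"]], rel=1e-10)

    def test_nonpositive_rate_rejected(self):
        tree = PhyloTree(TreeNode(children=[TreeNode("x", 0.1), TreeNode("y", 0.1)]))
        with pytest.raises(ValueError):
            site_likelihood({"x": "A", "y": "A"}, tree, rate=0.0)


class TestChapmanKolmogorov:
    def test_transition_matrices_compose(self):
        model = jtt_model()
        P = model.transition_matrix
        assert np.abs(P(0.3) @ P(0.7) - P(1.0)).max() < 1e-8

    def test_detailed_balance(self):
        model = jtt_model()
        Q, pi = model.rate_matrix, model.frequencies
        np.testing.assert_allclose(pi[:, None] * Q, (pi[:, None] * Q).T,
                                   atol=1e-12)

    def test_rows_sum_to_zero_and_mean_rate_one(self):
        model = jtt_model()
        np.testing.assert_allclose(model.rate_matrix.sum(1), 0.0, atol=1e-12)
        assert -np.sum(model.frequencies * np.diag(model.rate_matrix)) == (
            pytest.approx(1.0)
        )


class TestDiscreteGamma:
    def test_equal_weights_and_unit_mean(self):
        for alpha in (0.3, 1.0, 4.0):
            rates, weights = discrete_gamma(alpha, 16)
            assert np.allclose(weights, 1 / 16)
            assert (rates * weights).sum() == pytest.approx(1.0, abs=1e-10)

    def test_category_means_match_quadrature(self):
        from scipy import integrate
        from scipy.stats import gamma as gd

        alpha, K = 0.7, 8
        rates, _ = discrete_gamma(alpha, K)
        edges = gd.ppf(np.linspace(0, 1, K + 1), a=alpha, scale=1 / alpha)
        edges[-1] = np.inf
        for k in range(K):
            num, _ = integrate.quad(
                lambda r: r * gd.pdf(r, a=alpha, scale=1 / alpha),
                edges[k], min(edges[k + 1], 60.0),
            )
            assert rates[k] == pytest.approx(num * K, rel=1e-5)

    def test_more_dispersion_at_small_alpha(self):
        r_small, _ = discrete_gamma(0.2, 16)
        r_large, _ = discrete_gamma(5.0, 16)
        assert r_small.std() > r_large.std()


class TestComputeCs:
    def test_identical_columns_get_equal_unit_rates(self):
        # every column reads ACD down the rows: perfect symmetry across sites
        msa = MSAlignment(names=["a", "b", "c"],
                          rows=["AAAA", "CCCC", "DDDD"], query_index=0)
        _, cs = compute_cs(msa)
        np.testing.assert_allclose(cs.values, 1.0, atol=1e-8)

    def test_invariant_column_slower_than_hypervariable(self):
        tree = generate_tree(12, seed=1, height=0.8)
        rates = np.array([0.0] + [1.0] * 18 + [6.0])
        rates = rates / rates.mean()
        msa = simulate_msa(tree, rates, seed=2)
        _, cs = compute_cs(msa, tree=tree)
        assert cs.values[0] < cs.values[-1]

    def test_simulated_rate_recovery(self):
        rng = np.random.default_rng(42)
        tree = generate_tree(40, seed=42, height=1.0)
        rates = rng.gamma(1.0, 1.0, size=150)
        rates /= rates.mean()
        msa = simulate_msa(tree, rates, seed=43)
        post, cs = compute_cs(msa)
        rho = spearmanr(cs.values, rates).statistic
        assert rho > 0.7
        assert cs.values.mean() == pytest.approx(1.0)
        assert post.alpha > 0


class TestEvolutionaryTrace:
    def test_conserved_column_scores_minimum_one(self):
        msa = MSAlignment(names=list("abcd"), rows=["A", "A", "A", "A"],
                          query_index=0)
        assert compute_et(msa).values[0] == pytest.approx(1.0)

    def test_tree_concordant_variation_scores_lower(self):
        # two clades; variation along the clade split vs scattered within
        names = [f"t{i}" for i in range(8)]
        clade_split = ["A", "A", "A", "A", "G", "G", "G", "G"]
        scattered = ["A", "G", "A", "G", "A", "G", "A", "G"]
        rows = [a + b for a, b in zip(clade_split, scattered)]
        msa = MSAlignment(names=names, rows=rows, query_index=0)
        # ultrametric distances: first four close, last four close
        D = np.full((8, 8), 1.0)
        D[:4, :4] = 0.2
        D[4:, 4:] = 0.2
        np.fill_diagonal(D, 0.0)
        tree = build_upgma_tree(D, names)
        et = compute_et(msa, tree)
        assert et.values[0] < et.values[1]

    def test_relabeling_within_group_invariance(self):
        names = [f"t{i}" for i in range(6)]
        rows = ["AC", "AC", "AG", "GG", "GC", "GC"]
        D = np.full((6, 6), 1.0)
        D[:3, :3] = 0.2
        D[3:, 3:] = 0.2
        np.fill_diagonal(D, 0.0)
        tree = build_upgma_tree(D, names)
        msa1 = MSAlignment(names=names, rows=rows, query_index=0)
        # swap two rows inside the first clade
        rows2 = [rows[1], rows[0]] + rows[2:]
        msa2 = MSAlignment(names=names, rows=rows2, query_index=0)
        np.testing.assert_allclose(
            compute_et(msa1, tree).values, compute_et(msa2, tree).values
        )

    def test_single_sequence_error(self):
        msa = MSAlignment(names=["a"], rows=["ACD"], query_index=0)
        with pytest.raises(ValueError):
            compute_et(msa)
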