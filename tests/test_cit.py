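import itertools

import numpy as np
import pandas as pd
import pytest

from orbitdx import cit, normalization, synthetic_data as sd
from orbitdx.exceptions import StatisticsError

from conftest import make_matrix


def rank_assoc_oracle(values, labels):
    """Brute-force permutation p: enumerate every distinct relabelling.

    Statistic: sum over groups of n_g * (mean rank)^2, computed with plain
    Python arithmetic — a strictly increasing transform of the
    Kruskal–Wallis H for fixed data, so the p-value is identical.
    """
    values = list(values)
    n = len(values)
    ranks = [sorted(values).index(v) + 1 for v in values]  # no ties in fixtures
    groups = sorted(set(labels))

    def stat(lab):
        total = 0.0
        for g in groups:
            member = [r for r, l in zip(ranks, lab) if l == g]
            total += len(member) * (sum(member) / len(member)) ** 2
        return total

    observed = stat(labels)
    perms = set(itertools.permutations(labels))
    hits = sum(stat(p) >= observed - 1e-9 for p in perms)
    return hits / len(perms)


class TestAssociationP:
    @pytest.mark.parametrize("labels", [
        ["A"] * 4 + ["B"] * 4,
        ["A"] * 3 + ["B"] * 3 + ["C"] * 2,
    ])
    def test_exact_matches_bruteforce(self, labels):
        rng = np.random.default_rng(42)
        values = rng.normal(size=len(labels))
        p = cit.association_p(values, labels)
        assert p == pytest.approx(rank_assoc_oracle(values, labels), abs=1e-12)

    def test_perfectly_ordered_labels(self):
        # all group-A values below all group-B values, n=8
        values = np.arange(8.0)
        labels = ["A"] * 4 + ["B"] * 4
        p = cit.association_p(values, labels)
        assert p == pytest.approx(rank_assoc_oracle(values, labels), abs=1e-12)
        assert p == pytest.approx(2 / 70)  # the two extreme arrangements of C(8,4)

    def test_constant_values_p_one(self):
        assert cit.association_p([3.0] * 6, ["A"] * 3 + ["B"] * 3) == 1.0

    def test_monte_carlo_agrees_with_exact(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=10)
        labels = ["A"] * 5 + ["B"] * 5
        p_exact = cit.association_p(values, labels, method="exact")
        n_perm = 1999
        p_mc = cit.association_p(values, labels, method="mc", n_perm=n_perm, seed=1)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) <= 3 * se + 1 / (n_perm + 1)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(StatisticsError):
            cit.association_p([1.0, 2.0], ["A", "A"])
        with pytest.raises(ValueError):
            cit.association_p([1.0, 2.0], ["A", "B"], n_perm=10)


class TestBestCutoff:
    def test_midpoint_example(self):
        cut, stat = cit.best_cutoff([1.0, 2.0, 10.0, 11.0], ["A", "A", "B", "B"])
        assert cut == 6.0 and stat == pytest.approx(4.0)  # full 2x2 chi-square

    def test_all_equal_rejected(self):
        with pytest.raises(StatisticsError):
            cit.best_cutoff([5.0] * 4, ["A", "A", "B", "B"])

    def test_interleaved_labels_non_significant(self):
        values = np.arange(8.0)
        labels = ["A", "B"] * 4
        assert cit.association_p(values, labels) > 0.5

    def test_tie_breaks_toward_smaller_cutoff(self):
        # both midpoints separate one A from the rest equally well
        cut, _ = cit.best_cutoff([1.0, 2.0, 3.0], ["A", "B", "A"])
        assert cut == 1.5

    def test_recovers_planted_threshold(self):
        rng = np.random.default_rng(0)
        low = rng.normal(305, 60, 20)
        high = rng.normal(1220, 200, 20)
        cut, _ = cit.best_cutoff(np.concatenate([low, high]),
                                 ["A"] * 20 + ["B"] * 20)
        assert max(low) < cut < min(high)
        assert 400 < cut < 900


def _single_marker_matrix():
    rng = np.random.default_rng(3)
    sep = np.concatenate([rng.normal(10, 1, 10), rng.normal(30, 1, 10)])
    noise = {f"G{i}": rng.normal(20, 5, 20) for i in range(5)}
    m = make_matrix(endo={"MARKER": sep, **noise})
    labels = pd.Series(["A"] * 10 + ["B"] * 10, index=m.samples)
    return m, labels


class TestFitCtree:
    def test_dominant_marker_gives_depth_one_tree(self):
        m, labels = _single_marker_matrix()
        tree = cit.fit_ctree(m, labels, seed=0)
        assert cit.split_genes(tree) == ["MARKER"]
        assert tree.left.is_leaf and tree.right.is_leaf
        assert tree.adjusted_p <= 0.05
        # children partition the parent's samples
        assert tree.left.n + tree.right.n == tree.n

    def test_alpha_zero_yields_single_leaf(self):
        m, labels = _single_marker_matrix()
        tree = cit.fit_ctree(m, labels, alpha=0.0, seed=0)
        assert tree.is_leaf

    def test_invariant_to_monotone_transform_and_sample_order(self):
        m, labels = _single_marker_matrix()
        base = cit.fit_ctree(m, labels, seed=0)

        warped = m.copy()
        i = warped.probe_names.index("MARKER")
        warped.values[i] = np.exp(warped.values[i] / 10.0)
        tree_w = cit.fit_ctree(warped, labels, seed=0)
        assert cit.split_genes(tree_w) == cit.split_genes(base)

        perm = np.random.default_rng(1).permutation(m.n_samples)
        shuffled = m.subset_samples([m.samples[j] for j in perm])
        tree_s = cit.fit_ctree(shuffled, labels[shuffled.samples], seed=0)
        assert cit.split_genes(tree_s) == cit.split_genes(base)
        assert tree_s.cutoff == base.cutoff

    def test_three_tier_structure_on_handcrafted_data(self):
        # severe NSOI: high PLA2G2A; IgG4-ROD: high RBM47; mild NSOI: high
        # AQP1; MALT: low on all three. The recovered tree must use exactly
        # these three marker genes and resolve every entity into a pure leaf.
        # (Which marker lands in which tier is a coin flip for rank
        # statistics when every marker separates its group cleanly, so the
        # tier *order* is not asserted — only the recovered structure.)
        rng = np.random.default_rng(5)
        n = 8
        labels = (["severe NSOI"] * n + ["IgG4-ROD"] * n
                  + ["mild NSOI"] * n + ["MALT"] * n)
        pla = np.concatenate([rng.uniform(700, 900, n), rng.uniform(100, 500, 3 * n)])
        rbm = np.concatenate([rng.uniform(5, 30, n), rng.uniform(45, 70, n),
                              rng.uniform(5, 30, n), rng.uniform(5, 30, n)])
        aqp = np.concatenate([rng.uniform(5, 25, 2 * n), rng.uniform(140, 250, n),
                              rng.uniform(5, 25, n)])
        noise = {f"G{i}": rng.normal(100, 20, 4 * n) for i in range(10)}
        m = make_matrix(endo={"PLA2G2A": pla, "RBM47": rbm, "AQP1": aqp, **noise})
        tree = cit.fit_ctree(m, pd.Series(labels, index=m.samples), seed=0)
        assert set(cit.split_genes(tree)) == {"PLA2G2A", "RBM47", "AQP1"}

        def leaves(node):
            if node.is_leaf:
                return [node]
            return leaves(node.left) + leaves(node.right)

        leaf_nodes = leaves(tree)
        assert len(leaf_nodes) == 4
        assert all(len(leaf.class_counts) == 1 for leaf in leaf_nodes)
        assert sum(leaf.n for leaf in leaf_nodes) == 4 * n

    def test_empty_matrix_rejected(self):
        m = make_matrix(endo={"A": []})
        with pytest.raises(StatisticsError):
            cit.fit_ctree(m, pd.Series(dtype=object))


class TestPredict:
    def test_leaf_only_tree_returns_distribution(self):
        leaf = cit.TreeNode({"A": 3, "B": 1})
        assert cit.predict(leaf, {}) == {"A": 0.75, "B": 0.25}

    def test_value_at_cutoff_routes_left(self):
        tree = cit.TreeNode({"A": 2, "B": 2}, gene="X", cutoff=5.0, adjusted_p=0.01,
                            left=cit.TreeNode({"A": 2}), right=cit.TreeNode({"B": 2}))
        assert cit.predict(tree, {"X": 5.0}) == {"A": 1.0}
        assert cit.predict(tree, {"X": 5.0001}) == {"B": 1.0}

    def test_missing_gene_named(self):
        tree = cit.TreeNode({"A": 1, "B": 1}, gene="PLA2G2A", cutoff=1.0,
                            adjusted_p=0.01, left=cit.TreeNode({"A": 1}),
                            right=cit.TreeNode({"B": 1}))
        with pytest.raises(KeyError, match="PLA2G2A"):
            cit.predict(tree, {"OTHER": 2.0})

    def test_loocv_accuracy_on_planted_cohort(self):
        # 3 entities, one clean marker each, strength-2-style separation
        spec = sd.CohortSpec(
            groups=[("NSOI", 20), ("IgG4-ROD", 20), ("MALT", 20)],
            effects={"PLA2G2A": {"NSOI": 2.0}, "RBM47": {"IgG4-ROD": 2.0}},
            gene_means=sd.tree_gene_baselines(),
            seed=13,
        )
        panel = sd.build_panel(15, 3, 3, 0, required_genes=list(sd.TREE_GENES))
        cohort = sd.simulate_cohort(spec, panel)
        norm = normalization.normalize(cohort.counts)
        acc = cit.loocv_accuracy(norm, cohort.labels, seed=0, n_perm=9999)
        assert acc >= 0.9
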