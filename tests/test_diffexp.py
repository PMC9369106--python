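import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from orbitdx import diffexp, normalization, synthetic_data as sd
from orbitdx.exceptions import StatisticsError


def bh_stepup_oracle(pvals):
    """Independent Benjamini–Hochberg step-up implementation."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


class TestTestGene:
    def test_identical_arms_not_significant(self):
        p, d = diffexp.test_gene([5.0] * 6, [True] * 3 + [False] * 3)
        assert p == 1.0 and d is None

    def test_ranksum_matches_enumeration_oracle(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        in_group = np.array([True] * 3 + [False] * 3)
        p, d = diffexp.test_gene(values, in_group, method="ranksum")
        assert d == "down"
        # enumerate all 20 rank assignments; two-sided p of the U statistic
        r_obs = sum(sorted(values).index(v) + 1 for v in values[in_group])
        u_obs = r_obs - 3 * 4 / 2
        center = 9 / 2  # n1*n2/2
        count = 0
        for combo in itertools.combinations(range(6), 3):
            r = sum(sorted(values).index(values[i]) + 1 for i in combo)
            u = r - 3 * 4 / 2
            if abs(u - center) >= abs(u_obs - center) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 20, abs=1e-12)

    def test_planted_shift_direction(self):
        rng = np.random.default_rng(0)
        a = rng.normal(4.0, 1.0, 30)  # +2 log2FC arm
        b = rng.normal(2.0, 1.0, 30)
        p, d = diffexp.test_gene(np.concatenate([a, b]),
                                 np.array([True] * 30 + [False] * 30))
        assert d == "up" and p < 1e-6

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=20)
        in_group = np.arange(20) < 8
        p0, _ = diffexp.test_gene(values, in_group)
        perm = rng.permutation(20)
        p1, _ = diffexp.test_gene(values[perm], in_group[perm])
        assert p0 == pytest.approx(p1, rel=1e-12)

    def test_small_arm_rejected(self):
        with pytest.raises(StatisticsError):
            diffexp.test_gene([1.0, 2.0, 3.0], [True, False, False])


class TestBhAdjustment:
    def test_single_test_is_identity(self):
        _, adj, _, _ = multipletests([0.04], method="fdr_bh")
        assert adj[0] == pytest.approx(0.04)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 21)).tolist()
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(adj, bh_stepup_oracle(p), rtol=1e-12)


def _planted_cohort(n_per_group=30, seed=4):
    spec = sd.CohortSpec(
        groups=[("NSOI", n_per_group), ("IgG4-ROD", n_per_group), ("MALT", n_per_group)],
        effects=sd.default_marker_effects(2.0),
        gene_means=sd.marker_gene_baselines(),
        seed=seed,
    )
    return sd.simulate_cohort(spec, sd.validation_panel())


class TestDifferentialGenes:
    def test_recovers_planted_markers(self):
        cohort = _planted_cohort()
        norm = normalization.normalize(cohort.counts)
        mask = normalization.noise_filter(norm, cohort.labels)
        res = diffexp.differential_genes(norm, cohort.labels, mask)
        by = res.set_index(["entity", "gene"])
        # the single down-regulated NSOI marker comes out down and significant
        assert by.loc[("NSOI", "RPS27A"), "direction"] == "down"
        assert by.loc[("NSOI", "RPS27A"), "significant"]
        assert by.loc[("NSOI", "ANG"), "direction"] == "up"
        assert by.loc[("MALT", "RAC1"), "direction"] == "down"
        # adjusted p never below raw p
        assert (res["adjusted_p"] >= res["raw_p"] - 1e-12).all()

    def test_lymphoma_overlaps_exceed_nsoi_igg4(self):
        cohort = _planted_cohort()
        norm = normalization.normalize(cohort.counts)
        mask = normalization.noise_filter(norm, cohort.labels)
        res = diffexp.differential_genes(norm, cohort.labels, mask)
        summary = diffexp.overlap_sets(diffexp.significant_sets(res))
        malt_igg4 = len(summary.overlap("MALT", "IgG4-ROD"))
        nsoi_igg4 = len(summary.overlap("NSOI", "IgG4-ROD"))
        assert malt_igg4 > nsoi_igg4

    def test_null_cohort_fdr_control(self):
        # scale_sigma=0: the shared per-sample scale factor is a technical
        # confounder that normalization (not the DE test) is meant to remove
        spec = sd.CohortSpec(groups=[("NSOI", 10), ("MALT", 10)], seed=8,
                             scale_sigma=0.0)
        cohort = sd.simulate_cohort(spec, sd.build_panel(200, 5, 4, 0))
        res = diffexp.differential_genes(cohort.counts, cohort.labels)
        nsoi = res[res["entity"] == "NSOI"]
        raw_frac = (nsoi["raw_p"] <= 0.05).mean()
        assert 0.005 <= raw_frac <= 0.12  # near-nominal raw false-positive rate
        # BH controls the false-discovery *rate*, so an occasional null hit
        # is expected; the 200-gene screen must collapse to nearly nothing
        assert nsoi["significant"].sum() <= 2

    def test_significance_monotone_in_alpha(self):
        cohort = _planted_cohort(n_per_group=10, seed=6)
        res = diffexp.differential_genes(cohort.counts, cohort.labels)
        strict = set(res.loc[res["adjusted_p"] <= 0.01, "gene"])
        loose = set(res.loc[res["adjusted_p"] <= 0.10, "gene"])
        assert strict <= loose

    def test_single_entity_rejected(self):
        cohort = _planted_cohort(n_per_group=4, seed=1)
        labels = pd.Series("NSOI", index=cohort.labels.index)
        with pytest.raises(StatisticsError):
            diffexp.differential_genes(cohort.counts, labels)


class TestOverlapSets:
    def test_disjoint(self):
        summary = diffexp.overlap_sets({"a": {"X"}, "b": {"Y"}, "c": {"Z"}})
        assert (summary.pairs["n_overlap"] == 0).all()

    def test_hand_count(self):
        summary = diffexp.overlap_sets({"a": {"A", "B", "C"}, "b": {"B", "C", "D"}})
        row = summary.pairs.iloc[0]
        assert row["n_overlap"] == 2
        assert row["pct_of_a"] == pytest.approx(66.6667, abs=1e-3)

    def test_intersection_bounded_by_set_sizes(self):
        sets = {"a": set("ABCDE"), "b": set("DEFG"), "c": set()}
        summary = diffexp.overlap_sets(sets)
        for _, row in summary.pairs.iterrows():
            assert row["n_overlap"] <= min(len(sets[row["entity_a"]]),
                                           len(sets[row["entity_b"]]))
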