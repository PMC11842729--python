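import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

import microtriage as mt
from microtriage.diversity import _pseudo_f, expected_observed_features

from conftest import brute_force_unifrac, random_tree_and_presence


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestRarefy:
    def test_identity_at_full_depth(self):
        counts = np.array([5, 3, 2])
        np.testing.assert_array_equal(mt.rarefy(counts, 10, seed=0), counts)

    def test_forced_outcome(self):
        np.testing.assert_array_equal(mt.rarefy([100, 0], 10, seed=1), [10, 0])

    def test_depth_error_names_sample(self):
        table = mt.FeatureTable(np.array([[5], [1]]), ["a", "b"], ["shallow"])
        with pytest.raises(ValueError, match="shallow"):
            mt.rarefy_table(table, 100, seed=0)

    def test_hypergeometric_expectation(self):
        """Mean of 2000 seeded draws of (50,50) at depth 20 within 3 SE of 10."""
        rng = np.random.default_rng(123)
        draws = np.array([mt.rarefy([50, 50], 20, rng)[0] for _ in range(2000)])
        # variance of multivariate hypergeometric marginal
        var = 20 * 0.5 * 0.5 * (100 - 20) / (100 - 1)
        se = math.sqrt(var / 2000)
        assert abs(draws.mean() - 10) < 3 * se

    def test_never_exceeds_original_and_sums_exact(self, default_study):
        table, _, _, _, _ = default_study
        rt = mt.rarefy_table(table, depth=int(table.depths().min()), seed=3)
        assert (rt.counts <= table.counts).all()
        assert (rt.counts.sum(axis=0) == table.depths().min()).all()

    def test_ensemble_deterministic(self, tiny_table):
        e = mt.RarefactionEnsemble(tiny_table, n_reps=3, depth=4, seed=9)
        a = [t.counts.copy() for t in e.tables()]
        b = [t.counts.copy() for t in e.tables()]
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)


class TestAlphaMetrics:
    def test_shannon_uniform_closed_form(self):
        assert mt.shannon([10, 10, 10, 10]) == pytest.approx(math.log(4), abs=1e-12)

    def test_shannon_single_taxon_and_observed(self):
        assert mt.shannon([7, 0, 0]) == 0.0
        assert mt.observed_features([7, 0, 0]) == 1

    def test_shannon_three_to_one(self):
        expected = -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))
        assert mt.shannon([3, 1]) == pytest.approx(expected, abs=1e-12)

    def test_shannon_base2(self):
        assert mt.shannon([1, 1], base=2) == pytest.approx(1.0)

    def test_shannon_zero_taxon_invariance_and_uniform_maximum(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            counts = rng.integers(1, 50, size=6)
            assert mt.shannon(counts) == pytest.approx(
                mt.shannon(np.append(counts, 0)), abs=1e-12)
            assert mt.shannon(counts) <= math.log(6) + 1e-12

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            mt.shannon([0, 0])

    def test_rarefied_observed_matches_analytic_expectation(self):
        counts = np.array([100, 40, 10, 5, 1, 0, 25])
        depth = 50
        expected = expected_observed_features(counts, depth)
        rng = np.random.default_rng(7)
        obs = [mt.observed_features(mt.rarefy(counts, depth, rng)) for _ in range(500)]
        se = np.std(obs) / math.sqrt(len(obs))
        assert abs(np.mean(obs) - expected) < 3 * se + 1e-9


class TestTwoWayAnova:
    def test_balanced_toy_matches_textbook_sums_of_squares(self):
        """Balanced 2x2 with cell means (0,0,0,d): F ratios equal the
        hand-computed balanced-design decomposition."""
        d, eps, r = 2.0, 0.5, 4
        rows = []
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                mean = d if (a, b) == ("a2", "b2") else 0.0
                for k in range(r):
                    val = mean + (eps if k % 2 else -eps)
                    rows.append((a, b, val))
        data = pd.DataFrame(rows, columns=["fa", "fb", "y"])
        table = mt.two_way_anova(data, "y", "fa", "fb")
        y = data["y"]
        grand = y.mean()
        ss_a = sum(2 * r * (data[data.fa == a].y.mean() - grand) ** 2 for a in ("a1", "a2"))
        ss_b = sum(2 * r * (data[data.fb == b].y.mean() - grand) ** 2 for b in ("b1", "b2"))
        ss_cells = sum(
            r * (data[(data.fa == a) & (data.fb == b)].y.mean() - grand) ** 2
            for a in ("a1", "a2") for b in ("b1", "b2"))
        ss_ab = ss_cells - ss_a - ss_b
        ss_resid = sum((y - data.groupby(["fa", "fb"])["y"].transform("mean")) ** 2)
        ms_resid = ss_resid / (4 * r - 4)
        assert table.loc["C(fa)", "F"] == pytest.approx((ss_a / 1) / ms_resid, rel=1e-9)
        assert table.loc["C(fb)", "F"] == pytest.approx((ss_b / 1) / ms_resid, rel=1e-9)
        assert table.loc["C(fa):C(fb)", "F"] == pytest.approx((ss_ab / 1) / ms_resid, rel=1e-9)

    def test_alpha_ensemble_runs_with_tukey(self, default_study, default_triage):
        table, metadata, _, _, _ = default_study
        amp = table.select_features(default_triage.features_in_class(mt.AMPLICON))
        brains = list(metadata.index[metadata["source"] == "brain"])
        out = mt.alpha_ensemble(amp.select_samples(brains), metadata, n_reps=5, seed=2)
        assert set(out["per_sample"].columns) == {"shannon", "observed"}
        for metric in ("shannon", "observed"):
            anova = out["anova"][metric]
            assert (anova["PR(>F)"].dropna() <= 1).all()
            tk = out["tukey"][metric]
            # Tukey CI must bracket its difference estimate
            assert ((tk["lower"] <= tk["meandiff"]) & (tk["meandiff"] <= tk["upper"])).all()

    def test_constant_response_convention(self):
        # one feature only: every rarefied sample has Shannon 0
        table = mt.FeatureTable(np.array([[50, 60, 40, 70]]), ["a"],
                                ["s1", "s2", "s3", "s4"])
        meta = pd.DataFrame({
            "implant_status": ["acute", "acute", "chronic", "chronic"],
            "treatment": ["control", "antibiotic", "control", "antibiotic"],
        }, index=["s1", "s2", "s3", "s4"])
        out = mt.alpha_ensemble(table, meta, n_reps=3, seed=0)
        assert out["anova"]["shannon"] is None
        assert any("constant" in w for w in out["warnings"])


class TestUniFrac:
    def test_three_leaf_worked_example(self):
        tree = newick("((A:1,B:1):1,C:2);")
        assert mt.unweighted_unifrac({"A", "C"}, {"B", "C"}, tree) == pytest.approx(0.4, abs=1e-12)

    def test_identical_sets_zero(self):
        tree = mt.simulate_tree(8, seed=0)
        taxa = {l.taxon.label for l in tree.leaf_node_iter()}
        assert mt.unweighted_unifrac(taxa, taxa, tree) == 0.0

    def test_disjoint_on_star_tree(self):
        tree = newick("(A:1,B:1,C:1,D:1);")
        assert mt.unweighted_unifrac({"A", "B"}, {"C", "D"}, tree) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            tree, a, b = random_tree_and_presence(rng)
            ours = mt.unweighted_unifrac(a, b, tree)
            assert abs(ours - brute_force_unifrac(tree, a, b)) < 1e-12

    def test_matches_scikit_bio(self):
        """Independent cross-check against the reference implementation."""
        import io as _io

        from skbio import TreeNode
        from skbio.diversity import beta_diversity

        rng = np.random.default_rng(9)
        tree = mt.simulate_tree(10, seed=11)
        taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
        pres = rng.random((4, 10)) < 0.5
        pres[:, 0] = True  # no empty samples
        ids = [f"s{i}" for i in range(4)]
        ours = mt.unifrac_matrix(pres, taxa, tree, sample_ids=ids)
        sk_tree = TreeNode.read(_io.StringIO(tree.as_string(schema="newick").strip()))
        sk_tree = sk_tree.root_at_midpoint()
        ref = beta_diversity("unweighted_unifrac", pres.astype(int), ids=ids,
                             taxa=taxa, tree=sk_tree)
        np.testing.assert_allclose(ours.values, ref.data, atol=1e-10)

    def test_metric_properties_on_random_trees(self):
        rng = np.random.default_rng(3)
        tree = mt.simulate_tree(9, seed=4)
        taxa = [l.taxon.label for l in tree.leaf_node_iter()]
        index = mt.index_tree(tree)
        sets = []
        while len(sets) < 3:
            s = {t for t in taxa if rng.random() < 0.5}
            if s:
                sets.append(s)
        a, b, c = sets
        dab = mt.unweighted_unifrac(a, b, index)
        dba = mt.unweighted_unifrac(b, a, index)
        dac = mt.unweighted_unifrac(a, c, index)
        dcb = mt.unweighted_unifrac(c, b, index)
        assert dab == dba
        assert 0 <= dab <= 1
        assert dab <= dac + dcb + 1e-12

    def test_unknown_taxon_errors(self):
        tree = newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="ZZ"):
            mt.unweighted_unifrac({"A"}, {"ZZ"}, tree)
        with pytest.raises(ValueError):
            mt.unweighted_unifrac(set(), set(), tree)


class TestPCoA:
    def test_two_point_worked_example(self):
        dm = mt.DistanceMatrix(["a", "b"], np.array([[0.0, 2.0], [2.0, 0.0]]))
        res = mt.pcoa(dm)
        np.testing.assert_allclose(res.eigenvalues, [2.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(np.abs(res.coordinates["PC1"]), [1.0, 1.0], atol=1e-12)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_zero_matrix_has_no_axes(self):
        dm = mt.DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        res = mt.pcoa(dm)
        assert res.coordinates.shape[1] == 0
        np.testing.assert_allclose(res.eigenvalues, 0.0, atol=1e-12)

    def test_euclidean_embedding_round_trip(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            pts = rng.normal(size=(7, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            np.fill_diagonal(d, 0.0)
            res = mt.pcoa(mt.DistanceMatrix([f"p{i}" for i in range(7)], d))
            coords = res.coordinates.to_numpy()
            d2 = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
            assert np.max(np.abs(d - d2)) < 1e-8

    def test_matches_scikit_bio(self):
        from skbio.stats.ordination import pcoa as sk_pcoa

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        ours = mt.pcoa(mt.DistanceMatrix([str(i) for i in range(6)], d))
        ref = sk_pcoa(d)
        np.testing.assert_allclose(
            sorted(ours.eigenvalues, reverse=True)[:4],
            ref.eigvals.to_numpy()[:4], atol=1e-8)


class TestPermanova:
    def _dm_from_points(self, pts):
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        return mt.DistanceMatrix([f"s{i}" for i in range(len(pts))], d)

    def test_duplicate_points_no_separation(self):
        pts = np.vstack([np.eye(3), np.eye(3)])
        dm = self._dm_from_points(pts)
        res = mt.permanova(dm, ["a", "a", "a", "b", "b", "b"],
                           n_permutations=199, seed=0)
        assert res.p_value > 0.5

    def test_p_floor(self):
        """p never drops below 1/(1+n_permutations), even for perfectly
        separated groups."""
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(50, 1, (6, 2))])
        dm = self._dm_from_points(pts)
        res = mt.permanova(dm, ["a"] * 6 + ["b"] * 6, n_permutations=99, seed=1)
        assert res.p_value >= 1 / 100
        assert res.p_value <= 0.05  # the split is essentially unambiguous

    def test_matches_exhaustive_enumeration_n6(self):
        """Sampled permutation p agrees with full enumeration over all 20
        label splits of 2 groups of 3."""
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(6, 3))
        pts[:3] += 1.5
        dm = self._dm_from_points(pts)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        d2 = dm.values**2
        ss_total = d2.sum() / 12.0
        groups = np.array(["a", "b"])
        f_obs = _pseudo_f(d2, labels, groups, ss_total)
        f_all = []
        for combo in itertools.combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(combo)] = "a"
            f_all.append(_pseudo_f(d2, lab, groups, ss_total))
        exact_p = np.mean(np.asarray(f_all) >= f_obs - 1e-12)
        res = mt.permanova(dm, labels, n_permutations=5000, seed=3)
        se = math.sqrt(exact_p * (1 - exact_p) / 5000)
        assert abs(res.p_value - exact_p) < 4 * se + 2e-3

    def test_matches_scikit_bio_statistic(self):
        from skbio.stats.distance import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova as sk_permanova

        rng = np.random.default_rng(4)
        pts = rng.normal(size=(10, 3))
        pts[:5] += 1.0
        dm = self._dm_from_points(pts)
        labels = ["a"] * 5 + ["b"] * 5
        ours = mt.permanova(dm, labels, n_permutations=99, seed=0)
        ref = sk_permanova(SkDM(dm.values, ids=dm.labels), grouping=labels,
                           permutations=99)
        assert ours.statistic == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_singleton_group_errors(self):
        dm = mt.DistanceMatrix(["a", "b", "c"],
                               np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]]))
        with pytest.raises(ValueError, match="singleton"):
            mt.permanova(dm, ["x", "x", "y"], n_permutations=9, seed=0)


class TestBetaEnsemble:
    def test_single_replicate_bh_identity(self, default_study, default_triage):
        table, metadata, _, tree, _ = default_study
        amp = table.select_features(default_triage.features_in_class(mt.AMPLICON))
        cohort = list(metadata.index[(metadata["source"] == "brain")
                                     & (metadata["treatment"] == "control")])
        out = mt.beta_ensemble(amp.select_samples(cohort), tree, metadata,
                               n_reps=1, n_permutations=99, seed=0)
        assert out["p_adjusted"][0] == out["p_values"][0]
        assert out["max_adjusted_p"] == out["min_raw_p"]

    def test_planted_signal_detected(self, default_study, default_triage):
        table, metadata, _, tree, _ = default_study
        amp = table.select_features(default_triage.features_in_class(mt.AMPLICON))
        cohort = list(metadata.index[(metadata["source"] == "brain")
                                     & (metadata["treatment"] == "control")])
        out = mt.beta_ensemble(amp.select_samples(cohort), tree, metadata,
                               n_reps=5, n_permutations=199, seed=0)
        assert out["max_adjusted_p"] < 0.05

    def test_null_config_not_significant(self):
        """With identical pool compositions across groups the PERMANOVA
        stays null in most seeds."""
        from dataclasses import replace
        high = 0
        for seed in range(6):
            cfg = replace(mt.SimulationConfig(), seed=seed,
                          shared_pool_proportions=True,
                          invader_gut_frac=0.0, invader_unknown_frac=0.0)
            table, metadata, annotations, tree, truth = mt.simulate_study(cfg)
            tri = mt.triage_features(table, metadata, annotations)
            amp = table.select_features(tri.features_in_class(mt.AMPLICON))
            cohort = list(metadata.index[(metadata["source"] == "brain")
                                         & (metadata["treatment"] == "control")])
            out = mt.beta_ensemble(amp.select_samples(cohort), tree, metadata,
                                   n_reps=2, n_permutations=199, seed=seed)
            high += out["min_raw_p"] > 0.05
        assert high >= 4
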