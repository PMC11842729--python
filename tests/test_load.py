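import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import microtriage as mt
from microtriage._stats import dunn_test, loess_fit, spearman_correlation
from microtriage.triage import TriageConfig, TriageResult


def make_triage(classes: dict) -> TriageResult:
    s = pd.Series(classes)
    nan = pd.Series(np.nan, index=s.index)
    return TriageResult(s, nan, nan, TriageConfig())


class TestLoadProfiles:
    def test_ratio_arithmetic(self):
        table = mt.FeatureTable(np.array([[210], [60], [40]]), ["a", "h", "t"], ["s"])
        tri = make_triage({"a": mt.AMPLICON, "h": mt.HOST_GDNA,
                           "t": mt.TECHNICAL_CONTAMINANT})
        prof = mt.load_profiles(table, tri)
        assert prof.loc["s", "ratio"] == pytest.approx(2.10)
        assert prof.loc["s", "amplicon_reads"] + prof.loc["s", "contaminant_reads"] \
            == prof.loc["s", "total_reads"]

    def test_zero_amplicon_and_zero_contaminant(self):
        table = mt.FeatureTable(np.array([[0, 50], [50, 0]]), ["a", "h"], ["s1", "s2"])
        tri = make_triage({"a": mt.AMPLICON, "h": mt.HOST_GDNA})
        prof = mt.load_profiles(table, tri)
        assert prof.loc["s1", "ratio"] == 0.0
        assert math.isinf(prof.loc["s2", "ratio"])
        assert prof.loc["s2", "flag"] == "no_contaminant"

    def test_empty_sample_flagged(self):
        table = mt.FeatureTable(np.array([[0], [0]]), ["a", "h"], ["s"])
        tri = make_triage({"a": mt.AMPLICON, "h": mt.HOST_GDNA})
        prof = mt.load_profiles(table, tri)
        assert math.isnan(prof.loc["s", "ratio"]) and prof.loc["s", "flag"] == "empty"

    def test_ratio_invariant_to_relabeling_within_class(self, default_study, default_triage):
        """Moving reads between features of the same triage class leaves
        every sample's ratio unchanged."""
        table, _, _, _, _ = default_study
        prof1 = mt.load_profiles(table, default_triage)
        amp = default_triage.features_in_class(mt.AMPLICON)
        df = table.to_dataframe().copy()
        df.loc[amp[0]] += df.loc[amp[1]]
        df.loc[amp[1]] = 0
        prof2 = mt.load_profiles(mt.FeatureTable.from_dataframe(df), default_triage)
        pd.testing.assert_series_equal(prof1["ratio"], prof2["ratio"])


class TestSpearman:
    def test_perfect_inverse_is_minus_one(self):
        depths = np.array([10, 20, 40, 80, 160.0])
        rel = 1 / depths
        res = spearman_correlation(depths, rel)
        assert res.statistic == pytest.approx(-1.0)

    def test_degenerate_constant(self):
        res = spearman_correlation([1, 2, 3, 4, 5], [7, 7, 7, 7, 7])
        assert res.statistic == 0.0 and res.p_value == 1.0
        assert res.extra["degenerate"]

    def test_exact_p_matches_enumeration_n8(self):
        """rho and exact p equal brute-force enumeration over all 8! rank
        permutations (independent itertools oracle)."""
        rng = np.random.default_rng(5)
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        res = spearman_correlation(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        rho_obs = np.corrcoef(rx, ry)[0, 1]
        assert res.statistic == pytest.approx(rho_obs, abs=1e-12)
        count = total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            count += abs(r) >= abs(rho_obs) - 1e-12
            total += 1
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_large_n_uses_t_approximation(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = spearman_correlation(x, y)
        expected = stats.spearmanr(x, y)
        assert res.statistic == pytest.approx(expected.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(expected.pvalue, rel=1e-6)


class TestDepthAbundanceDiagnostics:
    def test_contaminant_class_negatively_correlated(self, default_study, default_triage):
        table, metadata, _, _, _ = default_study
        fecal = list(metadata.index[metadata["source"] == "fecal"])
        res = mt.depth_abundance_correlation(
            table.select_samples(fecal), default_triage, "CONTAMINANT")
        assert res.statistic < 0
        assert len(res.extra["loess"]) == len(fecal)

    def test_loess_matches_statsmodels(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess

        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 10, 40))
        y = np.sin(x) + rng.normal(0, 0.1, 40)
        ours = loess_fit(x, y, span=0.75)
        ref = lowess(y, x, frac=0.75, it=0, return_sorted=False)
        assert np.max(np.abs(ours["fitted"].to_numpy() - ref)) < 1e-8

    def test_requires_five_samples(self, default_study, default_triage):
        table, _, _, _, _ = default_study
        with pytest.raises(ValueError):
            mt.depth_abundance_correlation(
                table.select_samples(table.sample_ids[:4]), default_triage, "AMPLICON")


class TestCompareRatios:
    def test_identical_groups_give_p_one(self):
        prof = pd.DataFrame({"ratio": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]},
                            index=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=prof.index)
        res = mt.compare_ratios(prof, meta, "g")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_dunn_oracle_three_separated_groups(self):
        """Dunn z for {1,2,3},{10,20,30},{100,200,300}: mean ranks 2/5/8,
        pooled variance N(N+1)/12 = 7.5, z = 3/sqrt(5) adjacent."""
        prof = pd.DataFrame(
            {"ratio": [1, 2, 3, 10, 20, 30, 100, 200, 300.0]},
            index=[f"s{i}" for i in range(9)])
        meta = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3 + ["c"] * 3}, index=prof.index)
        res = mt.compare_ratios(prof, meta, "g")
        pair = res.pairwise.set_index(["group1", "group2"])
        z_adj = 3 / math.sqrt(5)
        assert abs(pair.loc[("a", "b"), "z"]) == pytest.approx(z_adj, abs=1e-12)
        assert abs(pair.loc[("a", "c"), "z"]) == pytest.approx(2 * z_adj, abs=1e-12)
        expected_p = 2 * stats.norm.sf(z_adj)
        assert pair.loc[("a", "b"), "p_value"] == pytest.approx(expected_p, rel=1e-12)

    def test_bh_never_below_raw(self, default_study, default_triage):
        table, metadata, _, _, _ = default_study
        prof = mt.load_profiles(table, default_triage)
        nonblank = metadata.index[metadata["source"] != "blank"]
        meta = metadata.assign(group=metadata["implant_status"])
        res = mt.compare_ratios(prof.loc[nonblank], meta, "group")
        assert (res.pairwise["p_adjusted"] >= res.pairwise["p_value"] - 1e-15).all()

    def test_infinite_ratios_rank_at_top(self):
        prof = pd.DataFrame({"ratio": [1.0, 2.0, np.inf, 10.0, 20.0, np.inf]},
                            index=[f"s{i}" for i in range(6)])
        meta = pd.DataFrame({"g": ["a"] * 3 + ["b"] * 3}, index=prof.index)
        res = mt.compare_ratios(prof, meta, "g")  # must not raise
        assert 0 <= res.p_value <= 1

    def test_small_groups_excluded(self):
        prof = pd.DataFrame({"ratio": [1.0, 2.0, 3.0, 4.0, 9.0]},
                            index=[f"s{i}" for i in range(5)])
        meta = pd.DataFrame({"g": ["a", "a", "b", "b", "c"]}, index=prof.index)
        res = mt.compare_ratios(prof, meta, "g")
        assert res.extra["excluded_groups"] == ["c"]


class TestBoxSummary:
    def test_whiskers_at_1p5_iqr(self):
        vals = list(range(1, 12)) + [100]  # one far outlier
        box = mt.box_summary(vals)
        assert box["median"] == 6.5
        assert box["whisker_high"] == 11  # outlier excluded
        assert box["whisker_low"] == 1
        assert box["n"] == 12
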