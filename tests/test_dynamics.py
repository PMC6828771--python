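"""Timing integration: rank-LOESS, PCA, categories, precedence, profiles,
correlations and fraction reporting."""

import numpy as np
import pandas as pd
import pytest

from woundchrom.dynamics import (classify_ac_category, loading_angle_deg,
                                 marking_expression_correlation,
                                 precedence_counts, rank_loess_timing,
                                 report_fraction, temporal_profiles,
                                 timing_pca)
from woundchrom.genomic import ValidationError


def _series(values, prefix="g"):
    return pd.Series(values, index=[f"{prefix}{i}" for i in range(len(values))])


class TestRankLoess:
    def test_constant_labels_flat_curve_zero_rho(self):
        levels = _series(np.linspace(0, 1, 60))
        labels = _series(np.full(60, 3.0))
        curve, rho = rank_loess_timing(levels, labels)
        assert np.allclose(curve["smoothed_cluster"], 3.0)
        assert rho == 0.0

    def test_perfect_monotone_decrease(self):
        levels = _series(np.arange(60, dtype=float))
        labels = _series(np.arange(60, 0, -1, dtype=float))
        curve, rho = rank_loess_timing(levels, labels)
        assert rho == pytest.approx(-1.0)
        sm = curve["smoothed_cluster"].to_numpy()
        assert (np.diff(sm) <= 1e-9).all()

    def test_invariant_to_monotone_level_transform(self):
        rng = np.random.default_rng(10)
        levels = _series(rng.uniform(1, 10, 80))
        labels = _series(rng.integers(1, 9, 80).astype(float))
        c1, r1 = rank_loess_timing(levels, labels)
        c2, r2 = rank_loess_timing(np.log(levels) ** 3, labels)
        assert np.allclose(c1["smoothed_cluster"], c2["smoothed_cluster"])
        assert r1 == pytest.approx(r2)

    def test_invalid_span(self):
        levels = _series(np.arange(60, dtype=float))
        with pytest.raises(ValidationError):
            rank_loess_timing(levels, levels, span=0.0)

    def test_acetylation_predicts_timing_on_synthetic(self, state,
                                                      synth_truth):
        """Pre-wound H3K9/14ac anticorrelates with induction timing; the
        elongation mark H3K36me3 does not."""
        truth, _ = synth_truth
        induced = truth.index[np.isfinite(truth["t_star"])]
        # proxy timing label: planted induction time ordering
        labels = truth.loc[induced, "t_star"].rank(method="dense")
        lv = state.level_matrix(0.0)
        _, rho_ac = rank_loess_timing(lv.loc[induced, "H3K9_14ac"], labels)
        _, rho_36 = rank_loess_timing(lv.loc[induced, "H3K36me3"], labels)
        assert rho_ac < -0.3
        assert abs(rho_ac) > abs(rho_36)


class TestTimingPCA:
    def test_rank_one_case(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=200)
        v = pd.DataFrame({"a": x, "b": 3 * x})
        _, var = timing_pca(v)
        assert var["PC1"] == pytest.approx(1.0)

    def test_independent_variables_split_variance(self):
        rng = np.random.default_rng(12)
        v = pd.DataFrame(rng.normal(size=(2000, 2)), columns=["a", "b"])
        _, var = timing_pca(v)
        assert abs(var["PC1"] - 0.5) < 0.05
        assert abs(var["PC2"] - 0.5) < 0.05

    def test_constant_variable_dropped(self):
        rng = np.random.default_rng(13)
        v = pd.DataFrame({"a": rng.normal(size=50), "c": np.ones(50)})
        loadings, _ = timing_pca(v)
        assert "c" not in loadings.index

    def test_sign_convention(self):
        rng = np.random.default_rng(14)
        v = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        loadings, _ = timing_pca(v)
        assert loadings.iloc[0]["PC1"] >= 0

    def test_timing_antiparallel_to_acetylation(self, state, synth_truth):
        truth, _ = synth_truth
        induced = truth.index[np.isfinite(truth["t_star"])]
        lv = state.level_matrix(0.0).loc[induced]
        v = lv.rank()
        v["timing"] = truth.loc[induced, "t_star"].rank(method="dense")
        loadings, _ = timing_pca(v)
        assert loading_angle_deg(loadings, "timing", "H3K9_14ac") > 90


class TestAcCategory:
    def test_hand_fixture(self):
        idx = pd.Index([f"g{i}" for i in range(6)])
        pre = pd.Series([1, 1, 0, 0, 1, 0], index=idx, dtype=bool)
        ac = pd.Series([np.inf, 3.0, 1.0, np.inf, 6.0, np.inf], index=idx)
        me3 = pd.Series([np.inf, np.inf, 3.0, 3.0, np.inf, np.inf], index=idx)
        res = classify_ac_category(pre, ac, me3)
        assert res["category"].tolist() == [
            "preac_no_gain", "preac_plus_gain", "gain_only", "no_ac",
            "preac_plus_gain", "no_ac"]
        assert res["me3_gain"].tolist() == [False, False, True, True,
                                            False, False]

    def test_rap26_type_profile(self):
        # unmarked gene gaining ac at 1 h and me3 at 3 h
        idx = pd.Index(["g"])
        res = classify_ac_category(
            pd.Series([False], index=idx),
            pd.Series([1.0], index=idx), pd.Series([3.0], index=idx))
        assert res.loc["g", "category"] == "gain_only"
        assert bool(res.loc["g", "me3_gain"])

    def test_missing_gene_rejected(self):
        idx = pd.Index(["g1", "g2"])
        with pytest.raises(ValidationError):
            classify_ac_category(pd.Series([True, False], index=idx),
                                 pd.Series([1.0], index=idx[:1]),
                                 pd.Series([1.0, 1.0], index=idx))

    def test_categories_partition(self, synth_truth):
        truth, _ = synth_truth
        pre = truth["pre_H3K9_14ac"]
        res = classify_ac_category(pre, truth["gain_time_H3K9_14ac"],
                                   truth["gain_time_H3K4me3"])
        assert res["category"].isin(
            ["preac_no_gain", "preac_plus_gain", "gain_only", "no_ac"]).all()
        assert len(res) == len(truth)


class TestPrecedence:
    @pytest.mark.parametrize("t_ac,t_me3,expected", [
        (1.0, 3.0, "ac_first"),
        (3.0, 3.0, "simultaneous"),
        (3.0, 1.0, "me3_first"),
        (1.0, np.inf, "only_ac"),
        (np.inf, 1.0, "only_me3"),
        (np.inf, np.inf, "neither"),
    ])
    def test_category_rules(self, t_ac, t_me3, expected):
        idx = pd.Index(["g"])
        res = precedence_counts(pd.Series([t_ac], index=idx),
                                pd.Series([t_me3], index=idx))
        assert res.table.loc["g", "category"] == expected

    def test_partition_and_inclusive_tally(self):
        idx = pd.Index([f"g{i}" for i in range(5)])
        ac = pd.Series([1.0, 3.0, 1.0, np.inf, np.inf], index=idx)
        me3 = pd.Series([3.0, 3.0, np.inf, 1.0, np.inf], index=idx)
        res = precedence_counts(ac, me3)
        assert int(res.counts.sum()) == 5
        assert res.counts_inclusive["ac_first"] == \
            res.counts["ac_first"] + res.counts["only_ac"]

    def test_planted_lag_yields_asymmetry(self, synth_truth):
        truth, _ = synth_truth
        slow = truth[truth["gene_class"] == "slow_gain_ac_then_me3"]
        res = precedence_counts(slow["gain_time_H3K9_14ac"],
                                slow["gain_time_H3K4me3"])
        assert res.ac_first >= 5 * max(res.me3_first, 1)


class TestProfiles:
    def test_single_gene_group(self):
        levels = pd.DataFrame({
            "gene_id": ["g"] * 2, "mark": ["m"] * 2,
            "time_h": [0.0, 1.0], "level": [1.0, 2.0]})
        groups = pd.Series({"g": "solo"})
        prof, _ = temporal_profiles(levels, groups)
        assert (prof["sd"] == 0).all()
        assert prof.set_index("time_h")["mean"].to_dict() == {0.0: 1.0,
                                                              1.0: 2.0}

    def test_gain_group_steps_up_on_synthetic(self, state, synth_truth,
                                              synth_config):
        truth, _ = synth_truth
        slow = truth.index[truth["gene_class"] == "slow_gain_ac_then_me3"]
        groups = pd.Series("slow", index=slow)
        lv = state.levels[state.levels["mark"] == "H3K9_14ac"]
        prof, _ = temporal_profiles(lv, groups)
        m = prof.set_index("time_h")["mean"]
        assert m[1.0] / m[0.0] == pytest.approx(synth_config.gain_fold,
                                                rel=0.15)

    def test_constant_group_is_flat(self, state, synth_truth):
        truth, _ = synth_truth
        rapid = truth.index[truth["gene_class"] == "rapid_preacetylated"]
        lv = state.levels[state.levels["mark"] == "H3K9_14ac"]
        prof, _ = temporal_profiles(lv, pd.Series("rapid", index=rapid))
        m = np.log2(prof.set_index("time_h")["mean"])
        assert m.max() - m.min() < 0.1


class TestCorrelation:
    def test_exact_linearity(self):
        x = _series(np.arange(20, dtype=float))
        assert marking_expression_correlation(x, 2 * x) == pytest.approx(1.0)

    def test_independent_null(self):
        rng = np.random.default_rng(15)
        x = _series(rng.normal(size=2000))
        y = _series(rng.normal(size=2000))
        assert abs(marking_expression_correlation(x, y)) < 0.05

    def test_zero_variance_flagged_nan(self):
        x = _series(np.ones(20))
        y = _series(np.arange(20, dtype=float))
        assert np.isnan(marking_expression_correlation(x, y))

    def test_too_few_pairs_rejected(self):
        x = _series(np.arange(5, dtype=float))
        with pytest.raises(ValidationError):
            marking_expression_correlation(x, x)


class TestReportFraction:
    @pytest.mark.parametrize("num,den,expected", [
        (961, 5777, "17%"),
        (116, 3665, "3.2%"),
        (80, 3665, "2.2%"),
        (1436, 5777, "25%"),
        (416, 1436, "29%"),
        (545, 4341, "13%"),
        (2791, 3665, "76%"),
        (1639, 3665, "45%"),
        (0, 7, "0.0%"),
    ])
    def test_reporting_convention(self, num, den, expected):
        assert report_fraction(num, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            report_fraction(1, 0)
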