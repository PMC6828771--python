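"""Representation factors, hypergeometric tails and distribution tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from woundchrom.enrich import (compare_level_distributions,
                               comark_enrichment,
                               cluster_category_enrichment, mark_enrichment,
                               representation_factor, term_enrichment)
from woundchrom.genomic import ValidationError


def hypergeom_tail_oracle(k, n, K, N):
    """Exhaustive enumeration of both hypergeometric tails."""
    def pmf(x):
        if x < max(0, n + K - N) or x > min(n, K):
            return 0.0
        return math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
    p_over = sum(pmf(x) for x in range(k, n + 1))
    p_under = sum(pmf(x) for x in range(0, k + 1))
    return p_over, p_under


class TestRepresentationFactor:
    def test_proportional_overlap_rf_one(self):
        assert representation_factor(5, 10, 10, 20).representation_factor \
            == pytest.approx(1.0)

    def test_enumerated_example(self):
        res = representation_factor(4, 8, 5, 20)
        assert res.representation_factor == pytest.approx(2.0)
        assert res.p_over == pytest.approx(7280 / 125970)

    def test_empty_overlap_single_term(self):
        res = representation_factor(0, 5, 5, 10)
        assert res.representation_factor == 0.0
        assert res.p_under == pytest.approx(1 / 252)

    @pytest.mark.parametrize("k,n,K,N", [(6, 5, 8, 20), (2, 5, 1, 20),
                                         (2, 5, 8, 6)])
    def test_constraint_violations(self, k, n, K, N):
        with pytest.raises(ValidationError):
            representation_factor(k, n, K, N)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_tails_match_enumeration(self, data):
        N = data.draw(st.integers(1, 30))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n + K - N), min(n, K)))
        res = representation_factor(k, n, K, N)
        p_over, p_under = hypergeom_tail_oracle(k, n, K, N)
        assert res.p_over == pytest.approx(p_over, abs=1e-12)
        assert res.p_under == pytest.approx(p_under, abs=1e-12)
        # the tails share P[X = k] exactly
        assert res.p_over + res.p_under - (p_over + p_under - 1) \
            == pytest.approx(1, abs=1e-12)

    def test_stars_follow_rf_direction(self):
        over = representation_factor(10, 10, 10, 100)
        assert over.representation_factor > 1 and len(over.stars) == 3
        under = representation_factor(0, 10, 80, 100)
        assert under.representation_factor < 1 and len(under.stars) == 3


class TestMarkEnrichment:
    def _marked(self, n, marked_ids):
        idx = [f"g{i}" for i in range(n)]
        return pd.DataFrame({"m": [g in marked_ids for g in idx]}, index=idx)

    def test_query_equals_marked_closed_form(self):
        marked_ids = {f"g{i}" for i in range(50)}
        table = self._marked(100, marked_ids)
        res = mark_enrichment(table, marked_ids, set(table.index))
        assert res.loc["m", "representation_factor"] == pytest.approx(100 / 50)
        assert res.loc["m", "pct_of_marked_in_query"] == pytest.approx(100.0)

    def test_null_rf_near_one(self):
        rng = np.random.default_rng(8)
        marked_ids = {f"g{i}" for i in range(50)}
        table = self._marked(100, marked_ids)
        rfs = []
        for _ in range(500):
            query = set(rng.choice(table.index, 20, replace=False))
            rfs.append(mark_enrichment(table, query, set(table.index))
                       .loc["m", "representation_factor"])
        assert 0.9 <= np.mean(rfs) <= 1.1

    def test_query_outside_universe_rejected(self):
        table = self._marked(10, {"g0"})
        with pytest.raises(ValidationError, match="absent"):
            mark_enrichment(table, {"nope"}, set(table.index))

    def test_planted_mark_enriched_among_induced(self, state, synth_truth):
        truth, _ = synth_truth
        induced = set(truth.index[np.isfinite(truth["t_star"])])
        res = mark_enrichment(state.marked, induced, set(truth.index))
        row = res.loc["H3K27ac"]
        # rapid and slow-gain induced classes carry pre-wound H3K27ac
        assert row["representation_factor"] > 1
        assert row["p_over"] < 0.001


class TestComarkEnrichment:
    def test_hand_fixture(self):
        idx = [f"g{i}" for i in range(10)]
        marked = pd.DataFrame({
            "A": [1, 1, 1, 1, 0, 0, 1, 0, 0, 0],
            "B": [1, 1, 0, 0, 1, 1, 0, 0, 0, 0],
        }, index=idx, dtype=bool)
        # marked universe = 7 genes (g7..g9 bear nothing); co-marked = {g0,g1}
        query = {"g0", "g1", "g2", "g4"}
        res = comark_enrichment(marked, query)
        row = res.loc["A+B"]
        assert (row["k"], row["n"], row["K"], row["N"]) == (2, 4, 2, 7)
        assert row["representation_factor"] == pytest.approx((2 / 4) / (2 / 7))

    def test_bivalent_class_overrepresented_among_induced(self, state,
                                                          synth_truth):
        truth, _ = synth_truth
        induced = set(truth.index[np.isfinite(truth["t_star"])])
        res = comark_enrichment(state.marked, induced,
                                pairs=[("H3K27me3", "H3K4me3")])
        row = res.loc["H3K27me3+H3K4me3"]
        assert row["representation_factor"] > 1
        assert row["p_over"] < 0.01

    def test_empty_universe_rejected(self):
        marked = pd.DataFrame({"A": [False, False]}, index=["g0", "g1"])
        with pytest.raises(ValidationError):
            comark_enrichment(marked, {"g0"})


class TestClusterCategoryEnrichment:
    def test_single_cluster_all_rf_one(self):
        idx = [f"g{i}" for i in range(30)]
        cats = pd.Series(["x"] * 15 + ["y"] * 15, index=idx)
        clus = pd.Series([1] * 30, index=idx)
        res = cluster_category_enrichment(cats, clus)
        assert np.allclose(res["representation_factor"], 1.0)

    def test_confined_category_closed_form(self):
        idx = [f"g{i}" for i in range(30)]
        cats = pd.Series(["x"] * 10 + ["y"] * 20, index=idx)
        clus = pd.Series([1] * 10 + [2] * 20, index=idx)
        res = cluster_category_enrichment(cats, clus).set_index(
            ["cluster", "category"])
        assert res.loc[(1, "x"), "representation_factor"] == \
            pytest.approx(30 / 10)
        assert res.loc[(2, "x"), "representation_factor"] == 0.0

    def test_missing_category_rejected(self):
        cats = pd.Series({"g0": "x"})
        clus = pd.Series({"g0": 1, "g1": 2})
        with pytest.raises(ValidationError):
            cluster_category_enrichment(cats, clus)


class TestLevelDistributions:
    def test_complete_separation_exact_p(self):
        lv = pd.Series(np.r_[np.arange(5), np.arange(5) + 10.0],
                       index=[f"g{i}" for i in range(10)])
        a = {f"g{i}" for i in range(5)}
        b = {f"g{i}" for i in range(5, 10)}
        _, p = compare_level_distributions(lv, a, b)
        assert p == pytest.approx(2 / 252)

    def test_identical_multisets_p_one(self):
        lv = pd.Series(np.r_[np.arange(6), np.arange(6)].astype(float),
                       index=[f"g{i}" for i in range(12)])
        a = {f"g{i}" for i in range(6)}
        b = {f"g{i}" for i in range(6, 12)}
        _, p = compare_level_distributions(lv, a, b)
        assert p > 0.99

    def test_overlapping_sets_rejected(self):
        lv = pd.Series(np.arange(6, dtype=float),
                       index=[f"g{i}" for i in range(6)])
        with pytest.raises(ValidationError):
            compare_level_distributions(lv, {"g0", "g1", "g2"},
                                        {"g2", "g3", "g4"})

    def test_induced_preacetylation_dominates_stable(self, state,
                                                     synth_truth):
        truth, _ = synth_truth
        lv = state.level_matrix(0.0)["H3K9_14ac"]
        rapid = set(truth.index[truth["gene_class"] == "rapid_preacetylated"])
        stable_set = set(truth.index[truth["gene_class"] == "stable"])
        _, p = compare_level_distributions(lv, rapid, stable_set)
        assert p < 1e-6


class TestTermEnrichment:
    def test_saturating_term(self):
        universe = {f"g{i}" for i in range(20)}
        annot = {g: {"all"} for g in universe}
        res = term_enrichment(annot, {f"g{i}" for i in range(5)}, universe)
        assert res.loc["all", "representation_factor"] == pytest.approx(1.0)
        assert res.loc["all", "p_over"] == pytest.approx(1.0)

    def test_term_identical_to_query(self):
        universe = {f"g{i}" for i in range(12)}
        query = {f"g{i}" for i in range(4)}
        annot = {g: {"t"} for g in query}
        res = term_enrichment(annot, query, universe)
        assert res.loc["t", "representation_factor"] == pytest.approx(12 / 4)
        assert res.loc["t", "p_over"] == pytest.approx(1 / math.comb(12, 4))

    def test_toy_annotation_matches_enumeration_oracle(self):
        universe = [f"g{i}" for i in range(12)]
        annot = pd.DataFrame({
            "gene": universe[:5] + universe[3:7] + universe[8:],
            "term": ["t1"] * 5 + ["t2"] * 4 + ["t3"] * 4,
        })
        query = {"g0", "g1", "g3", "g9"}
        res = term_enrichment(annot, query, set(universe))
        for term, genes in (("t1", set(universe[:5])),
                            ("t2", set(universe[3:7])),
                            ("t3", set(universe[8:]))):
            k = len(query & genes)
            p_over, _ = hypergeom_tail_oracle(k, 4, len(genes), 12)
            assert res.loc[term, "p_over"] == pytest.approx(p_over)

    def test_null_resampling_calibrated(self):
        rng = np.random.default_rng(9)
        universe = [f"g{i}" for i in range(100)]
        annot = {g: {"t"} for g in universe[:30]}
        hits = {0.05: 0, 0.01: 0}
        n_resamples = 2000
        for _ in range(n_resamples):
            query = set(rng.choice(universe, 15, replace=False))
            p = term_enrichment(annot, query, set(universe)).loc["t", "p_over"]
            for alpha in hits:
                hits[alpha] += p < alpha
        for alpha, count in hits.items():
            assert count / n_resamples <= alpha + 0.02
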