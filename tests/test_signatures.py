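import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from enterosig.signatures import (
    composition_by_group,
    dominant_es,
    enrichment_specificity,
    loading_diversity,
    rank_features,
)


class TestEnrichmentSpecificity:
    def test_exclusive_feature_extreme(self):
        # one feature loads on a single signature out of 8
        H = np.zeros((8, 2))
        H[3, 0] = 0.5
        H[:, 1] = 0.1
        tab = enrichment_specificity(H)
        row = tab[(tab.signature == 4) & (tab.feature_id == "f0")].iloc[0]
        assert row.enrichment == pytest.approx(8.000)
        assert row.specificity == pytest.approx(1.0)

    def test_uniform_feature(self):
        H = np.full((4, 1), 0.3)
        tab = enrichment_specificity(H)
        assert np.allclose(tab.enrichment, 1.0)

    def test_direct_arithmetic(self):
        H = np.array([[3.0], [1.0], [0.0], [0.0]])
        tab = enrichment_specificity(H)
        np.testing.assert_allclose(tab.specificity, [0.75, 0.25, 0, 0])
        np.testing.assert_allclose(tab.enrichment, [3, 1, 0, 0])

    @given(
        arrays(
            np.float64,
            st.tuples(st.integers(2, 6), st.integers(1, 8)),
            elements=st.floats(0, 10, allow_nan=False),
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_algebraic_invariants(self, H):
        k = H.shape[0]
        tab = enrichment_specificity(H)
        # enrichment = k * specificity everywhere
        np.testing.assert_allclose(tab.enrichment, k * tab.specificity, atol=1e-12)
        # specificity sums to 1 per feature with positive total
        sums = tab.groupby("feature_id")["specificity"].sum()
        totals = H.sum(axis=0)
        for j, fid in enumerate(f"f{j}" for j in range(H.shape[1])):
            if totals[j] > 0:
                assert sums[fid] == pytest.approx(1.0)
            else:
                assert sums[fid] == 0.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        H = rng.random((3, 5))
        a = enrichment_specificity(H)
        b = enrichment_specificity(10.0 * H)
        np.testing.assert_allclose(a.enrichment, b.enrichment)


class TestRankFeatures:
    def test_zero_cv_selects_zscore(self):
        H = np.tile([[0.5, 0.4, 0.3, 0.2, 0.1]], (2, 1))
        tab = enrichment_specificity(H)
        ranked = rank_features(tab, top_n=3)
        assert set(ranked.rank_mode) == {"zscore"}

    def test_high_cv_selects_fold_enrichment(self):
        H = np.zeros((4, 6))
        H[0] = [8, 0.1, 0.1, 0.1, 0.1, 0.1]
        H[1:] = 1.0
        tab = enrichment_specificity(H)
        ranked = rank_features(tab, top_n=3)
        assert "fold_enrichment" in set(
            ranked.loc[ranked.signature == 1, "rank_mode"]
        )

    def test_monotone_loadings_same_top_under_either_mode(self):
        H = np.array([[5.0, 4.0, 3.0, 2.0, 1.0]])
        tab = enrichment_specificity(H)
        ranked = rank_features(tab, top_n=3)
        assert list(ranked.feature_id) == ["f0", "f1", "f2"]

    def test_short_signature_warns(self):
        H = np.array([[1.0, 2.0]])
        with pytest.warns(UserWarning, match="top_n"):
            rank_features(enrichment_specificity(H), top_n=30)


class TestDominantES:
    def test_argmax(self):
        out = dominant_es(np.array([[0.1, 0.7, 0.2]]))
        assert out.dominant_es.iloc[0] == 2
        assert not out.tie.iloc[0]

    def test_tie_lowest_index_flagged(self):
        out = dominant_es(np.array([[0.5, 0.5]]))
        assert out.dominant_es.iloc[0] == 1
        assert out.tie.iloc[0]

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        W = rng.random((20, 4)) + 0.01
        scale = rng.uniform(0.5, 3, size=(20, 1))
        a = dominant_es(W)
        b = dominant_es(W * scale)
        pd.testing.assert_series_equal(a.dominant_es, b.dominant_es)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            dominant_es(np.array([[0.0, 0.0]]))


class TestComposition:
    def test_percentages(self):
        md = pd.DataFrame(
            {
                "line": ["SEN"] * 12,
                "timepoint": ["d4"] * 12,
            }
        )
        labels = pd.DataFrame({"dominant_es": [3] * 4 + [7] * 8})
        comp = composition_by_group(labels, md)
        pct = comp.set_index("dominant_es")["percent"]
        assert pct[3] == pytest.approx(33.3, abs=0.05)

    def test_cells_sum_to_100(self, cohort):
        from enterosig.signatures import dominant_es as dom

        labels = dom(cohort.truth.W_true)
        comp = composition_by_group(labels, cohort.metadata)
        sums = comp.groupby(["line", "timepoint"])["percent"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_single_sample_cell(self):
        md = pd.DataFrame({"line": ["TOL"], "timepoint": ["d4"]})
        labels = pd.DataFrame({"dominant_es": [2]})
        comp = composition_by_group(labels, md)
        assert comp.percent.iloc[0] == 100.0


class TestDiversity:
    def test_uniform_maximal(self):
        out = loading_diversity(np.full((1, 8), 0.125))
        assert out.H_prime.iloc[0] == pytest.approx(np.log(8))
        assert out.evenness.iloc[0] == pytest.approx(1.0)

    def test_single_loading_zero(self):
        W = np.zeros((1, 5))
        W[0, 2] = 1.0
        out = loading_diversity(W)
        assert out.H_prime.iloc[0] == 0.0
        assert out.evenness.iloc[0] == 0.0

    def test_two_equal_components(self):
        W = np.array([[0.5, 0.5, 0.0, 0.0]])
        out = loading_diversity(W)
        assert out.H_prime.iloc[0] == pytest.approx(np.log(2))

    def test_bounds(self):
        rng = np.random.default_rng(4)
        W = rng.random((50, 6)) + 1e-9
        out = loading_diversity(W)
        assert ((out.H_prime >= 0) & (out.H_prime <= np.log(6) + 1e-12)).all()
        assert ((out.evenness >= 0) & (out.evenness <= 1 + 1e-12)).all()
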