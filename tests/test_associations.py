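import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enterosig.associations import (
    _Design,
    cohens_d,
    fdr_adjust,
    fit_es_model,
    fit_phenotype_model,
    tmm_clr,
)
from enterosig.mixedlm import fit_lmm


class TestTmmClr:
    def test_identical_samples_unit_factors(self):
        W = np.tile([0.4, 0.3, 0.2, 0.1], (6, 1))
        out = tmm_clr(W)
        np.testing.assert_allclose(out.tmm_factors, 1.0, atol=1e-12)

    def test_clr_constant_row_is_zero(self):
        out = tmm_clr(np.tile([1.0, 1.0, 1.0, 1.0], (3, 1)))
        np.testing.assert_allclose(out.clr, 0.0, atol=1e-12)

    def test_clr_closed_form(self):
        W = np.tile([1.0, np.e**2, 1.0, 1.0], (3, 1))
        out = tmm_clr(W)
        np.testing.assert_allclose(out.clr[0], [-0.5, 1.5, -0.5, -0.5], atol=1e-9)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        W = rng.random((30, 5))
        W[rng.random(W.shape) < 0.2] = 0.0
        W[:, 0] += 0.01  # keep positive row sums
        out = tmm_clr(W)
        np.testing.assert_allclose(out.clr.sum(axis=1), 0.0, atol=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            tmm_clr(np.array([[-1.0, 2.0]]))


class TestFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_single_and_all_ones(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_families_independent(self):
        p = [0.01, 0.04, 0.01, 0.04]
        fam = ["a", "a", "b", "b"]
        out = fdr_adjust(p, fam)
        np.testing.assert_allclose(out[:2], out[2:])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=12))
    @settings(max_examples=40, deadline=None)
    def test_monotone_and_dominates_raw(self, p):
        adj = fdr_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1, 2, 3], [2, 1, 3])[0] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        d, lo, hi = cohens_d([1, 2, 3], [3, 4, 5])
        assert d == pytest.approx(-2.0)
        assert lo < d < hi

    def test_unit_sd_construction(self):
        rng = np.random.default_rng(12)
        # large samples with unit variance and unit mean difference
        x = rng.normal(1, 1, 5000)
        y = rng.normal(0, 1, 5000)
        d, lo, hi = cohens_d(x, y)
        assert d == pytest.approx(1.0, abs=0.06)
        assert lo <= d <= hi

    def test_ci_coverage(self):
        rng = np.random.default_rng(8)
        cover = 0
        for _ in range(200):
            x = rng.normal(0.96, 1, 13)
            y = rng.normal(0, 1, 12)
            _, lo, hi = cohens_d(x, y)
            cover += lo <= 0.96 <= hi
        assert cover / 200 >= 0.90

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1, 2])
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])


class TestMixedModel:
    def test_variance_components_match_statsmodels(self, metadata75):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(42)
        an = pd.factorize(metadata75["animal_id"])[0]
        y = rng.normal(0, 1, len(metadata75)) + rng.normal(0, 1, 25)[an]
        res = fit_es_model(y, metadata75)
        df = pd.DataFrame(
            {"y": y, "timepoint": metadata75.timepoint, "line": metadata75.line}
        )
        sm_fit = smf.mixedlm(
            "y ~ C(timepoint)*C(line)", df, groups=metadata75.animal_id
        ).fit(reml=True)
        assert res.fit.sigma_a2 == pytest.approx(sm_fit.cov_re.iloc[0, 0], rel=1e-3)
        assert res.fit.sigma_e2 == pytest.approx(sm_fit.scale, rel=1e-3)

    def test_balanced_design_classical_df(self, metadata75):
        # balanced 25 x 3 design: line df = n_animals - 2, within df = 46
        rng = np.random.default_rng(1)
        an = pd.factorize(metadata75["animal_id"])[0]
        y = rng.normal(0, 1, 75) + rng.normal(0, 1, 25)[an]
        res = fit_es_model(y, metadata75)
        dfs = res.anova.set_index("effect")["df_den"]
        assert dfs["line"] == pytest.approx(23, abs=0.5)
        assert dfs["timepoint"] == pytest.approx(46, abs=0.5)

    def test_no_random_variance_matches_ols(self, metadata75):
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, 75)  # no animal effect at all
        res = fit_es_model(y, metadata75)
        assert res.singular
        X = _Design(metadata75).X
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(res.fit.beta, beta_ols, atol=1e-4)

    def test_planted_time_effect_detected(self, metadata75):
        rng = np.random.default_rng(5)
        an = pd.factorize(metadata75["animal_id"])[0]
        y = rng.normal(0, 1, 75) + rng.normal(0, 1, 25)[an]
        y[(metadata75.timepoint == "d14").to_numpy()] += 3.0
        res = fit_es_model(y, metadata75)
        p = res.anova.set_index("effect").loc["timepoint", "p"]
        assert p < 0.001

    def test_emmeans_reduce_to_cell_means_balanced(self, metadata75):
        rng = np.random.default_rng(6)
        y = rng.normal(0, 1, 75)
        res = fit_es_model(y, metadata75)
        df = metadata75.assign(y=y)
        cells = df.groupby(["line", "timepoint"])["y"].mean()
        for _, row in res.emmeans.iterrows():
            assert row.emmean == pytest.approx(
                cells[(row.line, row.timepoint)], abs=1e-3
            )

    def test_phenotype_beta_recovery(self, metadata75):
        rng = np.random.default_rng(7)
        es = rng.random(75)
        P = 2.0 * es + rng.normal(0, 0.1, 75)
        res = fit_phenotype_model(P, es, metadata75)
        beta = res.fit.beta[res.fit.term_slices["loading"][0]]
        assert beta == pytest.approx(2.0, abs=0.2)

    def test_constant_phenotype_no_rejections(self, metadata75):
        rng = np.random.default_rng(8)
        es = rng.random(75)
        res = fit_phenotype_model(np.ones(75), es, metadata75)
        assert (res.anova["F"] < 1e-6).all()

    def test_contrast_recovers_planted_temporal_shift(self, metadata75):
        rng = np.random.default_rng(9)
        an = pd.factorize(metadata75["animal_id"])[0]
        delta = 2.0
        y = rng.normal(0, 0.5, 75) + rng.normal(0, 0.5, 25)[an]
        mask = ((metadata75.line == "TOL") & (metadata75.timepoint == "d14")).to_numpy()
        y[mask] += delta
        res = fit_es_model(y, metadata75)
        c = res.contrasts.set_index("contrast").loc["d4-d14 @ TOL"]
        assert abs((-c.estimate) - delta) < 2 * c.SE + 0.2
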