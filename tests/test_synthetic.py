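import numpy as np
import pandas as pd
import pytest

from enterosig.matrices import AbundanceMatrix
from enterosig.synthetic import (
    derive_ko_matrix,
    generate_phenotypes,
    make_ko_map,
    make_metadata,
    plant_signatures,
    sample_counts,
)


class TestMetadata:
    def test_study_design_dimensions(self):
        md = make_metadata(13, 12, ("d4", "d8", "d14"), drop=1, seed=0)
        assert len(md) == 74
        assert md["animal_id"].nunique() == 25
        assert md.groupby("animal_id")["line"].nunique().max() == 1
        assert md.groupby("animal_id").size().max() <= 3

    @pytest.mark.parametrize(
        "n_tol,n_sen,tps,drop,expected",
        [(1, 1, ("d4",), 0, 2), (2, 2, ("d4", "d8"), 1, 7)],
    )
    def test_row_counts(self, n_tol, n_sen, tps, drop, expected):
        md = make_metadata(n_tol, n_sen, tps, drop=drop, seed=7)
        assert len(md) == expected

    def test_seeded_determinism(self):
        a = make_metadata(2, 2, ("d4", "d8"), drop=1, seed=7)
        b = make_metadata(2, 2, ("d4", "d8"), drop=1, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            make_metadata(0, 12)
        with pytest.raises(ValueError):
            make_metadata(1, 1, ("d4",), drop=2)


class TestPlantSignatures:
    def test_simplex_invariants(self, metadata75):
        gt = plant_signatures(metadata75, k_true=4, n_features=200, seed=3)
        assert (gt.W_true >= 0).all() and (gt.H_true >= 0).all()
        np.testing.assert_allclose(gt.W_true.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(gt.H_true.sum(axis=1), 1.0, atol=1e-9)

    def test_large_alpha_gives_uniform_membership(self, metadata75):
        gt = plant_signatures(metadata75, k_true=4, n_features=50, alpha=1e6, seed=1)
        np.testing.assert_allclose(gt.W_true, 0.25, atol=0.01)

    def test_effect_shifts_cell_mean(self, metadata75):
        spec = {("TOL", "d14"): {1: 0.5}}
        gt = plant_signatures(
            metadata75, k_true=4, n_features=50, effect_spec=spec, seed=2
        )
        tol_d14 = (metadata75["line"] == "TOL") & (metadata75["timepoint"] == "d14")
        tol_d4 = (metadata75["line"] == "TOL") & (metadata75["timepoint"] == "d4")
        assert gt.W_true[tol_d14.to_numpy(), 1].mean() > gt.W_true[tol_d4.to_numpy(), 1].mean()

    def test_h_sparsity_matches_target(self, metadata75):
        gt = plant_signatures(
            metadata75, k_true=4, n_features=300, h_sparsity=0.9, seed=4
        )
        zero_frac = (gt.H_true == 0).mean()
        assert abs(zero_frac - 0.9) < 0.05

    def test_unknown_signature_in_effect_spec(self, metadata75):
        with pytest.raises(ValueError, match="unknown signature"):
            plant_signatures(
                metadata75, k_true=3, n_features=50,
                effect_spec={("TOL", "d4"): {7: 0.1}}, seed=0,
            )


class TestSampleCounts:
    def test_rows_sum_to_depth(self, metadata75):
        gt = plant_signatures(metadata75, k_true=3, n_features=80, seed=0)
        m = sample_counts(gt, metadata75, depth=5000, seed=1)
        np.testing.assert_array_equal(m.values.sum(axis=1), 5000)

    def test_large_depth_recovers_proportions(self, metadata75):
        gt = plant_signatures(metadata75, k_true=3, n_features=80, seed=0)
        m = sample_counts(gt, metadata75, depth=1_000_000, seed=1)
        P = gt.W_true @ gt.H_true
        assert np.max(np.abs(m.values / 1e6 - P)) < 1e-2

    def test_depth_one_single_nonzero(self, metadata75):
        gt = plant_signatures(metadata75, k_true=2, n_features=40, seed=0)
        m = sample_counts(gt, metadata75, depth=1, seed=2)
        assert ((m.values > 0).sum(axis=1) == 1).all()

    def test_seeded_reproducibility(self, metadata75):
        gt = plant_signatures(metadata75, k_true=3, n_features=60, seed=0)
        a = sample_counts(gt, metadata75, depth=1000, seed=9)
        b = sample_counts(gt, metadata75, depth=1000, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_overdispersion_inflates_variance(self, metadata75):
        gt = plant_signatures(metadata75, k_true=3, n_features=60, seed=0)
        tight = sample_counts(gt, metadata75, depth=10_000, seed=3)
        loose = sample_counts(gt, metadata75, depth=10_000, overdispersion=0.05, seed=3)
        P = gt.W_true @ gt.H_true
        assert np.abs(loose.values / 1e4 - P).mean() > np.abs(tight.values / 1e4 - P).mean()


class TestKOMatrix:
    def test_single_mag_aggregation(self):
        m = AbundanceMatrix([[10.0]], ["s1"], ["MAG1"])
        ko = derive_ko_matrix(m, {"MAG1": {"K1", "K2"}})
        assert ko.kind == "KO"
        assert ko.to_frame().loc["s1", "K1"] == 10
        assert ko.to_frame().loc["s1", "K2"] == 10

    def test_additivity(self):
        m = AbundanceMatrix([[3.0, 4.0]], ["s1"], ["MAG1", "MAG2"])
        ko = derive_ko_matrix(m, {"MAG1": {"K1"}, "MAG2": {"K1"}})
        assert ko.to_frame().loc["s1", "K1"] == 7

    def test_full_redundancy_collapses_rank(self, metadata75):
        # every MAG carries the same KO set -> all KO columns proportional
        gt = plant_signatures(metadata75, k_true=3, n_features=20, seed=0)
        mag = sample_counts(gt, metadata75, depth=1000, seed=0)
        shared = {"K1", "K2", "K3"}
        ko = derive_ko_matrix(mag, {m: shared for m in mag.feature_ids})
        from enterosig.prep import tss_normalize

        tss = tss_normalize(ko)
        assert np.linalg.matrix_rank(tss.values) == 1

    def test_empty_map_and_missing_mag(self):
        m = AbundanceMatrix([[1.0]], ["s1"], ["MAG1"])
        with pytest.raises(ValueError):
            derive_ko_matrix(m, {})
        with pytest.raises(ValueError, match="absent"):
            derive_ko_matrix(m, {"MAGX": {"K1"}})

    def test_guild_map_shares_blocks(self):
        mags = [f"MAG{i}" for i in range(20)]
        mapping = make_ko_map(mags, n_kos=500, n_guilds=2, kos_per_mag=50, seed=0)
        assert all(len(v) > 0 for v in mapping.values())


class TestPhenotypes:
    def test_noiseless_linear_map(self, metadata75):
        gt = plant_signatures(metadata75, k_true=3, n_features=50, seed=0)
        ph = generate_phenotypes(
            gt, metadata75, noise_sd=1e-12,
            pheno_beta={"p1": np.array([0.0, 2.0, 0.0])}, seed=0,
        )
        np.testing.assert_allclose(ph["p1"], 2 * gt.W_true[:, 1], atol=1e-9)

    def test_null_beta_uncorrelated(self, metadata75):
        gt = plant_signatures(metadata75, k_true=3, n_features=50, seed=0)
        ph = generate_phenotypes(
            gt, metadata75, noise_sd=1.0,
            pheno_beta={"p1": np.zeros(3)}, seed=1,
        )
        r = np.corrcoef(ph["p1"], gt.W_true[:, 0])[0, 1]
        assert abs(r) < 0.25

    def test_ols_recovers_slope(self, metadata75):
        gt = plant_signatures(metadata75, k_true=3, n_features=50, seed=0)
        ph = generate_phenotypes(
            gt, metadata75, noise_sd=0.1,
            pheno_beta={"p1": np.array([1.0, 0.0, 0.0])}, seed=2,
        )
        x = gt.W_true[:, 0]
        slope = np.polyfit(x, ph["p1"], 1)[0]
        assert abs(slope - 1.0) < 0.15

    def test_invalid_noise(self, metadata75):
        gt = plant_signatures(metadata75, k_true=2, n_features=20, seed=0)
        with pytest.raises(ValueError):
            generate_phenotypes(gt, metadata75, noise_sd=0.0)
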