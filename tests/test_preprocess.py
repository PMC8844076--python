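import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mmtfs
from mmtfs import (
    ConfigurationError,
    apply_minmax,
    apply_normalization,
    apply_zscore,
    fit_minmax,
    fit_normalization,
    fit_zscore,
    normalize_dataset,
    residualize_covariates,
)


class TestMinMax:
    def test_endpoints_and_midpoint(self):
        p = fit_minmax(np.array([0.0, 5.0, 10.0]), eps=1e-8)
        out = apply_minmax(np.array([0.0, 5.0, 10.0]), p)
        assert np.allclose(out, [0.0, 0.5, 1.0], atol=1e-7)

    def test_constant_column_maps_to_zero(self):
        p = fit_minmax(np.array([4.0, 4.0, 4.0]))
        assert np.all(apply_minmax(np.array([4.0, 4.0, 4.0]), p) == 0.0)

    def test_frozen_params_interpolate_unseen_value(self):
        p = fit_minmax(np.array([2.0, 4.0]), eps=1e-8)
        assert apply_minmax(np.array([3.0]), p) == pytest.approx(0.5, abs=1e-7)

    def test_training_output_in_unit_interval(self, rng):
        col = rng.normal(size=50)
        out = apply_minmax(col, fit_minmax(col))
        assert out.min() >= 0.0 and out.max() < 1.0

    @given(st.lists(st.integers(-10**6, 10**6), min_size=3, max_size=30, unique=True))
    @settings(deadline=None, derandomize=True)
    def test_strictly_monotone_on_nonconstant_columns(self, values):
        col = np.array(values, dtype=float)
        out = apply_minmax(col, fit_minmax(col))
        order = np.argsort(col)
        assert np.all(np.diff(out[order]) > 0)

    def test_nonfinite_input_rejected(self):
        with pytest.raises(mmtfs.DataFormatError):
            fit_minmax(np.array([1.0, np.nan]))


class TestZScore:
    def test_two_point_column(self):
        p = fit_zscore(np.array([1.0, 3.0]), eps=1e-8)
        out = apply_zscore(np.array([1.0, 3.0]), p)
        assert np.allclose(out, [-0.7071, 0.7071], atol=1e-3)

    def test_constant_column_maps_to_zero(self):
        p = fit_zscore(np.array([2.0, 2.0, 2.0]))
        assert np.all(apply_zscore(np.array([2.0, 2.0]), p) == 0.0)

    def test_centering_and_unit_sd(self, rng):
        col = rng.normal(3.0, 5.0, size=100)
        out = apply_zscore(col, fit_zscore(col))
        assert abs(out.mean()) < 1e-10
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-6)

    def test_single_value_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_zscore(np.array([1.0]))


class TestDatasetNormalization:
    def test_default_schemes_per_block(self, small_cohort):
        ds, _ = small_cohort
        out, params = normalize_dataset(ds)
        img, snp = out.block("imaging"), out.block("snp")
        assert img.min() >= 0.0 and img.max() < 1.0
        assert np.allclose(snp.mean(axis=0), 0.0, atol=1e-10)
        assert params["imaging"].scheme == "minmax" and params["snp"].scheme == "zscore"
        assert out.feature_names == ds.feature_names and out.modality_blocks == ds.modality_blocks

    def test_missing_scheme_is_config_error(self, small_cohort):
        ds, _ = small_cohort
        with pytest.raises(ConfigurationError, match="snp"):
            normalize_dataset(ds, schemes={"imaging": "minmax"})

    def test_frozen_params_no_clipping(self, small_cohort):
        ds, _ = small_cohort
        train = ds.subset_samples(range(0, ds.N, 2))
        test = ds.subset_samples(range(1, ds.N, 2))
        params = fit_normalization(train)
        out = apply_normalization(test, params)
        img = out.block("imaging")
        assert img.max() > 1.0 or img.min() < 0.0   # some test values escape [0,1)

    def test_all_constant_dataset_maps_to_zero(self, small_cohort):
        ds, _ = small_cohort
        const = ds.with_matrix(np.ones_like(ds.X))
        out, _ = normalize_dataset(const)
        assert np.all(out.X == 0.0)

    def test_refit_on_normalized_data_is_idempotent(self, small_cohort):
        ds, _ = small_cohort
        once, _ = normalize_dataset(ds)
        twice, _ = normalize_dataset(once)
        assert np.allclose(twice.X, once.X, atol=1e-5)

    def test_sample_permutation_equivariance(self, small_cohort, rng):
        ds, _ = small_cohort
        perm = rng.permutation(ds.N)
        out, _ = normalize_dataset(ds)
        out_p, _ = normalize_dataset(ds.subset_samples(perm))
        assert np.allclose(out_p.X, out.X[perm])


class TestResidualization:
    def test_covariate_equal_to_feature_gives_zero(self, small_cohort):
        ds, _ = small_cohort
        out = residualize_covariates(ds, ds.X[:, 0])
        assert np.allclose(out.X[:, 0], 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, small_cohort, rng):
        ds, _ = small_cohort
        C = rng.normal(size=(ds.N, 3))
        out = residualize_covariates(ds, C)
        Cc = C - C.mean(axis=0)
        assert np.max(np.abs(Cc.T @ out.X)) < 1e-8 * ds.N

    def test_intercept_only_centers(self, small_cohort):
        ds, _ = small_cohort
        out = residualize_covariates(ds, np.zeros((ds.N, 0)).reshape(ds.N, 0))
        assert np.allclose(out.X, ds.X - ds.X.mean(axis=0), atol=1e-10)

    def test_uncorrelated_covariate_leaves_feature_intact(self):
        spec = mmtfs.CohortSpec(n_per_class=1000, d_imaging=5, d_snp=5, seed=2)
        ds, _ = mmtfs.generate_cohort(spec)
        rng = np.random.default_rng(9)
        out = residualize_covariates(ds, rng.normal(size=ds.N))
        r = np.corrcoef(out.X[:, 0], ds.X[:, 0])[0, 1]
        assert r > 0.99

    def test_collinear_covariates_named(self, small_cohort):
        ds, _ = small_cohort
        c = np.arange(ds.N, dtype=float)
        with pytest.raises(ConfigurationError, match="age"):
            residualize_covariates(ds, np.column_stack([c, 2 * c]), ["age", "age_again"])
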