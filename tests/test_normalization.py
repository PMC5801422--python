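import numpy as np
import pytest
from scipy.stats import rankdata

from rhythmboot import (
    NormalizationMethod,
    constant_normalize,
    cyclic_loess_normalize,
    inject_array_bias,
    invariant_set_normalize,
    normalize,
    quantile_normalize,
    register_method,
)
from rhythmboot.errors import RegistryError, ValidationError
from rhythmboot.simulate import SyntheticConfig, generate_dataset

ALL_METHODS = ["quantile", "constant", "cyclic_loess", "invariant_set"]


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        out = quantile_normalize(np.array([[1.0, 2.0], [3.0, 4.0]]))
        np.testing.assert_allclose(out, [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_unchanged(self, rng):
        col = rng.normal(size=40)
        m = np.column_stack([col, col, col])
        np.testing.assert_allclose(quantile_normalize(m), m, atol=1e-12)

    def test_columns_share_sorted_values_exactly(self, rng):
        m = rng.normal(size=(100, 5))
        out = quantile_normalize(m)
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_array_equal(np.sort(out[:, j]), ref)

    def test_ties_get_mean_of_spanned_reference(self):
        # column 2 has a 2-way tie spanning reference positions 1 and 2
        m = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 9.0]])
        out = quantile_normalize(m)
        ref = (np.sort(m[:, 0]) + np.sort(m[:, 1])) / 2  # [3, 3.5, 6]
        assert out[0, 1] == out[1, 1] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out[2, 1] == pytest.approx(ref[2])

    def test_rank_structure_determines_output(self, rng):
        m = rng.normal(size=(60, 3))
        out1 = quantile_normalize(m)
        out2 = quantile_normalize(np.exp(m / 3) + m)  # common monotone relabeling
        for j in range(3):
            np.testing.assert_array_equal(
                rankdata(out1[:, j]), rankdata(out2[:, j])
            )

    def test_rank_preserved_within_column(self, rng):
        m = rng.normal(size=(50, 4))
        out = quantile_normalize(m)
        for j in range(4):
            assert np.all(np.diff(out[np.argsort(m[:, j]), j]) >= 0)


class TestConstantNormalize:
    def test_double_mean_column_shifted_minus_one(self):
        base = np.log2(np.array([[100.0], [200.0]]))
        double = np.log2(np.array([[200.0], [400.0]]))
        m = np.hstack([base, double])
        out = constant_normalize(m, baseline=0)
        np.testing.assert_allclose(out[:, 1], m[:, 1] - 1.0)
        np.testing.assert_allclose(out[:, 0], m[:, 0])

    def test_equal_means_unchanged(self):
        m = np.log2(np.array([[100.0, 150.0], [200.0, 150.0]]))
        np.testing.assert_allclose(constant_normalize(m), m, atol=1e-12)

    def test_all_natural_means_equal_baseline(self, rng):
        m = rng.normal(8, 1, size=(50, 6))
        out = constant_normalize(m, baseline=2)
        means = np.exp2(out).mean(axis=0)
        np.testing.assert_allclose(means, means[2], atol=1e-9)

    def test_rank_preserved_within_column(self, rng):
        m = rng.normal(size=(30, 3))
        out = constant_normalize(m)
        for j in range(3):
            np.testing.assert_array_equal(rankdata(out[:, j]), rankdata(m[:, j]))


class TestCyclicLoess:
    def test_identical_columns_unchanged(self, rng):
        col = rng.normal(8, 1, size=60)
        m = np.column_stack([col, col])
        np.testing.assert_allclose(cyclic_loess_normalize(m), m, atol=1e-9)

    def test_constant_offset_removed(self, rng):
        col = rng.normal(8, 1, size=80)
        d = 0.8
        m = np.column_stack([col, col + d])
        out = cyclic_loess_normalize(m, max_cycles=1)
        residual_offset = np.mean(out[:, 1] - out[:, 0])
        assert abs(residual_offset) < 0.05 * d

    def test_intensity_dependent_distortion_reduced(self, rng):
        col = rng.normal(8, 1.5, size=300)
        m = np.column_stack([col, col + 0.5 * np.sin(col)])
        out = cyclic_loess_normalize(m, max_cycles=3)
        before = np.mean(np.abs(m[:, 0] - m[:, 1]))
        after = np.mean(np.abs(out[:, 0] - out[:, 1]))
        assert after <= 0.3 * before

    def test_degenerate_A_range_warns_and_skips(self):
        m = np.full((30, 2), 5.0)
        m[:, 1] = 5.0  # all A identical
        with pytest.warns(UserWarning, match="degenerate"):
            out = cyclic_loess_normalize(m)
        np.testing.assert_allclose(out, m)


class TestInvariantSet:
    def test_identity_when_column_equals_baseline(self, rng):
        col = np.sort(rng.normal(8, 1, size=120))
        m = np.column_stack([col, col])
        out = invariant_set_normalize(m)
        np.testing.assert_allclose(out, m, atol=1e-6)

    def test_constant_shift_recovered(self, rng):
        base = rng.normal(8, 1, size=200)
        m = np.column_stack([base, base + 1.0])
        out = invariant_set_normalize(m)
        interior = (base > np.quantile(base, 0.1)) & (base < np.quantile(base, 0.9))
        np.testing.assert_allclose(out[interior, 1], base[interior], atol=0.05)

    def test_monotone_nonlinear_distortion_undone(self, rng):
        base = rng.normal(8, 1, size=300)
        distorted = 1.2 * base + 0.1 * (base - 8) ** 2
        m = np.column_stack([base, distorted])
        out = invariant_set_normalize(m)
        interior = (base > np.quantile(base, 0.1)) & (base < np.quantile(base, 0.9))
        assert np.mean(np.abs(out[interior, 1] - base[interior])) < 0.1

    def test_tiny_invariant_set_falls_back_to_constant(self, rng):
        # anti-monotone column: ranks fully reversed, invariant set collapses
        base = np.sort(rng.normal(8, 1, size=100))
        m = np.column_stack([base, base[::-1]])
        with pytest.warns(UserWarning, match="constant"):
            out = invariant_set_normalize(m, rank_tol=0.001)
        np.testing.assert_allclose(
            np.exp2(out[:, 1]).mean(), np.exp2(base).mean(), rtol=1e-9
        )


class TestNormalizeDispatch:
    def test_none_is_identity(self, small_dataset):
        ds, _ = small_dataset
        out = normalize(ds, "none")
        np.testing.assert_array_equal(out.intensities, ds.intensities)

    def test_unknown_method_rejected(self):
        with pytest.raises(RegistryError):
            NormalizationMethod("vsn")

    def test_metadata_preserved(self, small_dataset):
        ds, _ = small_dataset
        out = normalize(ds, "quantile")
        assert out.gene_ids == ds.gene_ids
        assert out.intensities.shape == ds.intensities.shape
        np.testing.assert_array_equal(out.time_points, ds.time_points)

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_near_identity_on_bias_free_data(self, method):
        # without technical bias the only between-array differences are
        # finite-sample ones, which shrink with the number of probes; the
        # pairwise loess method runs on a smaller design to stay fast
        if method == "cyclic_loess":
            cfg = SyntheticConfig(G=150, P=4, T=8, seed=11)
        else:
            cfg = SyntheticConfig(G=2000, P=8, T=48, seed=17)
        ds, _ = generate_dataset(cfg)
        out = normalize(ds, method)
        assert np.mean(np.abs(out.intensities - ds.intensities)) < 0.05

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_planted_offsets_reduced(self, method):
        ds, _ = generate_dataset(SyntheticConfig(G=60, P=4, T=8, seed=21))
        biased = inject_array_bias(ds, "offset", 0.5, seed=3)
        out = normalize(biased, method)

        def spread(d):
            col_means = d.as_matrix().mean(axis=0)
            return np.median(np.abs(col_means - np.median(col_means)))

        assert spread(out) <= spread(biased)

    def test_plugin_registration(self, small_dataset):
        ds, _ = small_dataset
        register_method("shift_one", lambda m: m + 1.0)
        out = normalize(ds, "shift_one")
        np.testing.assert_allclose(out.intensities, ds.intensities + 1.0)

    def test_log_scale_required(self, small_dataset):
        ds, _ = small_dataset
        natural = ds.with_intensities(np.exp2(ds.intensities))
        natural.is_log_scale = False
        with pytest.raises(ValidationError):
            normalize(natural, "quantile")
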