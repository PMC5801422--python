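import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rhythmboot import (
    compute_mse,
    fit_all_genes,
    fit_median_polish,
    median_polish_roundtrip_fixture,
    summarize_expression,
)
from rhythmboot.errors import DegreesOfFreedomError, ValidationError
from rhythmboot.simulate import SyntheticConfig, generate_dataset, noise_free

from ._oracles import median_polish_oracle

finite_matrices = arrays(
    float,
    st.tuples(st.integers(2, 6), st.integers(2, 8)),
    elements=st.floats(-50, 50, allow_nan=False),
)


def assert_reconstruction(fit, matrix, tol=1e-9):
    np.testing.assert_allclose(fit.reconstruct(), matrix, atol=tol)
    assert abs(np.median(fit.probe_effects)) < tol
    assert abs(np.median(fit.array_effects)) < tol


class TestFitMedianPolish:
    def test_exact_additive_decomposition(self):
        r = np.array([-1.0, 1.0])
        c = np.array([-2.0, 0.0, 2.0])
        m = 10.0 + r[:, None] + c[None, :]
        fit = fit_median_polish(m)
        assert fit.overall == pytest.approx(10.0)
        np.testing.assert_allclose(fit.probe_effects, r, atol=1e-12)
        np.testing.assert_allclose(fit.array_effects, c, atol=1e-12)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)
        assert fit.converged and fit.n_iterations <= 2

    def test_constant_matrix(self):
        fit = fit_median_polish(np.full((3, 4), 5.0))
        assert fit.overall == pytest.approx(5.0)
        np.testing.assert_allclose(fit.probe_effects, 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.array_effects, 0.0, atol=1e-12)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_single_outlier_absorbed_in_residual(self):
        r = np.array([0.0, 1.0, 2.0])
        c = np.array([0.0, 3.0, 6.0])
        m = 1.0 + r[:, None] + c[None, :]
        m[1, 1] += 10.0
        fit = fit_median_polish(m)
        # effects match the additive part; the outlier lands in its residual
        o, row, col, resid = median_polish_oracle(m.tolist())
        assert fit.overall == pytest.approx(o, abs=1e-9)
        np.testing.assert_allclose(fit.probe_effects, row, atol=1e-9)
        np.testing.assert_allclose(fit.array_effects, col, atol=1e-9)
        np.testing.assert_allclose(fit.residuals, resid, atol=1e-9)
        assert fit.residuals[1, 1] == pytest.approx(10.0, abs=1e-9)

    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(50):
            m = rng.normal(size=(5, 8))
            fit = fit_median_polish(m)
            o, row, col, resid = median_polish_oracle(m.tolist())
            assert fit.overall == pytest.approx(o, abs=1e-9)
            np.testing.assert_allclose(fit.probe_effects, row, atol=1e-9)
            np.testing.assert_allclose(fit.array_effects, col, atol=1e-9)
            np.testing.assert_allclose(fit.residuals, resid, atol=1e-9)

    def test_nonfinite_input_rejected(self):
        m = np.ones((2, 3))
        m[0, 1] = np.inf
        with pytest.raises(ValidationError):
            fit_median_polish(m)

    @given(finite_matrices)
    def test_reconstruction_and_centering_invariants(self, m):
        assert_reconstruction(fit_median_polish(m), m)

    @given(finite_matrices, st.randoms(use_true_random=False))
    def test_permutation_equivariance(self, m, rand):
        P, T = m.shape
        rp = list(range(P))
        ct = list(range(T))
        rand.shuffle(rp)
        rand.shuffle(ct)
        fit = fit_median_polish(m)
        permuted = fit_median_polish(m[np.ix_(rp, ct)])
        assert permuted.overall == pytest.approx(fit.overall, abs=1e-9)
        np.testing.assert_allclose(
            permuted.probe_effects, fit.probe_effects[rp], atol=1e-9
        )
        np.testing.assert_allclose(
            permuted.array_effects, fit.array_effects[ct], atol=1e-9
        )

    def test_corruption_of_one_cell_bounded(self, rng):
        r = rng.normal(size=5)
        c = rng.normal(size=5)
        base = 3.0 + r[:, None] + c[None, :]
        clean = fit_median_polish(base)
        for corruption in (1.0, 10.0, 1e4):
            m = base.copy()
            m[2, 3] += corruption
            fit = fit_median_polish(m)
            d_row = np.max(np.abs(fit.probe_effects - clean.probe_effects))
            d_col = np.max(np.abs(fit.array_effects - clean.array_effects))
            assert max(d_row, d_col) < corruption / 2
            assert fit.residuals[2, 3] == pytest.approx(corruption, rel=0.5)


class TestComputeMse:
    def test_zero_residuals(self):
        fit = fit_median_polish(np.full((2, 2), 1.0))
        assert compute_mse(fit) == 0.0

    def test_two_by_two_arithmetic(self):
        fit = fit_median_polish(np.zeros((2, 2)))
        fit.residuals = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert compute_mse(fit) == pytest.approx(4.0)

    def test_matches_brute_force(self, rng):
        m = rng.normal(size=(5, 6))
        fit = fit_median_polish(m)
        expected = float((fit.residuals**2).sum()) / (4 * 5)
        assert compute_mse(fit) == pytest.approx(expected, abs=1e-12)
        assert fit.sigma2 == pytest.approx(expected, abs=1e-12)

    def test_single_probe_rejected(self):
        fit = fit_median_polish(np.ones((1, 4)))
        with pytest.raises(DegreesOfFreedomError):
            compute_mse(fit)


class TestFitAllGenes:
    def test_matches_single_gene_fit(self, small_dataset):
        ds, _ = small_dataset
        fits = fit_all_genes(ds)
        assert len(fits) == ds.n_genes
        single = fit_median_polish(ds.intensities[0])
        assert fits.fits[0].overall == pytest.approx(single.overall)
        np.testing.assert_allclose(fits.fits[0].residuals, single.residuals)

    def test_gene_order_independence(self, small_dataset):
        ds, _ = small_dataset
        fits = fit_all_genes(ds)
        perm = np.arange(ds.n_genes)[::-1]
        shuffled = ds.with_intensities(ds.intensities[perm])
        shuffled.gene_ids = [ds.gene_ids[i] for i in perm]
        fits2 = fit_all_genes(shuffled)
        for i, j in enumerate(perm):
            assert fits2.fits[i].overall == pytest.approx(fits.fits[j].overall)

    def test_noise_free_recovery_of_planted_effects(self):
        cfg = noise_free(SyntheticConfig(G=10, P=5, T=16, seed=5))
        ds, fixture = median_polish_roundtrip_fixture(cfg)
        fits = fit_all_genes(ds)
        for got, expected in zip(fits.fits, fixture.fits):
            assert got.overall == pytest.approx(expected.overall, abs=1e-9)
            np.testing.assert_allclose(
                got.probe_effects, expected.probe_effects, atol=1e-9
            )
            np.testing.assert_allclose(
                got.array_effects, expected.array_effects, atol=1e-9
            )
            np.testing.assert_allclose(got.residuals, 0.0, atol=1e-9)
            assert got.sigma2 == pytest.approx(0.0, abs=1e-18)


class TestSummarizeExpression:
    def test_single_probe_passthrough(self):
        cfg = noise_free(SyntheticConfig(G=4, P=1, T=12, seed=2, probe_effect_sd=0.0))
        ds, _ = generate_dataset(cfg)
        expr = summarize_expression(ds)
        np.testing.assert_allclose(expr.values, ds.intensities[:, 0, :], atol=1e-9)

    def test_probe_shifts_do_not_change_profile_shape(self, rng):
        from rhythmboot import ProbeLevelDataset

        series = rng.normal(size=24)
        shifts = np.array([-1.0, 0.5, 2.0])
        arr = (series[None, :] + shifts[:, None])[None, :, :]
        ds = ProbeLevelDataset(arr, ["g"], np.arange(24), True)
        expr = summarize_expression(ds)
        # expression equals the common series up to one additive constant
        diff = expr.values[0] - series
        np.testing.assert_allclose(diff, diff[0], atol=1e-9)

    def test_recovers_planted_temporal_profile(self):
        cfg = SyntheticConfig(
            G=12, P=6, T=24, fraction_rhythmic=1.0, noise_sd_range=(0.1, 0.1), seed=9
        )
        ds, truth = generate_dataset(cfg)
        expr = summarize_expression(ds)
        # independent oracle: center each probe's series, take per-time medians
        for g in range(ds.n_genes):
            mat = ds.intensities[g]
            centered = mat - np.median(mat, axis=1, keepdims=True)
            oracle = np.median(centered, axis=0)
            got = expr.values[g] - expr.values[g].mean()
            assert np.corrcoef(got, oracle)[0, 1] > 0.99
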