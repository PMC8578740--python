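"""Whitening, FastICA runs, robust decomposition, dimension selection."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from modulon import (
    IcaDecomposition,
    PipelineConfig,
    RobustICA,
    center_to_reference,
    fastica_run,
    generate_compendium,
    reconstruction_error,
    robust_decompose,
    select_dimension,
    whiten,
)


def _matched_abs_corr(M: np.ndarray, M_true: np.ndarray) -> np.ndarray:
    """|Pearson r| of the optimal one-to-one matching, one value per true column."""

    def norm(A):
        A = A - A.mean(axis=0, keepdims=True)
        return A / np.linalg.norm(A, axis=0, keepdims=True)

    C = np.abs(norm(M_true).T @ norm(M))
    ri, ci = linear_sum_assignment(-C)
    return C[ri, ci]


class TestWhiten:
    def test_covariance_identity_and_reconstruction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(300, 12)) @ rng.normal(size=(12, 12))
        Z, dewhiten = whiten(X, 8)
        cov = Z @ Z.T / X.shape[0]
        assert np.allclose(cov, np.eye(8), atol=1e-8)
        # at full rank the dewhitening reproduces the row-centered matrix
        Zf, Df = whiten(X, 11)
        Xc = X - X.mean(axis=1, keepdims=True)
        assert np.allclose((Df @ Zf).T, Xc, atol=1e-8)

    def test_already_whitened_data_stays_white(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(500, 9))
        Z1, _ = whiten(X, 6)
        Z2, _ = whiten(Z1.T, 5)  # row-centering costs one degree of freedom
        assert np.allclose(Z2 @ Z2.T / Z2.shape[1], np.eye(5), atol=1e-8)

    def test_anisotropic_directions_equalized(self):
        # data whose two dominant sample-space directions have variances 4 and 1:
        # whitening must rescale them by 1/2 and 1 so both come out unit-variance
        rng = np.random.default_rng(5)
        basis = np.linalg.qr(rng.normal(size=(10, 2)))[0]  # orthonormal 10x2
        scores = rng.normal(size=(3000, 2)) * np.array([2.0, 1.0])
        X = scores @ basis.T + rng.normal(0, 1e-3, size=(3000, 10))
        Z, _ = whiten(X, 2)
        assert np.allclose(Z @ Z.T / X.shape[0], np.eye(2), atol=1e-8)

    def test_dimension_above_rank_raises_with_achievable_rank(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 10))
        with pytest.raises(ValueError, match="rank"):
            whiten(X, 10)  # row-centering caps rank at n_samples - 1

    def test_rank_deficient_data_names_rank(self):
        rng = np.random.default_rng(7)
        low = rng.normal(size=(60, 3)) @ rng.normal(size=(3, 12))
        with pytest.raises(ValueError, match="numerical rank"):
            whiten(low, 8)


class TestFasticaRun:
    def test_recovers_two_uniform_sources(self):
        rng = np.random.default_rng(12)
        S = rng.uniform(-1, 1, size=(1000, 2))  # independent non-Gaussian sources
        A_mix = rng.normal(size=(2, 5))
        X = S @ A_mix  # 1000 "genes" x 5 "samples"
        Z, _ = whiten(X, 2)
        cfg = PipelineConfig(n_runs=1, random_seed=0)
        W = fastica_run(Z, seed=99, config=cfg)
        G = Z.T @ W.T / np.sqrt(X.shape[0])
        r = _matched_abs_corr(G, S)
        assert np.all(r >= 0.99)

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(400, 8)) * rng.uniform(0.5, 2, size=(400, 1))
        Z, _ = whiten(X, 5)
        cfg = PipelineConfig(n_runs=1, random_seed=0)
        W1 = fastica_run(Z, seed=7, config=cfg)
        W2 = fastica_run(Z, seed=7, config=cfg)
        assert np.array_equal(W1, W2)

    def test_components_unit_norm(self):
        rng = np.random.default_rng(14)
        X = rng.standard_t(3, size=(600, 10))
        Z, _ = whiten(X, 6)
        W = fastica_run(Z, seed=3, config=PipelineConfig(n_runs=1))
        assert np.allclose(np.linalg.norm(W, axis=1), 1.0, atol=1e-8)


@pytest.fixture(scope="module")
def planted():
    comp, meta, trn, truth = generate_compendium(n_modules=5, seed=21, noise_sd=0.0)
    centered = center_to_reference(comp, meta)
    return centered, truth


class TestRobustDecompose:
    def test_noise_free_planted_modules_recovered(self, planted):
        centered, truth = planted
        cfg = PipelineConfig(n_runs=6, random_seed=2)
        dec = robust_decompose(centered, 5, cfg)
        assert dec.n_components == 5
        r = _matched_abs_corr(dec.M.to_numpy(), truth.M_true.to_numpy())
        assert np.all(r >= 0.99)

    def test_m_columns_unit_norm_and_sign_oriented(self, planted):
        centered, _ = planted
        dec = robust_decompose(centered, 5, PipelineConfig(n_runs=4, random_seed=5))
        M = dec.M.to_numpy()
        assert np.allclose(np.linalg.norm(M, axis=0), 1.0)
        peak = M[np.argmax(np.abs(M), axis=0), np.arange(M.shape[1])]
        assert np.all(peak > 0)

    def test_a_is_least_squares_optimum(self, planted):
        centered, _ = planted
        dec = robust_decompose(centered, 5, PipelineConfig(n_runs=4, random_seed=5))
        X = centered.values
        M, A = dec.M.to_numpy(), dec.A.to_numpy()
        base = np.linalg.norm(X - M @ A)
        rng = np.random.default_rng(0)
        for _ in range(20):
            i = rng.integers(A.shape[0])
            j = rng.integers(A.shape[1])
            for eps in (1e-3, -1e-3):
                A2 = A.copy()
                A2[i, j] += eps
                assert np.linalg.norm(X - M @ A2) >= base
    def test_determinism_bit_identical(self, planted):
        centered, _ = planted
        cfg = PipelineConfig(n_runs=5, random_seed=42)
        d1 = robust_decompose(centered, 5, cfg)
        d2 = robust_decompose(centered, 5, cfg)
        assert d1.M.equals(d2.M) and d1.A.equals(d2.A)
        assert d1.robustness.equals(d2.robustness)

    def test_single_run_every_component_robust(self, planted):
        centered, _ = planted
        dec = robust_decompose(centered, 5, PipelineConfig(n_runs=1, random_seed=9))
        assert dec.n_components == 5
        assert (dec.robustness == 1).all()

    def test_pure_noise_yields_fewer_robust_components(self):
        rng = np.random.default_rng(30)
        X = pd.DataFrame(rng.normal(size=(400, 24)))
        cfg = PipelineConfig(n_runs=8, random_seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # empty decomposition is a legal outcome
            dec = robust_decompose(X, 10, cfg)
        assert dec.n_components < 10
        # reconstruction contract still holds for whatever is returned
        err = reconstruction_error(X, dec)
        assert 0.0 <= err <= 1.0

    def test_reconstruction_error_monotone_in_components(self, planted):
        centered, _ = planted
        cfg = PipelineConfig(n_runs=4, random_seed=5)
        dec = robust_decompose(centered, 5, cfg)
        X = centered.values
        errors = []
        for k in range(1, dec.n_components + 1):
            M = dec.M.iloc[:, :k]
            A = np.linalg.lstsq(M.to_numpy(), X, rcond=None)[0]
            sub = IcaDecomposition(
                M=M, A=pd.DataFrame(A, index=M.columns, columns=dec.A.columns),
                robustness=dec.robustness.iloc[:k], n_runs=dec.n_runs,
                dimension=dec.dimension,
            )
            errors.append(reconstruction_error(centered, sub))
        assert all(e1 >= e2 - 1e-12 for e1, e2 in zip(errors, errors[1:]))


class TestRobustICAEstimator:
    def test_sklearn_api(self):
        comp, meta, _, truth = generate_compendium(
            n_genes=500, n_modules=3, seed=8, noise_sd=0.0
        )
        centered = center_to_reference(comp, meta)
        est = RobustICA(n_components=3, n_runs=4, random_state=0)
        params = est.get_params()
        assert params["n_runs"] == 4
        est.set_params(n_runs=5)
        est.fit(centered.values)
        assert est.M_.shape == (500, est.n_components_)
        A = est.transform(centered.values)
        assert A.shape == (est.n_components_, 36)
        recon = est.inverse_transform(A)
        assert recon.shape == centered.values.shape


class TestReconstructionError:
    def test_exact_factorization_is_zero(self):
        M = pd.DataFrame([[1.0], [0.0]], columns=["c1"])
        A = pd.DataFrame([[2.0, 3.0]], index=["c1"])
        dec = IcaDecomposition(M=M, A=A, robustness=pd.Series([1], index=["c1"]),
                               n_runs=1, dimension=1)
        X = M.to_numpy() @ A.to_numpy()
        assert reconstruction_error(X, dec) == 0.0

    def test_empty_decomposition_is_one(self):
        dec = IcaDecomposition(
            M=pd.DataFrame(index=[0, 1]), A=pd.DataFrame(columns=[0, 1]),
            robustness=pd.Series(dtype=int), n_runs=1, dimension=1,
        )
        assert reconstruction_error(np.eye(2), dec) == 1.0

    def test_worked_two_by_two_case(self):
        # X = I2, reconstruction [[1,0],[0,0]]: error = 1/sqrt(2)
        M = pd.DataFrame([[1.0], [0.0]], columns=["c1"])
        A = pd.DataFrame([[1.0, 0.0]], index=["c1"])
        dec = IcaDecomposition(M=M, A=A, robustness=pd.Series([1], index=["c1"]),
                               n_runs=1, dimension=1)
        assert reconstruction_error(np.eye(2), dec) == pytest.approx(1 / np.sqrt(2))

    def test_zero_matrix_rejected(self):
        dec = IcaDecomposition(
            M=pd.DataFrame(index=[0, 1]), A=pd.DataFrame(columns=[0, 1]),
            robustness=pd.Series(dtype=int), n_runs=1, dimension=1,
        )
        with pytest.raises(ValueError, match="zero"):
            reconstruction_error(np.zeros((2, 2)), dec)


class TestSelectDimension:
    def test_planted_five_modules_grid_selects_five(self):
        comp, meta, _, _ = generate_compendium(n_modules=5, seed=33, noise_sd=0.0)
        centered = center_to_reference(comp, meta)
        cfg = PipelineConfig(n_runs=5, random_seed=3)
        chosen, diagnostics = select_dimension(centered, [3, 5], cfg)
        assert chosen == 5
        counts = dict(zip(diagnostics["dimension"], diagnostics["n_robust_components"]))
        assert counts[5] == 5 and counts[3] <= 3

    def test_singleton_grid_returned(self):
        comp, meta, _, _ = generate_compendium(
            n_genes=500, n_modules=4, seed=34, noise_sd=0.0
        )
        centered = center_to_reference(comp, meta)
        chosen, _ = select_dimension(
            centered, [4], PipelineConfig(n_runs=3, random_seed=1)
        )
        assert chosen == 4

    def test_empty_grid_rejected(self, small_compendium, small_metadata):
        centered = center_to_reference(small_compendium, small_metadata)
        with pytest.raises(ValueError, match="non-empty"):
            select_dimension(centered, [], PipelineConfig(n_runs=2))
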