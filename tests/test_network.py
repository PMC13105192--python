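"""Delayed MVAR operators, Green functions and cross-spectra."""

import numpy as np
import pytest

from connspectra.network import (
    LeadField,
    SpectrumSet,
    StructuralPrior,
    StructuralWeights,
    build_ar_operator,
    check_stability,
    green_function,
    model_sensor_spectra,
    sensor_cross_spectrum,
    source_cross_spectrum,
    source_psd_diag,
    spectral_radius,
    transfer_function,
)
from connspectra.scenes import make_scene
from connspectra.spectral import (
    alpha_psd_matrix,
    default_grid,
    xi_psd_matrix,
)


def random_stable_structure(n, rng, density=0.3):
    C = np.where(rng.uniform(size=(n, n)) < density,
                 rng.uniform(0.1, 1.0, (n, n)), 0.0)
    np.fill_diagonal(C, 0.0)
    rho = spectral_radius(C)
    if rho > 0:
        C *= 0.6 / rho
    D = np.where(C > 0, rng.uniform(0.002, 0.03, (n, n)), 0.0)
    return C, D


class TestArOperator:
    def test_zero_frequency_gives_strengths(self):
        C = np.array([[0, 0.3], [0.5, 0]])
        D = np.array([[0, 0.01], [0.02, 0]])
        assert np.allclose(build_ar_operator(C, D, 0.0), C)

    def test_single_link_quarter_phase(self):
        # 2 pi * 25 Hz * 10 ms = pi/2  ->  pure -i phase
        C = np.array([[0, 0], [0.5, 0]])
        D = np.array([[0, 0], [0.01, 0]])
        A = build_ar_operator(C, D, 25.0)
        assert A[1, 0] == pytest.approx(-0.5j, abs=1e-12)

    def test_magnitude_preserved(self, rng):
        C, D = random_stable_structure(6, rng)
        A = build_ar_operator(C, D, 17.3)
        assert np.allclose(np.abs(A), C)

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError):
            build_ar_operator(np.eye(2), np.zeros((2, 2)), 1.0)


class TestStability:
    def test_empty_network_stable(self, grid):
        ok, rho = check_stability(np.zeros((4, 4)), np.zeros((4, 4)), grid)
        assert ok and rho == 0.0

    def test_overloaded_row_unstable(self, grid):
        C = np.zeros((3, 3))
        C[0, 1] = C[1, 0] = 1.5
        assert spectral_radius(C) >= 1.0  # eigenvalue oracle
        ok, rho = check_stability(C, np.full((3, 3), 0.01) * (C > 0), grid)
        assert not ok and rho >= 1.0

    def test_scaling_shrinks_radius_at_dc(self, rng):
        C, D = random_stable_structure(5, rng)
        r1 = spectral_radius(build_ar_operator(C, D, 0.0))
        r2 = spectral_radius(build_ar_operator(0.5 * C, D, 0.0))
        assert r2 <= r1 + 1e-12


class TestGreenFunction:
    def test_identity_for_decoupled(self):
        assert np.allclose(green_function(np.zeros((3, 3))), np.eye(3))

    def test_neumann_series_for_feedforward_chain(self, rng):
        # nilpotent lower-triangular operator: G = I + A + A^2 + ...
        A = np.tril(rng.uniform(0.1, 0.5, (5, 5)) *
                    np.exp(1j * rng.uniform(0, np.pi, (5, 5))), k=-1)
        G = green_function(A)
        neumann = np.eye(5, dtype=complex)
        term = np.eye(5, dtype=complex)
        for _ in range(5):
            term = term @ A
            neumann += term
        assert np.allclose(G, neumann, atol=1e-12)

    def test_inverse_identity(self, rng):
        C, D = random_stable_structure(8, rng)
        A = build_ar_operator(C, D, 10.0)
        G = green_function(A)
        assert np.allclose(G @ (np.eye(8) - A), np.eye(8), atol=1e-12)

    def test_singularity_reported(self):
        with pytest.raises(np.linalg.LinAlgError):
            green_function(np.eye(2))


class TestCrossSpectra:
    def test_diagonal_transfer(self):
        psd = np.array([1.0, 4.0, 0.0])
        H = transfer_function(np.eye(3, dtype=complex), psd)
        assert np.allclose(H, np.diag(np.sqrt(psd)))
        assert np.all(H[:, 2] == 0)  # inactive column is zero
        S = source_cross_spectrum(H)
        assert np.allclose(S, np.diag(psd))

    def test_negative_psd_rejected(self):
        with pytest.raises(ValueError):
            transfer_function(np.eye(2, dtype=complex), np.array([1.0, -0.1]))

    def test_single_generator_rank_one(self):
        G = np.array([[1, 0], [0.5 - 0.2j, 1]])
        H = transfer_function(G, np.array([2.0, 0.0]))
        S = source_cross_spectrum(H)
        assert np.linalg.matrix_rank(S, tol=1e-12) == 1

    def test_two_node_chain_by_hand(self):
        # node 1 drives node 2 with coupling c e^{-i theta}
        c, theta, s1, s2 = 0.5, 0.7, 2.0, 3.0
        A = np.array([[0, 0], [c * np.exp(-1j * theta), 0]])
        G = green_function(A)
        H = transfer_function(G, np.array([s1, s2]))
        assert H[1, 0] == pytest.approx(c * np.exp(-1j * theta) * np.sqrt(s1))
        S = source_cross_spectrum(H)
        assert S[1, 1].real == pytest.approx(c**2 * s1 + s2)
        d = source_psd_diag(G, np.array([s1, 0.0]), np.array([0.0, s2]))
        assert d[1] == pytest.approx(c**2 * s1 + s2)

    def test_local_limit_recovers_sum(self):
        xi = np.array([1.0, 2.0])
        al = np.array([0.3, 0.0])
        d = source_psd_diag(np.eye(2, dtype=complex), xi, al)
        assert np.allclose(d, xi + al)

    def test_power_identity_random_networks(self, rng):
        """Diagonal of the summed component cross-spectra equals the direct
        network power formula on random stable networks."""
        for _ in range(10):
            n = int(rng.integers(3, 30))
            C, D = random_stable_structure(n, rng)
            w = float(rng.uniform(1, 20))
            G = green_function(build_ar_operator(C, D, w))
            xi = rng.uniform(0, 3, n) * (rng.uniform(size=n) < 0.7)
            al = rng.uniform(0, 3, n) * (rng.uniform(size=n) < 0.5)
            S = (source_cross_spectrum(transfer_function(G, xi))
                 + source_cross_spectrum(transfer_function(G, al)))
            direct = source_psd_diag(G, xi, al)
            assert np.allclose(direct, np.diag(S).real, rtol=1e-10)

    def test_sensor_projection(self, rng):
        S = np.diag([1.0, 2.0, 3.0]).astype(complex)
        K = rng.normal(size=(2, 3))
        Sig = sensor_cross_spectrum(K, S, 0.5)
        assert np.trace(Sig).real == pytest.approx(
            np.trace(K @ S.real @ K.T) + 2 * 0.5)
        assert np.allclose(sensor_cross_spectrum(np.eye(3), S, 0.0), S)
        assert np.allclose(sensor_cross_spectrum(K, np.zeros((3, 3)), 0.7),
                           0.7 * np.eye(2))


class TestForwardModel:
    def test_spectra_hermitian_psd(self, small_scene, grid):
        sset = small_scene.analytic_sensor_spectra(grid)
        assert sset.check_psd()

    def test_decoupling_limit_exact(self, grid):
        """w_C = 0 gives sensor spectra K diag(xi + alpha) K^T + sigma^2 I."""
        scene = make_scene(10, 6, density=0.3, alpha_fraction=0.4, seed=9)
        scene.weights = StructuralWeights(0.0, 1.0)
        sset = scene.analytic_sensor_spectra(grid)
        s = (xi_psd_matrix(grid.omega, scene.field)
             + alpha_psd_matrix(grid.omega, scene.field))
        K = scene.lead.K
        for k in range(grid.n_omega):
            direct = (K * s[k][None, :]) @ K.T \
                + scene.lead.sigma_noise2 * np.eye(6)
            assert np.allclose(sset.spectra[k], direct, atol=1e-14)

    def test_causal_gating(self, grid):
        """Zeroing a generator's PSD removes its contribution everywhere."""
        scene = make_scene(8, 5, density=0.4, alpha_fraction=0.5, seed=11)
        k_gen = int(np.where(scene.field.active_xi)[0][0])
        full = scene.analytic_sensor_spectra(grid).spectra
        scene.field.A_xi[k_gen] = 0.0
        reduced = scene.analytic_sensor_spectra(grid).spectra
        assert np.max(np.abs(full - reduced)) > 1e-8  # it mattered
        # the difference is exactly the generator's rank-one contribution
        from connspectra.network import greens_over_grid
        from connspectra.spectral import psd_xi

        G = greens_over_grid(scene.prior, scene.weights, grid)
        scene.field.A_xi[k_gen] = 1.7  # reinstate with a known amplitude
        scene.field.validate()
        K = scene.lead.K
        for k in [0, 20, 46]:
            col = K @ G[k][:, k_gen]
            contrib = np.outer(col, col.conj()) * psd_xi(
                grid.omega[k], scene.field, k_gen)
            rebuilt = scene.analytic_sensor_spectra(grid).spectra[k]
            assert np.allclose(rebuilt - contrib, reduced[k], atol=1e-10)


class TestSpectrumSet:
    def test_rejects_non_hermitian(self, grid):
        S = np.zeros((grid.n_omega, 2, 2), dtype=complex)
        S[:, 0, 1] = 1.0  # asymmetric
        with pytest.raises(ValueError):
            SpectrumSet(grid, S)

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            StructuralPrior(np.array([[0, 1], [1, 0.0]]),
                            np.zeros((2, 2)))  # missing delays
        with pytest.raises(ValueError):
            StructuralPrior(-np.ones((2, 2)), np.ones((2, 2)))

    def test_lead_field_validation(self):
        with pytest.raises(ValueError):
            LeadField(np.array([[0.0, 0.0], [1.0, 2.0]]))
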