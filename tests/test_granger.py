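"""Spectral Geweke-Granger causality, DAI and permutation inference."""

import numpy as np
import pytest

from connspectra.granger import (
    component_sgc,
    dai,
    pairwise_sgc,
    parametric_pair_sgc,
    permutation_direction_test,
    wilson_factorize,
)
from connspectra.network import StructuralWeights
from connspectra.scenes import make_scene

FS_FACT = 64.0
N_HALF = 129
FREQS = np.linspace(0.0, FS_FACT / 2, N_HALF)


def pair_system(c12, c21, d12, d21, s1, s2):
    """2-node delayed AR system: transfer function and spectrum stacks."""
    H = np.empty((N_HALF, 2, 2), dtype=complex)
    S = np.empty((N_HALF, 2, 2), dtype=complex)
    for k, w in enumerate(FREQS):
        A = np.array([
            [0, c12 * np.exp(-2j * np.pi * w * d12)],
            [c21 * np.exp(-2j * np.pi * w * d21), 0],
        ])
        G = np.linalg.inv(np.eye(2) - A)
        H[k] = G @ np.diag(np.sqrt([s1, s2]))
        S[k] = H[k] @ H[k].conj().T
    return H, S


class TestPairwiseGeweke:
    def test_chain_matches_hand_computation(self):
        """Unidirectional chain: G_{1->2} = ln(1 + c^2 s1 / s2), reverse 0."""
        c, s1, s2 = 0.5, 1.0, 1.0
        H, S = pair_system(0.0, c, 0.0, 2 / FS_FACT, s1, s2)
        g_12, g_21 = pairwise_sgc(S, FREQS)
        assert np.allclose(g_12, np.log(1 + c**2 * s1 / s2), atol=1e-6)
        assert np.max(g_21) < 1e-10

    def test_chain_with_unequal_power(self):
        c, s1, s2 = 0.4, 2.0, 0.5
        H, S = pair_system(0.0, c, 0.0, 3 / FS_FACT, s1, s2)
        g_12, g_21 = pairwise_sgc(S, FREQS)
        assert np.allclose(g_12, np.log(1 + c**2 * s1 / s2), atol=1e-6)

    def test_diagonal_spectrum_no_causality(self):
        S = np.tile(np.diag([2.0, 3.0]).astype(complex), (N_HALF, 1, 1))
        g_12, g_21 = pairwise_sgc(S, FREQS)
        assert np.max(g_12) < 1e-10 and np.max(g_21) < 1e-10

    def test_parametric_and_wilson_routes_agree(self, rng):
        worst = 0.0
        for _ in range(15):
            c12, c21 = rng.uniform(0, 0.6, 2)
            d12, d21 = rng.integers(1, 6, 2) / FS_FACT
            s1, s2 = rng.uniform(0.5, 2, 2)
            H, S = pair_system(c12, c21, d12, d21, s1, s2)
            g12, g21 = pairwise_sgc(S, FREQS)
            p12, p21 = parametric_pair_sgc(H, S)
            worst = max(worst, np.max(np.abs(g12 - p12)),
                        np.max(np.abs(g21 - p21)))
        assert worst < 1e-3

    def test_nonpositive_spectrum_rejected(self):
        S = np.tile(np.diag([1.0, -0.1]).astype(complex), (N_HALF, 1, 1))
        with pytest.raises(ValueError):
            pairwise_sgc(S, FREQS)

    def test_wilson_reconstructs_spectrum(self, rng):
        _, S = pair_system(0.3, 0.2, 2 / FS_FACT, 4 / FS_FACT, 1.0, 1.5)
        H, Sig = wilson_factorize(S)
        rebuilt = H @ Sig[None] @ H.conj().transpose(0, 2, 1)
        assert np.allclose(rebuilt, S, atol=1e-8)


class TestComponentCausality:
    @pytest.fixture(scope="class")
    def scene(self):
        return make_scene(12, 8, density=0.3, alpha_fraction=0.4,
                          xi_fraction=0.4, seed=21)

    def test_decoupled_has_no_causality(self, scene):
        import copy

        sc = copy.deepcopy(scene)
        sc.weights = StructuralWeights(0.0, 1.0)
        out = component_sgc(sc.field, sc.prior, sc.weights,
                            component="alpha", n_half=129, f_nyquist=64.0)
        assert np.all(out["G"] == 0)

    def test_structurally_disconnected_pairs_exactly_zero(self, scene):
        from connspectra.granger import _reachability

        out = component_sgc(scene.field, scene.prior, scene.weights,
                            component="alpha", n_half=129, f_nyquist=64.0)
        R = _reachability(scene.weights.apply(scene.prior)[0])
        assert np.all(out["G"][~R] == 0)
        assert np.all(out["G"] >= 0)

    def test_inactive_source_suppressed(self, scene):
        """Zeroing a generator's component kills its outgoing causality."""
        import copy

        sc = copy.deepcopy(scene)
        src = int(np.where(sc.field.active_alpha)[0][0])
        out_before = component_sgc(sc.field, sc.prior, sc.weights,
                                   component="alpha", n_half=129,
                                   f_nyquist=64.0)
        sc.field.A_alpha[src] = 0.0
        out_after = component_sgc(sc.field, sc.prior, sc.weights,
                                  component="alpha", n_half=129,
                                  f_nyquist=64.0)
        # outgoing influence of the silenced generator collapses
        assert out_after["G"][:, src].max() <= \
            max(1e-6, 0.05 * max(out_before["G"][:, src].max(), 1e-12))

    def test_no_alpha_peak_skips(self, scene):
        import copy

        sc = copy.deepcopy(scene)
        sc.field.A_alpha[:] = 0.0
        out = component_sgc(sc.field, sc.prior, sc.weights, component="alpha")
        assert out["skipped"]

    def test_parcel_aggregation_of_constant_field(self):
        parcels = np.array([0, 0, 1, 1])
        G = np.full((4, 4), 0.7)
        # reuse the aggregation rule: mean over vertex pairs per parcel pair
        n_p = 2
        Gp = np.zeros((n_p, n_p))
        for a in range(n_p):
            for b in range(n_p):
                if a != b:
                    Gp[a, b] = G[np.ix_(parcels == a, parcels == b)].mean()
        assert np.allclose(Gp[0, 1], 0.7) and np.allclose(Gp[1, 0], 0.7)


class TestDai:
    def test_balanced_pair_is_zero(self):
        G = np.array([[0.0, 0.5], [0.5, 0.0]])
        out = dai(G)
        assert out[0, 1] == pytest.approx(0.0)

    def test_unidirectional_saturates(self):
        G = np.array([[0.0, 0.8], [0.0, 0.0]])  # only 1 -> 0
        out = dai(G)
        assert out[0, 1] == pytest.approx(1.0)
        assert out[1, 0] == pytest.approx(-1.0)
        assert np.all(np.abs(out[np.isfinite(out)]) <= 1.0)

    def test_antisymmetric_without_orientation(self, rng):
        G = rng.uniform(0.1, 1.0, (5, 5))
        np.fill_diagonal(G, 0.0)
        out = dai(G)
        m = np.isfinite(out)
        assert np.allclose(out[m], -out.T[m])

    def test_gradient_flip_flips_sign(self, rng):
        G = rng.uniform(0.1, 1.0, (4, 4))
        np.fill_diagonal(G, 0.0)
        grad = rng.normal(size=4)
        a = dai(G, grad)
        b = dai(G, -grad)
        m = np.isfinite(a)
        assert np.allclose(a[m], -b[m])

    def test_dead_pair_masked(self):
        G = np.zeros((2, 2))
        assert np.all(np.isnan(dai(G)))

    def test_negative_causality_rejected(self):
        with pytest.raises(ValueError):
            dai(np.array([[0.0, -1.0], [0.0, 0.0]]))


class TestDirectionPermutation:
    def test_planted_feedforward_detected(self, rng):
        n = 12
        grad = np.arange(n, dtype=float)
        G = rng.uniform(0.05, 0.1, (n, n))
        np.fill_diagonal(G, 0.0)
        ff = grad[:, None] > grad[None, :]  # target above source
        G[ff] += 0.5
        out = permutation_direction_test(G, grad, n_perm=500, seed=1)
        assert out["p_feedforward"] < 0.01
        assert out["p_feedback"] > 0.5

    def test_symmetric_causality_not_significant(self, rng):
        n = 10
        grad = rng.normal(size=n)
        base = rng.uniform(0.1, 1.0, (n, n))
        G = 0.5 * (base + base.T)
        np.fill_diagonal(G, 0.0)
        out = permutation_direction_test(G, grad, n_perm=300, seed=2)
        assert out["p_feedforward"] > 0.05

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_direction_test(np.ones((3, 3)), np.arange(3.0),
                                       n_perm=0)

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError):
            permutation_direction_test(np.zeros((3, 3)), np.arange(3.0),
                                       n_perm=100)
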