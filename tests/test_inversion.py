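"""Whittle likelihood, group-lasso machinery and MAP fitting."""

import numpy as np
import pytest

from connspectra.inversion import (
    FitConfig,
    _ModelContext,
    _random_init,
    field_to_x,
    fit_spectral_params,
    fit_structural_weights,
    group_penalty,
    group_penalty_x,
    laplace_wald,
    negloglik,
    negloglik_x,
    prox_group,
    select_bic,
    x_to_field,
)
from connspectra.network import LeadField, SpectrumSet, StructuralWeights
from connspectra.scenes import TrialEnsemble, make_scene, sample_cross_spectra
from connspectra.spectral import (
    ComponentField,
    alpha_psd_matrix,
    default_grid,
    xi_psd_matrix,
)


@pytest.fixture(scope="module")
def ctx_and_cfg(small_scene, small_ensemble):
    cfg = FitConfig(seed=0)
    ctx = _ModelContext(small_scene.prior, small_scene.weights,
                        small_scene.lead, small_ensemble)
    return ctx, cfg


class TestWhittleLikelihood:
    def test_saturated_value(self, small_scene, grid):
        """When the model equals the data, L = m sum (log det S + n_c)."""
        ens = sample_cross_spectra(small_scene, grid, m=50, seed=0)
        S = ens.spectra.spectra
        m, n_c = 50, small_scene.n_c
        expected = m * sum(
            np.linalg.slogdet(S[k])[1] + n_c for k in range(grid.n_omega)
        )
        # evaluate the Whittle form with Sigma_model := S_hat directly
        total = 0.0
        for k in range(grid.n_omega):
            L = np.linalg.cholesky(S[k])
            total += 2 * np.sum(np.log(np.diag(L).real)) + n_c
        assert m * total == pytest.approx(expected, rel=1e-10)

    def test_data_scaling_linearity(self, ctx_and_cfg, rng):
        """Scaling the data S -> c S adds m (c-1) sum tr(Sigma^-1 S)."""
        ctx, cfg = ctx_and_cfg
        x = _random_init(ctx, cfg, np.random.default_rng(1))
        f1, _ = negloglik_x(ctx, x, cfg, want_grad=False)
        c = 1.7
        S_saved = ctx.S_hat
        trace_term = 0.0
        from connspectra.inversion import _psd_tables

        s_xi, s_al, _ = _psd_tables(x, ctx.omega(), cfg)
        s = s_xi + s_al
        for k in range(ctx.omega().size):
            Kt = ctx.Kt[k]
            Sig = (Kt * s[k]) @ Kt.conj().T + ctx.sigma2 * np.eye(ctx.n_c)
            trace_term += np.real(np.trace(np.linalg.solve(Sig, ctx.S_hat[k])))
        ctx.S_hat = c * S_saved
        f2, _ = negloglik_x(ctx, x, cfg, want_grad=False)
        ctx.S_hat = S_saved
        assert f2 - f1 == pytest.approx(ctx.m * (c - 1) * trace_term, rel=1e-8)

    def test_gradient_matches_finite_differences(self, ctx_and_cfg):
        ctx, cfg = ctx_and_cfg
        x = _random_init(ctx, cfg, np.random.default_rng(3))
        _, g = negloglik_x(ctx, x, cfg)
        for (i, c) in [(0, 0), (2, 2), (4, 6), (7, 3), (10, 5)]:
            h = 1e-5 * max(abs(x[i, c]), 1.0)
            xp, xm = x.copy(), x.copy()
            xp[i, c] += h
            xm[i, c] -= h
            fp, _ = negloglik_x(ctx, xp, cfg, want_grad=False)
            fm, _ = negloglik_x(ctx, xm, cfg, want_grad=False)
            fd = (fp - fm) / (2 * h)
            assert g[i, c] == pytest.approx(fd, rel=1e-5)

    def test_roundtrip_field_coordinates(self, small_scene):
        cfg = FitConfig()
        x = field_to_x(small_scene.field, cfg)
        back = x_to_field(x, cfg)
        assert np.allclose(back.A_xi, small_scene.field.A_xi)
        assert np.allclose(back.F_alpha, small_scene.field.F_alpha)
        assert np.array_equal(back.active_alpha,
                              small_scene.field.active_alpha)


class TestGroupPenalty:
    def test_zero_field(self):
        assert group_penalty(ComponentField.zeros(5), lam=2.0) == 0.0

    def test_single_group_value(self):
        # one xi group with scaled norm 3 under lam 2 -> 2 * sqrt(3) * 3
        x = np.zeros((4, 7))
        x[1, :3] = [3.0, 0.0, 0.0]
        assert group_penalty_x(x, 2.0) == pytest.approx(2.0 * np.sqrt(3) * 3)

    def test_prox_identity_at_zero_penalty(self, rng):
        cfg = FitConfig()
        x = np.abs(rng.normal(size=(5, 7))) * 0.3 + 0.1
        out = prox_group(x, 0.0, cfg)
        # box projection may clip, but with moderate values it is identity
        assert np.allclose(out, x)

    def test_prox_kills_small_groups(self):
        cfg = FitConfig()
        x = np.zeros((2, 7))
        x[0, :3] = 0.1  # ||g|| ~ 0.17 < threshold * sqrt(3)
        out = prox_group(x, 0.5, cfg)
        assert np.all(out[0, :3] == 0)

    def test_prox_shrinks_by_expected_factor(self):
        cfg = FitConfig(bounds_A=(0.0, 1000.0), bounds_B=(0.0, 1000.0),
                        bounds_E=(0.5, 1000.0))
        x = np.zeros((1, 7))
        x[0, :3] = [2.0, 1.0, 2.0]  # ||g|| = 3
        t = 3.0 / (2.0 * np.sqrt(3))  # threshold*w_g = ||g||/2
        out = prox_group(x, t, cfg)
        assert np.allclose(out[0, :3], 0.5 * x[0, :3])


class TestSpectralFit:
    def test_decoupled_identity_leadfield_recovery(self, grid):
        """Noiseless decoupled case reduces to independent curve fits."""
        sc = make_scene(6, 6, density=0.0, alpha_fraction=0.5,
                        xi_fraction=0.5, seed=2, noise_fraction=0.0)
        sc.lead = LeadField(np.eye(6), 0.01)
        sig = sc.analytic_sensor_spectra(grid)
        ens = TrialEnsemble(SpectrumSet(grid, sig.spectra, m=200), 200)
        cfg = FitConfig(n_starts=3, max_iter=900, lam=0.05, seed=0, tol=1e-9)
        res = fit_spectral_params(ens, sc.weights, sc.prior, sc.lead, cfg)
        s_true = (xi_psd_matrix(grid.omega, sc.field)
                  + alpha_psd_matrix(grid.omega, sc.field))
        s_est = (xi_psd_matrix(grid.omega, res.field)
                 + alpha_psd_matrix(grid.omega, res.field))
        active = s_true.sum(axis=0) > 0
        it = np.trapezoid(s_true[:, active], grid.omega, axis=0)
        ie = np.trapezoid(s_est[:, active], grid.omega, axis=0)
        assert np.all(np.abs(ie - it) / it < 0.05)

    def test_matches_direct_curve_fit_oracle(self, grid):
        """Single-vertex noiseless spectrum: penalized fit agrees with an
        independent scipy curve fit of the Lorentzian."""
        from scipy.optimize import curve_fit

        sc = make_scene(2, 2, density=0.0, alpha_fraction=0.0,
                        xi_fraction=1.0, seed=3, noise_fraction=0.0)
        sc.lead = LeadField(np.eye(2), 1e-6)
        sig = sc.analytic_sensor_spectra(grid)
        ens = TrialEnsemble(SpectrumSet(grid, sig.spectra, m=100), 100)
        cfg = FitConfig(n_starts=2, max_iter=1500, lam=1e-3, seed=0, tol=1e-10)
        res = fit_spectral_params(ens, sc.weights, sc.prior, sc.lead, cfg)

        def lorentz(w, A, B, E):
            return A / (1 + B * w**2) ** E

        for i in range(2):
            y = sig.spectra[:, i, i].real
            popt, _ = curve_fit(lorentz, grid.omega, y,
                                p0=[1.0, 1.0, 1.0], maxfev=20000)
            est = lorentz(grid.omega, res.field.A_xi[i], res.field.B_xi[i],
                          res.field.E_xi[i])
            oracle = lorentz(grid.omega, *popt)
            assert np.allclose(est, oracle, rtol=0.05, atol=1e-3)

    def test_objective_trace_monotone_full_grid(self, small_scene,
                                                small_ensemble):
        cfg = FitConfig(n_starts=1, max_iter=80, lam=2.0, seed=0,
                        freq_subsample=1.0)
        res = fit_spectral_params(small_ensemble, small_scene.weights,
                                  small_scene.prior, small_scene.lead, cfg)
        assert np.all(np.diff(res.objective_trace) <= 1e-8)

    def test_best_of_starts_contract(self, small_scene, small_ensemble):
        """More starts can only improve the returned objective."""
        kw = dict(max_iter=60, lam=2.0, seed=0)
        r1 = fit_spectral_params(small_ensemble, small_scene.weights,
                                 small_scene.prior, small_scene.lead,
                                 FitConfig(n_starts=1, **kw))
        r3 = fit_spectral_params(small_ensemble, small_scene.weights,
                                 small_scene.prior, small_scene.lead,
                                 FitConfig(n_starts=3, **kw))
        assert r3.penalized_objective <= r1.penalized_objective + 1e-9

    def test_unstable_weights_rejected(self, small_scene, small_ensemble):
        with pytest.raises(ValueError):
            fit_spectral_params(small_ensemble, StructuralWeights(5.0, 1.0),
                                small_scene.prior, small_scene.lead,
                                FitConfig(n_starts=1))


class TestModelSelection:
    def _result(self, nll, k, lam):
        from connspectra.inversion import FitResult

        cfg = FitConfig(lam=lam)
        return FitResult(
            field=ComponentField.zeros(2), weights=StructuralWeights(0.1),
            objective_trace=np.array([nll]), penalized_objective=nll,
            negloglik=nll, bic=2 * nll + k * np.log(100),
            n_active_params=k, active_xi=np.zeros(2, bool),
            active_alpha=np.zeros(2, bool), converged=True, config=cfg,
        )

    def test_single_candidate(self):
        r = self._result(10.0, 3, 1.0)
        chosen, table = select_bic([r])
        assert chosen is r and len(table) == 1

    def test_tie_prefers_sparser(self):
        a = self._result(10.0, 10, 1.0)
        b = self._result(10.0, 5, 2.0)
        # equal fit: BIC penalty monotone in k
        assert b.bic < a.bic
        chosen, _ = select_bic([a, b])
        assert chosen is b
        assert a.bic - b.bic == pytest.approx(5 * np.log(100))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_bic([])


class TestLaplaceWald:
    @staticmethod
    def _truth_result(scene, cfg):
        """A FitResult sitting exactly at the generating field."""
        from connspectra.inversion import FitResult

        x = field_to_x(scene.field, cfg)
        return FitResult(
            field=scene.field, weights=scene.weights,
            objective_trace=np.zeros(1), penalized_objective=0.0,
            negloglik=0.0, bic=0.0, n_active_params=int(np.abs(x).sum() > 0),
            active_xi=scene.field.active_xi,
            active_alpha=scene.field.active_alpha,
            converged=True, config=cfg, x=x,
        )

    @staticmethod
    def _saturated_ensemble(scene, grid, m):
        sig = scene.analytic_sensor_spectra(grid)
        return TrialEnsemble(SpectrumSet(grid, sig.spectra, m=m), m)

    def test_trial_count_scaling_of_standard_errors(self, grid):
        """Doubling m doubles curvature, shrinking SEs by sqrt(2)."""
        sc = make_scene(5, 5, density=0.0, alpha_fraction=0.4,
                        xi_fraction=0.4, seed=4, noise_fraction=0.01)
        cfg = FitConfig(seed=0)
        res = self._truth_result(sc, cfg)
        out1 = laplace_wald(res, self._saturated_ensemble(sc, grid, 100),
                            sc.prior, sc.lead)
        out2 = laplace_wald(res, self._saturated_ensemble(sc, grid, 200),
                            sc.prior, sc.lead)
        ok = (out1["se"] > 0) & (out2["se"] > 0)
        assert ok.sum() >= 5
        assert np.allclose(out1["se"][ok] / out2["se"][ok], np.sqrt(2),
                           rtol=1e-3)

    def test_sensor_noise_reduces_curvature(self, grid):
        """More sensor noise flattens the likelihood and inflates SEs."""
        sc = make_scene(5, 5, density=0.0, alpha_fraction=0.4,
                        xi_fraction=0.4, seed=4, noise_fraction=0.01)
        cfg = FitConfig(seed=0)
        res = self._truth_result(sc, cfg)
        medians = []
        for extra in [0.0, 0.2, 0.5]:
            lead = LeadField(sc.lead.K, sc.lead.sigma_noise2 + extra)
            noisy = make_scene(5, 5, density=0.0, alpha_fraction=0.4,
                               xi_fraction=0.4, seed=4, noise_fraction=0.01)
            noisy.lead = lead
            ens = self._saturated_ensemble(noisy, grid, 100)
            out = laplace_wald(res, ens, sc.prior, lead)
            medians.append(np.median(out["se"][out["se"] > 0]))
        assert medians[0] < medians[1] < medians[2]

    def test_bh_stepup_rule(self):
        """Step-up rule hand-checked: sorted p (0.01, 0.02, 0.04, 0.8) at
        alpha 0.05 has largest k with p_(k) <= k alpha / n at k = 2, so
        exactly the two smallest p are rejected (0.04 > 3/4 * 0.05)."""
        from statsmodels.stats.multitest import multipletests

        rej, q, _, _ = multipletests(
            np.array([0.01, 0.02, 0.04, 0.8]), alpha=0.05, method="fdr_bh")
        assert list(rej) == [True, True, False, False]


class TestStructuralWeightSearch:
    def test_point_bounds_returned(self, small_scene, small_ensemble):
        cfg = FitConfig(seed=0, w_C_bounds=(0.3, 0.3), w_D_bounds=(1.1, 1.1),
                        bo_n_init=2, bo_budget=2, inner_iter=10)
        w = fit_structural_weights(small_ensemble, small_scene.prior,
                                   small_scene.lead, cfg)
        assert w == pytest.approx((0.3, 1.1))

    def test_decoupled_data_prefers_weak_coupling(self, grid):
        """Data generated without coupling: the search lands at small w_C and
        its objective beats every stronger-coupling candidate probed."""
        sc = make_scene(10, 8, density=0.3, alpha_fraction=0.3, seed=6,
                        w_C=0.0)
        ens = sample_cross_spectra(sc, grid, m=150, seed=7)
        cfg = FitConfig(seed=0, bo_n_init=4, bo_budget=10, inner_iter=30,
                        lam=2.0, w_C_bounds=(1e-3, 0.9))
        from connspectra.inversion import _profile_objective

        w_C, w_D = fit_structural_weights(ens, sc.prior, sc.lead, cfg)
        obj_best = _profile_objective(ens, sc.prior, sc.lead, cfg, w_C, w_D)
        obj_strong = _profile_objective(ens, sc.prior, sc.lead, cfg, 0.8, w_D)
        assert w_C < 0.15
        assert obj_best <= obj_strong
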