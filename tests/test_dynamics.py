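import math

import numpy as np
import pytest

from stdpmem.dynamics import (CueSpec, ModelParams, StorageInputSpec,
                              check_convergence, cue_input,
                              default_initial_state, integrate_retrieval,
                              integrate_storage, phasor_steady_state,
                              random_antisymmetric, storage_input)


def _random_spec(rng, n=3, N=24, omega=1.5):
    mem = rng.standard_normal((n, N))
    mem /= np.linalg.norm(mem, axis=1, keepdims=True)
    return StorageInputSpec(memories=mem,
                            phases=np.pi * np.arange(n) / n, omega=omega)


class TestInputs:
    def test_storage_input_matches_sine_sum(self, rng):
        spec = _random_spec(rng, n=4)
        for t in (0.0, 0.37, 2.0, 11.3):
            expect = sum(math.sin(spec.omega * t - xi) * m
                         for m, xi in zip(spec.memories, spec.phases))
            np.testing.assert_allclose(storage_input(spec, t), expect,
                                       atol=1e-14)

    def test_storage_input_zero_at_sampling_phase(self, rng):
        m = rng.standard_normal(10)
        spec = StorageInputSpec(memories=[m], phases=[0.7], omega=1.5)
        np.testing.assert_allclose(spec(0.7 / 1.5), 0.0, atol=1e-12)

    def test_phases_must_increase(self, rng):
        with pytest.raises(ValueError):
            StorageInputSpec(memories=rng.standard_normal((2, 5)),
                             phases=[0.5, 0.2])

    def test_single_cue_reduces_to_sin_omega_t(self, rng):
        m = rng.standard_normal(8)
        cue = CueSpec.single(m, omega=1.5)
        for t in (0.1, 1.0, 4.4):
            np.testing.assert_allclose(cue_input(cue, t),
                                       math.sin(1.5 * t) * m, atol=1e-14)

    def test_antiphase_components_cancel(self, rng):
        m = rng.standard_normal(8)
        cue = CueSpec(components=[(m, 0.3), (m, 0.3 + math.pi)], omega=1.5)
        for t in np.linspace(0, 10, 23):
            np.testing.assert_allclose(cue_input(cue, t), 0.0, atol=1e-12)

    def test_empty_cue_raises(self):
        with pytest.raises(ValueError):
            CueSpec(components=[])


class TestStorageIntegration:
    def test_free_decay_matches_exponential(self, rng):
        # b = 0, W0 = 0, rho = 0: x(t) = x0 exp(-t) up to O(dt^2) per step
        N = 6
        spec = StorageInputSpec(memories=[np.zeros(N)], phases=[0.0],
                                omega=1.5)
        params = ModelParams(rho=0.0, dt=0.01, T=3.0)
        x0 = rng.standard_normal(N)
        res = integrate_storage(params, spec, x0=x0, mode="dense")
        exact = np.exp(-res.trajectory.times)[:, None] * x0[None, :]
        assert np.max(np.abs(res.trajectory.states - exact)) < 1e-4

    def test_antisymmetry_conserved_on_random_runs(self, rng):
        spec = _random_spec(rng)
        params = ModelParams(T=12.0)
        res = integrate_storage(params, spec, seed=4, mode="dense")
        for W in res.snapshots:
            assert W.antisymmetry_defect() <= 1e-10

    def test_dense_and_factored_modes_agree(self, rng):
        spec = _random_spec(rng, N=30)
        params = ModelParams(T=12.0)
        x0 = default_initial_state(spec, seed=5)
        rd = integrate_storage(params, spec, x0=x0, mode="dense")
        rf = integrate_storage(params, spec, x0=x0, mode="factored")
        np.testing.assert_allclose(rf.trajectory.states,
                                   rd.trajectory.states, atol=1e-10)
        Wd, Wf = rd.snapshots[-1], rf.snapshots[-1]
        assert np.linalg.norm(Wf.to_dense() - Wd.to_dense()) \
            <= 1e-8 * Wd.frob()

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_blowup_reports_first_bad_step(self, rng):
        # a huge learning rate destabilizes the coupled system
        spec = _random_spec(rng, N=10)
        params = ModelParams(rho=500.0, gamma=0.0, T=40.0)
        with pytest.raises(FloatingPointError, match="step"):
            integrate_storage(params, spec, seed=0, mode="dense")

    def test_tau_below_dt_rejected(self, rng):
        spec = _random_spec(rng)
        params = ModelParams(tau=0.05, dt=0.1, T=10.0)
        with pytest.raises(ValueError):
            integrate_storage(params, spec, mode="dense")


class TestRetrievalAndOracle:
    def test_zero_connectivity_closed_form(self, rng):
        # x' = -x + sin(wt) m has steady state (sin wt - w cos wt)/(1+w^2) m
        N, omega = 5, 1.5
        m = rng.standard_normal(N)
        cue = CueSpec.single(m, omega=omega)
        W0 = random_antisymmetric(N, seed=0, scale=0.0)
        traj = integrate_retrieval(W0, cue, dt=0.01, T=20.0, x0=np.zeros(N))
        t = traj.times[-200:]
        expect = ((np.sin(omega * t) - omega * np.cos(omega * t))
                  / (1 + omega ** 2))[:, None] * m[None, :]
        assert np.max(np.abs(traj.states[-200:] - expect)) < 1e-4

    def test_phasor_matches_zero_connectivity_closed_form(self, rng):
        N, omega = 5, 1.5
        m = rng.standard_normal(N)
        cue = CueSpec.single(m, omega=omega)
        sol = phasor_steady_state(random_antisymmetric(N, 0, scale=0.0), cue)
        t = np.linspace(0, 10, 301)
        expect = ((np.sin(omega * t) - omega * np.cos(omega * t))
                  / (1 + omega ** 2))[:, None] * m[None, :]
        np.testing.assert_allclose(sol(t), expect, atol=1e-12)

    def test_phasor_residual_by_numerical_differentiation(self, rng):
        # substitute the phasor orbit into x' + x - W*x - b(t); residual ~ 0
        N = 40
        W = random_antisymmetric(N, seed=3)
        m = rng.standard_normal(N)
        cue = CueSpec.single(m, omega=1.5)
        sol = phasor_steady_state(W, cue)
        h = 1e-6
        t = np.linspace(1.0, 5.0, 50)
        xdot = (sol(t + h) - sol(t - h)) / (2 * h)
        x = sol(t)
        b = np.array([cue(ti) for ti in t])
        resid = xdot + x - x @ W.to_dense().T - b
        assert np.max(np.abs(resid)) < 1e-8 * np.linalg.norm(m)

    @pytest.mark.parametrize("N", [10, 100])
    def test_integrator_converges_to_phasor(self, N, rng):
        W = random_antisymmetric(N, seed=N)
        m = rng.standard_normal(N)
        cue = CueSpec.single(m, omega=1.5)
        traj = integrate_retrieval(W, cue, dt=0.01, T=15.0, seed=2)
        sol = phasor_steady_state(W, cue)
        i0 = traj.index_of(15.0 - 2 * math.pi / 1.5)
        ref = sol(traj.times[i0:])
        err = (np.linalg.norm(traj.states[i0:] - ref)
               / np.linalg.norm(ref))
        assert err < 1e-3

    def test_factored_and_dense_phasor_agree(self, rng):
        from stdpmem.dynamics import FactoredConnectivity
        N = 20
        F = FactoredConnectivity(N)
        p, q = rng.standard_normal((2, N))
        F.add_pair(p, q, 0.7)
        D = random_antisymmetric(N, 0, scale=0.0)
        D.W[:] = F.to_dense()
        m = rng.standard_normal(N)
        cue = CueSpec.single(m, omega=1.5)
        zf = phasor_steady_state(F, cue)(1.234)
        zd = phasor_steady_state(D, cue)(1.234)
        np.testing.assert_allclose(zf, zd, atol=1e-10)


class TestConvergenceCheck:
    def test_constant_snapshots_converged_with_zero_change(self):
        W = random_antisymmetric(8, seed=1)
        rep = check_convergence([W, W.copy()], omega=1.5)
        assert rep.converged and rep.rel_change == 0.0

    def test_pure_decay_never_converges(self, rng):
        # rho = 0 with W0 != 0: W decays as exp(-gamma t); the per-period
        # relative change stays at 1 - exp(-gamma * 2 pi / omega) >> tol
        N = 12
        spec = StorageInputSpec(memories=[np.zeros(N)], phases=[0.0],
                                omega=1.5)
        params = ModelParams(rho=0.0, T=30.0)
        W0 = random_antisymmetric(N, seed=2)
        res = integrate_storage(params, spec, x0=np.zeros(N), W0=W0,
                                mode="dense")
        rep = check_convergence(res.snapshots, omega=1.5,
                                times=res.snapshot_times)
        assert not rep.converged
        # closed form: W(t) = exp(-gamma t) W0, so comparing snapshots a
        # lag delta apart gives relative change exp(gamma delta) - 1
        times = np.asarray(res.snapshot_times)
        target = times[-1] - 2 * math.pi / 1.5
        delta = times[-1] - times[np.argmin(np.abs(times[:-1] - target))]
        expected = math.exp(params.gamma * delta) - 1.0
        assert rep.rel_change == pytest.approx(expected, rel=0.01)

    def test_all_zero_snapshots_flagged(self):
        Z = random_antisymmetric(5, 0, scale=0.0)
        rep = check_convergence([Z, Z.copy()], omega=1.5)
        assert not rep.converged and "zero" in rep.message

    def test_needs_two_snapshots(self):
        with pytest.raises(ValueError):
            check_convergence([random_antisymmetric(4, 0)], omega=1.5)
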