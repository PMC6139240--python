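"""ADMM solver tests.

Oracles: finite-difference stationarity of the augmented Lagrangian at
each block update, random-perturbation optimality for the proximal
blocks, and the POCS solver as an independent reference for the
zero-regularization limit (exercised at depth in the acceptance tests).
"""

from dataclasses import replace

import numpy as np
import pytest

from lrtvg import (
    SolverConfig,
    assemble_spectrum,
    degrade,
    dft3,
    gradient,
    idft3,
    is_conjugate_symmetric,
    make_phantom,
    solve,
)
from lrtvg.phantom_sim import AssembledSpectrum
from lrtvg.solver import (
    augmented_lagrangian,
    objective,
    update_duals,
    update_f,
    update_m,
    update_x,
    update_y,
)


def directional_derivative(fun, h=1e-6):
    return (fun(h) - fun(-h)) / (2 * h)


class TestConfig:
    def test_low_rank_requires_positive_epsilon(self):
        with pytest.raises(ValueError):
            SolverConfig(lambda_lr=0.1, epsilon=0.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(lambda_tv=-1.0)


class TestObjective:
    def test_zero_state_zero_data(self):
        shape = (4, 4, 4)
        data = AssembledSpectrum(
            f0_prime=np.zeros(shape, complex),
            omega=np.ones(shape, bool),
            profile_spectrum=np.ones(shape),
        )
        from lrtvg.solver import _initial_state

        state = _initial_state(data)
        cfg = SolverConfig(lambda_tv=0.1, lambda_lr=0.1, epsilon=0.01)
        assert objective(state, data, np.ones(shape), cfg) == 0.0

    def test_pure_data_term_hand_computed(self):
        # lambda_tv = lambda_lr = eps = 0 on a 2x2x2 instance: the
        # objective is half the squared misfit on Omega, by arithmetic
        shape = (2, 2, 2)
        f0 = np.zeros(shape, complex)
        f0[0, 0, 0] = 3.0
        f0[1, 0, 0] = 1.0
        omega = np.zeros(shape, bool)
        omega[0, 0, 0] = omega[1, 0, 0] = True
        data = AssembledSpectrum(f0, omega, np.ones(shape))
        from lrtvg.solver import _initial_state

        state = _initial_state(data)
        state.f = np.zeros(shape, complex)
        state.f[0, 0, 0] = 1.0  # misfit (3-1) on DC, (1-0) on the other
        cfg = SolverConfig(lambda_tv=0, lambda_lr=0, epsilon=0)
        expected = 0.5 * (2.0 ** 2 + 1.0 ** 2)
        assert objective(state, data, np.ones(shape), cfg) == pytest.approx(expected)

    def test_invariant_to_v_when_eps_zero(self, small_state):
        state, data, sup, _ = small_state
        cfg = SolverConfig(lambda_tv=0.05, lambda_lr=0.0, epsilon=0.0)
        j0 = objective(state, data, sup, cfg)
        state2 = replace(state, v=[vi + 1.0 for vi in state.v])
        assert objective(state2, data, sup, cfg) == pytest.approx(j0, rel=1e-12)


class TestBlockOptimality:
    """Each update is the exact minimizer of the augmented Lagrangian
    over its block (finite-difference / perturbation oracles)."""

    def test_f_update_stationarity(self, small_state, rng):
        state, data, sup, cfg = small_state
        f_new = update_f(state, data, cfg)
        assert is_conjugate_symmetric(f_new, rtol=1e-8)
        base = replace(state, f=f_new)
        for _ in range(5):
            delta = dft3(rng.normal(size=f_new.shape))  # symmetric direction
            delta = delta / np.linalg.norm(delta)

            def lag(h, d=delta):
                return augmented_lagrangian(
                    replace(base, f=f_new + h * d), data, sup, cfg
                )

            assert abs(directional_derivative(lag)) < 1e-6

    def test_f_update_fixed_points(self, phantom16):
        shape = phantom16.shape
        f0 = dft3(phantom16.truth)
        data = AssembledSpectrum(f0, np.ones(shape, bool), np.ones(shape))
        from lrtvg.solver import _initial_state

        cfg = SolverConfig(rho=1.0)
        state = _initial_state(data)  # x = idft3(f0), alpha = 0
        np.testing.assert_allclose(update_f(state, data, cfg), f0, atol=1e-12)
        # on the unmeasured region the update is pure consensus dft3(x)
        omega_partial = np.zeros(shape, bool)
        omega_partial[0, 0, 0] = True
        data2 = AssembledSpectrum(np.where(omega_partial, f0, 0), omega_partial,
                                  np.ones(shape))
        f2 = update_f(state, data2, cfg)
        np.testing.assert_allclose(
            f2[~omega_partial], dft3(state.x)[~omega_partial], atol=1e-12
        )

    def test_x_update_stationarity(self, small_state, rng):
        state, data, sup, cfg = small_state
        x_new = update_x(state, sup, cfg)
        base = replace(state, x=x_new)
        for _ in range(5):
            delta = rng.normal(size=x_new.shape)
            delta /= np.linalg.norm(delta)

            def lag(h, d=delta):
                return augmented_lagrangian(
                    replace(base, x=x_new + h * d), data, sup, cfg
                )

            assert abs(directional_derivative(lag)) < 1e-5

    def test_x_update_constructed_fixed_point(self, phantom16):
        # eps=0, full support, zero duals, y = L idft3(f): x = idft3(f)
        shape = phantom16.shape
        f0 = dft3(phantom16.truth)
        data = AssembledSpectrum(f0, np.ones(shape, bool), np.ones(shape))
        from lrtvg.solver import _initial_state

        cfg = SolverConfig(lambda_tv=0, lambda_lr=0, epsilon=0,
                           cg_tol=1e-13, cg_max_iter=500)
        state = _initial_state(data)
        state.y = gradient(idft3(state.f))
        x = update_x(state, np.ones(shape), cfg)
        np.testing.assert_allclose(x, idft3(state.f), atol=1e-8)

    def test_x_system_is_spd(self, small_state, rng):
        state, data, sup, cfg = small_state
        from lrtvg.solver import _x_system_shape_ops

        a_op, _ = _x_system_shape_ops(1.0 - sup.astype(float), cfg)
        for _ in range(10):
            w = rng.normal(size=int(np.prod(sup.shape)))
            assert w @ a_op.matvec(w) > 0

    def test_y_update_prox_optimality(self, small_state, rng):
        state, data, sup, cfg = small_state
        y_new = update_y(state, cfg)
        base = augmented_lagrangian(replace(state, y=y_new), data, sup, cfg)
        for _ in range(200):
            pert = y_new + 1e-3 * rng.normal(size=y_new.shape)
            assert augmented_lagrangian(
                replace(state, y=pert), data, sup, cfg
            ) >= base - 1e-10

    def test_y_update_limits(self, small_state):
        state, _, _, cfg = small_state
        free = replace(state, z=np.zeros_like(state.z))
        c0 = SolverConfig(lambda_tv=0.0, rho=cfg.rho)
        np.testing.assert_allclose(update_y(free, c0), gradient(state.x), atol=1e-12)
        chuge = SolverConfig(lambda_tv=1e9, rho=cfg.rho)
        assert np.all(update_y(state, chuge) == 0.0)

    def test_m_update_prox_optimality(self, small_state, rng):
        state, data, sup, cfg = small_state
        m_new, _ = update_m(state, cfg)
        base = augmented_lagrangian(replace(state, m=m_new), data, sup, cfg)
        for _ in range(200):
            pert = [mi + 1e-3 * rng.normal(size=mi.shape) for mi in m_new]
            assert augmented_lagrangian(
                replace(state, m=pert), data, sup, cfg
            ) >= base - 1e-10

    def test_m_update_limits(self, small_state):
        state, _, _, cfg = small_state
        c0 = SolverConfig(lambda_lr=0.0, epsilon=cfg.epsilon)
        m0, _ = update_m(state, c0)
        for i in range(3):
            np.testing.assert_allclose(m0[i], state.x + state.v[i], atol=1e-12)
        chuge = SolverConfig(lambda_lr=1e12, epsilon=cfg.epsilon)
        mh, _ = update_m(state, chuge)
        for mi in mh:
            assert np.abs(mi).max() < 1e-10


class TestDuals:
    def test_unchanged_at_exact_consensus(self, small_state):
        state, data, sup, cfg = small_state
        s = replace(
            state,
            x=state.x,
            f=dft3(state.x),
            y=gradient(state.x),
            m=[state.x.copy() for _ in range(3)],
        )
        s.x = s.x * sup  # satisfy the support constraint
        s.f = dft3(s.x)
        s.y = gradient(s.x)
        s.m = [s.x.copy() for _ in range(3)]
        v0 = [vi.copy() for vi in s.v]
        z0, a0, g0 = s.z.copy(), s.alpha.copy(), s.gamma_dual.copy()
        update_duals(s, sup, cfg)
        for vi, vi0 in zip(s.v, v0):
            np.testing.assert_allclose(vi, vi0, atol=1e-10)
        np.testing.assert_allclose(s.z, z0, atol=1e-10)
        np.testing.assert_allclose(s.alpha, a0, atol=1e-10)
        np.testing.assert_allclose(s.gamma_dual, g0, atol=1e-10)

    def test_increments_linear_in_rho(self, small_state):
        state, data, sup, cfg = small_state
        s1 = replace(state, z=state.z.copy(), alpha=state.alpha.copy(),
                     gamma_dual=state.gamma_dual.copy(),
                     v=[v.copy() for v in state.v])
        s2 = replace(state, z=state.z.copy(), alpha=state.alpha.copy(),
                     gamma_dual=state.gamma_dual.copy(),
                     v=[v.copy() for v in state.v])
        update_duals(s1, sup, SolverConfig(rho=1.0))
        update_duals(s2, sup, SolverConfig(rho=2.0))
        np.testing.assert_allclose(s2.z - state.z, 2 * (s1.z - state.z), atol=1e-12)
        np.testing.assert_allclose(
            s2.alpha - state.alpha, 2 * (s1.alpha - state.alpha), atol=1e-12
        )


class TestSolve:
    def test_deterministic(self, noisy_data32):
        p, _, data = noisy_data32
        cfg = SolverConfig(max_iter=10, tol=1e-12)
        a = solve(data, p.support, cfg)
        b = solve(data, p.support, cfg)
        assert np.array_equal(a.volume, b.volume)
        assert a.diagnostics["cost_history"] == b.diagnostics["cost_history"]

    def test_support_enforced_exactly_on_output(self, noisy_data32):
        p, _, data = noisy_data32
        res = solve(data, p.support, SolverConfig(max_iter=15, tol=1e-12))
        assert np.all(res.volume[(1 - p.support).astype(bool)] == 0)

    def test_conjugate_symmetry_preserved(self, noisy_data32):
        p, _, data = noisy_data32
        res = solve(data, p.support, SolverConfig(max_iter=15, tol=1e-12))
        assert is_conjugate_symmetric(res.state.f, rtol=1e-8)

    def test_cost_monotone_from_first_iterate(self, noisy_data32):
        p, _, data = noisy_data32
        res = solve(data, p.support, SolverConfig(max_iter=60, tol=1e-12))
        ch = res.diagnostics["cost_history"]
        assert all(b <= a + 1e-9 * abs(a) for a, b in zip(ch[1:], ch[2:]))

    def test_tvg_is_small_epsilon_limit(self, consistent16):
        """TVG (lambda_lr = eps = 0, slack blocks skipped) agrees with an
        LRTVG run at lambda_lr = 0 and vanishing eps."""
        p, data = consistent16
        kw = dict(lambda_tv=0.01, lambda_lr=0.0, rho=1.0, max_iter=400,
                  tol=1e-10)
        a = solve(data, p.support, SolverConfig(epsilon=0.0, **kw))
        b = solve(data, p.support, SolverConfig(epsilon=1e-6, **kw))
        rel = np.linalg.norm(a.volume - b.volume) / np.linalg.norm(a.volume)
        assert rel < 1e-8

    def test_shape_mismatch_rejected(self, noisy_data32):
        _, _, data = noisy_data32
        with pytest.raises(ValueError):
            solve(data, np.ones((8, 8, 8)), SolverConfig())
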