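import warnings

import numpy as np
import pytest

from mcscale import (
    CrossTerms,
    ObservedData,
    UnitCell,
    bin_shells,
    cross_v,
    factor_products,
    fit_driver,
    generate_hkl,
    ls_gradient,
    ls_hessian,
    ls_residual,
    r_factor,
    solve_shell_alg1,
    solve_shell_alg2,
    solve_shell_alg3,
    solve_shell_alg4,
)
from conftest import random_components


def make_instance(rng, n_refl=200, m=3, k_scale=1.0):
    """Error-free instance: random components, known k, exact observations."""
    f = random_components(rng, n_refl, m)
    k_true = k_scale * rng.uniform(0.2, 1.5, m)
    total = k_true @ f
    obs = ObservedData(amplitude=np.abs(total))
    return f, k_true, obs


class TestCrossV:
    def test_orthogonal_phases(self):
        ct = cross_v(np.array([[1.0 + 0j], [0.0 + 1j]]))
        assert ct.v[0, 0, 1] == pytest.approx(0.0)

    def test_diagonal_is_intensity(self):
        ct = cross_v(np.array([[2.0 + 0j]]))
        assert ct.v[0, 0, 0] == pytest.approx(4.0)

    def test_matches_half_sum_oracle(self, rng):
        f = random_components(rng, 50, 2)
        ct = cross_v(f)
        # oracle: v_nm = (F_n conj(F_m) + conj(F_n) F_m) / 2
        oracle = 0.5 * (f[0] * np.conj(f[1]) + np.conj(f[0]) * f[1])
        assert np.allclose(ct.v[:, 0, 1], oracle.real)
        assert np.allclose(oracle.imag, 0.0)

    def test_symmetry_and_nonnegative_diagonal(self, rng):
        ct = cross_v(random_components(rng, 30, 4))
        assert np.allclose(ct.v, np.swapaxes(ct.v, 1, 2))
        diag = np.einsum("snn->sn", ct.v)
        assert np.all(diag >= 0)

    def test_misaligned_error(self, rng):
        from mcscale import Component

        a = Component(id="a", f=np.ones(5, dtype=complex))
        b = Component(id="b", f=np.ones(6, dtype=complex))
        with pytest.raises(ValueError):
            cross_v([a, b])


class TestResidual:
    def test_zero_at_truth(self, rng):
        f, k_true, obs = make_instance(rng)
        assert ls_residual(k_true, cross_v(f), obs) == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        ct = CrossTerms(v=np.ones((1, 1, 1)))
        obs = ObservedData(amplitude=np.array([2.0]), intensity=np.array([4.0]))
        assert ls_residual(np.array([1.0]), ct, obs) == pytest.approx(9.0)

    def test_matches_double_loop_oracle(self, rng):
        f = random_components(rng, 20, 3)
        k = rng.uniform(0, 2, 3)
        obs = ObservedData(amplitude=rng.uniform(1, 10, 20))
        total = 0.0
        for s in range(20):
            model = 0.0
            for n in range(3):
                for m in range(3):
                    model += k[n] * k[m] * (f[n, s] * np.conj(f[m, s])).real
            total += (obs.intensity[s] - model) ** 2
        assert ls_residual(k, cross_v(f), obs) == pytest.approx(total, rel=1e-12)

    def test_sign_flip_invariance(self, rng):
        f, k_true, obs = make_instance(rng)
        k = rng.uniform(0.1, 2, 3)
        ct = cross_v(f)
        assert ls_residual(k, ct, obs) == pytest.approx(ls_residual(-k, ct, obs), rel=1e-12)

    def test_empty_shell_error(self, rng):
        f, _, obs = make_instance(rng)
        with pytest.raises(ValueError):
            ls_residual(np.ones(3), cross_v(f), obs, shell=np.array([], dtype=int))


class TestDerivatives:
    def test_gradient_zero_at_truth(self, rng):
        f, k_true, obs = make_instance(rng)
        g = ls_gradient(k_true, cross_v(f), obs)
        assert np.allclose(g, 0.0, atol=1e-6 * np.max(obs.intensity) ** 2)

    def test_gradient_matches_finite_differences(self, rng):
        f, _, obs = make_instance(rng, n_refl=50)
        ct = cross_v(f)
        k = rng.uniform(0.3, 1.5, 3)
        g = ls_gradient(k, ct, obs)
        for p in range(3):
            h = 1e-6 * (1.0 + abs(k[p]))
            kp, km = k.copy(), k.copy()
            kp[p] += h
            km[p] -= h
            fd = (ls_residual(kp, ct, obs) - ls_residual(km, ct, obs)) / (2 * h)
            assert g[p] == pytest.approx(fd, rel=1e-5)

    def test_hessian_matches_finite_differences(self, rng):
        f, _, obs = make_instance(rng, n_refl=50)
        ct = cross_v(f)
        k = rng.uniform(0.3, 1.5, 3)
        hess = ls_hessian(k, ct, obs)
        assert np.allclose(hess, hess.T, rtol=1e-12)
        for p in range(3):
            h = 1e-6 * (1.0 + abs(k[p]))
            kp, km = k.copy(), k.copy()
            kp[p] += h
            km[p] -= h
            fd = (ls_gradient(kp, ct, obs) - ls_gradient(km, ct, obs)) / (2 * h)
            assert np.allclose(hess[p], fd, rtol=1e-4, atol=1e-4 * np.abs(hess).max())


class TestAlg2:
    def test_truth_is_fixed_point(self, rng):
        f, k_true, obs = make_instance(rng)
        out = solve_shell_alg2(cross_v(f), obs, None, k_init=k_true)
        assert np.allclose(out, k_true, rtol=1e-8)

    @pytest.mark.parametrize("use_hessian", [False, True])
    def test_error_free_recovery(self, rng, use_hessian):
        f, k_true, obs = make_instance(rng, n_refl=400, m=4)
        k_init = k_true * 10 ** rng.uniform(-1, 1, 4)
        out = solve_shell_alg2(cross_v(f), obs, None, k_init=k_init, use_hessian=use_hessian)
        assert np.allclose(out, k_true, rtol=1e-6)

    def test_matches_dense_grid_search(self, rng):
        # N=1 (two components): exhaustive grid oracle over k in [0,2]^2
        f = random_components(rng, 60, 2)
        k_true = np.array([0.8, 1.2])
        obs = ObservedData(amplitude=np.abs(k_true @ f))
        ct = cross_v(f)
        grid = np.arange(0.0, 2.0, 1e-3)
        best, best_val = None, np.inf
        i_obs = obs.intensity
        v00, v01, v11 = ct.v[:, 0, 0], ct.v[:, 0, 1], ct.v[:, 1, 1]
        for k0 in np.arange(0.5, 1.1, 1e-3):  # narrowed window around truth for speed
            model0 = k0 * k0 * v00
            for k1 in np.arange(0.9, 1.5, 1e-3):
                val = np.sum((i_obs - model0 - 2 * k0 * k1 * v01 - k1 * k1 * v11) ** 2)
                if val < best_val:
                    best, best_val = (k0, k1), val
        out = solve_shell_alg2(ct, obs, None, k_init=np.array([0.6, 1.0]))
        assert np.allclose(out, best, atol=2e-3)

    def test_worse_than_init_never_returned(self, rng):
        f, k_true, obs = make_instance(rng)
        ct = cross_v(f)
        k_init = rng.uniform(0.5, 1.5, 3)
        out = solve_shell_alg2(ct, obs, None, k_init=k_init, max_iter=1)
        assert ls_residual(out, ct, obs) <= ls_residual(np.maximum(k_init, 0), ct, obs) + 1e-9


class TestAlg3:
    def test_error_free_n2(self, rng):
        f, k_true, obs = make_instance(rng, n_refl=300, m=3)
        out = solve_shell_alg3(cross_v(f), obs, None)
        assert np.allclose(out, k_true, rtol=1e-6)

    def test_single_component_closed_form(self, rng):
        f = random_components(rng, 100, 1)
        obs = ObservedData(amplitude=rng.uniform(1, 5, 100))
        out = solve_shell_alg3(cross_v(f), obs, None)
        v00 = (np.abs(f[0]) ** 2)
        expected = np.sqrt(np.sum(obs.intensity * v00) / np.sum(v00**2))
        assert out[0] == pytest.approx(expected, rel=1e-10)

    def test_exact_product_table_factorization(self, rng):
        k = rng.uniform(0.3, 2.0, 4)
        u = np.outer(k, k)
        assert np.allclose(factor_products(u), k, rtol=1e-10)

    def test_no_positive_evidence_warns(self):
        u = -np.ones((2, 2))
        with pytest.warns(UserWarning, match="no positive"):
            out = factor_products(u)
        assert np.allclose(out, 0.0)


class TestAlg4:
    def test_exact_phases_solve_in_one_iteration(self, rng):
        f, k_true, obs = make_instance(rng)
        out = solve_shell_alg4(f, obs, None, k_init=k_true, max_iter=1)
        assert np.allclose(out, k_true, rtol=1e-10)

    def test_error_free_recovery(self, rng):
        f, k_true, obs = make_instance(rng, n_refl=500, m=8)
        k_init = k_true * 10 ** rng.uniform(-1, 1, 8)
        out = solve_shell_alg4(f, obs, None, k_init=k_init, tol=1e-12, max_iter=200)
        assert np.allclose(out, k_true, rtol=1e-6)

    def test_two_reflection_cramer_oracle(self):
        # manufactured 2x2 system solved by hand via Cramer's rule
        f = np.array([[1.0 + 0j, 2.0 + 0j], [1.0 + 0j, -1.0 + 0j]])
        k_true = np.array([2.0, 0.5])
        total = k_true @ f  # real positive amplitudes: (2.5, 3.5)
        obs = ObservedData(amplitude=np.abs(total))
        # phases exact from k_init = truth; system: Vbar k = w
        vbar = np.array([[5.0, -1.0], [-1.0, 2.0]])  # v01 = Re(1*1 + 2*(-1)) = -1
        w = np.array([np.sum(total * np.conj(f[0])).real, np.sum(total * np.conj(f[1])).real])
        det = vbar[0, 0] * vbar[1, 1] - vbar[0, 1] * vbar[1, 0]
        k_cramer = np.array([
            (w[0] * vbar[1, 1] - vbar[0, 1] * w[1]) / det,
            (vbar[0, 0] * w[1] - w[0] * vbar[1, 0]) / det,
        ])
        out = solve_shell_alg4(f, obs, None, k_init=k_true, max_iter=1)
        assert np.allclose(out, k_cramer, rtol=1e-12)
        assert np.allclose(k_cramer, k_true, rtol=1e-12)


class TestAlg1:
    def test_single_component_matches_grid(self, rng):
        f = random_components(rng, 80, 1)
        obs = ObservedData(amplitude=np.abs(1.3 * f[0] + 0.05 * rng.normal(size=80)))
        out = solve_shell_alg1(f, obs, None)
        grid = np.arange(0.0, 3.0, 1e-4)
        vals = [np.sum((obs.amplitude - np.abs(t * f[0])) ** 2) for t in grid]
        assert out[0] == pytest.approx(grid[int(np.argmin(vals))], abs=2e-4)

    def test_orthogonal_components_recovered(self, rng):
        # components supported on disjoint reflection blocks never mix
        n = 100
        f = np.zeros((2, n), dtype=complex)
        f[0, :50] = random_components(rng, 50, 1)
        f[1, 50:] = random_components(rng, 50, 1)
        k_true = np.array([0.7, 1.4])
        obs = ObservedData(amplitude=np.abs(k_true @ f))
        out = solve_shell_alg1(f, obs, None)
        assert np.allclose(out, k_true, rtol=1e-5)

    def test_correlated_components_worse_than_alg2(self, rng):
        # strongly correlated pair: sequential search is restricted
        base = random_components(rng, 150, 1)[0]
        f = np.stack([base, base + 0.15 * random_components(rng, 150, 1)[0]])
        k_true = np.array([0.9, 0.6])
        obs = ObservedData(amplitude=np.abs(k_true @ f))
        ct = cross_v(f)
        k1 = solve_shell_alg1(f, obs, None)
        k2 = solve_shell_alg2(ct, obs, None, k_init=np.array([1.0, 1.0]))
        assert ls_residual(k1, ct, obs) >= ls_residual(k2, ct, obs) - 1e-9


class TestOracleEquivalence:
    def test_algorithms_agree_small_n(self, rng):
        for _ in range(10):
            m = rng.integers(1, 4)
            f, k_true, obs = make_instance(rng, n_refl=300, m=m)
            ct = cross_v(f)
            k_init = k_true * 10 ** rng.uniform(-0.5, 0.5, m)
            k2 = solve_shell_alg2(ct, obs, None, k_init=k_init)
            k3 = solve_shell_alg3(ct, obs, None)
            k4 = solve_shell_alg4(f, obs, None, k_init=k_init, tol=1e-12, max_iter=200)
            assert np.allclose(k2, k_true, rtol=1e-4)
            assert np.allclose(k3, k_true, rtol=1e-4)
            assert np.allclose(k4, k_true, rtol=1e-4)


class TestRFactor:
    def test_identical(self):
        assert r_factor(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == 0.0

    def test_zero_model(self):
        assert r_factor(np.array([1.0, 2.0]), np.zeros(2)) == 1.0

    def test_hand_case(self):
        assert r_factor(np.array([10.0, 10.0]), np.array([9.0, 12.0])) == pytest.approx(0.15)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            r_factor(np.array([]), np.array([]))


class TestFitDriver:
    def _synthetic(self, rng, n_shells=4, m=3):
        cell = UnitCell(25, 25, 25)
        miller = generate_hkl(cell, 3.0)
        n = len(miller)
        f = random_components(rng, n, m)
        # damp components so they decay with resolution like real ones
        f *= np.exp(-20.0 * miller.s**2 / 4.0)
        k_true = rng.uniform(0.3, 1.2, m)
        k_true[0] = 1.0
        obs = ObservedData(amplitude=np.abs(k_true @ f))
        shells = bin_shells(miller, n_shells=n_shells, min_per_shell=10)
        return f, k_true, obs, shells

    def test_single_shell_matches_direct_alg4(self, rng):
        f, k_true, obs, _ = self._synthetic(rng, m=3)
        from mcscale import MillerSet
        from mcscale.reflections import ResolutionShells

        n = f.shape[1]
        shells = ResolutionShells(
            boundaries=np.array([1e6, 1e-6]),
            assignment=np.zeros(n, dtype=int),
            counts=np.array([n]),
        )
        scales = fit_driver(obs, f, shells, algorithm="4", tol=1e-10)
        direct = solve_shell_alg4(f, obs, None, k_init=np.ones(3), tol=1e-10, max_iter=200)
        c_driver = scales.k_overall[0] * scales.k[0]
        assert np.allclose(c_driver, direct, rtol=1e-5)

    @pytest.mark.parametrize("algorithm", ["2", "2h", "4"])
    def test_multishell_error_free_recovery(self, rng, algorithm):
        f, k_true, obs, shells = self._synthetic(rng)
        scales = fit_driver(obs, f, shells, algorithm=algorithm, tol=1e-9)
        c = scales.k_overall[:, None] * scales.k
        assert np.allclose(c, k_true[None, :], rtol=1e-6)

    def test_zero_components_pure_overall_scaling(self, rng):
        f, _, obs, shells = self._synthetic(rng, m=1)
        scales = fit_driver(obs, f[:1], shells, algorithm="4", tol=1e-10)
        # with a single component the per-shell scale is the amplitude ratio
        for i in range(shells.n_shells):
            idx = shells.indices(i)
            ratio = obs.amplitude[idx].sum() / np.abs(f[0, idx]).sum()
            assert scales.k_overall[i] == pytest.approx(ratio, rel=1e-6)

    def test_residual_history_non_increasing_error_free(self, rng):
        f, _, obs, shells = self._synthetic(rng)
        scales = fit_driver(obs, f, shells, algorithm="4", tol=1e-9)
        r = np.array(scales.log["r_history"])
        assert np.all(np.diff(r) <= 1e-10)

    def test_unknown_algorithm(self, rng):
        f, _, obs, shells = self._synthetic(rng)
        with pytest.raises(ValueError, match="algorithm"):
            fit_driver(obs, f, shells, algorithm="9")

    def test_clip_reports_nonnegative(self, rng):
        f, _, obs, shells = self._synthetic(rng)
        scales = fit_driver(obs, f, shells, algorithm="4", clip=True)
        assert np.all(scales.k >= 0)

    def test_alg3_large_n_conditioning_warning(self, rng):
        # many correlated components: the product system becomes rank
        # deficient and the condition monitor must flag it
        f, k_true, obs, shells = self._synthetic(rng, m=10)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            scales = fit_driver(obs, f, shells, algorithm="3")
        assert any(s.get("ill_conditioned") for s in scales.log["shell_logs"]) or any(
            "ill-conditioned" in str(w.message) for w in rec
        )
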