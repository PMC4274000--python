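"""Shrinkage prox, Lipschitz estimation, objectives/gradients, FISTA, TV."""

import numpy as np
import pytest
from scipy.linalg import qr

import patchct as pc
from patchct.solvers import (
    SolverParams,
    fista_solve,
    fista_solve_floating,
    gradient_overlap,
    objective_floating,
    objective_overlap,
    tv_prox,
    tv_solve,
)


class TestShrinkage:
    def test_below_threshold_zero(self):
        assert pc.shrinkage(0.5, 1.0) == 0.0

    def test_symmetric_values(self):
        np.testing.assert_allclose(pc.shrinkage(np.array([2.0, -2.0]), 1.0), [1.0, -1.0])

    def test_zero_threshold_identity(self, rng):
        v = rng.standard_normal(50)
        np.testing.assert_array_equal(pc.shrinkage(v, 0.0), v)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            pc.shrinkage(1.0, -0.1)

    def test_is_exact_prox_by_grid_minimization(self, rng):
        """sign(v)*max(|v|-t,0) minimizes t|u| + 0.5(u-v)^2 on a dense grid."""
        grid = np.linspace(-6.0, 6.0, 100001)
        for _ in range(50):
            v = float(rng.uniform(-3, 3))
            t = float(rng.uniform(0, 2))
            best = grid[np.argmin(t * np.abs(grid) + 0.5 * (grid - v) ** 2)]
            assert pc.shrinkage(v, t) == pytest.approx(best, abs=2e-4)


class TestLipschitzPower:
    def test_identity(self):
        L = pc.lipschitz_power(lambda x: x, lambda x: x, (10,), 30, seed=0)
        assert L == pytest.approx(1.0, abs=1e-9)

    def test_scaling(self):
        L = pc.lipschitz_power(lambda x: 3.0 * x, lambda x: 3.0 * x, (7,), 30, 0)
        assert L == pytest.approx(9.0, abs=1e-6)

    def test_dense_operator_vs_svd(self, rng):
        A = rng.standard_normal((20, 12))
        L = pc.lipschitz_power(lambda x: A @ x, lambda y: A.T @ y, (12,), 200, 1)
        s2 = np.linalg.svd(A, compute_uv=False)[0] ** 2
        assert L == pytest.approx(s2, rel=0.01)

    def test_zero_operator_warns(self):
        with pytest.warns(UserWarning, match="zero"):
            L = pc.lipschitz_power(lambda x: 0.0 * x, lambda x: 0.0 * x, (5,), 10, 0)
        assert L == 0.0


class TestObjectiveOverlap:
    def test_zero_everything(self, small_dictionary, small_problem):
        lat, core, geom, sino = small_problem
        params = SolverParams(lambda_sparsity=1.0, omega_overlap=1.0)
        zero_sino = pc.Sinogram(np.zeros(geom.shape), geom)
        w = np.zeros((lat.n_patches, small_dictionary.n_atoms))
        assert objective_overlap(w, zero_sino, small_dictionary, lat, core, params) == 0.0

    def test_consistent_input_leaves_only_l1(self, small_dictionary, small_problem):
        lat, core, geom, _ = small_problem
        # constant-image coefficients: all patches agree everywhere
        rng = np.random.default_rng(0)
        const_coeff, *_ = np.linalg.lstsq(
            small_dictionary.atoms.T, np.full(16, 0.7), rcond=None
        )
        w = np.tile(const_coeff, (lat.n_patches, 1))
        sol = pc.compose_solution(w, lat, core, small_dictionary)
        data = pc.forward_project(sol, geom)
        lam = 0.37
        params = SolverParams(lambda_sparsity=lam, omega_overlap=5.0)
        obj = objective_overlap(w, data, small_dictionary, lat, core, params)
        assert obj == pytest.approx(lam * np.sum(np.abs(w)), rel=1e-9)

    def test_omega_scales_similarity_term_only(self, small_dictionary, small_problem, rng):
        lat, core, geom, sino = small_problem
        w = rng.standard_normal((lat.n_patches, small_dictionary.n_atoms))
        vals = []
        for om in (1.0, 2.0):
            params = SolverParams(lambda_sparsity=0.0, omega_overlap=om)
            vals.append(objective_overlap(w, sino, small_dictionary, lat, core, params))
        p0 = SolverParams(lambda_sparsity=0.0, omega_overlap=0.0)
        base = objective_overlap(w, sino, small_dictionary, lat, core, p0)
        assert vals[1] - base == pytest.approx(2.0 * (vals[0] - base), rel=1e-9)


class TestGradientOverlap:
    def test_zero_coeffs_zero_data_zero_gradient(self, small_dictionary, small_problem):
        lat, core, geom, _ = small_problem
        params = SolverParams(lambda_sparsity=0.3, omega_overlap=2.0)
        zero_sino = pc.Sinogram(np.zeros(geom.shape), geom)
        w = np.zeros((lat.n_patches, small_dictionary.n_atoms))
        g = gradient_overlap(w, zero_sino, small_dictionary, lat, core, params)
        np.testing.assert_allclose(g, 0.0, atol=1e-14)

    def test_matches_finite_differences(self, small_dictionary, small_problem):
        lat, core, geom, sino = small_problem
        rng = np.random.default_rng(21)
        params = SolverParams(lambda_sparsity=0.0, omega_overlap=2.5)
        w = 0.3 * rng.standard_normal((lat.n_patches, small_dictionary.n_atoms))
        g = gradient_overlap(w, sino, small_dictionary, lat, core, params)
        for _ in range(30):
            i = rng.integers(lat.n_patches)
            j = rng.integers(small_dictionary.n_atoms)
            h = 1e-6 * max(1.0, abs(w[i, j]))
            wp, wm = w.copy(), w.copy()
            wp[i, j] += h
            wm[i, j] -= h
            fd = (
                objective_overlap(wp, sino, small_dictionary, lat, core, params)
                - objective_overlap(wm, sino, small_dictionary, lat, core, params)
            ) / (2 * h)
            assert g[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-8)

    def test_identity_mode_classical_patch_gradient(self, small_dictionary, rng):
        """omega=0, P=identity: gradient equals the dense patch-fitting form."""
        lat = pc.build_lattice(8, 4, 4)
        core = pc.core_map(lat)
        img = rng.standard_normal((8, 8))
        w = rng.standard_normal((lat.n_patches, small_dictionary.n_atoms))
        params = SolverParams(omega_overlap=0.0, mode="denoising")
        g = gradient_overlap(w, img, small_dictionary, lat, core, params)
        D = small_dictionary.atoms.T  # (16, K)
        for p, (r, c) in enumerate(lat.corners):
            y = img[r : r + 4, c : c + 4].ravel()
            expected = 2.0 * D.T @ (D @ w[p] - y)
            np.testing.assert_allclose(g[p], expected, rtol=1e-10)


class TestFistaSolve:
    def test_large_lambda_returns_zero(self, small_dictionary, small_problem):
        lat, core, geom, sino = small_problem
        p0 = SolverParams(lambda_sparsity=0.0, omega_overlap=1.0)
        g0 = gradient_overlap(
            np.zeros((lat.n_patches, small_dictionary.n_atoms)),
            sino, small_dictionary, lat, core, p0,
        )
        lam = 1.5 * np.abs(g0).max()
        params = SolverParams(lambda_sparsity=lam, omega_overlap=1.0, n_iter=20)
        trace = fista_solve(sino, small_dictionary, lat, core, params)
        np.testing.assert_array_equal(trace.coeffs, 0.0)

    def test_orthonormal_closed_form(self):
        H = qr(np.random.default_rng(5).standard_normal((64, 64)))[0]
        d = pc.Dictionary(H.T, m=8)
        lat = pc.build_lattice(8, 8, 8)
        core = pc.core_map(lat)
        y = np.random.default_rng(6).standard_normal((8, 8))
        lam = 0.4
        params = SolverParams(
            lambda_sparsity=lam, omega_overlap=0.0, n_iter=400, mode="denoising"
        )
        trace = fista_solve(y, d, lat, core, params)
        closed = pc.shrinkage(H.T @ y.ravel(), lam / 2.0)
        np.testing.assert_allclose(
            trace.coeffs.ravel(), closed, rtol=1e-6, atol=1e-9
        )

    def test_final_objective_matches_long_ista(self, small_dictionary):
        """FISTA agrees with a plain-ISTA limit on a small toy problem."""
        lat = pc.build_lattice(8, 4, 2)
        core = pc.core_map(lat)
        rng = np.random.default_rng(13)
        img = rng.standard_normal((8, 8))
        params = SolverParams(
            lambda_sparsity=0.2, omega_overlap=1.0, n_iter=600, mode="denoising"
        )
        trace = fista_solve(img, small_dictionary, lat, core, params)
        assert trace.objectives[-1] <= trace.objectives[0]
        # plain ISTA reference
        from patchct.solvers import _gradient_overlap_fast, _overlap_lipschitz, _Projector, shrinkage

        proj = _Projector(None, 1, 8)
        L = _overlap_lipschitz(small_dictionary, lat, core, 1.0, proj, 0)
        tau = 0.9 / L
        w = np.zeros((lat.n_patches, small_dictionary.n_atoms))
        data = img[None]
        for _ in range(5000):
            g, _, _ = _gradient_overlap_fast(
                w, data, small_dictionary, lat, core, 1.0, proj
            )
            w = shrinkage(w - tau * g, tau * 0.2)
        ista_obj = objective_overlap(w, img, small_dictionary, lat, core, params)
        assert trace.objectives[-1] == pytest.approx(ista_obj, rel=1e-5)

    def test_divergence_raises_with_tau_hint(self, small_dictionary, small_problem):
        lat, core, geom, sino = small_problem
        params = SolverParams(
            lambda_sparsity=0.0, omega_overlap=1.0, n_iter=200, step_tau=10.0
        )
        with pytest.raises(RuntimeError, match="tau"):
            fista_solve(sino, small_dictionary, lat, core, params)

    def test_s_equals_m_omega_irrelevant(self, small_dictionary, rng):
        lat = pc.build_lattice(8, 4, 4)
        core = pc.core_map(lat)
        img = rng.standard_normal((8, 8))
        sols = []
        for om in (0.0, 50.0):
            params = SolverParams(
                lambda_sparsity=0.1, omega_overlap=om, n_iter=300, mode="denoising"
            )
            sols.append(fista_solve(img, small_dictionary, lat, core, params).coeffs)
        np.testing.assert_allclose(sols[0], sols[1], atol=1e-5)

    def test_large_omega_enforces_patch_agreement(self, small_dictionary, rng):
        lat = pc.build_lattice(8, 4, 2)
        core = pc.core_map(lat)
        img = rng.random((8, 8))
        weak = SolverParams(
            lambda_sparsity=1e-4, omega_overlap=1e-2, n_iter=2000, mode="denoising"
        )
        strong = SolverParams(
            lambda_sparsity=1e-4, omega_overlap=1e2, n_iter=2000, mode="denoising"
        )
        res_weak = np.abs(
            pc.overlap_residual(
                fista_solve(img, small_dictionary, lat, core, weak).coeffs,
                lat, core, small_dictionary,
            )
        ).max()
        res_strong = np.abs(
            pc.overlap_residual(
                fista_solve(img, small_dictionary, lat, core, strong).coeffs,
                lat, core, small_dictionary,
            )
        ).max()
        assert res_strong < res_weak
        assert res_strong < 1e-3 * (img.max() - img.min())


class TestFloatingFunctional:
    def test_zero_everything(self, small_dictionary, small_problem):
        lat, core, geom, _ = small_problem
        params = SolverParams(lambda_sparsity=1.0, omega_overlap=1.0)
        zero_sino = pc.Sinogram(np.zeros(geom.shape), geom)
        w = np.zeros((lat.n_patches, small_dictionary.n_atoms))
        assert objective_floating(
            w, np.zeros((16, 16)), zero_sino, small_dictionary, lat, params
        ) == 0.0

    def test_consistency_with_overlap_form(self, small_dictionary, small_problem):
        """When all patches agree, fixing the free image to the composed
        solution makes the two functionals coincide."""
        lat, core, geom, _ = small_problem
        const_coeff, *_ = np.linalg.lstsq(
            small_dictionary.atoms.T, np.full(16, 0.7), rcond=None
        )
        w = np.tile(const_coeff, (lat.n_patches, 1))
        sol = pc.compose_solution(w, lat, core, small_dictionary)
        data = pc.forward_project(sol, geom)
        params = SolverParams(lambda_sparsity=0.3, omega_overlap=4.0)
        f_over = objective_overlap(w, data, small_dictionary, lat, core, params)
        f_float = objective_floating(w, sol, data, small_dictionary, lat, params)
        assert f_float == pytest.approx(f_over, rel=1e-10)

    def test_convex_along_random_segments(self, small_dictionary, small_problem, rng):
        lat, core, geom, sino = small_problem
        params = SolverParams(lambda_sparsity=0.2, omega_overlap=2.0)

        def f(w, img):
            return objective_floating(w, img, sino, small_dictionary, lat, params)

        for _ in range(5):
            w0, w1 = rng.standard_normal((2, lat.n_patches, small_dictionary.n_atoms))
            i0, i1 = rng.standard_normal((2, 16, 16))
            mid = f(0.5 * (w0 + w1), 0.5 * (i0 + i1))
            assert mid <= 0.5 * f(w0, i0) + 0.5 * f(w1, i1) + 1e-9

    def test_zero_data_zero_solution(self, small_dictionary, small_problem):
        lat, core, geom, _ = small_problem
        zero_sino = pc.Sinogram(np.zeros(geom.shape), geom)
        params = SolverParams(lambda_sparsity=0.5, omega_overlap=2.0, n_iter=50)
        trace = fista_solve_floating(zero_sino, small_dictionary, lat, params)
        np.testing.assert_allclose(trace.solution, 0.0, atol=1e-12)
        np.testing.assert_allclose(trace.coeffs, 0.0, atol=1e-12)


def _condat_tv_1d(y, lam):
    """Direct (taut-string) 1-D total-variation denoising oracle:
    min 0.5*sum (u-y)^2 + lam*sum|diff(u)| (Condat's algorithm)."""
    y = np.asarray(y, float)
    N = len(y)
    if lam <= 0:
        return y.copy()
    x = np.empty(N)
    k = k0 = km = kp = 0
    vmin, vmax = y[0] - lam, y[0] + lam
    umin, umax = lam, -lam
    while True:
        if k == N - 1:
            if umin < 0:
                x[k0 : km + 1] = vmin
                k = k0 = km = km + 1
                vmin = y[k]
                umin = lam
                vmax = y[k] + 2 * lam
                umax = -lam
                if k == N - 1:
                    x[k] = vmin + umin
                    break
            elif umax > 0:
                x[k0 : kp + 1] = vmax
                k = k0 = kp = kp + 1
                vmax = y[k]
                umax = -lam
                vmin = y[k] - 2 * lam
                umin = lam
                if k == N - 1:
                    x[k] = vmax + umax
                    break
            else:
                x[k0:N] = vmin + umin / (k - k0 + 1)
                break
        else:
            if y[k + 1] + umin < vmin - lam:
                x[k0 : km + 1] = vmin
                k = k0 = km = kp = km + 1
                vmin = y[k]
                vmax = y[k] + 2 * lam
                umin, umax = lam, -lam
            elif y[k + 1] + umax > vmax + lam:
                x[k0 : kp + 1] = vmax
                k = k0 = km = kp = kp + 1
                vmin = y[k] - 2 * lam
                vmax = y[k]
                umin, umax = lam, -lam
            else:
                k += 1
                umin += y[k] - vmin
                umax += y[k] - vmax
                if umin >= lam:
                    vmin += (umin - lam) / (k - k0 + 1)
                    umin = lam
                    km = k
                if umax <= -lam:
                    vmax += (umax + lam) / (k - k0 + 1)
                    umax = -lam
                    kp = k
    return x


class TestTV:
    def test_constant_image_unchanged(self):
        c = np.full((16, 16), 3.0)
        np.testing.assert_allclose(tv_solve(c, None, 1.0, n_iter=20), c)

    def test_mu_zero_identity(self, rng):
        img = rng.random((12, 12))
        np.testing.assert_array_equal(tv_solve(img, None, 0.0), img)

    def test_1d_step_matches_taut_string_oracle(self):
        rng = np.random.default_rng(0)
        z = np.concatenate([np.zeros(10), np.ones(10)]) + rng.normal(0, 0.1, 20)
        mu = 0.4
        x = tv_solve(z, None, mu, n_iter=60, n_inner=400)
        oracle = _condat_tv_1d(z, mu / 2.0)
        np.testing.assert_allclose(x, oracle, atol=1e-4)

    def test_prox_reduces_objective(self, rng):
        z = rng.standard_normal((10, 10))
        alpha = 0.3
        from patchct.solvers import tv_iso

        u = tv_prox(z, alpha, n_inner=200)
        assert alpha * tv_iso(u) + 0.5 * np.sum((u - z) ** 2) < alpha * tv_iso(z)

    def test_tomographic_mode_runs(self):
        ph = pc.generate_phantom(pc.PhantomSpec(side=32, seed=2, kind="blob"))
        geom = pc.ProjectionGeometry(np.arange(20) * 9.0, 48, 32)
        sino = pc.forward_project(ph, geom)
        rec = tv_solve(sino, geom, mu=0.5, n_iter=80, n_inner=30)
        assert pc.ssim(rec, ph, 1.0) > 0.7


class TestDenoise:
    def test_huge_lambda_zero_output(self, small_dictionary):
        lat = pc.build_lattice(8, 4, 2)
        core = pc.core_map(lat)
        img = np.random.default_rng(2).random((8, 8))
        params = SolverParams(
            lambda_sparsity=1e6, omega_overlap=1.0, n_iter=30, mode="denoising"
        )
        np.testing.assert_array_equal(
            pc.denoise(img, small_dictionary, lat, core, params), 0.0
        )

    def test_representable_image_recovered(self):
        """A clean dictionary-representable image survives near-unregularized
        denoising almost exactly."""
        atoms = np.linalg.qr(np.random.default_rng(8).standard_normal((16, 16)))[0]
        d = pc.Dictionary(atoms, m=4)
        lat = pc.build_lattice(16, 4, 4)
        core = pc.core_map(lat)
        rng = np.random.default_rng(9)
        img = rng.random((16, 16))
        params = SolverParams(
            lambda_sparsity=1e-8, omega_overlap=0.0, n_iter=500, mode="denoising"
        )
        out = pc.denoise(img, d, lat, core, params)
        assert pc.ssim(out, img, 1.0) > 0.999

    def test_descent_from_zero(self, small_dictionary, rng):
        lat = pc.build_lattice(8, 4, 2)
        core = pc.core_map(lat)
        img = rng.random((8, 8))
        params = SolverParams(
            lambda_sparsity=0.05, omega_overlap=1.0, n_iter=100, mode="denoising"
        )
        trace = fista_solve(img, small_dictionary, lat, core, params)
        assert trace.objectives[-1] <= trace.objectives[0]

    def test_mode_enforced(self, small_dictionary):
        lat = pc.build_lattice(8, 4, 2)
        core = pc.core_map(lat)
        params = SolverParams(mode="tomography")
        with pytest.raises(ValueError, match="denoising"):
            pc.denoise(np.zeros((8, 8)), small_dictionary, lat, core, params)
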