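"""Proximal-gradient solvers for patch-dictionary CT reconstruction.

The reconstruction functional minimized here, over the per-patch coefficient
matrix w (one row per patch, one column per atom), is

    F(w) = || P S(w) - d ||^2
         + omega * sum_p sum_{x in patch p} (patch_p(w)(x) - S(w)(x))^2
         + lambda * ||w||_1

where patch_p(w) is the linear combination of dictionary atoms on patch p,
S(w) is the global solution composed from the patch *cores*, and P is the
forward projector (tomography) or the identity (denoising).  The omega term
pushes every overlapping patch toward the composed solution wherever they
share pixels; with a non-overlapping lattice (s = m) it vanishes identically.
The squared norms are *not* halved, so the Lipschitz constant of the smooth
gradient is 2 ||A||^2 for the stacked linear operator A, and the FISTA step
tau defaults to 0.9 / L.

A competing "floating solution" form keeps the global image I as a free
variable coupled to the patches:

    F(w, I) = || P I - d ||^2 + omega * sum_p ||patch_p(w) - I|_p||^2
            + lambda * ||w||_1

It is minimized by the same FISTA scheme on the joint variable (shrinkage on
the coefficient block only), and serves as the convergence baseline.  A
total-variation-penalized solver (isotropic TV, Chambolle dual prox) provides
the piecewise-constant-prior baseline.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .dictionary import Dictionary
from .geometry import ProjectionGeometry, Sinogram
from .patches import (
    CoreMap,
    PatchLattice,
    compose_patches,
    extract_patches,
    gather_solution,
    scatter_core,
    scatter_patches,
)

__all__ = [
    "SolverParams",
    "SolverTrace",
    "shrinkage",
    "lipschitz_power",
    "objective_overlap",
    "gradient_overlap",
    "fista_solve",
    "objective_floating",
    "fista_solve_floating",
    "tv_solve",
    "denoise",
]


@dataclass
class SolverParams:
    """Regularization weights and iteration controls.

    lambda_sparsity weights the l1 norm of the patch coefficients;
    omega_overlap weights the patch-similarity term.  step_tau = 0 requests
    the automatic step 0.9 / L with L estimated by power iteration.
    """

    lambda_sparsity: float = 0.0
    omega_overlap: float = 0.0
    n_iter: int = 100
    step_tau: float = 0.0
    seed: int = 0
    mode: str = "tomography"
    tol: float = 0.0
    restart: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda_sparsity) or self.lambda_sparsity < 0:
            raise ValueError("lambda_sparsity must be finite and >= 0")
        if not np.isfinite(self.omega_overlap) or self.omega_overlap < 0:
            raise ValueError("omega_overlap must be finite and >= 0")
        if self.step_tau < 0:
            raise ValueError("step_tau must be >= 0 (0 selects 0.9/L)")
        if self.mode not in ("tomography", "denoising"):
            raise ValueError("mode must be 'tomography' or 'denoising'")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


@dataclass
class SolverTrace:
    """Objective history and final state of a solver run.

    ``objectives[0]`` is the objective at the (all-zero) initialization, one
    further entry per iteration actually run.  ``solution`` is the composed
    image (channel-stacked when vectorial); for the floating functional it is
    the free image variable.
    """

    objectives: np.ndarray
    coeffs: np.ndarray
    n_iter_run: int
    solution: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.objectives)):
            raise ValueError("objective trace contains non-finite values")
        if len(self.objectives) != self.n_iter_run + 1:
            raise ValueError("trace length must be n_iter_run + 1")


def shrinkage(v: np.ndarray, t: float) -> np.ndarray:
    """Soft-thresholding sign(v) * max(|v| - t, 0): the prox of t*||.||_1."""
    if t < 0:
        raise ValueError("shrinkage threshold must be >= 0")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def lipschitz_power(op, op_adjoint, shape, n_power_iter: int = 50, seed: int = 0):
    """Estimate ||A||^2 (largest eigenvalue of A^T A) by power iteration.

    ``op``/``op_adjoint`` are callables forming a matched linear pair; the
    estimate is the Lipschitz constant of x -> A^T A x, i.e. the Lipschitz
    constant of the gradient of 0.5*||Ax - b||^2.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(shape)
    nv = np.linalg.norm(v)
    v = v / nv
    lam = 0.0
    for _ in range(n_power_iter):
        w = op_adjoint(op(v))
        lam = float(np.linalg.norm(w))
        if lam == 0.0:
            warnings.warn("operator is numerically zero; Lipschitz estimate 0")
            return 0.0
        v = w / lam
    return lam


# ---------------------------------------------------------------------------
# data / projector plumbing


class _Projector:
    """Channel-wise application of P (forward projection) or the identity."""

    def __init__(self, geom: ProjectionGeometry | None, channels: int, side: int):
        self.geom = geom
        self.channels = channels
        self.side = side
        if geom is not None and geom.image_side != side:
            raise ValueError("geometry image_side does not match lattice")

    @property
    def data_shape(self) -> tuple:
        if self.geom is None:
            return (self.channels, self.side, self.side)
        return (self.channels, *self.geom.shape)

    def forward(self, img_stack: np.ndarray) -> np.ndarray:
        if self.geom is None:
            return img_stack
        mat = self.geom.matrix()
        out = np.empty(self.data_shape)
        for c in range(self.channels):
            out[c] = (mat @ img_stack[c].ravel()).reshape(self.geom.shape)
        return out

    def adjoint(self, data: np.ndarray) -> np.ndarray:
        if self.geom is None:
            return data
        mat = self.geom.matrix()
        out = np.empty((self.channels, self.side, self.side))
        for c in range(self.channels):
            out[c] = (mat.T @ data[c].ravel()).reshape(self.side, self.side)
        return out


def _as_data_stack(data, channels: int):
    """Normalize data to a (C, ...) array; returns (stack, geometry-or-None)."""
    if isinstance(data, Sinogram):
        return data.values[None], data.geometry
    if isinstance(data, (list, tuple)) and data and isinstance(data[0], Sinogram):
        if len(data) != channels:
            raise ValueError("one sinogram per channel required")
        geom = data[0].geometry
        for s in data:
            if s.geometry is not geom and s.geometry != geom:
                raise ValueError("all sinograms must share one geometry")
        return np.stack([s.values for s in data]), geom
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr, None


def _resolve(data, lat: PatchLattice, params: SolverParams, P):
    stack, geom_from_data = _as_data_stack(data, lat.channels)
    geom = P if isinstance(P, ProjectionGeometry) else geom_from_data
    if params.mode == "denoising":
        geom = None
    if params.mode == "tomography" and geom is None:
        raise ValueError("tomography mode requires sinogram data or a geometry")
    proj = _Projector(geom, lat.channels, lat.image_side)
    if stack.shape != proj.data_shape:
        raise ValueError(f"data shape {stack.shape}, expected {proj.data_shape}")
    return stack, proj


def _coeff_adjoint(stack: np.ndarray, dictionary: Dictionary) -> np.ndarray:
    """T^T: patch-value stack (N, C, m, m) -> coefficient matrix (N, K)."""
    return stack.reshape(stack.shape[0], -1) @ dictionary.atoms.T


# ---------------------------------------------------------------------------
# overlap functional


def _smooth_parts(coeffs, data_stack, dictionary, lat, core, omega, proj):
    V = compose_patches(coeffs, lat, dictionary)
    S = gather_solution(V, core)
    fid_res = proj.forward(S) - data_stack
    r = V - extract_patches(S, lat) if omega > 0 else None
    return S, fid_res, r


def objective_overlap(
    coeffs, data, dictionary: Dictionary, lat: PatchLattice, core: CoreMap,
    params: SolverParams, P=None,
) -> float:
    """Value of the overlap functional F(w) (fidelity + omega-term + l1)."""
    data_stack, proj = _resolve(data, lat, params, P)
    coeffs = np.asarray(coeffs, dtype=float)
    _, fid_res, r = _smooth_parts(
        coeffs, data_stack, dictionary, lat, core, params.omega_overlap, proj
    )
    obj = float(np.sum(fid_res**2))
    if r is not None:
        obj += params.omega_overlap * float(np.sum(r**2))
    obj += params.lambda_sparsity * float(np.sum(np.abs(coeffs)))
    return obj


def gradient_overlap(
    coeffs, data, dictionary: Dictionary, lat: PatchLattice, core: CoreMap,
    params: SolverParams, P=None,
) -> np.ndarray:
    """Gradient of the smooth part of the overlap functional (l1 excluded).

    One forward projection of the composed solution and one backprojection of
    the fidelity residual per call, plus the patch-space overlap correction.
    """
    data_stack, proj = _resolve(data, lat, params, P)
    coeffs = np.asarray(coeffs, dtype=float)
    return _gradient_overlap_fast(
        coeffs, data_stack, dictionary, lat, core, params.omega_overlap, proj
    )[0]


def _gradient_overlap_fast(coeffs, data_stack, dictionary, lat, core, omega, proj):
    S, fid_res, r = _smooth_parts(coeffs, data_stack, dictionary, lat, core, omega, proj)
    g_img = proj.adjoint(fid_res)
    grad = 2.0 * _coeff_adjoint(scatter_core(g_img, core), dictionary)
    smooth_val = float(np.sum(fid_res**2))
    if r is not None:
        corr = r - scatter_core(scatter_patches(r, lat), core)
        grad += 2.0 * omega * _coeff_adjoint(corr, dictionary)
        smooth_val += omega * float(np.sum(r**2))
    return grad, smooth_val, S


def _overlap_lipschitz(dictionary, lat, core, omega, proj, seed):
    """L of the smooth gradient: 2 * ||A||^2 for the stacked operator A."""

    def op(w):
        V = compose_patches(w, lat, dictionary)
        S = gather_solution(V, core)
        top = proj.forward(S)
        if omega > 0:
            r = V - extract_patches(S, lat)
            return np.concatenate([top.ravel(), math.sqrt(omega) * r.ravel()])
        return top.ravel()

    def op_adj(u):
        nd = int(np.prod(proj.data_shape))
        top = u[:nd].reshape(proj.data_shape)
        g = _coeff_adjoint(scatter_core(proj.adjoint(top), core), dictionary)
        if omega > 0:
            r = u[nd:].reshape(lat.n_patches, lat.channels, lat.m, lat.m)
            corr = r - scatter_core(scatter_patches(r, lat), core)
            g = g + math.sqrt(omega) * _coeff_adjoint(corr, dictionary)
        return g

    norm_sq = lipschitz_power(
        op, op_adj, (lat.n_patches, dictionary.n_atoms), n_power_iter=50, seed=seed
    )
    return 2.0 * norm_sq


def _run_fista(x0, smooth_grad, objective, prox, n_iter, tol, tau, restart=False):
    """Beck–Teboulle FISTA; returns (trace list, final x, iters run).

    ``restart=True`` enables function-value adaptive restart (momentum reset
    whenever the objective increases), useful for computing well-converged
    reference solutions; the default is the plain method.
    """
    x = x0
    y = x0
    t = 1.0
    trace = [objective(x)]
    ref = max(abs(trace[0]), 1e-300)
    it_run = 0
    for _ in range(n_iter):
        g = smooth_grad(y)
        x_new = prox(y - tau * g)
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
        y = x_new + ((t - 1.0) / t_new) * (x_new - x)
        x, t = x_new, t_new
        obj = objective(x)
        if restart and obj > trace[-1]:
            t = 1.0
            y = x
        trace.append(obj)
        it_run += 1
        if not np.isfinite(obj) or obj > 1e3 * ref:
            raise RuntimeError(
                f"FISTA diverged (objective {obj:.3e} vs initial {trace[0]:.3e}); "
                f"the step tau={tau:.3e} is too large for this problem"
            )
        if tol > 0 and abs(trace[-2] - obj) <= tol * max(abs(trace[-2]), 1e-300):
            break
    return trace, x, it_run


def fista_solve(
    data, dictionary: Dictionary, lat: PatchLattice, core: CoreMap,
    params: SolverParams, P=None,
) -> SolverTrace:
    """Minimize the overlap functional by FISTA from zero coefficients."""
    data_stack, proj = _resolve(data, lat, params, P)
    lam, omega = params.lambda_sparsity, params.omega_overlap
    tau = params.step_tau
    if tau == 0.0:
        L = _overlap_lipschitz(dictionary, lat, core, omega, proj, params.seed)
        if L == 0.0:
            raise RuntimeError("zero operator: cannot set an automatic step")
        tau = 0.9 / L

    l1 = lambda w: lam * float(np.sum(np.abs(w)))

    def objective(w):
        _, sm, _ = _gradient_overlap_fast(
            w, data_stack, dictionary, lat, core, omega, proj
        )
        return sm + l1(w)

    def grad(w):
        return _gradient_overlap_fast(
            w, data_stack, dictionary, lat, core, omega, proj
        )[0]

    x0 = np.zeros((lat.n_patches, dictionary.n_atoms))
    trace, x, it_run = _run_fista(
        x0, grad, objective, lambda z: shrinkage(z, tau * lam),
        params.n_iter, params.tol, tau, restart=params.restart,
    )
    sol = gather_solution(compose_patches(x, lat, dictionary), core)
    return SolverTrace(
        np.asarray(trace), x, it_run, sol[0] if lat.channels == 1 else sol
    )


# ---------------------------------------------------------------------------
# floating-solution functional


def objective_floating(
    coeffs, free_image, data, dictionary: Dictionary, lat: PatchLattice,
    params: SolverParams, P=None,
) -> float:
    """Value of the floating functional F(w, I): fidelity on the free image,
    omega-coupling between patches and the free image, l1 on coefficients."""
    data_stack, proj = _resolve(data, lat, params, P)
    coeffs = np.asarray(coeffs, dtype=float)
    I = np.asarray(free_image, dtype=float)
    if I.ndim == 2:
        I = I[None]
    V = compose_patches(coeffs, lat, dictionary)
    fid = float(np.sum((proj.forward(I) - data_stack) ** 2))
    coup = float(np.sum((V - extract_patches(I, lat)) ** 2))
    return (
        fid
        + params.omega_overlap * coup
        + params.lambda_sparsity * float(np.sum(np.abs(coeffs)))
    )


def fista_solve_floating(
    data, dictionary: Dictionary, lat: PatchLattice, params: SolverParams, P=None,
) -> SolverTrace:
    """FISTA on the joint variable (coefficients, free image).

    The smooth gradient acts on both blocks; shrinkage is applied to the
    coefficient block only.  ``solution`` in the returned trace is the free
    image."""
    data_stack, proj = _resolve(data, lat, params, P)
    lam, omega = params.lambda_sparsity, params.omega_overlap
    nK = lat.n_patches * dictionary.n_atoms
    img_shape = (lat.channels, lat.image_side, lat.image_side)

    def split(z):
        return z[:nK].reshape(lat.n_patches, dictionary.n_atoms), z[nK:].reshape(
            img_shape
        )

    def grad(z):
        w, I = split(z)
        V = compose_patches(w, lat, dictionary)
        coup = V - extract_patches(I, lat)
        gI = 2.0 * proj.adjoint(proj.forward(I) - data_stack) - 2.0 * omega * (
            scatter_patches(coup, lat)
        )
        gw = 2.0 * omega * _coeff_adjoint(coup, dictionary)
        return np.concatenate([gw.ravel(), gI.ravel()])

    def objective(z):
        w, I = split(z)
        return objective_floating(w, I, data_stack, dictionary, lat, params, proj.geom)

    def prox(z):
        w, I = split(z)
        return np.concatenate(
            [shrinkage(w, tau * lam).ravel(), I.ravel()]
        )

    tau = params.step_tau
    if tau == 0.0:

        def op(z):
            w, I = split(z)
            V = compose_patches(w, lat, dictionary)
            top = proj.forward(I)
            coup = V - extract_patches(I, lat)
            return np.concatenate([top.ravel(), math.sqrt(omega) * coup.ravel()])

        def op_adj(u):
            nd = int(np.prod(proj.data_shape))
            top = u[:nd].reshape(proj.data_shape)
            coup = math.sqrt(omega) * u[nd:].reshape(
                lat.n_patches, lat.channels, lat.m, lat.m
            )
            gw = _coeff_adjoint(coup, dictionary)
            gI = proj.adjoint(top) - scatter_patches(coup, lat)
            return np.concatenate([gw.ravel(), gI.ravel()])

        L = 2.0 * lipschitz_power(
            op, op_adj, nK + int(np.prod(img_shape)), n_power_iter=50, seed=params.seed
        )
        if L == 0.0:
            raise RuntimeError("zero operator: cannot set an automatic step")
        tau = 0.9 / L

    z0 = np.zeros(nK + int(np.prod(img_shape)))
    trace, z, it_run = _run_fista(
        z0, grad, objective, prox, params.n_iter, params.tol, tau,
        restart=params.restart,
    )
    w, I = split(z)
    return SolverTrace(
        np.asarray(trace), w, it_run, I[0] if lat.channels == 1 else I
    )


# ---------------------------------------------------------------------------
# total variation baseline


def _tv_grad(u: np.ndarray) -> np.ndarray:
    """Forward differences along each axis, replicate boundary (last diff 0)."""
    g = np.zeros((u.ndim, *u.shape))
    for ax in range(u.ndim):
        sl_hi = [slice(None)] * u.ndim
        sl_hi[ax] = slice(0, u.shape[ax] - 1)
        g[ax][tuple(sl_hi)] = np.diff(u, axis=ax)
    return g


def _tv_div(p: np.ndarray) -> np.ndarray:
    """Negative adjoint of :func:`_tv_grad` (discrete divergence).

    The last forward difference along each axis is identically zero, so the
    corresponding dual component is inert; it is zeroed before differencing,
    which makes (grad, -div) an exactly adjoint pair for arbitrary duals.
    """
    out = np.zeros(p.shape[1:])
    for ax in range(p.shape[0]):
        pa = p[ax].copy()
        sl_last = [slice(None)] * pa.ndim
        sl_last[ax] = slice(pa.shape[ax] - 1, pa.shape[ax])
        pa[tuple(sl_last)] = 0.0
        sl0 = [slice(None)] * pa.ndim
        sl0[ax] = slice(0, 1)
        out += np.diff(pa, axis=ax, prepend=np.zeros_like(pa[tuple(sl0)]))
    return out


def tv_iso(u: np.ndarray) -> float:
    """Isotropic total variation: sum of Euclidean norms of the gradient."""
    g = _tv_grad(np.asarray(u, dtype=float))
    return float(np.sum(np.sqrt(np.sum(g**2, axis=0))))


def tv_prox(z: np.ndarray, alpha: float, n_inner: int = 50) -> np.ndarray:
    """argmin_u alpha*TV_iso(u) + 0.5*||u - z||^2.

    Solved in the dual (gradient projection onto per-pixel unit balls) with
    Beck–Teboulle momentum — the fast variant of Chambolle's dual TV scheme.
    """
    if alpha <= 0:
        return z.copy()
    z = np.asarray(z, dtype=float)
    p = np.zeros((z.ndim, *z.shape))
    q = p.copy()
    t = 1.0
    step = 1.0 / (4.0 * z.ndim)
    for _ in range(n_inner):
        u = z - alpha * _tv_div(q)
        p_new = q - (step / alpha) * _tv_grad(u)
        mag = np.sqrt(np.sum(p_new**2, axis=0))
        p_new /= np.maximum(1.0, mag)[None]
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t * t))
        q = p_new + ((t - 1.0) / t_new) * (p_new - p)
        p, t = p_new, t_new
    return z - alpha * _tv_div(p)


def tv_solve(data, geom: ProjectionGeometry | None, mu: float, n_iter: int = 200,
             n_inner: int = 40, seed: int = 0) -> np.ndarray:
    """Minimize ||P I - d||^2 + mu * TV_iso(I) by FISTA with a TV prox.

    ``geom=None`` selects denoising (P = identity, ``data`` is an image or a
    1-D signal); otherwise ``data`` is a :class:`Sinogram` for ``geom``.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    if geom is None:
        d = np.asarray(
            data.values if isinstance(data, Sinogram) else data, dtype=float
        )
        if mu == 0.0:
            return d.copy()
        x0 = d.copy()
        A = lambda u: u
        At = lambda u: u
        L = 2.0
    else:
        sino = data if isinstance(data, Sinogram) else Sinogram(np.asarray(data), geom)
        d = sino.values
        mat = geom.matrix()
        n = geom.image_side
        A = lambda u: (mat @ u.ravel()).reshape(geom.shape)
        At = lambda u: (mat.T @ u.ravel()).reshape(n, n)
        L = 2.0 * lipschitz_power(A, At, (n, n), n_power_iter=30, seed=seed)
        x0 = np.zeros((n, n))
    tau = 0.9 / L

    def objective(u):
        return float(np.sum((A(u) - d) ** 2)) + mu * tv_iso(u)

    trace, x, _ = _run_fista(
        x0,
        lambda u: 2.0 * At(A(u) - d),
        objective,
        lambda z: tv_prox(z, tau * mu, n_inner=n_inner),
        n_iter,
        0.0,
        tau,
    )
    return x


def denoise(
    img: np.ndarray, dictionary: Dictionary, lat: PatchLattice, core: CoreMap,
    params: SolverParams,
) -> np.ndarray:
    """Patch-dictionary denoising: the overlap functional with P = identity."""
    if params.mode != "denoising":
        raise ValueError("denoise requires params.mode == 'denoising'")
    trace = fista_solve(img, dictionary, lat, core, params, P=None)
    return trace.solution
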