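"""Scikit-learn-style reconstruction estimators.

Each reconstructor follows the estimator protocol: constructor arguments are
plain hyper-parameters (``get_params`` / ``set_params`` work, so the classes
compose with sklearn model selection), ``fit(X)`` consumes the measured data
(a :class:`~patchct.geometry.Sinogram`, or an image in denoising mode) and
the results live in trailing-underscore attributes (``image_``, ``coeffs_``,
``objective_trace_``).  The module-level solver functions in
:mod:`patchct.solvers` are the engine underneath.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import solvers
from .dictionary import Dictionary
from .dpc import reconstruct_vectorial
from .geometry import Sinogram, fbp
from .patches import build_lattice, core_map

__all__ = [
    "FBPReconstructor",
    "TVReconstructor",
    "DictionaryReconstructor",
    "FloatingDictionaryReconstructor",
    "VectorialDPCReconstructor",
]


class FBPReconstructor(BaseEstimator):
    """Filtered backprojection baseline."""

    def __init__(self, filter_name: str = "ramp"):
        self.filter_name = filter_name

    def fit(self, X: Sinogram, y=None):
        self.image_ = fbp(X, self.filter_name)
        return self


class TVReconstructor(BaseEstimator):
    """Isotropic-TV-penalized reconstruction (FISTA + Chambolle dual prox)."""

    def __init__(self, mu: float = 1.0, n_iter: int = 200, n_inner: int = 40,
                 seed: int = 0):
        self.mu = mu
        self.n_iter = n_iter
        self.n_inner = n_inner
        self.seed = seed

    def fit(self, X, y=None):
        geom = X.geometry if isinstance(X, Sinogram) else None
        self.image_ = solvers.tv_solve(
            X, geom, self.mu, n_iter=self.n_iter, n_inner=self.n_inner,
            seed=self.seed,
        )
        return self


class _PatchReconstructorBase(BaseEstimator):
    def __init__(self, dictionary: Dictionary | None = None, step: int = 4,
                 lam: float = 1.0, omega: float = 100.0, n_iter: int = 200,
                 step_tau: float = 0.0, tol: float = 0.0, seed: int = 0):
        self.dictionary = dictionary
        self.step = step
        self.lam = lam
        self.omega = omega
        self.n_iter = n_iter
        self.step_tau = step_tau
        self.tol = tol
        self.seed = seed

    def _setup(self, X):
        if self.dictionary is None:
            raise ValueError("a trained Dictionary is required")
        if isinstance(X, Sinogram):
            side, mode, geom = X.geometry.image_side, "tomography", X.geometry
        elif isinstance(X, (list, tuple)):
            side, mode, geom = X[0].geometry.image_side, "tomography", X[0].geometry
        else:
            arr = np.asarray(X)
            side, mode, geom = arr.shape[-1], "denoising", None
        lat = build_lattice(side, self.dictionary.m, self.step,
                            self.dictionary.channels)
        core = core_map(lat)
        params = solvers.SolverParams(
            lambda_sparsity=self.lam, omega_overlap=self.omega,
            n_iter=self.n_iter, step_tau=self.step_tau, seed=self.seed,
            mode=mode, tol=self.tol,
        )
        return lat, core, params, geom


class DictionaryReconstructor(_PatchReconstructorBase):
    """Overlapping-patch dictionary reconstruction (the overlap functional)."""

    def fit(self, X, y=None):
        lat, core, params, geom = self._setup(X)
        trace = solvers.fista_solve(X, self.dictionary, lat, core, params, geom)
        self.image_ = trace.solution
        self.coeffs_ = trace.coeffs
        self.objective_trace_ = trace.objectives
        self.n_iter_ = trace.n_iter_run
        return self


class FloatingDictionaryReconstructor(_PatchReconstructorBase):
    """Free-image ("floating solution") dictionary functional baseline."""

    def fit(self, X, y=None):
        lat, _, params, geom = self._setup(X)
        trace = solvers.fista_solve_floating(X, self.dictionary, lat, params, geom)
        self.image_ = trace.solution
        self.coeffs_ = trace.coeffs
        self.objective_trace_ = trace.objectives
        self.n_iter_ = trace.n_iter_run
        return self


class VectorialDPCReconstructor(_PatchReconstructorBase):
    """Two-channel DPC reconstruction with a vectorial dictionary."""

    def fit(self, X: Sinogram, y=None):
        if self.dictionary is None or self.dictionary.channels != 2:
            raise ValueError("a two-channel Dictionary is required")
        lat, core, params, _ = self._setup(X)
        image, trace = reconstruct_vectorial(X, self.dictionary, lat, core, params)
        self.image_ = image
        self.coeffs_ = trace.coeffs
        self.objective_trace_ = trace.objectives
        self.n_iter_ = trace.n_iter_run
        return self
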