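"""Dictionary training: OMP sparse coding and K-SVD, scalar or vectorial.

Atoms are unit-norm flattened patches of shape (channels, m, m), stored
row-wise in a (K, channels*m*m) array with the two channels of a vectorial
atom stacked (X half first, then Y).  Vectorial training patches are built by
Sobel-filtering a training image and extracting both derivative channels per
patch, so a single coefficient multiplies both halves of an atom and the two
gradient components stay intrinsically correlated.

`KSVD` follows the scikit-learn estimator protocol (``fit`` on an
(n_samples, n_features) patch matrix, learned atoms in ``atoms_``);
:func:`ksvd_train` is the functional wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from sklearn.base import BaseEstimator
from sklearn.linear_model import orthogonal_mp_gram

__all__ = [
    "Dictionary",
    "SparseCode",
    "omp_code",
    "KSVD",
    "ksvd_train",
    "sobel_gradient",
    "build_training_set",
    "atom_mosaic",
]


@dataclass
class Dictionary:
    """K unit-norm atoms over an m x m patch support with C channels."""

    atoms: np.ndarray  # (K, C*m*m)
    m: int
    channels: int = 1

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float)
        if self.atoms.ndim != 2 or self.atoms.shape[1] != self.channels * self.m**2:
            raise ValueError("atoms must be (K, channels*m*m)")
        if not np.all(np.isfinite(self.atoms)):
            raise ValueError("atoms must be finite")
        norms = np.linalg.norm(self.atoms, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero-norm atom encountered")
        if np.max(np.abs(norms - 1.0)) > 1e-8:
            raise ValueError("atoms must have unit Euclidean norm")

    @property
    def n_atoms(self) -> int:
        return int(self.atoms.shape[0])

    @property
    def patch_dim(self) -> int:
        return int(self.atoms.shape[1])


@dataclass
class SparseCode:
    """Support and values of one OMP-coded patch (|support| <= T0)."""

    support: np.ndarray
    values: np.ndarray

    def dense(self, n_atoms: int) -> np.ndarray:
        out = np.zeros(n_atoms)
        out[self.support] = self.values
        return out


def omp_code(
    patch: np.ndarray, dictionary: Dictionary, T0: int, tol: float = 1e-12
) -> SparseCode:
    """Orthogonal matching pursuit for one patch.

    Greedily selects the atom with maximum |correlation| with the current
    residual, then least-squares refits on the selected support; stops after
    T0 atoms or when the residual norm drops to ``tol``.
    """
    if T0 < 1:
        raise ValueError("T0 must be >= 1")
    y = np.asarray(patch, dtype=float).ravel()
    if y.size != dictionary.patch_dim:
        raise ValueError("patch length does not match dictionary atoms")
    D = dictionary.atoms
    support: list[int] = []
    values = np.zeros(0)
    residual = y.copy()
    for _ in range(min(T0, dictionary.n_atoms)):
        if np.linalg.norm(residual) <= tol:
            break
        corr = D @ residual
        corr[support] = 0.0
        k = int(np.argmax(np.abs(corr)))
        support.append(k)
        sub = D[support].T  # (dim, |S|)
        values, *_ = np.linalg.lstsq(sub, y, rcond=None)
        residual = y - sub @ values
    return SparseCode(np.asarray(support, dtype=int), np.asarray(values))


def _omp_batch(patches: np.ndarray, atoms: np.ndarray, T0: int) -> np.ndarray:
    """Sparse-code many patches at once -> (n_patches, K) coefficient matrix."""
    gram = atoms @ atoms.T
    xy = atoms @ patches.T
    codes = orthogonal_mp_gram(gram, xy, n_nonzero_coefs=min(T0, atoms.shape[0]))
    return np.atleast_2d(codes.T)


def _fix_atom_sign(atom: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(np.abs(atom) > 1e-12)
    if nz.size and atom[nz[0]] < 0:
        return -atom
    return atom


class KSVD(BaseEstimator):
    """K-SVD dictionary learning with OMP sparse coding.

    Alternates a full OMP coding pass with per-atom rank-1 SVD updates of the
    atom and its coefficients; unused atoms are replaced by the currently
    worst-represented training patch.  Deterministic for a fixed ``seed``.

    Parameters
    ----------
    n_atoms : int
        Dictionary size K.
    T0 : int
        OMP sparsity (atoms per patch).
    n_iter : int
        Number of coding/update sweeps.
    include_dc : bool
        Prepend a frozen constant atom (never updated) so smooth regions are
        representable.  Appropriate for raw intensity patches; gradient
        (vectorial) patches are zero-mean by construction and training on
        synthetic coefficient data should disable it.
    seed : int
        Seed for the initial atom selection.

    Attributes
    ----------
    atoms_ : ndarray of shape (n_atoms, n_features)
        Learned unit-norm atoms.
    errors_ : ndarray
        Mean squared training-set reconstruction error after each sweep.
    """

    def __init__(
        self,
        n_atoms: int = 100,
        T0: int = 5,
        n_iter: int = 5,
        include_dc: bool = True,
        seed: int = 0,
    ) -> None:
        self.n_atoms = n_atoms
        self.T0 = T0
        self.n_iter = n_iter
        self.include_dc = include_dc
        self.seed = seed

    def fit(self, X: np.ndarray, y=None) -> "KSVD":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, n_features)")
        n_samples, dim = X.shape
        if n_samples < self.n_atoms:
            raise ValueError("need at least n_atoms training patches")
        norms = np.linalg.norm(X, axis=1)
        if np.max(norms) < 1e-12:
            raise ValueError("degenerate training set: all patches are zero")
        rng = np.random.default_rng(self.seed)

        n_frozen = 1 if self.include_dc else 0
        atoms = np.empty((self.n_atoms, dim))
        if self.include_dc:
            atoms[0] = 1.0 / np.sqrt(dim)
        # initialize learnable atoms from distinct energetic training patches
        order = np.argsort(-norms)
        pool = order[: max(4 * self.n_atoms, self.n_atoms)]
        pick = rng.choice(pool.size, size=self.n_atoms - n_frozen, replace=False)
        init = X[pool[np.sort(pick)]]
        atoms[n_frozen:] = init / np.linalg.norm(init, axis=1, keepdims=True)
        for k in range(n_frozen, self.n_atoms):
            atoms[k] = _fix_atom_sign(atoms[k])

        errors = []
        for _ in range(self.n_iter):
            codes = _omp_batch(X, atoms, self.T0)  # (n_samples, K)
            recon = codes @ atoms
            for k in range(n_frozen, self.n_atoms):
                users = np.flatnonzero(codes[:, k])
                if users.size == 0:
                    resid_norms = np.linalg.norm(X - recon, axis=1)
                    worst = int(np.argmax(resid_norms))
                    atom = X[worst] / np.linalg.norm(X[worst])
                    atoms[k] = _fix_atom_sign(atom)
                    continue
                # residual without atom k's contribution, on its users
                E = X[users] - recon[users] + np.outer(codes[users, k], atoms[k])
                u, sv, vt = np.linalg.svd(E, full_matrices=False)
                atom = _fix_atom_sign(vt[0])
                sign = 1.0 if np.allclose(atom, vt[0]) else -1.0
                new_codes = sign * sv[0] * u[:, 0]
                recon[users] += np.outer(new_codes, atom) - np.outer(
                    codes[users, k], atoms[k]
                )
                atoms[k] = atom
                codes[users, k] = new_codes
            errors.append(float(np.mean(np.sum((X - codes @ atoms) ** 2, axis=1))))
        self.atoms_ = atoms
        self.errors_ = np.asarray(errors)
        self.n_features_in_ = dim
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """OMP codes of ``X`` against the learned atoms."""
        X = np.asarray(X, dtype=float)
        return _omp_batch(X, self.atoms_, self.T0)


def ksvd_train(
    patches: np.ndarray,
    K: int,
    T0: int,
    n_iter: int,
    seed: int = 0,
    *,
    m: int | None = None,
    channels: int = 1,
    include_dc: bool = True,
) -> Dictionary:
    """Train a :class:`Dictionary` with K-SVD (functional wrapper over KSVD).

    ``patches`` may be an (n, C, m, m) stack or a flat (n, C*m*m) matrix (in
    which case ``m`` must be given).
    """
    patches = np.asarray(patches, dtype=float)
    if patches.ndim == 4:
        _, channels, m, _ = patches.shape
        patches = patches.reshape(patches.shape[0], -1)
    elif m is None:
        raise ValueError("m is required for flat patch matrices")
    est = KSVD(n_atoms=K, T0=T0, n_iter=n_iter, include_dc=include_dc, seed=seed)
    est.fit(patches)
    return Dictionary(est.atoms_, m=m, channels=channels)


def sobel_gradient(img: np.ndarray) -> np.ndarray:
    """Two-channel Sobel derivative field of an image, reflect-padded.

    Returns shape (2, n, n): channel 0 is the X (column-axis) derivative,
    channel 1 the Y (row-axis) derivative, with the standard 3x3 kernels (a
    unit ramp along X yields a constant X response of 8 x slope).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("image must be 2-D with side >= 3")
    gx = ndi.sobel(img, axis=1, mode="reflect")
    gy = ndi.sobel(img, axis=0, mode="reflect")
    return np.stack([gx, gy])


def build_training_set(
    imgs: list[np.ndarray],
    lat_params: tuple[int, int],
    vectorial: bool = False,
    var_tol: float = 1e-10,
) -> np.ndarray:
    """Assemble the K-SVD training patch stack from training images.

    ``lat_params`` is (m, s) for the extraction lattice.  In vectorial mode
    each image is Sobel-filtered first and the two derivative channels are
    stacked per patch (flat length 2*m*m).  Near-constant patches (variance
    below ``var_tol`` in every channel) are dropped.
    """
    from .patches import build_lattice, extract_patches

    if not imgs:
        raise ValueError("need at least one training image")
    m, s = lat_params
    channels = 2 if vectorial else 1
    stacks = []
    for img in imgs:
        img = np.asarray(img, dtype=float)
        lat = build_lattice(img.shape[0], m, s, channels)
        data = sobel_gradient(img) if vectorial else img
        stacks.append(extract_patches(data, lat))
    stack = np.concatenate(stacks, axis=0)
    flat = stack.reshape(stack.shape[0], -1)
    variances = flat.var(axis=1)
    kept = flat[variances > var_tol]
    if kept.shape[0] == 0:
        raise ValueError("all training patches were filtered out (near-constant)")
    return kept


def atom_mosaic(dictionary: Dictionary, n_cols: int = 10, pad: int = 1) -> np.ndarray:
    """Grid image of atoms for inspection; vectorial atoms are drawn as the X
    half stacked over the Y half."""
    m, c = dictionary.m, dictionary.channels
    tiles = dictionary.atoms.reshape(-1, c, m, m)
    tiles = tiles.reshape(-1, c * m, m)  # stack channels vertically
    k = tiles.shape[0]
    n_rows = -(-k // n_cols)
    h, w = c * m + pad, m + pad
    out = np.full((n_rows * h + pad, n_cols * w + pad), np.nan)
    for i in range(k):
        r, cc = divmod(i, n_cols)
        t = tiles[i]
        lo, hi = t.min(), t.max()
        t = (t - lo) / (hi - lo) if hi > lo else np.zeros_like(t)
        out[pad + r * h : pad + r * h + c * m, pad + cc * w : pad + cc * w + m] = t
    return np.nan_to_num(out, nan=1.0)
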