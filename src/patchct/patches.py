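"""Overlapping patch lattice, core maps and solution composition.

The patch system is a base non-overlapping m x m tiling of the image plus all
its translates by (i*s, j*s) for 0 <= i, j < m/s, keeping only translates that
fall fully inside the image.  Every pixel is covered by at least one patch
(the base tiling) and, away from the borders, by exactly (m/s)**2 patches.

Each pixel is assigned to the patch whose center is nearest (its *core*
patch); the core indicators partition the image exactly, and the global
solution is composed by reading, at every pixel, the value of its core
patch's linear combination of dictionary atoms.  The overlap residual — the
disagreement between every covering patch and the composed solution — is the
quantity the similarity term of the reconstruction functional penalizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatchLattice",
    "CoreMap",
    "build_lattice",
    "core_map",
    "compose_patch",
    "compose_solution",
    "overlap_residual",
    "extract_patches",
]


@dataclass
class PatchLattice:
    """Overlapping patch system over a square image.

    ``corners`` is an (n_patches, 2) array of (row, col) patch corners in a
    fixed deterministic order: the base tiling row-major, then the translate
    offsets (i, j) in lexicographic order, each again row-major.
    """

    image_side: int
    m: int
    s: int
    channels: int
    corners: np.ndarray

    @property
    def n_patches(self) -> int:
        return int(self.corners.shape[0])

    @property
    def patch_dim(self) -> int:
        """Flattened patch length m*m*channels."""
        return self.m * self.m * self.channels

    def pixel_indices(self) -> np.ndarray:
        """(n_patches, m, m) flat image indices of every patch pixel."""
        rr = self.corners[:, 0, None, None] + np.arange(self.m)[None, :, None]
        cc = self.corners[:, 1, None, None] + np.arange(self.m)[None, None, :]
        return rr * self.image_side + cc


@dataclass
class CoreMap:
    """Per-pixel nearest-center patch assignment (the core partition).

    ``pixel_patch[y, x]`` is the index of the patch whose center is nearest to
    pixel (y, x) (ties broken by lowest patch index); ``local_row``/``local_col``
    are the pixel's coordinates inside that patch.  ``flat_core`` indexes a
    flattened (n_patches, m, m) patch stack so that gathering/scattering the
    composed solution is a single fancy-indexing operation.
    """

    lattice: PatchLattice
    pixel_patch: np.ndarray
    local_row: np.ndarray
    local_col: np.ndarray
    flat_core: np.ndarray = field(repr=False)


def build_lattice(image_side: int, m: int, s: int, channels: int = 1) -> PatchLattice:
    """Build the overlapping patch lattice (base tiling plus clipped translates)."""
    if channels not in (1, 2):
        raise ValueError("channels must be 1 or 2")
    if m < 1 or s < 1 or s > m:
        raise ValueError("require 1 <= s <= m")
    if image_side % m != 0:
        raise ValueError(f"patch side m={m} must divide image_side={image_side}")
    if m % s != 0:
        raise ValueError(f"step s={s} must divide m={m}")
    base = np.arange(0, image_side, m)
    corners = []
    for i in range(m // s):
        for j in range(m // s):
            rows = base + i * s
            cols = base + j * s
            rows = rows[rows + m <= image_side]
            cols = cols[cols + m <= image_side]
            rr, cc = np.meshgrid(rows, cols, indexing="ij")
            corners.append(np.stack([rr.ravel(), cc.ravel()], axis=1))
    corners = np.concatenate(corners, axis=0)
    lat = PatchLattice(image_side, m, s, channels, corners)
    # base tiling alone already covers every pixel
    return lat


def core_map(lat: PatchLattice) -> CoreMap:
    """Assign every pixel to its nearest patch center (lowest index on ties)."""
    n = lat.image_side
    centers = lat.corners + (lat.m - 1) / 2.0  # (N, 2)
    ys, xs = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    pts = np.stack([ys.ravel(), xs.ravel()], axis=1).astype(float)
    # exact squared distances (all quantities are multiples of 0.5, so ties
    # are exact in floating point and argmin's first-occurrence rule gives the
    # lowest patch index)
    best_idx = np.empty(n * n, dtype=np.int64)
    best_d = np.full(n * n, np.inf)
    chunk = 256
    for p0 in range(0, lat.n_patches, chunk):
        c = centers[p0 : p0 + chunk]
        d = (
            np.square(pts[:, 0:1] - c[None, :, 0])
            + np.square(pts[:, 1:2] - c[None, :, 1])
        )
        idx = np.argmin(d, axis=1)
        dmin = d[np.arange(d.shape[0]), idx]
        better = dmin < best_d
        best_idx[better] = idx[better] + p0
        best_d[better] = dmin[better]
    pixel_patch = best_idx.reshape(n, n)
    local_row = ys - lat.corners[pixel_patch, 0]
    local_col = xs - lat.corners[pixel_patch, 1]
    if np.any(local_row < 0) or np.any(local_row >= lat.m) or np.any(
        local_col < 0
    ) or np.any(local_col >= lat.m):
        raise RuntimeError("core assignment fell outside its patch support")
    flat_core = (pixel_patch * lat.m + local_row) * lat.m + local_col
    return CoreMap(lat, pixel_patch, local_row, local_col, flat_core.ravel())


def compose_patch(coeffs_p: np.ndarray, dictionary) -> np.ndarray:
    """Linear combination of atoms for one patch -> (C, m, m) values."""
    coeffs_p = np.asarray(coeffs_p, dtype=float)
    if coeffs_p.shape != (dictionary.n_atoms,):
        raise ValueError(
            f"coefficient length {coeffs_p.shape} does not match K={dictionary.n_atoms}"
        )
    m, c = dictionary.m, dictionary.channels
    return (coeffs_p @ dictionary.atoms).reshape(c, m, m)


def compose_patches(coeffs: np.ndarray, lat: PatchLattice, dictionary) -> np.ndarray:
    """All patches at once -> (n_patches, C, m, m) stack."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (lat.n_patches, dictionary.n_atoms):
        raise ValueError(
            f"coefficients shape {coeffs.shape}, expected "
            f"({lat.n_patches}, {dictionary.n_atoms})"
        )
    if dictionary.channels != lat.channels or dictionary.m != lat.m:
        raise ValueError("dictionary patch shape does not match lattice")
    return (coeffs @ dictionary.atoms).reshape(
        lat.n_patches, lat.channels, lat.m, lat.m
    )


def gather_solution(patch_stack: np.ndarray, core: CoreMap) -> np.ndarray:
    """Compose the global solution from a (N, C, m, m) stack via core lookup."""
    lat = core.lattice
    n = lat.image_side
    out = np.empty((lat.channels, n, n))
    for c in range(lat.channels):
        out[c] = patch_stack[:, c].reshape(-1)[core.flat_core].reshape(n, n)
    return out


def scatter_core(img: np.ndarray, core: CoreMap) -> np.ndarray:
    """Adjoint of :func:`gather_solution`: image -> (N, C, m, m) stack."""
    lat = core.lattice
    img = img.reshape(lat.channels, -1)
    out = np.zeros((lat.n_patches, lat.channels, lat.m, lat.m))
    for c in range(lat.channels):
        flat = out[:, c].reshape(-1)
        flat[core.flat_core] = img[c]
        out[:, c] = flat.reshape(lat.n_patches, lat.m, lat.m)
    return out


def compose_solution(
    coeffs: np.ndarray, lat: PatchLattice, core: CoreMap, dictionary
) -> np.ndarray:
    """Global solution: every pixel takes its core patch's composed value.

    Returns (image_side, image_side) for single-channel lattices and
    (2, image_side, image_side) for vectorial ones.
    """
    stack = compose_patches(coeffs, lat, dictionary)
    sol = gather_solution(stack, core)
    return sol[0] if lat.channels == 1 else sol


def extract_patches(img: np.ndarray, lat: PatchLattice) -> np.ndarray:
    """Extract the (n_patches, C, m, m) stack of raw patches from an image."""
    img = np.asarray(img, dtype=float)
    if lat.channels == 1 and img.shape == (lat.image_side, lat.image_side):
        img = img[None]
    if img.shape != (lat.channels, lat.image_side, lat.image_side):
        raise ValueError(
            f"image shape {img.shape} does not match lattice "
            f"({lat.channels}, {lat.image_side}, {lat.image_side})"
        )
    idx = lat.pixel_indices()
    out = np.empty((lat.n_patches, lat.channels, lat.m, lat.m))
    for c in range(lat.channels):
        out[:, c] = img[c].ravel()[idx]
    return out


def scatter_patches(stack: np.ndarray, lat: PatchLattice) -> np.ndarray:
    """Adjoint of :func:`extract_patches`: sum patches back onto the grid."""
    n = lat.image_side
    idx = lat.pixel_indices().ravel()
    out = np.empty((lat.channels, n, n))
    for c in range(lat.channels):
        out[c] = np.bincount(idx, weights=stack[:, c].ravel(), minlength=n * n).reshape(
            n, n
        )
    return out


def overlap_residual(
    coeffs: np.ndarray, lat: PatchLattice, core: CoreMap, dictionary
) -> np.ndarray:
    """Per-patch, per-pixel disagreement with the composed solution.

    Element (p, c, u, v) is (composed patch p at its pixel (u, v)) minus (the
    global solution at that pixel).  Its squared sum is the similarity term of
    the reconstruction functional; it vanishes identically when s = m.
    """
    stack = compose_patches(coeffs, lat, dictionary)
    sol = gather_solution(stack, core)
    return stack - extract_patches(sol, lat)
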