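"""Seeded generators for every input the package's experiments need.

Reconstruction phantoms are deliberately *textured* — smooth random
backgrounds, soft-edged ellipses, oriented line textures and mild shading —
because a piecewise-constant target (Shepp–Logan style) plays to the
strengths of gradient-sparsity priors and does not resemble the continuous
grey-level structure of phase-contrast medical images.  Training images come
from the same family with an independent seed, so the dictionary is never
trained on the image it reconstructs.

The noise model is scaled Poisson: with g = f^2 * max(sinogram), each sample
s is replaced by g * Poisson(s / g), which gives a relative standard
deviation of exactly f at the maximum-valued bin (the "f of the maximal
sinogram value" convention).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import scipy.ndimage as ndi

from .geometry import ProjectionGeometry, Sinogram, default_detector_width

__all__ = [
    "PhantomSpec",
    "BenchmarkCase",
    "generate_phantom",
    "generate_training_image",
    "add_poisson_noise",
    "make_vector_phantom",
    "benchmark_case",
]

_KINDS = ("textured", "blob", "lines")


@dataclass(frozen=True)
class PhantomSpec:
    """Deterministic phantom description: side (pixels), seed, and kind."""

    side: int = 128
    seed: int = 0
    kind: str = "textured"

    def __post_init__(self) -> None:
        if self.side < 32:
            raise ValueError("phantom side must be >= 32")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}")


def _coords(n: int) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    return (y - n / 2.0) / n, (x - n / 2.0) / n


def _soft_ellipses(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    yy, xx = _coords(n)
    out = np.zeros((n, n))
    for _ in range(count):
        cy, cx = rng.uniform(-0.40, 0.40, size=2)
        ay, ax = rng.uniform(0.025, 0.09, size=2)
        th = rng.uniform(0.0, np.pi)
        amp = rng.uniform(0.07, 0.18) * rng.choice([-1.0, 1.0])
        u = (yy - cy) * np.cos(th) + (xx - cx) * np.sin(th)
        v = -(yy - cy) * np.sin(th) + (xx - cx) * np.cos(th)
        q = (u / ay) ** 2 + (v / ax) ** 2
        edge = rng.uniform(0.05, 0.12)
        out += amp / (1.0 + np.exp(np.clip((q - 1.0) / edge, -60.0, 60.0)))
    return out


def _line_textures(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    yy, xx = _coords(n)
    out = np.zeros((n, n))
    for _ in range(count):
        phi = rng.uniform(0.0, np.pi)
        freq = rng.uniform(8.0, 28.0) * 2.0 * np.pi
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = rng.uniform(0.04, 0.09)
        cy, cx = rng.uniform(-0.35, 0.35, size=2)
        sigma = rng.uniform(0.05, 0.11)
        env = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
        out += amp * env * np.sin(freq * (xx * np.cos(phi) + yy * np.sin(phi)) + phase)
    return out


def _thin_bars(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    yy, xx = _coords(n)
    out = np.zeros((n, n))
    for _ in range(count):
        phi = rng.uniform(0.0, np.pi)
        cy, cx = rng.uniform(-0.34, 0.34, size=2)
        length = rng.uniform(0.06, 0.2)
        width = rng.uniform(0.008, 0.018)
        amp = rng.uniform(0.10, 0.24) * rng.choice([-1.0, 1.0])
        u = (yy - cy) * np.cos(phi) + (xx - cx) * np.sin(phi)
        v = -(yy - cy) * np.sin(phi) + (xx - cx) * np.cos(phi)
        out += amp * np.exp(-0.5 * (u / width) ** 2) * np.exp(-0.5 * (v / length) ** 2)
    return out


def _dots(rng: np.random.Generator, n: int, count: int) -> np.ndarray:
    yy, xx = _coords(n)
    out = np.zeros((n, n))
    for _ in range(count):
        cy, cx = rng.uniform(-0.44, 0.44, size=2)
        sigma = rng.uniform(0.007, 0.016)
        amp = rng.uniform(0.10, 0.24) * rng.choice([-1.0, 1.0])
        out += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))
    return out


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic textured (or blob / line-texture) phantom in [0, 1].

    The textured family layers a smooth random background, many soft-edged
    ellipses, oriented sinusoidal gratings, thin high-contrast bars, small
    bright/dark dots (micro-calcification-like) and a mild shading ramp:
    continuous grey levels everywhere, plenty of structured fine detail, and
    nowhere piecewise constant.
    """
    n = spec.side
    rng = np.random.default_rng([spec.seed, _KINDS.index(spec.kind)])
    yy, xx = _coords(n)
    if spec.kind == "blob":
        img = 0.85 * np.exp(-(yy**2 + xx**2) / (2.0 * 0.18**2))
        img += 0.25 * np.exp(-((yy - 0.12) ** 2 + (xx + 0.1) ** 2) / (2.0 * 0.08**2))
        return np.clip(img, 0.0, 1.0)
    smooth = ndi.gaussian_filter(rng.standard_normal((n, n)), sigma=n / 28.0)
    smooth *= 0.07 / max(smooth.std(), 1e-12)
    img = 0.45 + smooth
    img += _soft_ellipses(rng, n, int(rng.integers(16, 25)))
    n_lines = int(rng.integers(8, 13)) if spec.kind == "lines" else int(rng.integers(5, 9))
    img += _line_textures(rng, n, n_lines)
    img += _thin_bars(rng, n, int(rng.integers(3, 7)))
    img += _dots(rng, n, int(rng.integers(6, 12)))
    # mild global shading
    gy, gx = rng.uniform(-0.06, 0.06, size=2)
    img += gy * yy + gx * xx
    return np.clip(img, 0.0, 1.0)


def generate_training_image(
    spec: PhantomSpec, phantom_seed: int | None = None
) -> np.ndarray:
    """Training image from the same family; refuses the phantom's own seed so
    the dictionary is always learnt from a different image."""
    if phantom_seed is not None and spec.seed == phantom_seed:
        raise ValueError(
            "training image seed equals the reconstruction phantom seed; "
            "the training image must be a different image"
        )
    return generate_phantom(spec)


def add_poisson_noise(sino: Sinogram, fraction: float, seed: int = 0) -> Sinogram:
    """Scaled-Poisson sinogram noise with relative std ``fraction`` at the
    maximum-valued bin; fraction 0 returns the input unchanged."""
    if fraction < 0:
        raise ValueError("noise fraction must be >= 0")
    vals = sino.values
    if np.any(vals < 0):
        raise ValueError("Poisson noise requires a non-negative sinogram")
    peak = float(vals.max())
    if fraction == 0.0 or peak == 0.0:
        return Sinogram(vals.copy(), sino.geometry)
    g = fraction**2 * peak
    rng = np.random.default_rng(seed)
    noisy = g * rng.poisson(vals / g).astype(float)
    return Sinogram(noisy, sino.geometry)


def make_vector_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """A phantom and its Sobel gradient field (the DPC ground truth pair)."""
    from .dictionary import sobel_gradient

    phantom = generate_phantom(spec)
    return phantom, sobel_gradient(phantom)


@dataclass(frozen=True)
class BenchmarkCase:
    """Fully parameterized, seeded experiment bundle.

    ``geometry`` is the (few-view) acquisition actually reconstructed from;
    for the DPC case ``dense_geometry`` is the full-view acquisition the
    few-view protocol subsamples (every ``subsample``-th view).
    """

    name: str
    phantom: PhantomSpec
    training: PhantomSpec
    n_views: int
    n_det: int
    noise_fraction: float = 0.0
    noise_seed: int = 0
    vectorial: bool = False
    dense_views: int = 0
    subsample: int = 1
    # patch system / dictionary
    m: int = 8
    step: int = 4
    train_step: int = 2
    n_atoms: int = 100
    T0: int = 5
    ksvd_iters: int = 5
    dict_seed: int = 0
    # solver defaults (calibrated once by the built-in parameter scan)
    lam: float = 2.0
    omega: float = 100.0
    n_iter: int = 400
    lam_grid: tuple = ()
    omega_grid: tuple = ()
    # functional-comparison protocol (strong coupling; see docs/methods.md)
    cmp_lam: float = 0.1
    cmp_omega: float = 1e4
    cmp_iters: int = 6000

    @property
    def geometry(self) -> ProjectionGeometry:
        angles = np.arange(self.n_views) * 180.0 / self.n_views
        return ProjectionGeometry(angles, self.n_det, self.phantom.side)

    @property
    def dense_geometry(self) -> ProjectionGeometry:
        if self.dense_views == 0:
            return self.geometry
        angles = np.arange(self.dense_views) * 180.0 / self.dense_views
        return ProjectionGeometry(angles, self.n_det, self.phantom.side)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BenchmarkCase":
        d = json.loads(text)
        d["phantom"] = PhantomSpec(**d["phantom"])
        d["training"] = PhantomSpec(**d["training"])
        d["lam_grid"] = tuple(d["lam_grid"])
        d["omega_grid"] = tuple(d["omega_grid"])
        return cls(**d)


_CASE_NAMES = ("lena80", "lena80_noisy", "dpc200")


def benchmark_case(name: str, seed: int = 0, side: int = 128) -> BenchmarkCase:
    """The three seeded benchmark protocols.

    * ``lena80``: textured phantom, 80 uniform views over [0, 180), no noise;
    * ``lena80_noisy``: same plus scaled-Poisson noise, f = 0.3% of the
      sinogram maximum;
    * ``dpc200``: vectorial gradient phantom, every 5th view of a 200-view
      acquisition.
    """
    if name not in _CASE_NAMES:
        raise ValueError(f"unknown benchmark {name!r}; choose from {_CASE_NAMES}")
    phantom = PhantomSpec(side=side, seed=seed * 1000 + 13)
    training = PhantomSpec(side=side, seed=seed * 1000 + 29)
    n_det = default_detector_width(side)
    common = dict(
        phantom=phantom,
        training=training,
        n_det=n_det,
        dict_seed=seed * 1000 + 41,
        noise_seed=seed * 1000 + 57,
    )
    if name == "dpc200":
        dense = 200
        sub = 5
        return BenchmarkCase(
            name=name,
            n_views=dense // sub,
            dense_views=dense,
            subsample=sub,
            vectorial=True,
            lam=0.5,
            omega=100.0,
            n_iter=800,
            **common,
        )
    noise = 0.003 if name == "lena80_noisy" else 0.0
    return BenchmarkCase(
        name=name,
        n_views=80,
        noise_fraction=noise,
        lam=0.1,
        omega=10.0,
        n_iter=3000,
        lam_grid=(0.02, 0.1, 0.5),
        omega_grid=(10.0, 100.0, 1000.0),
        **common,
    )
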