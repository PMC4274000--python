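"""File formats: HDF5 and 32-bit TIFF for images/sinograms, HDF5 for
dictionaries and coefficient sets, CSV for solver traces, TOML for solver
configuration."""

from __future__ import annotations

import tomllib
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .dictionary import Dictionary
from .geometry import ProjectionGeometry, Sinogram
from .patches import PatchLattice
from .solvers import SolverParams, SolverTrace

__all__ = [
    "save_image", "load_image",
    "save_sinogram", "load_sinogram",
    "save_dictionary", "load_dictionary",
    "save_coeffs", "load_coeffs",
    "save_vector_image", "load_vector_image",
    "save_trace_csv", "load_solver_config",
]


def save_image(path, img: np.ndarray, **attrs) -> None:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(img, dtype=np.float32))
        return
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("image", data=np.asarray(img, dtype=np.float64))
        for k, v in attrs.items():
            ds.attrs[k] = v


def load_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    with h5py.File(path, "r") as f:
        return np.asarray(f["image"][()], dtype=float)


def save_sinogram(path, sino: Sinogram) -> None:
    g = sino.geometry
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("sinogram", data=sino.values)
        f.create_dataset("angles", data=g.angles)
        ds.attrs["n_det"] = g.n_det
        ds.attrs["image_side"] = g.image_side
        ds.attrs["pixel_size"] = g.pixel_size


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as f:
        ds = f["sinogram"]
        geom = ProjectionGeometry(
            np.asarray(f["angles"][()]),
            int(ds.attrs["n_det"]),
            int(ds.attrs["image_side"]),
            float(ds.attrs["pixel_size"]),
        )
        return Sinogram(np.asarray(ds[()]), geom)


def save_dictionary(path, d: Dictionary) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("atoms", data=d.atoms)
        ds.attrs["m"] = d.m
        ds.attrs["C"] = d.channels
        ds.attrs["K"] = d.n_atoms


def load_dictionary(path) -> Dictionary:
    with h5py.File(path, "r") as f:
        ds = f["atoms"]
        return Dictionary(np.asarray(ds[()]), int(ds.attrs["m"]), int(ds.attrs["C"]))


def save_coeffs(path, coeffs: np.ndarray, lat: PatchLattice) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("coeffs", data=np.asarray(coeffs))
        ds.attrs["image_side"] = lat.image_side
        ds.attrs["m"] = lat.m
        ds.attrs["s"] = lat.s
        ds.attrs["C"] = lat.channels


def load_coeffs(path) -> tuple[np.ndarray, PatchLattice]:
    from .patches import build_lattice

    with h5py.File(path, "r") as f:
        ds = f["coeffs"]
        lat = build_lattice(
            int(ds.attrs["image_side"]), int(ds.attrs["m"]), int(ds.attrs["s"]),
            int(ds.attrs["C"]),
        )
        return np.asarray(ds[()]), lat


def save_vector_image(path, vimg: np.ndarray) -> None:
    path = Path(path)
    vimg = np.asarray(vimg)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, vimg.astype(np.float32))  # 2-page stack
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("grad_x", data=vimg[0])
        f.create_dataset("grad_y", data=vimg[1])


def load_vector_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=float)
    with h5py.File(path, "r") as f:
        return np.stack(
            [np.asarray(f["grad_x"][()]), np.asarray(f["grad_y"][()])]
        ).astype(float)


def save_trace_csv(path, trace: SolverTrace) -> None:
    arr = np.column_stack([np.arange(len(trace.objectives)), trace.objectives])
    np.savetxt(path, arr, delimiter=",", header="iteration,objective", comments="")


def load_solver_config(path) -> SolverParams:
    """Read a ``[solver]`` TOML table into :class:`SolverParams`."""
    with open(path, "rb") as f:
        cfg = tomllib.load(f).get("solver", {})
    return SolverParams(
        lambda_sparsity=float(cfg.get("lambda", 0.0)),
        omega_overlap=float(cfg.get("omega", 0.0)),
        n_iter=int(cfg.get("iters", 100)),
        step_tau=float(cfg.get("tau", 0.0)),
        seed=int(cfg.get("seed", 0)),
        mode=str(cfg.get("mode", "tomography")),
        tol=float(cfg.get("tol", 0.0)),
    )


def save_atom_mosaic(path, dictionary: Dictionary, n_cols: int = 10) -> None:
    """Export the dictionary's atom grid as an 8-bit PNG for inspection
    (vectorial atoms are drawn as the X half stacked over the Y half)."""
    from PIL import Image as PILImage

    from .dictionary import atom_mosaic

    mosaic = atom_mosaic(dictionary, n_cols=n_cols)
    PILImage.fromarray((255 * mosaic).astype("uint8")).save(path)
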