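"""Image-quality scoring: SSIM, the FBP-relative improvement factor Q, and
the regularization-parameter scan."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

__all__ = ["QualityReport", "ssim", "improvement_factor", "parameter_scan"]


@dataclass
class QualityReport:
    """SSIM of a method and of FBP against ground truth, and the Q factor.

    For vectorial reconstructions the fields hold per-channel arrays.
    """

    ssim_method: float | np.ndarray
    ssim_fbp: float | np.ndarray
    q_factor: float | np.ndarray

    def __post_init__(self) -> None:
        for v in (self.ssim_method, self.ssim_fbp):
            if np.any(np.asarray(v) > 1.0 + 1e-12) or np.any(np.asarray(v) < -1.0):
                raise ValueError("SSIM values must lie in [-1, 1]")


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None) -> float:
    """Mean local SSIM with the reference configuration of Wang et al.:
    11x11 Gaussian window (sigma 1.5), K1 = 0.01, K2 = 0.03.

    ``data_range`` defaults to the dynamic range of ``b`` (the reference).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if data_range is None:
        data_range = float(b.max() - b.min())
        if data_range == 0.0:
            data_range = 1.0
    return float(
        structural_similarity(
            a,
            b,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def improvement_factor(
    rec: np.ndarray, fbp_rec: np.ndarray, exact: np.ndarray,
    data_range: float | None = None,
) -> float:
    """Normalized SSIM gain over FBP:

        Q = (SSIM(rec, exact) - SSIM(fbp, exact)) / (1 - SSIM(fbp, exact))

    Q = 0 means no improvement over FBP, Q = 1 a perfect reconstruction;
    returns 0 when the FBP reconstruction is already exact.
    """
    s_rec = ssim(rec, exact, data_range)
    s_fbp = ssim(fbp_rec, exact, data_range)
    if s_fbp >= 1.0:
        return 0.0
    return (s_rec - s_fbp) / (1.0 - s_fbp)


def parameter_scan(
    data, dictionary, lat, core, grid, exact: np.ndarray, fbp_rec: np.ndarray,
    params_template=None, data_range: float | None = None,
) -> pd.DataFrame:
    """One reconstruction and Q per (lambda, omega) grid point.

    ``grid`` is an iterable of (lambda, omega) pairs.  Returns a DataFrame
    with columns lam, omega, ssim, q, sorted in grid order, with the best row
    (max q, first on ties) flagged in the ``best`` column.
    """
    from dataclasses import replace

    from .solvers import SolverParams, fista_solve

    grid = list(grid)
    if not grid:
        raise ValueError("parameter grid is empty")
    if params_template is None:
        params_template = SolverParams()
    rows = []
    for lam, omega in grid:
        p = replace(params_template, lambda_sparsity=lam, omega_overlap=omega)
        trace = fista_solve(data, dictionary, lat, core, p)
        rows.append(
            {
                "lam": lam,
                "omega": omega,
                "ssim": ssim(trace.solution, exact, data_range),
                "q": improvement_factor(trace.solution, fbp_rec, exact, data_range),
            }
        )
    table = pd.DataFrame(rows)
    table["best"] = False
    table.loc[table["q"].idxmax(), "best"] = True
    return table
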