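"""First-level GLM estimation.

Fits the time-series model voxel-wise with AR(1) prewhitening: an OLS pass
estimates a single pooled lag-1 residual autocorrelation over in-mask voxels
(one Cochrane-Orcutt refinement), data and design are whitened with the
exact AR(1) square-root (including the sqrt(1 - rho^2) first row), and a
second OLS pass yields the betas.  Contrast images -- the unit flowing into
every group analysis -- are weighted beta combinations, optionally on the
standardized-beta (correlation) scale.

Also provides the isotropic Gaussian smoothing applied to the volumes
before model fitting (default 8 mm FWHM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .design import DesignMatrix

__all__ = [
    "BoldRun",
    "GLMFit",
    "ContrastImage",
    "smooth_gaussian",
    "fit_first_level",
    "compute_contrast",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BoldRun:
    """A single subject's 4-D run: (x, y, z, t) data, TR, and a brain mask."""

    data: np.ndarray
    tr: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    motion: np.ndarray | None = None
    subject_id: str | int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4-D (x, y, z, t)")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must equal the spatial shape")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class GLMFit:
    """Whitened-OLS estimates for one run.

    ``betas`` is voxels x regressors (in-mask voxels, mask order given by
    ``np.flatnonzero(mask)``); ``dof`` = T - rank(X), the whitening
    transform being square and invertible.
    """

    betas: np.ndarray
    residual_variance: np.ndarray
    dof: int
    rho: float
    mask: np.ndarray
    column_names: list[str]
    design_sd: np.ndarray  # per-column SD of the unwhitened design
    data_sd: np.ndarray  # per-voxel SD of the unwhitened time series
    tr: float


@dataclass
class ContrastImage:
    """Per-subject 3-D map of a named contrast; NaN outside the mask."""

    name: str
    values: np.ndarray
    subject_id: str | int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("contrast image must be 3-D")


def smooth_gaussian(
    volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float | tuple = 1.0
) -> np.ndarray:
    """Separable isotropic Gaussian smoothing (reflecting boundary).

    ``sigma = fwhm / (2 sqrt(2 ln 2))`` per axis, converted to voxel units;
    a 4-D input is smoothed volume by volume (no temporal smoothing).
    ``fwhm_mm = 0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    vox = np.broadcast_to(np.atleast_1d(np.asarray(voxel_size_mm, float)), (3,))
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vox
    arr = np.asarray(volume, dtype=float)
    if arr.ndim == 3:
        return gaussian_filter(arr, sigma=sigma_vox, mode="reflect")
    if arr.ndim == 4:
        return gaussian_filter(arr, sigma=(*sigma_vox, 0.0), mode="reflect")
    raise ValueError("expected a 3-D or 4-D volume")


def _ar1_whitening_matrix(n: int, rho: float) -> np.ndarray:
    """Exact AR(1) square-root inverse: W such that W Sigma W' = I (up to scale)."""
    w = np.eye(n)
    w[0, 0] = np.sqrt(1.0 - rho**2)
    idx = np.arange(1, n)
    w[idx, idx - 1] = -rho
    return w


def _check_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name a culprit column for the error message
        culprits = []
        keep: list[int] = []
        for j in range(x.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(x[:, trial]) == len(trial):
                keep.append(j)
            else:
                culprits.append(names[j])
        raise np.linalg.LinAlgError(
            f"design is rank deficient; dependent columns: {culprits}"
        )


def fit_first_level(run: BoldRun, x: DesignMatrix) -> GLMFit:
    """Two-pass prewhitened OLS over in-mask voxels.

    Pass 1: plain OLS; pool the lag-1 residual autocorrelation across all
    in-mask voxels into a single rho.  Pass 2: whiten data and design with
    the exact AR(1) transform and refit.  Raises on TR or length mismatch
    and on rank-deficient designs (naming the dependent columns).
    """
    if not np.isclose(run.tr, x.tr):
        raise ValueError(f"TR mismatch: run {run.tr} vs design {x.tr}")
    t = run.n_volumes
    if t != x.n_volumes:
        raise ValueError(f"volume count mismatch: run {t} vs design {x.n_volumes}")
    xm = x.values
    if t < xm.shape[1] + 10:
        raise ValueError("too few volumes for the design (need >= P + 10)")
    _check_rank(xm, x.column_names)

    flat = run.data.reshape(-1, t)
    vox_idx = np.flatnonzero(run.mask.ravel())
    y = flat[vox_idx].T.astype(float)  # T x V

    pinv = np.linalg.pinv(xm)
    resid = y - xm @ (pinv @ y)
    num = float(np.sum(resid[1:] * resid[:-1]))
    den = float(np.sum(resid * resid))
    rho = 0.0 if den == 0.0 else num / den
    rho = float(np.clip(rho, -0.99, 0.99))

    w = _ar1_whitening_matrix(t, rho)
    wy = w @ y
    wx = w @ xm
    pinv_w = np.linalg.pinv(wx)
    betas = pinv_w @ wy  # P x V
    wresid = wy - wx @ betas
    dof = t - np.linalg.matrix_rank(xm)
    sigma2 = np.sum(wresid**2, axis=0) / dof

    return GLMFit(
        betas=betas.T,
        residual_variance=sigma2,
        dof=dof,
        rho=rho,
        mask=run.mask,
        column_names=list(x.column_names),
        design_sd=xm.std(axis=0, ddof=0),
        data_sd=y.std(axis=0, ddof=0),
        tr=run.tr,
    )


def compute_contrast(
    fit: GLMFit,
    weights: dict[str, float],
    name: str | None = None,
    standardized: bool = False,
    subject_id: str | int | None = None,
) -> ContrastImage:
    """Weighted beta combination per voxel as a 3-D map.

    With ``standardized=True`` each beta is rescaled to the model with
    z-scored regressors and z-scored data (``beta * sd(x_j) / sd(y)``), the
    correlation-scale coefficient; useful for the responsivity measure.
    Unknown column names raise a KeyError.
    """
    unknown = set(weights) - set(fit.column_names)
    if unknown:
        raise KeyError(f"unknown design columns in contrast: {sorted(unknown)}")
    vol = np.full(fit.mask.shape, np.nan)
    acc = np.zeros(fit.betas.shape[0])
    for col, wgt in weights.items():
        j = fit.column_names.index(col)
        b = fit.betas[:, j]
        if standardized:
            sd_y = np.where(fit.data_sd > 0, fit.data_sd, np.inf)
            b = b * fit.design_sd[j] / sd_y
        acc += wgt * b
    vol[fit.mask] = acc
    if name is None:
        name = "+".join(f"{w:+g}*{c}" for c, w in weights.items())
    return ContrastImage(name=name, values=vol, subject_id=subject_id)
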