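"""BOLD preprocessing and seed time-series extraction.

Implements the last two preprocessing steps applied before targeting —
high-pass temporal filtering above 0.01 Hz and minimal 4-mm-FWHM Gaussian
spatial smoothing — plus the two seed extraction rules: the plain mask
average (DLPFC series) and the seedmap-weighted gray-matter average used
to estimate the small pregenual-cingulate seed with better signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, InvalidParameterError, ZeroVarianceError
from .volumes import ScalarVolume, VolumeMask, VoxelGrid, _check_same_grid

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class BoldSeries:
    """A T x V time-by-voxel matrix bound to a grid.

    Voxels follow the C-order flattening of the grid; ``tr`` is the
    repetition time in seconds.
    """

    grid: VoxelGrid
    data: np.ndarray  # (T, V)
    tr: float

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.tr <= 0:
            raise InvalidParameterError(f"tr must be > 0 s, got {self.tr}")
        if self.data.shape[0] < 2:
            raise InvalidParameterError("a BoldSeries needs at least 2 frames")
        if self.data.shape[1] != self.grid.n_voxels:
            raise InvalidParameterError(
                f"data has {self.data.shape[1]} voxels, grid has {self.grid.n_voxels}"
            )
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("BoldSeries values must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr)


@dataclass
class SeedSeries:
    """A single extracted time course."""

    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("SeedSeries values must be finite")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Temporal filtering


def _dct_basis(n_frames: int, tr: float, cutoff_hz: float) -> np.ndarray:
    """Unit-norm DCT-II regressors with frequencies at or below the cutoff.

    Basis k has frequency k / (2 * T * tr); removing these together with the
    mean implements a deterministic, edge-safe high-pass filter.
    """
    t = np.arange(n_frames)
    k_max = int(np.floor(2.0 * n_frames * tr * cutoff_hz))
    cols = [np.ones(n_frames) / np.sqrt(n_frames)]
    for k in range(1, k_max + 1):
        b = np.cos(np.pi * k * (t + 0.5) / n_frames)
        cols.append(b / np.linalg.norm(b))
    return np.column_stack(cols)


def highpass(series: BoldSeries, cutoff_hz: float = 0.01) -> BoldSeries:
    """Remove the mean and all fluctuations slower than ``cutoff_hz``.

    Implemented as regression on a discrete-cosine low-frequency basis;
    the per-voxel mean is always removed.
    """
    if cutoff_hz >= series.nyquist_hz:
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz >= Nyquist {series.nyquist_hz} Hz"
        )
    if cutoff_hz < 0:
        raise InvalidParameterError("cutoff must be non-negative")
    data = np.asarray(series.data)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(float)
    basis = _dct_basis(series.n_frames, series.tr, cutoff_hz).astype(data.dtype)
    filtered = data - basis @ (basis.T @ data)
    return BoldSeries(grid=series.grid, data=filtered, tr=series.tr)


# ---------------------------------------------------------------------------
# Spatial smoothing


def _smooth_3d(vol: np.ndarray, grid: VoxelGrid, fwhm_mm: float) -> np.ndarray:
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / grid.voxel_size
    return ndimage.gaussian_filter(vol, sigma=sigma_vox, mode="constant", truncate=6.0)


def smooth_gaussian(obj, fwhm_mm: float):
    """Isotropic Gaussian smoothing with kernel width given as FWHM in mm.

    sigma = FWHM / (2 sqrt(2 ln 2)), converted to voxel units per axis.
    FWHM 0 is the identity.  The discrete kernel is normalised, so the total
    image sum is conserved wherever the kernel support stays inside the
    volume.
    """
    if fwhm_mm < 0:
        raise InvalidParameterError("FWHM must be >= 0")
    if fwhm_mm == 0:
        return obj
    if isinstance(obj, ScalarVolume):
        return ScalarVolume(obj.grid, _smooth_3d(obj.value, obj.grid, fwhm_mm))
    if isinstance(obj, BoldSeries):
        sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / obj.grid.voxel_size
        vol4d = np.asarray(obj.data).reshape(obj.n_frames, *obj.grid.shape)
        out = ndimage.gaussian_filter(
            vol4d, sigma=(0.0, *sigma_vox), mode="constant", truncate=6.0
        )
        return BoldSeries(grid=obj.grid, data=out.reshape(obj.n_frames, -1), tr=obj.tr)
    raise TypeError(f"cannot smooth object of type {type(obj).__name__}")


# ---------------------------------------------------------------------------
# Series extraction


def mean_series(series: BoldSeries, mask: VolumeMask, label: str = "") -> SeedSeries:
    """Unweighted per-frame mean over mask member voxels."""
    _check_same_grid(series.grid, mask.grid)
    idx = mask.linear_indices()
    if idx.size == 0:
        raise EmptyMaskError("mean_series requires a non-empty mask")
    return SeedSeries(np.asarray(series.data[:, idx], dtype=float).mean(axis=1), label)


def seedmap_series(
    series: BoldSeries,
    weights: ScalarVolume,
    include: VolumeMask,
    exclude: VolumeMask | None = None,
    label: str = "seedmap",
) -> SeedSeries:
    """Connectivity-weighted spatial average over include-minus-exclude voxels.

    output(t) = sum_v w_v x_v(t) / sum_v |w_v|.  Weights keep their sign;
    normalising by the absolute-weight sum keeps the output scale stable
    when the weight map carries mixed signs.
    """
    _check_same_grid(series.grid, weights.grid)
    effective = include if exclude is None else include.minus(exclude)
    idx = effective.linear_indices()
    if idx.size == 0:
        raise EmptyMaskError("no voxels remain after exclusion")
    w = weights.flat[idx]
    denom = np.sum(np.abs(w))
    if denom == 0:
        raise ZeroVarianceError("all effective seedmap weights are zero")
    values = np.asarray(series.data[:, idx], dtype=float) @ w / denom
    return SeedSeries(values, label)


def pearson_r(a: SeedSeries, b: SeedSeries) -> float:
    """Product-moment correlation of two equal-length series."""
    x = np.asarray(a.values, dtype=float)
    y = np.asarray(b.values, dtype=float)
    if len(x) != len(y):
        raise InvalidParameterError("series lengths differ")
    if len(x) < 3:
        raise InvalidParameterError("need at least 3 samples")
    x = x - x.mean()
    y = y - y.mean()
    sx = np.sqrt(np.sum(x * x))
    sy = np.sqrt(np.sum(y * y))
    if sx == 0 or sy == 0:
        raise ZeroVarianceError("correlation of a constant series is undefined")
    return float(np.clip(np.sum(x * y) / (sx * sy), -1.0, 1.0))


def fisher_z(r: float) -> float:
    """Fisher z-transform, arctanh(r), clipped just inside (-1, 1)."""
    return float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)))
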