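"""Voxelwise DLPFC–PGC connectivity mapping and stimulation-target selection.

The personalised target is found by correlating every voxel in the DLPFC
search mask with the PGC seed series, keeping the top fraction (0.5% by
default) of voxels by correlation, clustering them into connected
components, and taking the centroid of the largest cluster as the
stimulation site.  Also provides the Fisher-z connectivity-change score
(dFC) between sessions and the electric-field summary indices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, InvalidParameterError
from .signal import (
    BoldSeries,
    SeedSeries,
    fisher_z,
    highpass,
    mean_series,
    pearson_r,
    seedmap_series,
    smooth_gaussian,
)
from .volumes import (
    ScalarVolume,
    SpherePrescription,
    VolumeMask,
    VoxelGrid,
    _check_same_grid,
    make_sphere_mask,
)

log = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ConnectivityMap:
    """Per-voxel seed correlation, defined on the search mask only."""

    grid: VoxelGrid
    r_value: np.ndarray  # grid.shape, NaN outside search mask
    search_mask: VolumeMask

    def defined_values(self) -> np.ndarray:
        return self.r_value.ravel()[self.search_mask.linear_indices()]


@dataclass
class TargetReport:
    """The selected stimulation target and the statistics behind it."""

    centroid_mm: tuple[float, float, float]
    snapped_voxel_mm: tuple[float, float, float]
    cluster_size: int
    cluster_mean_r: float
    peak_voxel_mm: tuple[float, float, float]
    threshold_r: float
    n_selected: int
    fraction: float
    connectivity: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EfieldSummary:
    """Electric-field indices over the target ROI (V/m)."""

    mean_vpm: float
    peak_vpm: float
    pct_above_threshold: float
    threshold_vpm: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------


def map_connectivity(series: BoldSeries, seed: SeedSeries, search: VolumeMask) -> ConnectivityMap:
    """Pearson r between each search-mask voxel's series and the seed series.

    Voxels with zero variance are assigned r = 0 with a logged warning.
    """
    _check_same_grid(series.grid, search.grid)
    idx = search.linear_indices()
    if idx.size == 0:
        raise EmptyMaskError("search mask is empty")
    if len(seed) != series.n_frames:
        raise InvalidParameterError("seed series length does not match frame count")
    x = np.asarray(series.data[:, idx], dtype=float)
    x = x - x.mean(axis=0)
    s = np.asarray(seed.values, dtype=float)
    s = s - s.mean()
    s_norm = np.linalg.norm(s)
    if s_norm == 0:
        raise InvalidParameterError("seed series has zero variance")
    x_norm = np.linalg.norm(x, axis=0)
    dead = x_norm == 0
    if dead.any():
        log.warning("%d zero-variance voxels in search mask assigned r=0", int(dead.sum()))
        x_norm[dead] = 1.0
    r = (s @ x) / (s_norm * x_norm)
    r[dead] = 0.0
    r = np.clip(r, -1.0, 1.0)
    vol = np.full(series.grid.n_voxels, np.nan)
    vol[idx] = r
    return ConnectivityMap(series.grid, vol.reshape(series.grid.shape), search)


def select_top_fraction(cmap: ConnectivityMap, fraction: float) -> VolumeMask:
    """The ceil(fraction * N) search voxels with the largest correlation.

    Ties at the cut are broken by larger r, then by lowest linear voxel
    index, so the selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise InvalidParameterError(f"fraction must be in (0, 1], got {fraction}")
    idx = cmap.search_mask.linear_indices()
    if idx.size == 0:
        raise EmptyMaskError("connectivity map has no defined voxels")
    r = cmap.r_value.ravel()[idx]
    k = int(math.ceil(fraction * idx.size))
    order = np.lexsort((idx, -r))  # primary: r descending; secondary: index ascending
    chosen = idx[order[:k]]
    member = np.zeros(cmap.search_mask.grid.n_voxels, dtype=bool)
    member[chosen] = True
    return VolumeMask(cmap.search_mask.grid, member.reshape(cmap.search_mask.grid.shape))


def connected_components(mask: VolumeMask, connectivity: int = 26) -> list[VolumeMask]:
    """Maximal connected subsets of the mask under 6/18/26-neighbourhood.

    Returned sorted by size descending, size ties by lowest member linear
    index.  An empty mask yields an empty list.
    """
    if connectivity not in _STRUCTURES:
        raise InvalidParameterError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    labels, n = ndimage.label(mask.member, structure=_STRUCTURES[connectivity])
    comps = []
    flat = labels.ravel()
    for lab in range(1, n + 1):
        members = flat == lab
        comps.append((int(members.sum()), int(np.flatnonzero(members)[0]), members))
    comps.sort(key=lambda c: (-c[0], c[1]))
    return [VolumeMask(mask.grid, m.reshape(mask.grid.shape)) for _, _, m in comps]


def locate_target(
    cmap: ConnectivityMap, fraction: float = 0.005, connectivity: int = 26
) -> TargetReport:
    """Centroid of the largest contiguous cluster of top-fraction voxels.

    Cluster-size ties are broken by higher mean r, then by lowest member
    index.  The snapped voxel is the cluster member nearest the centroid
    (ties toward higher r); the peak voxel is the cluster's r maximum.
    """
    selected = select_top_fraction(cmap, fraction)
    comps = connected_components(selected, connectivity)
    r_flat = cmap.r_value.ravel()

    def mean_r(c: VolumeMask) -> float:
        return float(r_flat[c.linear_indices()].mean())

    top_size = comps[0].n_members
    contenders = [c for c in comps if c.n_members == top_size]
    cluster = max(contenders, key=lambda c: (mean_r(c), -int(c.linear_indices()[0])))

    coords = cluster.coords_mm()
    idx = cluster.linear_indices()
    r_members = r_flat[idx]
    centroid = coords.mean(axis=0)
    dist = np.linalg.norm(coords - centroid, axis=1)
    snap_order = np.lexsort((-r_members, dist))  # nearest first, ties by higher r
    snapped = coords[snap_order[0]]
    peak = coords[int(np.argmax(r_members))]
    sel_r = r_flat[selected.linear_indices()]
    return TargetReport(
        centroid_mm=tuple(float(v) for v in centroid),
        snapped_voxel_mm=tuple(float(v) for v in snapped),
        cluster_size=cluster.n_members,
        cluster_mean_r=float(r_members.mean()),
        peak_voxel_mm=tuple(float(v) for v in peak),
        threshold_r=float(sel_r.min()),
        n_selected=selected.n_members,
        fraction=float(fraction),
        connectivity=int(connectivity),
    )


# ---------------------------------------------------------------------------
# Session-to-session connectivity change


def session_fc(
    series: BoldSeries,
    target_center_mm,
    seed_weights: ScalarVolume,
    gm_mask: VolumeMask,
    exclude_mask: VolumeMask,
    sphere_radius_mm: float = 10.0,
    cutoff_hz: float = 0.01,
    fwhm_mm: float = 4.0,
) -> float:
    """DLPFC-target-to-PGC correlation for one session.

    The session is high-pass filtered then smoothed; the target series is
    the mean over a sphere at the target centroid, the PGC series is the
    seedmap-weighted gray-matter average excluding the DLPFC.
    """
    proc = smooth_gaussian(highpass(series, cutoff_hz), fwhm_mm)
    sphere = make_sphere_mask(
        series.grid, SpherePrescription(tuple(target_center_mm), sphere_radius_mm, "target")
    ).intersect(gm_mask)
    if sphere.n_members == 0:
        raise EmptyMaskError("target sphere contains no gray-matter voxels")
    tgt = mean_series(proc, sphere, "target")
    pgc = seedmap_series(proc, seed_weights, gm_mask, exclude_mask, "pgc-seedmap")
    return pearson_r(tgt, pgc)


def delta_fc(
    pre: BoldSeries,
    post: BoldSeries,
    target: TargetReport,
    seed_weights: ScalarVolume,
    gm_mask: VolumeMask,
    exclude_mask: VolumeMask,
    sphere_radius_mm: float = 10.0,
    cutoff_hz: float = 0.01,
    fwhm_mm: float = 4.0,
) -> float:
    """Fisher-z connectivity change, z(r_post) - z(r_pre).

    Both sessions are processed identically; the target sphere is placed at
    the centroid selected from the pre session.
    """
    _check_same_grid(pre.grid, post.grid)
    args = (target.centroid_mm, seed_weights, gm_mask, exclude_mask,
            sphere_radius_mm, cutoff_hz, fwhm_mm)
    return fisher_z(session_fc(post, *args)) - fisher_z(session_fc(pre, *args))


# ---------------------------------------------------------------------------
# Electric-field indices


def efield_summary(field: ScalarVolume, roi: VolumeMask, threshold_vpm: float = 150.0) -> EfieldSummary:
    """Mean/peak field over the ROI and percent of ROI voxels above threshold.

    The suprathreshold rule is a strict inequality (field > threshold).
    """
    _check_same_grid(field.grid, roi.grid)
    idx = roi.linear_indices()
    if idx.size == 0:
        raise EmptyMaskError("e-field ROI is empty")
    vals = field.flat[idx]
    if np.any(vals < 0):
        raise InvalidParameterError("e-field magnitudes must be non-negative")
    return EfieldSummary(
        mean_vpm=float(vals.mean()),
        peak_vpm=float(vals.max()),
        pct_above_threshold=float(100.0 * np.mean(vals > threshold_vpm)),
        threshold_vpm=float(threshold_vpm),
    )
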