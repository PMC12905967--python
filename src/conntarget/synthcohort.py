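"""Seeded generators for phantom BOLD data and synthetic clinical cohorts.

The phantom plants a voxel cluster inside the DLPFC search mask whose
signal shares a latent band-limited time course with a spherical
pregenual-cingulate (PGC) seed region, on a gray-matter ellipsoid filled
with white noise plus a spatially smooth confound.  A group-average-style
connectivity weight map, peaked at the PGC, accompanies the data so that
the seedmap extraction path can be exercised end to end.

The cohort generator emulates the statistical structure of a small
open-label migraine trial: ~10 baseline headache days/month (truncated
normal on 3–30), a latent responder class with a large proportional
reduction in headache days sustained at follow-up, headache intensity on a
0–10 numeric rating scale, PSQI sleep scores (0–21) with no treatment
effect, a 3-category patient global impression of change derived from the
realised reduction, and a connectivity-change score (dFC) whose
distribution is shifted upward in responders.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import InvalidParameterError
from .signal import BoldSeries
from .volumes import (
    ScalarVolume,
    SpherePrescription,
    VolumeMask,
    VoxelGrid,
    build_dlpfc_mask,
    make_sphere_mask,
    mni_grid,
    mm_to_voxel,
    pgc_standin_mask,
)

COHORT_COLUMNS = [
    "patient_id",
    "responder_latent",
    "days_baseline",
    "days_post",
    "days_followup",
    "intensity_baseline",
    "intensity_post",
    "intensity_followup",
    "psqi_baseline",
    "psqi_post",
    "psqi_followup",
    "pgic_post",
    "pgic_followup",
    "dfc",
]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic resting-state phantom.

    The defaults are a desk-scale surrogate for a 600-frame, TR = 1 s,
    2-mm-isotropic acquisition: a 4-mm grid and 200 frames.
    """

    grid: VoxelGrid = field(default_factory=mni_grid)
    t_frames: int = 200
    tr: float = 1.0
    hotspot_center_mm: tuple[float, float, float] = (-38.0, 36.0, 40.0)
    hotspot_radius_mm: float = 8.0
    coupling_gain: float = 1.0
    post_gain_factor: float = 1.0
    noise_sd: float = 1.0
    confound_amplitude: float = 0.3
    smooth_confound_fwhm_mm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_frames < 100:
            raise InvalidParameterError("phantom needs at least 100 frames")
        if self.noise_sd <= 0:
            raise InvalidParameterError("noise_sd must be > 0")
        if self.coupling_gain < 0:
            raise InvalidParameterError("coupling_gain must be >= 0")


@dataclass
class PhantomData:
    """Everything a targeting run needs, generated from one PhantomSpec."""

    pre: BoldSeries
    post: BoldSeries
    pgc_mask: VolumeMask
    gm_mask: VolumeMask
    group_weights: ScalarVolume
    dlpfc_mask: VolumeMask
    hotspot_mask: VolumeMask


def _gm_ellipsoid(grid: VoxelGrid) -> VolumeMask:
    """A brain-shaped gray-matter stand-in: an ellipsoid inside the MNI box."""
    coords = grid.voxel_coords_mm()
    center = np.array([0.0, -18.0, 18.0])
    semi = np.array([72.0, 90.0, 78.0])
    inside = np.sum(((coords - center) / semi) ** 2, axis=1) <= 1.0
    return VolumeMask(grid, inside.reshape(grid.shape))


def _band_limited_series(rng: np.random.Generator, t: int, smooth_frames: float = 2.0) -> np.ndarray:
    """Unit-variance low-frequency latent time course."""
    s = ndimage.gaussian_filter1d(rng.standard_normal(t), smooth_frames)
    return (s - s.mean()) / s.std()


def _session(
    rng: np.random.Generator,
    spec: PhantomSpec,
    latent: np.ndarray,
    gm_idx: np.ndarray,
    pgc_idx: np.ndarray,
    hot_idx: np.ndarray,
    confound_loading: np.ndarray,
    gain: float,
) -> BoldSeries:
    t, v = spec.t_frames, spec.grid.n_voxels
    data = np.zeros((t, v), dtype=np.float32)
    block = rng.standard_normal((t, gm_idx.size), dtype=np.float32)
    block *= np.float32(spec.noise_sd)
    confound_tc = _band_limited_series(rng, t).astype(np.float32)
    block += np.float32(spec.confound_amplitude) * np.outer(
        confound_tc, confound_loading.astype(np.float32)
    )
    data[:, gm_idx] = block
    data[:, pgc_idx] += latent[:, None].astype(np.float32)
    data[:, hot_idx] += (gain * latent)[:, None].astype(np.float32)
    return BoldSeries(grid=spec.grid, data=data, tr=spec.tr)


def make_phantom(spec: PhantomSpec) -> PhantomData:
    """Generate a pre/post phantom pair plus masks and the group weight map.

    Fully reproducible from ``spec.seed``: the latent time course, the
    session noise streams and the confound each draw from their own child
    stream of a single seed sequence.
    """
    grid = spec.grid
    gm = _gm_ellipsoid(grid)
    pgc = pgc_standin_mask(grid).intersect(gm)
    dlpfc = build_dlpfc_mask(grid).intersect(gm)
    hotspot = make_sphere_mask(
        grid, SpherePrescription(spec.hotspot_center_mm, spec.hotspot_radius_mm, "hotspot")
    ).intersect(dlpfc)
    if hotspot.n_members == 0:
        raise InvalidParameterError(
            "hotspot sphere does not intersect the DLPFC search mask on this grid"
        )
    center_vox = mm_to_voxel(grid, spec.hotspot_center_mm)
    if np.any(center_vox < -0.5) or np.any(center_vox > np.asarray(grid.shape) - 0.5):
        raise InvalidParameterError("hotspot centre lies outside the grid")

    ss = np.random.SeedSequence(spec.seed)
    rng_latent, rng_pre, rng_post, rng_conf = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    latent = _band_limited_series(rng_latent, spec.t_frames)

    gm_idx = gm.linear_indices()
    loading_vol = np.zeros(grid.shape)
    loading_vol.ravel()[gm_idx] = rng_conf.standard_normal(gm_idx.size)
    from .signal import _smooth_3d  # shared kernel code

    loading_vol = _smooth_3d(loading_vol, grid, spec.smooth_confound_fwhm_mm)
    sd = loading_vol.ravel()[gm_idx].std() or 1.0
    confound_loading = loading_vol.ravel()[gm_idx] / sd

    pre = _session(rng_pre, spec, latent, gm_idx, pgc.linear_indices(),
                   hotspot.linear_indices(), confound_loading, spec.coupling_gain)
    post = _session(rng_post, spec, latent, gm_idx, pgc.linear_indices(),
                    hotspot.linear_indices(), confound_loading,
                    spec.coupling_gain * spec.post_gain_factor)

    # Group weight map: smoothed PGC indicator, peaked at the seed.
    w = np.zeros(grid.shape)
    w.ravel()[pgc.linear_indices()] = 1.0
    w = _smooth_3d(w, grid, 12.0)
    w[~gm.member] = 0.0
    peak = w.max() or 1.0
    weights = ScalarVolume(grid, w / peak)

    return PhantomData(pre, post, pgc, gm, weights, dlpfc, hotspot)


# ---------------------------------------------------------------------------
# Clinical cohort


@dataclass
class CohortSpec:
    """Parameters of one synthetic trial cohort.

    Defaults mirror the marginals of the emulated trial: 21 patients,
    baseline headache days 10.2 +/- 7.1 truncated to 3–30, a responder
    probability of 11/21, responders reducing headache days by ~55% and
    non-responders by ~5%, and a standardised responder/non-responder
    separation of 1.1 on the connectivity-change score.
    """

    n_patients: int = 21
    baseline_days_mean: float = 10.2
    baseline_days_sd: float = 7.1
    baseline_days_bounds: tuple[float, float] = (3.0, 30.0)
    responder_prob: float = 11.0 / 21.0
    responder_reduction_mean: float = 0.55
    responder_reduction_sd: float = 0.15
    nonresponder_reduction_mean: float = 0.05
    nonresponder_reduction_sd: float = 0.15
    timepoint_jitter_sd: float = 0.05
    dfc_effect: float = 1.1
    dfc_sd: float = 0.15
    dfc_nonresponder_mean: float = 0.0
    intensity_baseline_mean: float = 5.7
    intensity_baseline_sd: float = 1.5
    intensity_reduction_scale: float = 4.0
    psqi_baseline_mean: float = 7.7
    psqi_baseline_sd: float = 3.0
    round_days: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.responder_prob <= 1:
            raise InvalidParameterError("responder_prob must be in [0, 1]")
        if self.n_patients < 1:
            raise InvalidParameterError("cohort needs at least 1 patient")
        lo, hi = self.baseline_days_bounds
        if not 0 <= lo < hi <= 31:
            raise InvalidParameterError("baseline day bounds must satisfy 0 <= lo < hi <= 31")


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _pgic(reduction: np.ndarray) -> np.ndarray:
    """3-category global impression from the realised proportional reduction."""
    out = np.where(reduction > 0.15, "improvement",
                   np.where(reduction < -0.05, "worsening", "no_change"))
    return out


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one cohort table, reproducible from ``spec.seed``."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_patients
    lo, hi = spec.baseline_days_bounds
    baseline = _truncnorm(rng, spec.baseline_days_mean, spec.baseline_days_sd, lo, hi, n)
    responder = rng.random(n) < spec.responder_prob

    red_mean = np.where(responder, spec.responder_reduction_mean, spec.nonresponder_reduction_mean)
    red_sd = np.where(responder, spec.responder_reduction_sd, spec.nonresponder_reduction_sd)
    base_reduction = rng.normal(red_mean, red_sd)
    red_post = np.clip(base_reduction + rng.normal(0, spec.timepoint_jitter_sd, n), 0.0, 1.0)
    red_fu = np.clip(base_reduction + rng.normal(0, spec.timepoint_jitter_sd, n), 0.0, 1.0)

    days_post = baseline * (1 - red_post)
    days_fu = baseline * (1 - red_fu)
    if spec.round_days:
        baseline = np.round(baseline)
        days_post = np.round(days_post)
        days_fu = np.round(days_fu)

    inten_base = np.clip(np.round(rng.normal(spec.intensity_baseline_mean,
                                             spec.intensity_baseline_sd, n)), 0, 10)
    inten_post = np.clip(np.round(inten_base - spec.intensity_reduction_scale * red_post), 0, 10)
    inten_fu = np.clip(np.round(inten_base - spec.intensity_reduction_scale * red_fu), 0, 10)

    psqi_base = np.clip(np.round(rng.normal(spec.psqi_baseline_mean, spec.psqi_baseline_sd, n)), 0, 21)
    psqi_post = np.clip(psqi_base + rng.integers(-1, 2, n), 0, 21)
    psqi_fu = np.clip(psqi_base + rng.integers(-1, 2, n), 0, 21)

    dfc_mean = np.where(
        responder,
        spec.dfc_nonresponder_mean + spec.dfc_effect * spec.dfc_sd,
        spec.dfc_nonresponder_mean,
    )
    dfc = rng.normal(dfc_mean, spec.dfc_sd)

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "responder_latent": responder,
            "days_baseline": baseline,
            "days_post": days_post,
            "days_followup": days_fu,
            "intensity_baseline": inten_base,
            "intensity_post": inten_post,
            "intensity_followup": inten_fu,
            "psqi_baseline": psqi_base,
            "psqi_post": psqi_post,
            "psqi_followup": psqi_fu,
            "pgic_post": _pgic(red_post),
            "pgic_followup": _pgic(red_fu),
            "dfc": dfc,
        },
        columns=COHORT_COLUMNS,
    )


def write_cohort(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def spec_sidecar(spec) -> dict:
    """JSON-serialisable echo of a generator spec (grids reduced to shape/affine)."""
    d = asdict(spec)
    if "grid" in d:
        d["grid"] = {"shape": list(spec.grid.shape), "affine": np.asarray(spec.grid.affine).tolist()}
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
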