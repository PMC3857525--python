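"""Pre-processing: brain masking, affine registration, smoothing, pipeline.

This stage turns a native-space FLAIR/T1 pair plus tissue maps into the
skull-stripped, template-space, cerebellum/brainstem-free, smoothed FLAIR
on which global intensity thresholding operates. Steps, in order:

1. co-register FLAIR to T1 (intensity-based affine registration),
2. build a binary brain mask by summing GM+WM+CSF tissue maps and
   multiply it into both images (skull-stripping),
3. register the skull-stripped T1 to a template and carry the FLAIR
   along the composed transform onto the template grid,
4. zero everything under the exclusion mask (cerebellum + brainstem),
5. smooth with a Gaussian kernel (default 2 mm FWHM).

Registration maximizes the correlation ratio of moving intensities binned
against the fixed image, with a coarse-to-fine pyramid (downsample factors
4, 2, 1), a derivative-free simplex search at each level, and
center-of-mass initialization. Tissue segmentation itself is not
performed here: tissue probability maps are an input.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage, optimize

from .image_core import (
    AffineTransform,
    BinaryMask,
    GridMismatchError,
    Volume,
    apply_mask,
    resample,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TissueMaps",
    "PreprocessConfig",
    "PreprocessResult",
    "build_brain_mask",
    "register_affine",
    "smooth_gaussian",
    "preprocess_pipeline",
    "fwhm_to_sigma_mm",
]

# FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian
_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


class DegenerateInputError(ValueError):
    """Raised when an input cannot support the requested computation."""


def fwhm_to_sigma_mm(fwhm_mm: float) -> float:
    """Convert Gaussian FWHM (mm) to standard deviation (mm)."""
    return fwhm_mm / _FWHM_FACTOR


@dataclass
class TissueMaps:
    """GM / WM / CSF maps (probabilistic or binary) on one grid, values in [0,1]."""

    gm: Volume
    wm: Volume
    csf: Volume

    def __post_init__(self) -> None:
        if not (self.gm.same_grid(self.wm) and self.gm.same_grid(self.csf)):
            raise GridMismatchError("GM/WM/CSF maps must share one grid")
        for name in ("gm", "wm", "csf"):
            vol = getattr(self, name)
            if vol.data.min() < 0.0 or vol.data.max() > 1.0:
                logger.warning("%s map has values outside [0,1]; clipping", name)
                setattr(self, name, Volume(np.clip(vol.data, 0.0, 1.0), vol.affine))


@dataclass
class PreprocessConfig:
    fwhm_mm: float = 2.0
    brain_mask_threshold: float = 0.5
    registration_dof: str = "affine12"  # or "rigid6"
    cost: str = "correlation_ratio"  # or "least_squares"
    coreg_interpolation: str = "nearest"
    normalization_interpolation: str = "trilinear"
    mask_normalized_smoothing: bool = False
    n_bins: int = 32
    max_iter_per_level: int = 200
    pyramid_factors: tuple[int, ...] = (4, 2, 1)

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be positive")
        if not 0 < self.brain_mask_threshold <= 1:
            raise ValueError("brain_mask_threshold must be in (0, 1]")
        if self.registration_dof not in ("rigid6", "affine12"):
            raise ValueError(f"unknown registration_dof {self.registration_dof!r}")
        if self.cost not in ("correlation_ratio", "least_squares"):
            raise ValueError(f"unknown cost {self.cost!r}")


class PreprocessResult(NamedTuple):
    """Pipeline output: processed FLAIR plus provenance."""

    flair: Volume
    brain_mask: BinaryMask  # brain minus exclusion, on the template grid
    flair_to_t1: AffineTransform
    t1_to_template: AffineTransform


def build_brain_mask(tissues: TissueMaps, threshold: float = 0.5) -> BinaryMask:
    """Binary brain mask: 1 where gm + wm + csf >= threshold.

    With binary tissue maps that partition the brain the sum is exactly 1
    inside and 0 outside, so any threshold in (0, 1] recovers the brain.
    """
    total = tissues.gm.data + tissues.wm.data + tissues.csf.data
    mask = BinaryMask.from_bool(total >= threshold, tissues.gm.affine.copy())
    if mask.n_voxels == 0:
        logger.warning("brain mask is empty (tissue sum below %.3g everywhere)", threshold)
    return mask


def _voxel_spacings_mm(vol: Volume) -> np.ndarray:
    return np.linalg.norm(vol.affine[:3, :3], axis=0)


def smooth_gaussian(vol: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with the kernel width given in mm FWHM.

    Per-axis sigma in voxels is ``fwhm / (2 sqrt(2 ln 2)) / spacing``.
    Borders are zero-padded, matching plain smoothing of a skull-stripped
    image whose background is zero.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = fwhm_to_sigma_mm(fwhm_mm) / _voxel_spacings_mm(vol)
    out = ndimage.gaussian_filter(vol.data, sigma=sigma_vox, mode="constant", cval=0.0)
    return Volume(out.astype(np.float32), vol.affine.copy())


# --------------------------------------------------------------------------
# affine registration
# --------------------------------------------------------------------------


def _center_of_mass_mm(vol: Volume) -> np.ndarray:
    w = np.abs(vol.data).astype(np.float64)
    total = w.sum()
    if total <= 0:
        com_idx = (np.asarray(vol.grid_shape, dtype=float) - 1) / 2.0
    else:
        com_idx = np.array(ndimage.center_of_mass(w))
    return vol.affine[:3, :3] @ com_idx + vol.affine[:3, 3]


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation about x, then y, then z; angles in degrees."""
    ax, ay, az = np.deg2rad([rx, ry, rz])
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx_m = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry_m = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz_m = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz_m @ ry_m @ rx_m


def _params_to_transform(params: np.ndarray, center_mm: np.ndarray, dof: str) -> AffineTransform:
    """Build a world-space affine from natural-unit parameters.

    ``params`` is [tx, ty, tz (mm), rx, ry, rz (deg)] for rigid6, extended
    with [sx, sy, sz, hxy, hxz, hyz] (percent deviations) for affine12.
    Rotation/scale/shear act about ``center_mm``.
    """
    t = np.asarray(params[:3], dtype=float)
    rot = _rotation_matrix(*params[3:6])
    if dof == "affine12":
        scale = np.diag(1.0 + np.asarray(params[6:9], dtype=float) / 100.0)
        hxy, hxz, hyz = np.asarray(params[9:12], dtype=float) / 100.0
        shear = np.array([[1.0, hxy, hxz], [0.0, 1.0, hyz], [0.0, 0.0, 1.0]])
        lin = rot @ scale @ shear
    else:
        lin = rot
    m = np.eye(4)
    m[:3, :3] = lin
    m[:3, 3] = t + center_mm - lin @ center_mm
    return AffineTransform(m)


def _downsample(vol: Volume, factor: int) -> Volume:
    if factor == 1:
        return vol
    data = ndimage.gaussian_filter(vol.data, sigma=factor / 2.0, mode="constant", cval=0.0)
    data = data[::factor, ::factor, ::factor]
    affine = vol.affine @ np.diag([factor, factor, factor, 1.0])
    return Volume(np.ascontiguousarray(data), affine)


def _correlation_ratio_cost(
    fixed_data: np.ndarray, moved_data: np.ndarray, n_bins: int, bin_edges: np.ndarray
) -> float:
    """1 - correlation ratio of moved intensities binned by fixed intensity.

    Computed over the overlap of the nonzero supports. Lower is better;
    0 means the fixed image perfectly predicts the moved intensities.
    """
    overlap = (fixed_data > 0) & (moved_data > 0)
    n = int(overlap.sum())
    if n < 64:
        return 2.0  # essentially no overlap: worse than any real alignment
    f = fixed_data[overlap]
    m = moved_data[overlap].astype(np.float64)
    total_var = m.var()
    if total_var <= 0:
        return 2.0
    bins = np.clip(np.digitize(f, bin_edges), 1, n_bins) - 1
    counts = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=m, minlength=n_bins)
    sumsq = np.bincount(bins, weights=m * m, minlength=n_bins)
    nz = counts > 0
    within = sumsq[nz] - sums[nz] ** 2 / counts[nz]
    return float(within.sum() / (n * total_var))


def _least_squares_cost(fixed_data: np.ndarray, moved_data: np.ndarray) -> float:
    overlap = (fixed_data > 0) & (moved_data > 0)
    n = int(overlap.sum())
    if n < 64:
        return np.inf
    d = fixed_data[overlap].astype(np.float64) - moved_data[overlap]
    return float(np.mean(d * d))


def register_affine(
    moving: Volume, fixed: Volume, config: PreprocessConfig | None = None
) -> AffineTransform:
    """Estimate the world-to-world affine aligning ``moving`` to ``fixed``.

    Multi-resolution derivative-free search (Nelder-Mead simplex at each
    pyramid level) over 6 or 12 parameters, starting from center-of-mass
    alignment; cost is the correlation ratio over the nonzero-support
    overlap by default. The returned transform never scores worse than the
    starting one. Raises :class:`DegenerateInputError` for constant images.
    """
    config = config or PreprocessConfig()
    for name, vol in (("moving", moving), ("fixed", fixed)):
        support = vol.data[vol.data != 0]
        if support.size < 2 or support.std() == 0:
            raise DegenerateInputError(f"{name} image is constant; cannot register")

    dof = config.registration_dof
    n_params = 6 if dof == "rigid6" else 12
    center = _center_of_mass_mm(fixed)
    x0 = np.zeros(n_params)
    x0[:3] = _center_of_mass_mm(fixed) - _center_of_mass_mm(moving)

    levels = sorted(set(config.pyramid_factors), reverse=True)
    # simplex step per level, natural units (mm / deg / percent)
    steps = {f: max(0.25, f / 2.0) for f in levels}

    best_x = x0.copy()
    for factor in levels:
        fx = _downsample(fixed, factor)
        mv = _downsample(moving, factor)
        fixed_pos = fx.data[fx.data > 0]
        if fixed_pos.size == 0:
            continue
        edges = np.linspace(fixed_pos.min(), fixed_pos.max() + 1e-6, config.n_bins + 1)[1:-1]

        def cost(x: np.ndarray) -> float:
            t = _params_to_transform(x, center, dof)
            moved = resample(mv, t, fx, "trilinear")
            if config.cost == "least_squares":
                return _least_squares_cost(fx.data, moved.data)
            return _correlation_ratio_cost(fx.data, moved.data, config.n_bins, edges)

        step = steps[factor]
        simplex = np.vstack([best_x] + [best_x + step * e for e in np.eye(n_params)])
        res = optimize.minimize(
            cost,
            best_x,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "maxiter": config.max_iter_per_level,
                "xatol": 0.02 if factor == 1 else 0.1,
                "fatol": 1e-8,
                "adaptive": n_params > 6,
            },
        )
        if not res.success:
            logger.warning(
                "registration simplex did not converge at level %d (%s); using best found",
                factor,
                res.message,
            )
        if cost(res.x) <= cost(best_x):
            best_x = res.x
    return _params_to_transform(best_x, center, dof)


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------


def preprocess_pipeline(
    flair: Volume,
    t1: Volume,
    tissues: TissueMaps,
    template: Volume,
    exclusion_mask: BinaryMask,
    config: PreprocessConfig | None = None,
) -> PreprocessResult:
    """Run the full pre-processing chain; see module docstring for the steps.

    Returns the processed FLAIR on the template grid together with the
    final brain-minus-exclusion mask (also on the template grid) and the
    two estimated transforms.
    """
    config = config or PreprocessConfig()
    if not exclusion_mask.same_grid(template):
        raise GridMismatchError("exclusion mask must live on the template grid")

    def timed(name, fn):
        t0 = time.perf_counter()
        out = fn()
        logger.info("stage %-22s %6.2f s", name, time.perf_counter() - t0)
        return out

    flair_to_t1 = timed("coregister flair->t1", lambda: register_affine(flair, t1, config))
    flair_in_t1 = resample(flair, flair_to_t1, t1, config.coreg_interpolation)

    brain = build_brain_mask(tissues, config.brain_mask_threshold)
    if not brain.same_grid(t1):
        raise GridMismatchError("tissue maps must share the T1 grid")
    flair_stripped = apply_mask(flair_in_t1, brain)
    t1_stripped = apply_mask(t1, brain)

    t1_to_template = timed(
        "normalize t1->template", lambda: register_affine(t1_stripped, template, config)
    )
    flair_norm = resample(
        flair_stripped, t1_to_template, template, config.normalization_interpolation
    )
    brain_norm = resample(brain, t1_to_template, template, "nearest")

    keep = exclusion_mask.complement()
    flair_kept = apply_mask(flair_norm, keep)
    final_mask = BinaryMask.from_bool(
        (brain_norm.data > 0) & (keep.data > 0), template.affine.copy()
    )

    smoothed = timed("smooth", lambda: smooth_gaussian(flair_kept, config.fwhm_mm))
    if config.mask_normalized_smoothing:
        norm = smooth_gaussian(Volume(final_mask.data, final_mask.affine), config.fwhm_mm)
        with np.errstate(divide="ignore", invalid="ignore"):
            data = np.where(norm.data > 1e-3, smoothed.data / norm.data, 0.0)
        smoothed = Volume(np.nan_to_num(data).astype(np.float32), smoothed.affine)

    return PreprocessResult(smoothed, final_mask, flair_to_t1, t1_to_template)
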