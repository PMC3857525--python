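"""WMH detection by global intensity thresholding, edit merging, volumetry.

White matter hyperintensities are bright on FLAIR, so after pre-processing
the lesion map is obtained by a single global threshold on the intensity
histogram: a voxel is lesion when its intensity is at least
``mean + k * SD`` of all brain voxels (default k = 1.5). False positives
and negatives are fixed deterministically by merging add/remove edit
masks. Lesion load is the 1-voxel count times the voxel volume, in cm^3.

Conventions: "all brain voxels" means the in-mask voxels when a brain mask
is supplied, otherwise the strictly positive voxels (masking writes exact
zeros, which would otherwise drag the mean down); the SD uses the sample
(N-1) denominator; a voxel exactly at the threshold is lesion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .image_core import BinaryMask, GridMismatchError, Volume, voxel_volume_mm3

logger = logging.getLogger(__name__)

__all__ = [
    "IntensityStats",
    "SegmentationResult",
    "brain_intensity_stats",
    "threshold_segment",
    "apply_edits",
    "lesion_volume_cm3",
]


class DegenerateInputError(ValueError):
    """Raised when fewer than two voxels enter the intensity statistics."""


@dataclass(frozen=True)
class IntensityStats:
    """Mean/SD of brain-voxel intensity and the voxel count behind them."""

    mean: float
    sd: float
    n_voxels: int


@dataclass
class SegmentationResult:
    """A lesion map plus full threshold provenance and volumetry.

    Invariants maintained by every constructor in this module:
    ``threshold == stats.mean + k * stats.sd``, ``n_lesion_voxels`` equals
    the 1-count of ``lesion_map``, and ``volume_cm3`` equals
    ``n_lesion_voxels * voxel_volume_mm3 / 1000``.
    """

    lesion_map: BinaryMask
    stats: IntensityStats
    k: float
    threshold: float
    n_lesion_voxels: int
    volume_cm3: float
    n_voxels_added: int = 0
    n_voxels_removed: int = 0

    def to_report_dict(self) -> dict:
        d = asdict(self)
        d.pop("lesion_map")
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_report_dict(), fh, indent=2)


def brain_intensity_stats(
    vol: Volume, mask: BinaryMask | None = None, ddof: int = 1
) -> IntensityStats:
    """Mean and SD of the brain-voxel intensities.

    Statistics run over in-mask voxels when ``mask`` is given, else over
    the strictly positive voxels (zero background excluded).
    """
    if mask is not None:
        if not vol.same_grid(mask):
            raise GridMismatchError(
                f"volume grid {vol.grid_shape} does not match mask grid {mask.grid_shape}"
            )
        values = vol.data[mask.data > 0]
    else:
        values = vol.data[vol.data > 0]
    if values.size < 2:
        raise DegenerateInputError(
            f"need at least 2 voxels for intensity statistics, got {values.size}"
        )
    values = values.astype(np.float64)
    return IntensityStats(float(values.mean()), float(values.std(ddof=ddof)), int(values.size))


def _finalize(lesion: BinaryMask, stats: IntensityStats, k: float, **extra) -> SegmentationResult:
    n = lesion.n_voxels
    return SegmentationResult(
        lesion_map=lesion,
        stats=stats,
        k=k,
        threshold=stats.mean + k * stats.sd,
        n_lesion_voxels=n,
        volume_cm3=n * voxel_volume_mm3(lesion) / 1000.0,
        **extra,
    )


def threshold_segment(
    vol: Volume, mask: BinaryMask | None = None, k: float = 1.5, ddof: int = 1
) -> SegmentationResult:
    """Segment probable WMH at the global threshold ``mean + k * SD``.

    A voxel is lesion when it qualifies for the statistics (in mask, or
    positive when no mask is given) and its intensity is >= the threshold.
    """
    stats = brain_intensity_stats(vol, mask, ddof=ddof)
    thr = stats.mean + k * stats.sd
    qualifies = mask.data > 0 if mask is not None else vol.data > 0
    lesion = BinaryMask.from_bool(qualifies & (vol.data >= thr), vol.affine.copy())
    logger.info(
        "threshold %.4g (mean %.4g + %.2g x sd %.4g) over %d voxels -> %d lesion voxels",
        thr, stats.mean, k, stats.sd, stats.n_voxels, lesion.n_voxels,
    )
    return _finalize(lesion, stats, k)


def apply_edits(
    seg: SegmentationResult,
    additions: BinaryMask | None = None,
    removals: BinaryMask | None = None,
) -> SegmentationResult:
    """Merge manual-correction masks: (lesion U additions) minus removals.

    Removals win on overlap. Counts and volume are recomputed; threshold
    and stats are carried over; the numbers of voxels actually added and
    removed are recorded for provenance.
    """
    current = seg.lesion_map.data > 0
    for name, m in (("additions", additions), ("removals", removals)):
        if m is not None and not m.same_grid(seg.lesion_map):
            raise GridMismatchError(f"{name} mask grid does not match the lesion map grid")
    added = np.zeros_like(current) if additions is None else (additions.data > 0) & ~current
    out = current | added
    removed = np.zeros_like(current) if removals is None else (removals.data > 0) & out
    out = out & ~removed
    lesion = BinaryMask.from_bool(out, seg.lesion_map.affine.copy())
    return _finalize(
        lesion,
        seg.stats,
        seg.k,
        n_voxels_added=int(added.sum()),
        n_voxels_removed=int(removed.sum()),
    )


def lesion_volume_cm3(mask: BinaryMask) -> float:
    """Lesion load in cm^3: 1-voxel count times voxel volume (mm^3) / 1000."""
    return mask.n_voxels * voxel_volume_mm3(mask) / 1000.0
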