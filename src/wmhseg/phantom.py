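"""Synthetic FLAIR/T1 brain phantoms with known lesion geometry.

The phantom is a concentric-ellipsoid brain — CSF ventricles inside a
white-matter core inside a grey-matter shell — with an optional inferior
"cerebellum/brainstem" block and ellipsoidal hyperintense lesions stamped
into the white matter at specified world-mm positions. Every compartment
is constructed voxel-exactly, so the ground-truth lesion map and tissue
maps are known without estimation; Gaussian noise is added to the FLAIR
and T1 intensities only, never to the ground truth. A non-identity
``true_flair_to_t1`` transform moves the FLAIR off the T1 grid so that
registration has something real to recover.

The template is the phantom's own noise-free T1, which makes spatial
normalization a near-identity problem by default; registration stress
tests inject known transforms instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .image_core import (
    AffineTransform,
    BinaryMask,
    GridMismatchError,
    Volume,
    resample,
    write_volume,
)
from .preprocess import TissueMaps
from .segment import lesion_volume_cm3
from .evaluate import dice

logger = logging.getLogger(__name__)

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "score_against_truth",
    "write_bundle",
]


class PhantomSpecError(ValueError):
    """Raised when a phantom specification is geometrically impossible."""


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal lesion: center and radii in world mm, FLAIR intensity."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    intensity: float | None = None  # None -> spec.tissue_means["lesion"]


def _default_lesions() -> list[LesionSpec]:
    # one dominant confluent periventricular-type lesion plus a small deep
    # lesion, ~3.6% of the phantom brain volume -- the load fraction of a
    # moderate-to-high-burden clinical subject
    return [
        LesionSpec(center_mm=(48.0, 72.0, 34.0), radii_mm=(14.0, 11.0, 10.0)),
        LesionSpec(center_mm=(36.0, 40.0, 30.0), radii_mm=(4.0, 4.0, 3.0)),
    ]


@dataclass
class PhantomSpec:
    """Geometry, intensities and noise level of a synthetic brain.

    Intensities are arbitrary units chosen to mimic FLAIR contrast: CSF
    dark (ventricles are suppressed), GM slightly below WM, lesions well
    above WM. The default lesion mean of 160 against WM 100 +/- 5 puts the
    lesions 12 noise-SDs above white matter.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 60)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_means: dict = field(
        default_factory=lambda: {"csf": 30.0, "gm": 90.0, "wm": 100.0, "lesion": 160.0}
    )
    t1_means: dict = field(default_factory=lambda: {"csf": 30.0, "gm": 70.0, "wm": 110.0})
    noise_sd: float = 5.0
    lesions: list[LesionSpec] = field(default_factory=_default_lesions)
    include_cerebellum_block: bool = True
    true_flair_to_t1: AffineTransform = field(default_factory=AffineTransform.identity)
    seed: int = 0

    # brain geometry as fractions of the grid extent (world mm computed below)
    def _geometry(self) -> dict:
        extent = np.asarray(self.grid_shape, dtype=float) * np.asarray(self.spacing_mm)
        center = extent / 2.0 + np.array([0.0, 0.0, 4.0])
        return {
            "center": center,
            "outer_radii": extent * np.array([0.40, 0.46, 0.40]),
            "wm_radii": extent * np.array([0.32, 0.38, 0.30]),
            "ventricle_radii": extent * np.array([0.085, 0.125, 0.10]),
            "block_lo": extent * np.array([0.32, 0.22, 0.03]),
            "block_hi": extent * np.array([0.68, 0.58, 0.20]),
        }


class PhantomBundle(NamedTuple):
    flair: Volume
    t1: Volume
    tissues: TissueMaps
    brain_mask: BinaryMask
    exclusion_mask: BinaryMask
    template: Volume
    ground_truth: BinaryMask
    spec: PhantomSpec


class TruthScore(NamedTuple):
    dsc: float
    volume_error_cm3: float
    false_positive_voxels: int
    false_negative_voxels: int


def _world_grids(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    sp = spec.spacing_mm
    return np.ogrid[
        0 : spec.grid_shape[0] * sp[0] : sp[0],
        0 : spec.grid_shape[1] * sp[1] : sp[1],
        0 : spec.grid_shape[2] * sp[2] : sp[2],
    ]


def _ellipsoid(spec: PhantomSpec, center, radii) -> np.ndarray:
    x, y, z = _world_grids(spec)
    return (
        ((x - center[0]) / radii[0]) ** 2
        + ((y - center[1]) / radii[1]) ** 2
        + ((z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomBundle:
    """Construct the full phantom bundle; deterministic for a fixed seed.

    Raises :class:`PhantomSpecError` when a lesion ellipsoid is not fully
    contained in the white-matter compartment.
    """
    spec = spec or PhantomSpec()
    geo = spec._geometry()
    affine = np.diag(list(spec.spacing_mm) + [1.0])

    outer = _ellipsoid(spec, geo["center"], geo["outer_radii"])
    wm = _ellipsoid(spec, geo["center"], geo["wm_radii"])
    ventricle = _ellipsoid(spec, geo["center"], geo["ventricle_radii"])
    gm = outer & ~wm
    csf = ventricle
    wm = wm & ~ventricle

    block = np.zeros(spec.grid_shape, dtype=bool)
    if spec.include_cerebellum_block:
        x, y, z = _world_grids(spec)
        lo, hi = geo["block_lo"], geo["block_hi"]
        block = (
            (x >= lo[0]) & (x <= hi[0])
            & (y >= lo[1]) & (y <= hi[1])
            & (z >= lo[2]) & (z <= hi[2])
        ) & ~outer
        gm = gm | block

    truth = np.zeros(spec.grid_shape, dtype=bool)
    for i, lesion in enumerate(spec.lesions):
        les = _ellipsoid(spec, lesion.center_mm, lesion.radii_mm)
        if not np.all(wm[les]):
            raise PhantomSpecError(
                f"lesion {i} at {lesion.center_mm} mm is not fully inside white matter"
            )
        truth |= les

    head = outer | block
    flair = np.zeros(spec.grid_shape, dtype=np.float64)
    t1 = np.zeros(spec.grid_shape, dtype=np.float64)
    for comp, fl_mean, t1_mean in (
        (csf, spec.tissue_means["csf"], spec.t1_means["csf"]),
        (gm, spec.tissue_means["gm"], spec.t1_means["gm"]),
        (wm, spec.tissue_means["wm"], spec.t1_means["wm"]),
    ):
        flair[comp] = fl_mean
        t1[comp] = t1_mean
    for lesion in spec.lesions:
        les = _ellipsoid(spec, lesion.center_mm, lesion.radii_mm)
        flair[les] = lesion.intensity if lesion.intensity is not None else spec.tissue_means["lesion"]
        # lesions are near-isointense to WM on T1; leave t1 at the WM mean

    template = Volume(t1.copy(), affine)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        # noise only inside the head: the zero background models the exact
        # zeros that skull-stripping writes into real data
        t1 = t1 + np.where(head, rng.normal(0.0, spec.noise_sd, spec.grid_shape), 0.0)
        flair_noise = np.where(head, rng.normal(0.0, spec.noise_sd, spec.grid_shape), 0.0)
    else:
        flair_noise = 0.0

    flair_vol = Volume(np.clip(flair + flair_noise, 0.0, None), affine)
    moved = spec.true_flair_to_t1
    if not np.allclose(moved.matrix, np.eye(4)):
        flair_vol = resample(flair_vol, moved.inverse(), flair_vol, "trilinear")

    tissues = TissueMaps(
        gm=Volume(gm.astype(np.float32), affine),
        wm=Volume((wm | truth).astype(np.float32), affine),
        csf=Volume(csf.astype(np.float32), affine),
    )
    bundle = PhantomBundle(
        flair=flair_vol,
        t1=Volume(np.clip(t1, 0.0, None), affine),
        tissues=tissues,
        brain_mask=BinaryMask.from_bool(head, affine),
        exclusion_mask=BinaryMask.from_bool(block, affine),
        template=template,
        ground_truth=BinaryMask.from_bool(truth, affine),
        spec=spec,
    )
    logger.info(
        "phantom: %d brain voxels, %d lesion voxels (%.3f cm^3), noise SD %.3g",
        bundle.brain_mask.n_voxels,
        bundle.ground_truth.n_voxels,
        lesion_volume_cm3(bundle.ground_truth),
        spec.noise_sd,
    )
    return bundle


def score_against_truth(seg: BinaryMask, bundle: PhantomBundle) -> TruthScore:
    """Score a segmentation against the phantom's constructed ground truth."""
    truth = bundle.ground_truth
    if seg.grid_shape != truth.grid_shape:
        raise GridMismatchError(
            f"segmentation grid {seg.grid_shape} does not match phantom grid {truth.grid_shape}"
        )
    a = seg.data > 0
    b = truth.data > 0
    return TruthScore(
        dsc=dice(seg, truth),
        volume_error_cm3=lesion_volume_cm3(seg) - lesion_volume_cm3(truth),
        false_positive_voxels=int((a & ~b).sum()),
        false_negative_voxels=int((~a & b).sum()),
    )


def write_bundle(bundle: PhantomBundle, out_dir: str | Path) -> dict:
    """Write every bundle image as NIfTI plus a JSON manifest of truth counts."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = {
        "flair": bundle.flair,
        "t1": bundle.t1,
        "gm": bundle.tissues.gm,
        "wm": bundle.tissues.wm,
        "csf": bundle.tissues.csf,
        "brain_mask": bundle.brain_mask,
        "exclusion_mask": bundle.exclusion_mask,
        "template": bundle.template,
        "ground_truth": bundle.ground_truth,
    }
    for name, vol in names.items():
        write_volume(vol, out / f"{name}.nii.gz")
    manifest = {
        "seed": bundle.spec.seed,
        "grid_shape": list(bundle.spec.grid_shape),
        "spacing_mm": list(bundle.spec.spacing_mm),
        "noise_sd": bundle.spec.noise_sd,
        "n_brain_voxels": bundle.brain_mask.n_voxels,
        "n_lesion_voxels": bundle.ground_truth.n_voxels,
        "true_lesion_volume_cm3": lesion_volume_cm3(bundle.ground_truth),
        "files": {k: f"{k}.nii.gz" for k in names},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
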