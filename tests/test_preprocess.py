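import numpy as np
import pytest

from wmhseg.image_core import AffineTransform, Volume, apply_mask, resample
from wmhseg.phantom import PhantomSpec, generate_phantom
from wmhseg.preprocess import (
    DegenerateInputError,
    PreprocessConfig,
    TissueMaps,
    build_brain_mask,
    fwhm_to_sigma_mm,
    preprocess_pipeline,
    register_affine,
    smooth_gaussian,
)

from conftest import small_phantom_spec


def _tissue_partition(shape=(16, 16, 16), affine=None):
    """Binary GM/WM/CSF maps partitioning a centered ball."""
    affine = np.eye(4) if affine is None else affine
    idx = np.indices(shape, dtype=float)
    r = np.sqrt(((idx - 7.5) ** 2).sum(axis=0))
    ball = r <= 6.0
    wm = ball & (r <= 3.0)
    csf = ball & (r > 3.0) & (r <= 4.5)
    gm = ball & ~wm & ~csf
    mk = lambda a: Volume(a.astype(np.float32), affine)
    return TissueMaps(mk(gm), mk(wm), mk(csf)), ball


class TestBrainMask:
    def test_binary_partition_recovers_ball_exactly(self):
        tissues, ball = _tissue_partition()
        mask = build_brain_mask(tissues, 0.5)
        assert np.array_equal(mask.data > 0, ball)

    def test_empty_tissues_give_empty_mask_with_warning(self, caplog):
        z = Volume(np.zeros((4, 4, 4)), np.eye(4))
        with caplog.at_level("WARNING"):
            mask = build_brain_mask(TissueMaps(z, z.copy(), z.copy()), 0.5)
        assert mask.n_voxels == 0
        assert "empty" in caplog.text

    def test_probability_sum_below_threshold_excluded(self):
        base = np.zeros((4, 4, 4), dtype=np.float32)
        gm = base.copy(); gm[1, 1, 1] = 0.2
        wm = base.copy(); wm[1, 1, 1] = 0.1
        csf = base.copy(); csf[1, 1, 1] = 0.1  # sums to 0.4 < 0.5
        gm[2, 2, 2] = wm[2, 2, 2] = csf[2, 2, 2] = 0.2  # sums to 0.6
        tissues = TissueMaps(*(Volume(a, np.eye(4)) for a in (gm, wm, csf)))
        mask = build_brain_mask(tissues, 0.5)
        assert mask.data[1, 1, 1] == 0
        assert mask.data[2, 2, 2] == 1


class TestSmoothing:
    def test_fwhm_to_sigma_closed_form(self):
        assert fwhm_to_sigma_mm(2.0) == pytest.approx(0.84932, abs=1e-5)

    def test_constant_interior_unchanged(self):
        vol = Volume(np.full((24, 24, 24), 3.0), np.eye(4))
        out = smooth_gaussian(vol, 2.0)
        assert np.allclose(out.data[6:-6, 6:-6, 6:-6], 3.0, atol=1e-4)

    def test_unit_impulse_mass_conserved_and_spread(self):
        data = np.zeros((17, 17, 17), dtype=np.float32)
        data[8, 8, 8] = 1.0
        out = smooth_gaussian(Volume(data, np.eye(4)), 2.0)
        assert out.data.sum() == pytest.approx(1.0, abs=1e-3)
        assert out.data.max() < 1.0

    def test_sigma_respects_voxel_spacing(self):
        # same physical kernel on a 2 mm grid has half the voxel sigma, so
        # the kernel mass concentrates: peak and near-neighbour values rise
        data = np.zeros((17, 17, 17), dtype=np.float32)
        data[8, 8, 8] = 1.0
        fine = smooth_gaussian(Volume(data, np.eye(4)), 4.0)
        coarse = smooth_gaussian(Volume(data, np.diag([2, 2, 2, 1.0])), 4.0)
        assert coarse.data[8, 8, 8] > fine.data[8, 8, 8]
        assert coarse.data[9, 8, 8] > fine.data[9, 8, 8]

    def test_commutes_with_whole_voxel_shift(self):
        rng = np.random.default_rng(5)
        data = np.zeros((20, 20, 20), dtype=np.float32)
        data[6:12, 6:12, 6:12] = rng.uniform(1, 2, (6, 6, 6))
        vol = Volume(data, np.eye(4))
        shifted = Volume(np.roll(data, 2, axis=0), np.eye(4))
        assert np.allclose(
            np.roll(smooth_gaussian(vol, 2.0).data, 2, axis=0),
            smooth_gaussian(shifted, 2.0).data,
            atol=1e-5,
        )

    def test_nonpositive_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(Volume(np.zeros((3, 3, 3)), np.eye(4)), 0.0)


@pytest.fixture(scope="module")
def reg_bundle():
    """Lesion-free 64x64x40 low-noise phantom for registration tests."""
    return generate_phantom(PhantomSpec(grid_shape=(64, 64, 40), noise_sd=2.0, lesions=[], seed=0))


class TestRegistration:
    def test_constant_image_rejected(self):
        flat = Volume(np.ones((8, 8, 8)), np.eye(4))
        with pytest.raises(DegenerateInputError):
            register_affine(flat, flat)

    def test_self_registration_is_near_identity(self, reg_bundle):
        t1 = reg_bundle.t1
        rec = register_affine(t1, t1, PreprocessConfig(registration_dof="affine12"))
        center = np.array([32.0, 32.0, 20.0])
        disp = rec.apply_to_points(center)[0] - center
        scales = np.linalg.norm(rec.matrix[:3, :3], axis=0)
        assert np.linalg.norm(disp) <= 0.1
        assert np.all(np.abs(scales - 1.0) <= 0.005)

    def test_recovers_known_translation(self, reg_bundle):
        t1 = reg_bundle.t1
        true = AffineTransform.from_translation((4.0, -3.0, 2.0))
        moved = resample(t1, true.inverse(), t1, "trilinear")
        rec = register_affine(moved, t1, PreprocessConfig(registration_dof="rigid6"))
        center = np.array([32.0, 32.0, 20.0])
        err = rec.apply_to_points(center)[0] - true.apply_to_points(center)[0]
        assert np.linalg.norm(err) <= 0.5

    def test_recovers_known_isotropic_scale(self, reg_bundle):
        t1 = reg_bundle.t1
        center = np.array([32.0, 32.0, 20.0])
        m = np.eye(4)
        m[:3, :3] *= 1.1
        m[:3, 3] = center - 1.1 * center
        true = AffineTransform(m)
        moved = resample(t1, true.inverse(), t1, "trilinear")
        rec = register_affine(moved, t1, PreprocessConfig(registration_dof="affine12"))
        scales = np.linalg.norm(rec.matrix[:3, :3], axis=0)
        assert np.all(np.abs(scales - 1.1) <= 0.022)


class TestPipeline:
    def test_identity_phantom_close_to_mask_then_smooth(self, small_bundle_noise_free):
        b = small_bundle_noise_free
        res = preprocess_pipeline(
            b.flair, b.t1, b.tissues, b.template, b.exclusion_mask, PreprocessConfig()
        )
        keep = b.exclusion_mask.complement()
        ref = smooth_gaussian(apply_mask(apply_mask(b.flair, b.brain_mask), keep), 2.0)
        diff = np.abs(res.flair.data - ref.data)
        # estimated (not assumed) registration leaves sub-voxel drift that
        # nearest-neighbour resampling turns into sparse edge-voxel flips
        assert diff.mean() < 1.0
        assert (diff > 5.0).mean() < 0.02

    def test_output_grid_and_affine_equal_template(self, small_bundle):
        b = small_bundle
        res = preprocess_pipeline(
            b.flair, b.t1, b.tissues, b.template, b.exclusion_mask, PreprocessConfig()
        )
        assert res.flair.grid_shape == b.template.grid_shape
        assert np.allclose(res.flair.affine, b.template.affine)
        assert res.brain_mask.grid_shape == b.template.grid_shape

    def test_exclusion_zone_is_suppressed(self, small_bundle):
        b = small_bundle
        res = preprocess_pipeline(
            b.flair, b.t1, b.tissues, b.template, b.exclusion_mask, PreprocessConfig()
        )
        wm_mean = b.spec.tissue_means["wm"]
        core = b.exclusion_mask.data > 0
        assert res.brain_mask.data[core].sum() == 0
        # smoothing may leak a little across the boundary, never more than
        # a few percent of the white-matter mean
        assert np.abs(res.flair.data[core]).max() < 0.05 * wm_mean * 3

    def test_offset_flair_lesion_lands_at_true_template_position(self):
        spec = small_phantom_spec(
            true_flair_to_t1=AffineTransform.from_translation((3.0, 0.0, 0.0))
        )
        b = generate_phantom(spec)
        res = preprocess_pipeline(
            b.flair, b.t1, b.tissues, b.template, b.exclusion_mask, PreprocessConfig()
        )
        thr = np.percentile(res.flair.data[res.brain_mask.data > 0], 99.0)
        lesion_est = res.flair.data >= thr
        centroid = np.array(np.nonzero(lesion_est)).mean(axis=1)
        true_centroid = np.array(np.nonzero(b.ground_truth.data)).mean(axis=1)
        assert np.all(np.abs(centroid - true_centroid) <= 1.0)


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(fwhm_mm=-1.0)
    with pytest.raises(ValueError):
        PreprocessConfig(registration_dof="rigid9")
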