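"""Rigid transforms, greyscale preparation and pyramidal registration."""

import numpy as np
import pytest
from scipy import ndimage

from voxelgram import register as reg
from voxelgram.rawio import ChannelImage
from voxelgram.register import (GreyImage, PyramidConfig, RigidTransform2D,
                                SplineImage)
from voxelgram.sections import SectionImage, SectionSpec


def smooth_phantom(size=96, seed=0, blobs=2):
    """Band-limited test image with asymmetric blobs on an ellipse."""
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    c = (size - 1) / 2
    img = 60.0 * (((yy - c) / (0.4 * size)) ** 2
                  + ((xx - c) / (0.45 * size)) ** 2 <= 1)
    for _ in range(blobs):
        by, bx = rng.uniform(0.25 * size, 0.75 * size, 2)
        img += 120.0 * np.exp(-(((yy - by) ** 2 + (xx - bx) ** 2)
                                / (2 * (0.04 * size) ** 2)))
    img = ndimage.gaussian_filter(img, 1.5)
    return GreyImage(np.clip(img, 0, 255), np.ones((size, size), bool))


class TestRigidTransform:
    def test_inverse_composes_to_identity(self):
        t = RigidTransform2D(theta=13.0, tx=4.5, ty=-2.25, centre=(31.5, 40.0))
        both = t.compose(t.inverse())
        assert abs(both.theta) < 1e-9
        assert abs(both.tx) < 1e-9 and abs(both.ty) < 1e-9

    def test_apply_matches_matrix(self):
        t = RigidTransform2D(theta=90.0, tx=0.0, ty=0.0, centre=(0.0, 0.0))
        out = t.apply(np.array([[1.0, 0.0]]))
        np.testing.assert_allclose(out, [[0.0, 1.0]], atol=1e-12)

    def test_scaled_halves_translations_only(self):
        t = RigidTransform2D(theta=5.0, tx=4.0, ty=-6.0, centre=(10.0, 10.0))
        s = t.scaled(0.5)
        assert s.theta == 5.0 and s.tx == 2.0 and s.ty == -3.0


class TestNormalizeGrey:
    def test_three_value_linear_map(self):
        img = np.array([[2.0, 3.0, 4.0]])
        out = reg.normalize_grey(img)
        np.testing.assert_allclose(out.values, [[0.0, 127.5, 255.0]])

    def test_constant_image_maps_to_zero(self):
        out = reg.normalize_grey(np.full((3, 3), 9.0))
        np.testing.assert_array_equal(out.values, 0.0)

    def test_masked_outlier_does_not_affect_scaling(self):
        vals = np.array([[2.0, 3.0, 4.0, 1e6]])
        mask = np.array([[True, True, True, False]])
        out = reg.normalize_grey(vals, mask)
        np.testing.assert_allclose(out.values[0, :3], [0.0, 127.5, 255.0])
        assert out.values[0, 3] == 0.0

    def test_explicit_range_clips(self):
        vals = np.array([[0.0, 50.0, 100.0]])
        out = reg.normalize_grey(vals, vrange=(0.0, 50.0))
        np.testing.assert_allclose(out.values, [[0.0, 255.0, 255.0]])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            reg.normalize_grey(np.ones((3, 3)), np.zeros((3, 3), bool))

    def test_channel_image_input_keeps_label(self):
        img = ChannelImage(values=np.array([[1.0, 2.0]]), isotope="31P")
        assert reg.normalize_grey(img).label == "31P"


class TestComposite:
    def test_equal_weights_average(self):
        a = GreyImage(np.full((2, 2), 200.0), np.ones((2, 2), bool))
        b = GreyImage(np.full((2, 2), 100.0), np.ones((2, 2), bool))
        out = reg.composite_channel([a, b])
        np.testing.assert_array_equal(out.values, 150.0)

    def test_unit_weight_returns_first_channel(self):
        a = GreyImage(np.full((2, 2), 42.0), np.ones((2, 2), bool))
        b = GreyImage(np.full((2, 2), 7.0), np.ones((2, 2), bool))
        out = reg.composite_channel([a, b], [1.0, 0.0])
        np.testing.assert_array_equal(out.values, a.values)

    def test_bad_weights_rejected(self):
        a = GreyImage(np.zeros((2, 2)), np.ones((2, 2), bool))
        with pytest.raises(ValueError, match="sum to 1"):
            reg.composite_channel([a, a], [0.4, 0.7])
        with pytest.raises(ValueError, match="non-negative"):
            reg.composite_channel([a, a], [1.5, -0.5])

    def test_mask_union(self):
        m1 = np.zeros((2, 2), bool); m1[0] = True
        m2 = np.zeros((2, 2), bool); m2[:, 0] = True
        a = GreyImage(np.zeros((2, 2)), m1)
        b = GreyImage(np.zeros((2, 2)), m2)
        assert reg.composite_channel([a, b]).mask.sum() == 3


class TestResample:
    def test_identity_is_exact(self):
        g = smooth_phantom()
        out = reg.resample(g, RigidTransform2D(centre=(47.5, 47.5)))
        assert np.abs(out.values - g.values).max() == 0.0

    def test_integer_translation_is_exact_shift(self):
        g = smooth_phantom()
        t = RigidTransform2D(tx=2.0, ty=0.0, centre=(47.5, 47.5))
        out = reg.resample(g, t)
        np.testing.assert_allclose(out.values[:, 2:], g.values[:, :-2],
                                   atol=1e-8)
        assert np.abs(out.values[:, :2]).max() == 0.0  # vacated edge filled

    def test_rotation_round_trip(self):
        g = smooth_phantom()
        c = (47.5, 47.5)
        fwd = reg.resample(g, RigidTransform2D(theta=10.0, centre=c))
        back = reg.resample(fwd, RigidTransform2D(theta=-10.0, centre=c))
        interior = np.zeros(g.values.shape, bool)
        interior[20:76, 20:76] = True
        err = np.abs(back.values - g.values)[interior].max()
        assert err < 1e-3 * 255

    def test_spline_model_reproduces_source_at_pixels(self):
        g = smooth_phantom()
        sp = SplineImage(g.values)
        rr, cc = np.meshgrid(np.arange(96), np.arange(96), indexing="ij")
        vals = sp(rr.ravel().astype(float), cc.ravel().astype(float))
        np.testing.assert_allclose(vals.reshape(96, 96), g.values, atol=1e-9)


class TestRegisterPair:
    def test_identity_recovery(self):
        g = smooth_phantom()
        res = reg.register_pair(g, g)
        assert abs(res.transform.theta) <= 0.05
        assert abs(res.transform.tx) <= 0.1 and abs(res.transform.ty) <= 0.1
        assert res.residual < 1e-3

    def test_known_transform_recovery_two_blob(self):
        g = smooth_phantom(96, seed=3)
        t = RigidTransform2D(theta=7.0, tx=4.0, ty=-3.0, centre=(47.5, 47.5))
        test = reg.resample(g, t.inverse())
        res = reg.register_pair(g, test)
        assert abs(res.transform.theta - 7.0) < 0.5
        assert abs(res.transform.tx - 4.0) < 0.5
        assert abs(res.transform.ty + 3.0) < 0.5

    def test_final_residual_never_exceeds_identity_residual(self):
        g = smooth_phantom(64, seed=4)
        other = smooth_phantom(64, seed=9, blobs=3)
        res = reg.register_pair(g, other)
        identity_resid = np.sqrt(np.mean(
            (g.values - other.values) ** 2)) / 255.0
        assert res.residual <= identity_resid + 1e-12

    def test_residual_trace_non_increasing_on_phantom(self):
        g = smooth_phantom(96, seed=5)
        t = RigidTransform2D(theta=-6.0, tx=3.0, ty=2.0, centre=(47.5, 47.5))
        res = reg.register_pair(g, reg.resample(g, t.inverse()))
        trace = np.asarray(res.residuals)
        assert np.all(np.diff(trace) <= 1e-6)

    def test_empty_mask_rejected(self):
        g = smooth_phantom(32)
        empty = GreyImage(np.zeros((32, 32)), np.zeros((32, 32), bool))
        with pytest.raises(ValueError, match="empty mask"):
            reg.register_pair(g, empty)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="congruent"):
            reg.register_pair(smooth_phantom(32), smooth_phantom(64))


def make_stack(n=4, size=64, seed=2, theta_max=6.0, shift_max=4.0):
    """Identical textured sections under known rigid mounts.

    The base image is a band-limited random field restricted to an
    ellipse that sits well inside the frame, so masks survive the
    perturbations without clipping at the frame edge."""
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    cv = (size - 1) / 2
    ell = (((yy - cv) / (0.32 * size)) ** 2
           + ((xx - cv) / (0.38 * size)) ** 2) <= 1
    field = ndimage.gaussian_filter(rng.standard_normal((size, size)), 2.0)
    base = np.where(ell, 100.0 + 30.0 * field / field.std(), 0.0)
    base = np.clip(base, 0, None)
    c = (cv, cv)
    sections, truths = [], []
    for k in range(n):
        t = (RigidTransform2D(centre=c) if k == 0 else
             RigidTransform2D(theta=float(rng.uniform(-theta_max, theta_max)),
                              tx=float(rng.uniform(-shift_max, shift_max)),
                              ty=float(rng.uniform(-shift_max, shift_max)),
                              centre=c))
        mounted = np.clip(reg.warp_values(base, t.inverse(), order=3), 0, None)
        mask = reg.warp_mask(ell, t.inverse())
        channels = {
            "31P": ChannelImage(mounted, isotope="31P"),
            "197Au": ChannelImage(mounted * 0.5, isotope="197Au"),
        }
        sections.append(SectionImage(
            channels=channels, mask=mask,
            spec=SectionSpec(order_index=k, bbox=(0, 0, size, size))))
        truths.append(t)
    return sections, truths


class TestRegisterStack:
    def test_single_section_gives_empty_results(self):
        secs, _ = make_stack(n=1)
        assert reg.register_stack(secs, ("31P",)) == []

    def test_known_perturbations_recovered(self):
        secs, truths = make_stack(n=4)
        results = reg.register_stack(secs, ("31P",))
        for res, t in zip(results, truths[1:]):
            assert abs(res.transform.theta - t.theta) < 0.5
            assert np.hypot(res.transform.tx - t.tx,
                            res.transform.ty - t.ty) < 0.5

    def test_missing_channel_raises(self):
        secs, _ = make_stack(n=2)
        with pytest.raises(KeyError, match="66Zn"):
            reg.register_stack(secs, ("66Zn",))

    def test_transform_shared_across_channels(self):
        # the parameter set recovered from one channel is applied verbatim
        # to every channel of the section
        secs, _ = make_stack(n=3)
        results = reg.register_stack(secs, ("31P",))
        aligned = reg.apply_results(secs, results)
        for k in (1, 2):
            t = results[k - 1].transform
            expect = reg.warp_values(secs[k].channels["197Au"].values, t)
            mask = reg.warp_mask(secs[k].mask, t)
            expect[~mask] = 0.0
            np.testing.assert_allclose(
                aligned[k].channels["197Au"].values, expect, atol=1e-9)


class TestApplyResults:
    def test_identity_results_leave_sections_unchanged(self):
        secs, _ = make_stack(n=3, theta_max=0.0, shift_max=0.0)
        c = (31.5, 31.5)
        results = [reg.RegistrationResult(transform=RigidTransform2D(centre=c))
                   for _ in range(2)]
        aligned = reg.apply_results(secs, results)
        for a, s in zip(aligned, secs):
            np.testing.assert_array_equal(a.channels["31P"].values,
                                          s.channels["31P"].values)

    def test_tissue_count_preserved_under_small_transforms(self):
        secs, _ = make_stack(n=3)
        results = reg.register_stack(secs, ("31P",))
        aligned = reg.apply_results(secs, results)
        for a, s in zip(aligned[1:], secs[1:]):
            assert abs(int(a.mask.sum()) - int(s.mask.sum())) \
                <= 0.02 * s.mask.sum()

    def test_masked_exterior_stays_zero(self):
        secs, _ = make_stack(n=2)
        masked = []
        for s in secs:
            m = np.zeros(s.mask.shape, bool)
            m[10:50, 10:50] = True
            ch = {k: v.copy_with(np.where(m, v.values, 0.0))
                  for k, v in s.channels.items()}
            masked.append(SectionImage(channels=ch, mask=m, spec=s.spec))
        results = reg.register_stack(masked, ("31P",))
        aligned = reg.apply_results(masked, results)
        assert np.abs(aligned[1].channels["31P"].values[~aligned[1].mask]).max() == 0.0


class TestAlignmentResidual:
    def test_identical_images_give_zero(self):
        g = smooth_phantom(32)
        assert reg.alignment_residual(g, g) == 0.0

    def test_extreme_disagreement_gives_one(self):
        m = np.ones((4, 4), bool)
        a = GreyImage(np.full((4, 4), 255.0), m)
        b = GreyImage(np.zeros((4, 4)), m)
        assert reg.alignment_residual(a, b) == 1.0

    def test_two_pixel_arithmetic(self):
        m = np.array([[True, True]])
        a = GreyImage(np.array([[0.0, 255.0]]), m)
        b = GreyImage(np.array([[255.0, 255.0]]), m)
        assert reg.alignment_residual(a, b) == 0.5

    def test_empty_union_rejected(self):
        a = GreyImage(np.zeros((2, 2)), np.zeros((2, 2), bool))
        with pytest.raises(ValueError, match="union"):
            reg.alignment_residual(a, a)


def test_transform_serialisation_round_trip(tmp_path):
    c = (15.5, 15.5)
    results = [
        reg.RegistrationResult(
            transform=RigidTransform2D(theta=3.25, tx=-1.5, ty=0.75, centre=c),
            residuals=[0.3, 0.2, 0.1], converged=True, evaluations=321),
    ]
    path = reg.save_transforms(results, tmp_path / "t.json", frame_shape=(32, 32))
    back = reg.load_transforms(path)
    assert back[0].transform == results[0].transform
    assert back[0].residuals == results[0].residuals
    assert back[0].evaluations == 321


def test_pyramid_config_invariants():
    cfg = PyramidConfig(levels=4, factor=2)
    assert cfg.coarsest_fraction == pytest.approx(1 / 16)
    with pytest.raises(ValueError):
        PyramidConfig(levels=0)
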