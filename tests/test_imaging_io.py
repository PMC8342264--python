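import numpy as np
import pytest
import imageio.v3 as iio
from skimage.measure import label

from embolocate.imaging_io import (
    BlockfaceStack,
    DimensionMismatchError,
    RigidTransform2D,
    apply_rigid,
    compute_brain_volume,
    midline_rotation_angle,
    read_image_series,
    register_rigid,
    rigid_align_stack,
    rotate_stack_by_midline,
)


def _write_series(tmp_path, images):
    paths = []
    for i, img in enumerate(images):
        p = tmp_path / f"section_{i:03d}.png"
        iio.imwrite(p, img)
        paths.append(p)
    return paths


class TestReadImageSeries:
    def test_preserves_count_order_and_calibration(self, tmp_path):
        rng = np.random.default_rng(0)
        images = [rng.integers(0, 255, (32, 40, 3), dtype=np.uint8) for _ in range(67)]
        paths = _write_series(tmp_path, images)
        stack = read_image_series(paths, pixel_size_um=6.5, section_thickness_um=100.0)
        assert stack.n_sections == 67
        assert stack.pixel_size_um == 6.5
        assert stack.section_thickness_um == 100.0
        np.testing.assert_array_equal(stack[0], images[0])
        np.testing.assert_array_equal(stack[66], images[66])

    def test_mixed_dimensions_rejected(self, tmp_path):
        images = [np.zeros((32, 40, 3), np.uint8), np.zeros((30, 40, 3), np.uint8)]
        paths = _write_series(tmp_path, images)
        with pytest.raises(DimensionMismatchError):
            read_image_series(paths, 6.5, 100.0)

    def test_unreadable_file_names_the_culprit(self, tmp_path):
        bad = tmp_path / "broken.png"
        bad.write_bytes(b"not an image")
        with pytest.raises(OSError, match="broken.png"):
            read_image_series([bad], 6.5, 100.0)


class TestRigidTransform:
    def test_inverse_composes_to_identity(self):
        t = RigidTransform2D(rotation_deg=17.0, translation=(5.2, -3.1))
        shape = (100, 120)
        ident = t.compose(t.inverse(shape), shape)
        assert abs(ident.rotation_deg) < 1e-9
        assert np.allclose(ident.translation, 0.0, atol=1e-9)

    def test_point_mapping_matches_composition(self):
        a = RigidTransform2D(rotation_deg=10.0, translation=(3.0, 1.0))
        b = RigidTransform2D(rotation_deg=-4.0, translation=(-1.0, 2.0))
        shape = (50, 60)
        pts = np.array([[5.0, 7.0], [30.0, 40.0]])
        via_compose = a.compose(b, shape).apply_points(pts, shape)
        sequential = a.apply_points(b.apply_points(pts, shape), shape)
        np.testing.assert_allclose(via_compose, sequential, atol=1e-9)


class TestMidlineRotation:
    def test_vertical_midline_is_identity(self):
        assert midline_rotation_angle([(50, 10), (50, 90)]) == 0.0

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="midline"):
            midline_rotation_angle([(5, 5), (5, 5)])

    def test_tilted_midline_becomes_vertical(self):
        # a line 10 degrees off vertical; after rotation its endpoints share x
        stack = BlockfaceStack(np.zeros((3, 80, 80), np.uint8), 6.5, 100.0)
        theta = np.deg2rad(10.0)
        p1 = (40.0, 10.0)
        p2 = (40.0 + 70.0 * np.sin(theta), 10.0 + 70.0 * np.cos(theta))
        rotated, angle = rotate_stack_by_midline(stack, [p1, p2])
        assert angle == pytest.approx(10.0, abs=1e-9)
        # replicate the applied transform on the endpoints
        h, w = 80, 80
        t = RigidTransform2D(rotation_deg=angle)
        q1, q2 = t.apply_points(np.array([p1, p2]), (h, w))
        assert abs(q1[0] - q2[0]) < 0.5

    def test_same_rotation_applied_to_all_sections_without_clipping(self):
        rng = np.random.default_rng(3)
        sections = np.zeros((4, 60, 60), np.uint8)
        sections[:, 20:40, 25:35] = 200
        stack = BlockfaceStack(sections, 6.5, 100.0)
        rotated, angle = rotate_stack_by_midline(stack, [(10.0, 5.0), (20.0, 55.0)])
        # foreground mass is conserved within interpolation effects on every section
        for i in range(4):
            before = (stack[i] > 100).sum()
            after = (rotated[i] > 100).sum()
            assert after == pytest.approx(before, rel=0.05)
        # all output sections share the padded canvas
        assert rotated.sections.shape[1:] == rotated[0].shape


class TestRigidAlignStack:
    def test_identical_sections_give_identity(self, blob_image):
        stack = BlockfaceStack(np.stack([blob_image] * 4), 6.5, 100.0)
        aligned, transforms = rigid_align_stack(stack)
        for t in transforms:
            assert abs(t.rotation_deg) <= 0.1
            assert np.all(np.abs(t.translation) <= 0.1)

    def test_known_shift_recovered(self, blob_image):
        shifted = apply_rigid(blob_image, RigidTransform2D(translation=(7, -3)), order=1)
        stack = BlockfaceStack(np.stack([blob_image, shifted]), 6.5, 100.0)
        _, transforms = rigid_align_stack(stack, reference=0)
        t = transforms[1]
        assert t.translation[0] == pytest.approx(-7, abs=0.5)
        assert t.translation[1] == pytest.approx(3, abs=0.5)

    def test_known_rotation_recovered(self, blob_image):
        rotated = apply_rigid(blob_image, RigidTransform2D(rotation_deg=2.0), order=1)
        stack = BlockfaceStack(np.stack([blob_image, rotated]), 6.5, 100.0)
        _, transforms = rigid_align_stack(stack, reference=0)
        assert transforms[1].rotation_deg == pytest.approx(-2.0, abs=0.2)

    def test_chained_perturbations_recovered(self, blob_image):
        # known per-section rigid perturbations, chained through the stack
        rng = np.random.default_rng(5)
        true = [RigidTransform2D()]
        sections = [blob_image]
        shape = blob_image.shape
        for _ in range(3):
            t = RigidTransform2D(
                rotation_deg=float(rng.uniform(-2, 2)),
                translation=(float(rng.uniform(-5, 5)), float(rng.uniform(-5, 5))),
            )
            true.append(t)
            sections.append(apply_rigid(blob_image, t, order=1))
        stack = BlockfaceStack(np.stack(sections), 6.5, 100.0)
        _, transforms = rigid_align_stack(stack, reference=0)
        for est, t in zip(transforms, true):
            inv = t.inverse(shape)
            assert est.rotation_deg == pytest.approx(inv.rotation_deg, abs=0.2)
            assert est.translation[0] == pytest.approx(inv.translation[0], abs=0.5)
            assert est.translation[1] == pytest.approx(inv.translation[1], abs=0.5)

    def test_all_black_section_warns_identity(self, blob_image):
        stack = BlockfaceStack(
            np.stack([blob_image, np.zeros_like(blob_image)]), 6.5, 100.0
        )
        with pytest.warns(UserWarning, match="all-black"):
            _, transforms = rigid_align_stack(stack, reference=0)
        assert transforms[1].rotation_deg == 0.0
        assert transforms[1].translation == (0.0, 0.0)

    def test_component_count_preserved_under_nearest_neighbour(self, blob_image):
        mask = (blob_image > 120).astype(np.uint8)
        n_before = label(mask, connectivity=2).max()
        moved = apply_rigid(mask, RigidTransform2D(rotation_deg=3.0, translation=(4, 2)), order=0)
        n_after = label(moved, connectivity=2).max()
        assert n_after == n_before


class TestBrainVolume:
    def test_arithmetic(self):
        # 1e6 foreground px at 6.5 um/px and 100 um thickness -> 4.225 mm^3
        section = np.full((1000, 1000), 255, np.uint8)
        stack = BlockfaceStack(section[None], 6.5, 100.0)
        assert compute_brain_volume(stack) == pytest.approx(4.225)

    def test_black_stack_is_zero(self):
        stack = BlockfaceStack(np.zeros((5, 50, 50), np.uint8), 6.5, 100.0)
        assert compute_brain_volume(stack) == 0.0

    def test_linear_in_section_count(self):
        rng = np.random.default_rng(1)
        section = (rng.random((60, 60)) > 0.5).astype(np.uint8) * 200
        single = BlockfaceStack(section[None], 6.5, 100.0)
        double = BlockfaceStack(np.stack([section, section]), 6.5, 100.0)
        assert compute_brain_volume(double) == pytest.approx(2 * compute_brain_volume(single))

    def test_invariant_under_rigid_transform(self, blob_image):
        stack = BlockfaceStack(blob_image[None], 6.5, 100.0)
        moved = apply_rigid(blob_image, RigidTransform2D(rotation_deg=5.0, translation=(3, -2)), order=0)
        moved_stack = BlockfaceStack(moved[None], 6.5, 100.0)
        v0 = compute_brain_volume(stack)
        v1 = compute_brain_volume(moved_stack)
        assert v1 == pytest.approx(v0, rel=0.01)
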