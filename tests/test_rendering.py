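"""Transfer function, ray-cast compositing, orthoslices, meshes, snapshots."""

import math

import numpy as np
import pytest

from voxscene import (
    ImageVolume,
    TransferFunction,
    composite_front_to_back,
    create_scene,
    custom_triangle_mesh,
    load_snapshot,
    render_mesh,
    render_orthoslices,
    render_volume,
    save_snapshot,
    snapshot,
)
from voxscene.fixtures import make_sphere_volume
from voxscene.rendering import orthoslice_planes


class TestTransferFunction:
    def test_zero_intensity_is_fully_transparent(self):
        assert TransferFunction(255).alpha(0) == 0.0

    def test_max_intensity_opaque_when_content_opaque(self):
        assert TransferFunction(255, content_transparency=0.0).alpha(255) == 1.0

    def test_alpha_non_decreasing_over_all_8bit_intensities(self):
        alphas = TransferFunction(255).alpha(np.arange(256))
        assert np.all(np.diff(alphas) >= 0)

    def test_content_transparency_scales_alpha(self):
        tf = TransferFunction(255, content_transparency=0.25)
        assert tf.alpha(255) == pytest.approx(0.75)

    def test_classify_returns_rgba(self):
        rgba = TransferFunction(255, color=(1, 0, 0)).classify(255)
        assert rgba.shape == (4,)
        assert np.allclose(rgba, [1, 0, 0, 1])


class TestCompositing:
    @pytest.mark.parametrize("a,n", [(0.1, 5), (0.3, 10), (0.02, 64)])
    def test_homogeneous_samples_match_closed_form(self, a, n):
        colors = np.ones((n, 3))
        _, alpha = composite_front_to_back(colors, np.full(n, a))
        assert alpha == pytest.approx(1 - (1 - a) ** n, abs=1e-6)

    def test_front_to_back_equals_back_to_front_oracle(self, rng):
        colors = rng.random((20, 3))
        alphas = rng.random(20) * 0.4
        C, A = composite_front_to_back(colors, alphas)
        # back-to-front "over" of the same samples
        Cb, Ab = np.zeros(3), 0.0
        for c, a in zip(colors[::-1], alphas[::-1]):
            Cb = a * c + (1 - a) * Cb
            Ab = a + (1 - a) * Ab
        assert np.allclose(C, Cb, atol=1e-12)
        assert A == pytest.approx(Ab, abs=1e-12)

    def test_composited_alpha_never_exceeds_one(self, rng):
        _, A = composite_front_to_back(rng.random((50, 3)), rng.random(50))
        assert A <= 1.0 + 1e-12


class TestVolumeRendering:
    def test_empty_scene_renders_background(self):
        scene = create_scene(32, 16)
        scene.background = (0.2, 0.3, 0.4)
        img = render_volume(scene)
        assert img.pixels.shape == (16, 32, 4)
        assert np.allclose(img.pixels[:, :, :3], [0.2, 0.3, 0.4])

    def test_edit_changes_render(self):
        vol = ImageVolume(np.zeros((8, 8, 8), np.uint8))
        scene = create_scene(32, 32)
        scene.add_voltex(vol)
        scene.reset_view()
        before = render_volume(scene).pixels
        vol.set_voxel(4, 4, 4, 255)
        after = render_volume(scene).pixels
        assert np.any(before != after)

    def test_view_rotation_equals_inverse_data_rotation(self, smooth_volume):
        """Rotating the view 90° about z matches rotating the voxel grid by
        the inverse rotation, pixel for pixel."""
        scene = create_scene(64, 64)
        scene.add_voltex(smooth_volume)
        scene.reset_view()
        scene.rotate((0, 0, 1), 90.0)
        turned_view = render_volume(scene).pixels

        rotated = ImageVolume(
            np.ascontiguousarray(np.rot90(smooth_volume.data, k=-1, axes=(1, 2)))
        )
        scene2 = create_scene(64, 64)
        scene2.add_voltex(rotated)
        scene2.reset_view()
        assert np.abs(turned_view - render_volume(scene2).pixels).max() <= 2 / 255

    def test_opacity_correction_keeps_composite_consistent(self):
        """Halving the sampling step with opacity correction changes the
        homogeneous-volume composite only by boundary discretization."""
        vol = ImageVolume(np.full((16, 16, 16), 128, np.uint8))
        scene = create_scene(32, 32)
        scene.add_voltex(vol)
        scene.reset_view()
        default = render_volume(scene).pixels[16, 16, 0]
        halved = render_volume(scene, step=0.25).pixels[16, 16, 0]
        assert halved == pytest.approx(default, abs=0.01)

    def test_hidden_content_contributes_nothing(self):
        vol = make_sphere_volume((16, 16, 16), radius=5)
        scene = create_scene(32, 32)
        c = scene.add_voltex(vol)
        scene.reset_view()
        empty = create_scene(32, 32)
        c.visible = False
        assert np.array_equal(render_volume(scene).pixels, render_volume(empty).pixels)
        c.visible = True
        shown = render_volume(scene).pixels
        c.visible = False
        c.visible = True
        assert np.array_equal(render_volume(scene).pixels, shown)


class TestOrthoslices:
    def test_z_plane_block_equals_voxel_slice(self, rng):
        vol = ImageVolume(rng.integers(0, 256, (4, 6, 8), dtype=np.uint8).astype(np.uint8))
        scene = create_scene(32, 32)
        c = scene.add_orthoslice(vol)
        img = render_orthoslices(scene)
        iz = c.slice_positions[2]
        block = img.pixels[16 : 16 + 6, 16 : 16 + 8, 0]
        assert np.allclose(block, vol.data[iz] / 255.0, atol=1e-9)

    def test_three_planes_per_content(self):
        scene = create_scene(32, 32)
        c = scene.add_orthoslice(ImageVolume(np.zeros((4, 4, 4), np.uint8)))
        assert len(orthoslice_planes(c)) == 3

    def test_out_of_range_slice_rejected(self):
        scene = create_scene(32, 32)
        c = scene.add_orthoslice(ImageVolume(np.zeros((4, 4, 4), np.uint8)))
        with pytest.raises(IndexError):
            c.set_slice_positions(4, 0, 0)


class TestMeshRendering:
    def test_empty_mesh_renders_background(self):
        scene = create_scene(16, 16)
        scene.add_custom_mesh(custom_triangle_mesh(np.zeros((0, 3))))
        assert np.allclose(render_mesh(scene).pixels[:, :, :3], 0.0)

    def test_sphere_silhouette_matches_projected_disk(self):
        scene = create_scene(128, 128)
        scene.add_isosurface(make_sphere_volume((48, 48, 48), radius=20), threshold=128)
        scene.reset_view()
        img = render_mesh(scene)
        covered = int((img.pixels[:, :, :3].sum(axis=2) > 0).sum())
        r_px = 20.0 * scene.view_zoom
        assert covered == pytest.approx(math.pi * r_px**2, rel=0.05)

    def test_back_facing_triangle_still_visible(self):
        # wound so its normal points away from the camera
        scene = create_scene(32, 32)
        scene.add_custom_mesh(
            custom_triangle_mesh([(0, 0, 0), (0, 10, 0), (10, 0, 0)])
        )
        scene.reset_view()
        img = render_mesh(scene)
        assert (img.pixels[:, :, :3].sum(axis=2) > 0).sum() > 0


class TestSnapshot:
    def test_snapshot_dimensions_match_viewport(self):
        scene = create_scene(640, 480)
        img = snapshot(scene)
        assert (img.width, img.height) == (640, 480)

    def test_all_hidden_equals_empty_scene(self):
        scene = create_scene(48, 48)
        vol = make_sphere_volume((16, 16, 16), radius=5)
        a = scene.add_voltex(vol)
        b = scene.add_orthoslice(vol)
        scene.reset_view()
        a.visible = False
        b.visible = False
        empty = create_scene(48, 48)
        assert np.array_equal(snapshot(scene).pixels, snapshot(empty).pixels)

    def test_png_round_trip_at_8bit_quantization(self, tmp_path):
        scene = create_scene(40, 30)
        scene.add_orthoslice(make_sphere_volume((16, 16, 16), radius=5))
        scene.reset_view()
        p = tmp_path / "snap.png"
        save_snapshot(scene, p)
        back = load_snapshot(p)
        assert np.array_equal(back.to_uint8(), snapshot(scene).to_uint8())

    def test_landmarks_rendered_as_colored_disks(self):
        vol = ImageVolume(np.zeros((8, 8, 8), np.uint8))
        scene = create_scene(64, 64)
        c = scene.add_voltex(vol)
        scene.reset_view()
        c.landmarks.add("tip", (4.0, 4.0, 4.0), color=(0.0, 1.0, 0.0), radius=2.0)
        img = snapshot(scene)
        assert np.any(img.pixels[:, :, 1] > 0.5)
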