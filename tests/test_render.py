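import numpy as np
import pytest

from volcoloc import (
    Camera,
    MultiChannelStack,
    RenderSettings,
    VoxelGrid,
    composite_front_to_back,
    ray_box_intersect,
    render,
    render_isosurface,
    render_raycast,
    render_slices,
    sample_trilinear,
)
from volcoloc.render import _ray_box_batch, sample_volume

from .reference import back_to_front_composite


def mono_stack(values, spacing=(1.0, 1.0, 1.0), color=(1.0, 1.0, 1.0)):
    return MultiChannelStack(
        channels=(VoxelGrid(np.asarray(values, dtype=np.uint8), spacing=spacing),),
        colors=(color,),
    )


def cube_stack(n=16, value=128, spacing=(1.0, 1.0, 1.0)):
    return mono_stack(np.full((n, n, n), value, dtype=np.uint8), spacing=spacing)


def front_camera(stack, width=32, height=32, dist_factor=2.0, fov=30.0):
    lz, ly, lx = stack.extent_um
    return Camera(
        position=(lx / 2, ly / 2, -dist_factor * max(lx, ly, lz)),
        view_dir=(0.0, 0.0, 1.0),
        fov_deg=fov, width=width, height=height,
    )


class TestTrilinear:
    def test_voxel_center_identity(self, rng):
        values = rng.integers(0, 256, (4, 5, 6)).astype(np.uint8)
        grid = VoxelGrid(values, spacing=(0.4, 0.2, 0.3))
        for _ in range(10):
            iz, iy, ix = (int(rng.integers(0, n)) for n in values.shape)
            point = ((ix + 0.5) * 0.3, (iy + 0.5) * 0.2, (iz + 0.5) * 0.4)
            assert sample_trilinear(grid, point) == pytest.approx(float(values[iz, iy, ix]))

    def test_midpoint_linearity(self):
        values = np.zeros((1, 1, 2), dtype=np.uint8)
        values[0, 0, 1] = 1
        grid = VoxelGrid(values, spacing=(1.0, 1.0, 1.0))
        assert sample_trilinear(grid, (1.0, 0.5, 0.5)) == pytest.approx(0.5)

    def test_cell_center_eighth_weight(self):
        # one corner of the 2x2x2 cell holds 8, the rest 0: the cell center
        # weights every corner by 1/8 -> 1.0
        values = np.zeros((2, 2, 2), dtype=np.uint8)
        values[0, 0, 0] = 8
        grid = VoxelGrid(values, spacing=(1.0, 1.0, 1.0))
        assert sample_trilinear(grid, (1.0, 1.0, 1.0)) == pytest.approx(1.0)

    def test_out_of_bounds_zero(self):
        grid = VoxelGrid(np.full((2, 2, 2), 200, dtype=np.uint8), spacing=(1, 1, 1))
        assert sample_trilinear(grid, (-0.1, 1.0, 1.0)) == 0.0
        assert sample_trilinear(grid, (1.0, 1.0, 2.5)) == 0.0

    def test_clamp_to_edge_inside(self):
        grid = VoxelGrid(np.full((2, 2, 2), 100, dtype=np.uint8), spacing=(1, 1, 1))
        # between boundary and voxel center: clamped, not faded to zero
        assert sample_trilinear(grid, (0.1, 0.1, 0.1)) == pytest.approx(100.0)


class TestRayBox:
    def test_axis_aligned_hit(self):
        t = ray_box_intersect((0.5, 0.5, -1.0), (0.0, 0.0, 1.0), (0, 0, 0), (1, 1, 1))
        assert t == pytest.approx((1.0, 2.0))

    def test_parallel_outside_misses(self):
        assert ray_box_intersect((2.0, 0.5, -1.0), (0.0, 0.0, 1.0), (0, 0, 0), (1, 1, 1)) is None

    def test_zero_direction_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            ray_box_intersect((0, 0, 0), (0.0, 0.0, 0.0), (0, 0, 0), (1, 1, 1))

    def test_against_point_marching_oracle(self, rng):
        lo, hi = np.zeros(3), np.array([2.0, 3.0, 1.5])
        origins = rng.uniform(-3, 6, (1000, 3))
        dirs = rng.normal(size=(1000, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        t_near, t_far, hit = _ray_box_batch(origins, dirs, lo, hi)
        ts = np.linspace(0.0, 12.0, 400)
        for i in range(0, 1000, 7):
            pts = origins[i] + ts[:, None] * dirs[i]
            inside = np.all((pts >= lo - 1e-9) & (pts <= hi + 1e-9), axis=1)
            if hit[i] and t_far[i] >= 0:
                lo_t, hi_t = max(t_near[i], 0.0), t_far[i]
                strict = (ts > lo_t + 0.05) & (ts < hi_t - 0.05)
                assert np.all(inside[strict])
                outside = (ts < lo_t - 0.05) | (ts > hi_t + 0.05)
                assert not np.any(inside[outside])
            else:
                assert not np.any(inside)


class TestCompositing:
    def test_two_half_slabs(self):
        acc = np.zeros(4)
        acc = composite_front_to_back(acc, np.array([1.0, 1.0, 1.0, 0.5]))
        acc = composite_front_to_back(acc, np.array([1.0, 1.0, 1.0, 0.5]))
        assert acc[3] == pytest.approx(0.75)

    def test_opaque_absorbs(self):
        acc = composite_front_to_back(np.zeros(4), np.array([0.2, 0.4, 0.6, 1.0]))
        out = composite_front_to_back(acc, np.array([1.0, 0.0, 0.0, 1.0]))
        np.testing.assert_allclose(out, acc)

    def test_front_to_back_equals_back_to_front(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 12))
            samples = rng.uniform(0, 1, (n, 4))
            acc = np.zeros(4)
            for s in samples:
                acc = composite_front_to_back(acc, s)
            rgb_btf, a_btf = back_to_front_composite(samples)
            np.testing.assert_allclose(acc[:3], rgb_btf, atol=1e-9)
            np.testing.assert_allclose(acc[3], a_btf, atol=1e-9)


class TestRaycast:
    def test_empty_volume_is_background(self):
        stack = mono_stack(np.zeros((8, 8, 8), dtype=np.uint8))
        settings = RenderSettings(mode="raycast", background=(0.1, 0.2, 0.3))
        img = render_raycast(stack, front_camera(stack), settings)
        np.testing.assert_allclose(img[..., :3], np.broadcast_to((0.1, 0.2, 0.3), img[..., :3].shape))
        assert np.all(img[..., 3] == 0.0)

    def test_central_voxel_projects_to_image_center(self):
        values = np.zeros((9, 9, 9), dtype=np.uint8)
        values[4, 4, 4] = 255
        stack = mono_stack(values)
        cam = front_camera(stack, width=33, height=33, fov=40.0)
        img = render_raycast(stack, cam, RenderSettings(mode="raycast", step=0.25))
        brightness = img[..., :3].sum(axis=-1)
        assert np.unravel_index(np.argmax(brightness), brightness.shape) == (16, 16)

    def test_homogeneous_cube_alpha_closed_form(self):
        value = 32
        stack = cube_stack(n=16, value=value)
        i = value / 255.0
        expected = 1.0 - (1.0 - i) ** 16.0  # L = 16, dt_ref = 1
        cam = Camera(position=(8.0, 8.0, -40.0), view_dir=(0, 0, 1),
                     fov_deg=5.0, width=5, height=5)
        errors = []
        for step in (1.0, 0.5, 0.25, 0.125):
            img = render_raycast(stack, cam, RenderSettings(
                mode="raycast", step=step, early_stop_alpha=1.0))
            errors.append(abs(img[2, 2, 3] - expected))
        assert errors[-1] < 0.02
        assert errors[-1] <= errors[0] + 1e-9

    def test_step_halving_bound(self):
        stack = cube_stack(n=8, value=100)
        cam = Camera(position=(4.0, 4.0, -20.0), view_dir=(0, 0, 1),
                     fov_deg=5.0, width=3, height=3)
        alphas = []
        for step in (0.5, 0.25):
            img = render_raycast(stack, cam, RenderSettings(
                mode="raycast", step=step, early_stop_alpha=1.0))
            alphas.append(img[1, 1, 3])
        # opacity correction makes the result nearly step-independent
        assert abs(alphas[0] - alphas[1]) < 0.01

    def test_global_opacity_zero_is_background(self):
        stack = cube_stack(8)
        for mode, fn in (("raycast", render_raycast), ("slices", render_slices)):
            img = fn(stack, front_camera(stack), RenderSettings(
                mode=mode, global_opacity=0.0, background=(0.3, 0.1, 0.0)))
            np.testing.assert_allclose(
                img[..., :3], np.broadcast_to((0.3, 0.1, 0.0), img[..., :3].shape), atol=1e-12)

    def test_components_in_unit_range(self, rng):
        values = rng.integers(0, 256, (8, 8, 8)).astype(np.uint8)
        stack = mono_stack(values, color=(0.2, 0.9, 0.4))
        for mode in ("raycast", "slices", "isosurface"):
            img = render(stack, front_camera(stack, 16, 16),
                         RenderSettings(mode=mode, iso_value=0.5))
            assert np.all(img >= 0.0) and np.all(img <= 1.0)

    def test_camera_volume_corotation_equivariance(self):
        rng = np.random.default_rng(3)
        values = rng.integers(0, 256, (12, 12, 12)).astype(np.uint8)
        stack = mono_stack(values)
        n = 12.0
        cam = Camera(position=(n / 2, n / 2, -2.5 * n), view_dir=(0, 0, 1),
                     fov_deg=30, width=24, height=24)
        base = render_raycast(stack, cam, RenderSettings(mode="raycast", step=0.5))
        # rotate volume and camera together by +90 deg about the volume center z-axis:
        # world (x, y) -> (c - (y - c), c + (x - c))
        c = n / 2.0
        rotated_values = np.rot90(values, k=-1, axes=(1, 2))
        rotated_stack = mono_stack(rotated_values)
        pos = np.asarray(cam.position)
        rot = lambda p: np.array([c - (p[1] - c), c + (p[0] - c), p[2]])
        cam_rot = Camera(position=tuple(rot(pos)),
                         view_dir=(0, 0, 1),
                         up=tuple(rot(np.array([0, 1, 0]) + np.array([c, c, 0])) - np.array([c, c, 0])),
                         fov_deg=30, width=24, height=24)
        rotated = render_raycast(rotated_stack, cam_rot, RenderSettings(mode="raycast", step=0.5))
        np.testing.assert_allclose(rotated, base, atol=1e-9)


class TestSlices:
    def test_empty_volume_is_background(self):
        stack = mono_stack(np.zeros((8, 8, 8), dtype=np.uint8))
        img = render_slices(stack, front_camera(stack), RenderSettings(
            mode="slices", background=(0.5, 0.5, 0.5)))
        np.testing.assert_allclose(img[..., :3], 0.5)

    def test_matches_raycast_on_smooth_phantom(self):
        zz, yy, xx = np.meshgrid(*[np.arange(24)] * 3, indexing="ij")
        r2 = (zz - 11.5) ** 2 + (yy - 11.5) ** 2 + (xx - 11.5) ** 2
        values = (200 * np.exp(-r2 / (2 * 36.0))).astype(np.uint8)
        stack = mono_stack(values, color=(0.9, 0.5, 0.2))
        cam = front_camera(stack, width=40, height=40, fov=35.0)
        step = 0.5
        ray_img = render_raycast(stack, cam, RenderSettings(
            mode="raycast", step=step, early_stop_alpha=1.0))
        # matched sampling density: one slice per step distance along the view axis
        depth_span = 24.0
        count = int(np.ceil(depth_span / step)) + 2
        slice_img = render_slices(stack, cam, RenderSettings(
            mode="slices", slice_count=count))
        diff = np.abs(ray_img - slice_img)[..., :3].mean()
        assert diff < 0.02

    def test_camera_inside_volume(self):
        stack = cube_stack(n=12, value=180)
        inside_cam = Camera(position=(6.0, 6.0, 6.0), view_dir=(0, 0, 1),
                            fov_deg=45, width=12, height=12)
        settings_s = RenderSettings(mode="slices", background=(0.0, 0.0, 0.0))
        slice_img = render_slices(stack, inside_cam, settings_s)
        assert slice_img[..., 3].max() > 0.1  # visualization persists inside
        ray_img = render_raycast(stack, inside_cam, RenderSettings(mode="raycast"))
        assert np.all(ray_img[..., 3] == 0.0)  # box-face contract: disappears

    def test_too_few_slices_rejected(self):
        with pytest.raises(ValueError, match="slice_count"):
            RenderSettings(mode="slices", slice_count=1)


class TestIsosurface:
    def test_slab_face_on_fully_lit(self):
        values = np.zeros((16, 16, 16), dtype=np.uint8)
        values[6:10, :, :] = 255  # slab spanning x-y, faces perpendicular to z
        stack = mono_stack(values, color=(0.0, 1.0, 0.0))
        cam = Camera(position=(8.0, 8.0, -30.0), view_dir=(0, 0, 1),
                     fov_deg=10, width=9, height=9)
        img = render_isosurface(stack, cam, RenderSettings(
            mode="isosurface", iso_value=0.5, step=0.25))
        center = img[4, 4]
        assert center[3] == 1.0
        assert center[1] == pytest.approx(1.0, abs=1e-6)  # n . l = 1 on the face

    def test_sphere_silhouette_matches_disc(self):
        n = 24
        zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
        r = np.sqrt((zz - 11.5) ** 2 + (yy - 11.5) ** 2 + (xx - 11.5) ** 2)
        values = np.where(r <= 7.0, 255, 0).astype(np.uint8)
        stack = mono_stack(values)
        dist = 4.0 * n
        # voxel index 11.5 sits at world 12.0 (centers at index + 0.5)
        cam = Camera(position=(12.0, 12.0, 12.0 - dist), view_dir=(0, 0, 1),
                     fov_deg=14.0, width=64, height=64)
        img = render_isosurface(stack, cam, RenderSettings(
            mode="isosurface", iso_value=0.5, step=0.2))
        hit = img[..., 3] > 0
        # analytic projection of the r=7 sphere at distance `dist`
        tan_half = np.tan(np.deg2rad(7.0))
        px = ((np.arange(64) + 0.5) / 64 * 2 - 1) * tan_half
        py = (1 - (np.arange(64) + 0.5) / 64 * 2) * tan_half
        gx, gy = np.meshgrid(px, py)
        sin_alpha = np.sqrt(gx ** 2 + gy ** 2) / np.sqrt(gx ** 2 + gy ** 2 + 1)
        disc = sin_alpha <= 7.0 / dist
        from scipy.ndimage import binary_dilation
        assert not np.any(hit & ~binary_dilation(disc, iterations=2))
        assert not np.any(disc & ~binary_dilation(hit, iterations=2))

    def test_iso_above_max_is_background(self):
        stack = cube_stack(n=8, value=100)
        img = render_isosurface(stack, front_camera(stack, 8, 8), RenderSettings(
            mode="isosurface", iso_value=0.9, background=(0.1, 0.1, 0.1)))
        np.testing.assert_allclose(img[..., :3], 0.1)
        assert np.all(img[..., 3] == 0.0)


class TestCameraValidation:
    def test_parallel_view_up_rejected(self):
        with pytest.raises(ValueError, match="parallel"):
            Camera(position=(0, 0, 0), view_dir=(0, 1, 0), up=(0, 1, 0))

    def test_bad_fov_rejected(self):
        with pytest.raises(ValueError, match="fov"):
            Camera(position=(0, 0, 0), view_dir=(0, 0, 1), fov_deg=200.0)

    def test_left_handed_right_vector(self):
        cam = Camera(position=(0, 0, 0), view_dir=(0, 0, 1), up=(0, 1, 0))
        f, r, u = cam.basis()
        np.testing.assert_allclose(r, [1, 0, 0], atol=1e-12)  # x to the right
        np.testing.assert_allclose(u, [0, 1, 0], atol=1e-12)  # y up
        np.testing.assert_allclose(f, [0, 0, 1], atol=1e-12)  # z away from viewer
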