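"""CPU re-implementation of direct volume rendering for confocal stacks.

Three modes are provided:

* ``raycast``    — image-order ray casting through the bounding box with
  front-to-back compositing and early ray termination.
* ``slices``     — object-order rendering of view-perpendicular proxy planes
  composited back to front; keeps working with the camera inside the volume.
* ``isosurface`` — pseudo-isosurface ray casting: first sample crossing the
  iso value is shaded with the central-difference gradient and a headlight.

Transfer function (per channel): normalized intensity below the noise
threshold maps to zero opacity; otherwise alpha_raw = i * channel_opacity *
global_opacity and color = display color * i.  Channels are merged per sample
by over-compositing in channel order.  Sample opacity is corrected for the
step size via alpha = 1 - (1 - alpha_raw)**(dt / dt_ref) with dt_ref the
minimum voxel spacing, so renderings converge as the step shrinks.

The world frame is left-handed, y up, z away from the viewer; the volume
occupies [0, Lx] x [0, Ly] x [0, Lz] micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .volume_io import MultiChannelStack, VoxelGrid, normalized_channels

MODES = ("raycast", "slices", "isosurface")


@dataclass(frozen=True)
class Camera:
    """Perspective pinhole camera in the left-handed, y-up world frame."""

    position: tuple[float, float, float]
    view_dir: tuple[float, float, float]
    up: tuple[float, float, float] = (0.0, 1.0, 0.0)
    fov_deg: float = 45.0
    width: int = 64
    height: int = 64

    def __post_init__(self) -> None:
        if not 0.0 < self.fov_deg < 180.0:
            raise ValueError("fov must lie in (0, 180) degrees")
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        v = np.asarray(self.view_dir, dtype=float)
        u = np.asarray(self.up, dtype=float)
        if np.linalg.norm(v) == 0 or np.linalg.norm(u) == 0:
            raise ValueError("view direction and up vector must be nonzero")
        if np.linalg.norm(np.cross(u, v)) < 1e-12:
            raise ValueError("view direction and up vector must not be parallel")

    def basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (forward, right, up) triple."""
        f = np.asarray(self.view_dir, dtype=float)
        f = f / np.linalg.norm(f)
        r = np.cross(np.asarray(self.up, dtype=float), f)
        r = r / np.linalg.norm(r)
        u = np.cross(f, r)
        return f, r, u

    def ray_directions(self) -> np.ndarray:
        """Unit ray directions through all pixel centers, shape (H, W, 3).

        Row 0 is the top of the image (maximum world y of the view plane).
        """
        f, r, u = self.basis()
        tan_half = np.tan(np.deg2rad(self.fov_deg) / 2.0)
        aspect = self.width / self.height
        px = ((np.arange(self.width) + 0.5) / self.width * 2.0 - 1.0) * tan_half * aspect
        py = (1.0 - (np.arange(self.height) + 0.5) / self.height * 2.0) * tan_half
        dirs = (
            f[None, None, :]
            + px[None, :, None] * r[None, None, :]
            + py[:, None, None] * u[None, None, :]
        )
        return dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)


@dataclass(frozen=True)
class RenderSettings:
    """Rendering parameters shared by all three modes.

    ``step`` is the ray sampling distance as a fraction of the minimum voxel
    spacing.  ``noise_low`` holds per-channel normalized low thresholds in
    [0, 1] acting as the noise filter.  ``slice_count`` of ``None`` defaults
    to twice the largest grid dimension.
    """

    mode: str = "raycast"
    step: float = 0.5
    slice_count: int | None = None
    global_opacity: float = 1.0
    channel_opacity: tuple[float, ...] | None = None
    noise_low: tuple[float, ...] | None = None
    iso_value: float = 0.5
    early_stop_alpha: float = 0.99
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown render mode {self.mode!r}; expected {MODES}")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.slice_count is not None and self.slice_count < 2:
            raise ValueError("slice_count must be >= 2")
        if not 0.0 <= self.global_opacity <= 1.0:
            raise ValueError("global_opacity must be in [0, 1]")
        if not 0.0 < self.early_stop_alpha <= 1.0:
            raise ValueError("early_stop_alpha must be in (0, 1]")

    def per_channel(self, n_channels: int) -> tuple[np.ndarray, np.ndarray]:
        """Resolved (channel_opacity, noise_low) arrays of length n_channels."""
        op = self.channel_opacity
        op = np.ones(n_channels) if op is None else np.asarray(op, dtype=float)
        lo = self.noise_low
        lo = np.zeros(n_channels) if lo is None else np.asarray(lo, dtype=float)
        if op.shape != (n_channels,) or lo.shape != (n_channels,):
            raise ValueError("channel_opacity and noise_low must have one entry per channel")
        return op, lo


def sample_volume(values: np.ndarray, spacing, points_xyz: np.ndarray) -> np.ndarray:
    """Trilinear sampling of a (z, y, x) grid at world points (n, 3) (x, y, z).

    Clamp-to-edge inside the volume bounds; points outside [0, L] on any axis
    return 0.
    """
    points_xyz = np.atleast_2d(points_xyz)
    dz, dy, dx = spacing
    x, y, z = points_xyz[:, 0], points_xyz[:, 1], points_xyz[:, 2]
    coords = np.stack([z / dz - 0.5, y / dy - 0.5, x / dx - 0.5])
    out = map_coordinates(np.asarray(values, dtype=np.float64), coords, order=1, mode="nearest")
    nz, ny, nx = values.shape
    inside = (
        (x >= 0) & (x <= nx * dx)
        & (y >= 0) & (y <= ny * dy)
        & (z >= 0) & (z <= nz * dz)
    )
    out[~inside] = 0.0
    return out


def sample_trilinear(grid: VoxelGrid, point_xyz) -> float:
    """Trilinear interpolation of a (normalized) grid at one world point."""
    return float(sample_volume(grid.values, grid.spacing, np.asarray(point_xyz, float))[0])


def ray_box_intersect(origin, direction, bounds_lo, bounds_hi):
    """Slab-method ray/AABB intersection.

    Returns ``(t_near, t_far)`` or ``None`` on a miss (``t_far < max(t_near, 0)``).
    """
    direction = np.asarray(direction, dtype=float)
    if np.all(direction == 0):
        raise ValueError("ray direction must be nonzero")
    t_near, t_far, hit = _ray_box_batch(
        np.asarray(origin, float)[None, :], direction[None, :],
        np.asarray(bounds_lo, float), np.asarray(bounds_hi, float),
    )
    if not hit[0]:
        return None
    return float(t_near[0]), float(t_far[0])


def _ray_box_batch(origins, dirs, lo, hi):
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / dirs
        t1 = (lo - origins) * inv
        t2 = (hi - origins) * inv
    entry = np.minimum(t1, t2)
    leave = np.maximum(t1, t2)
    # rays parallel to a slab: inside -> (-inf, inf), outside -> empty interval
    parallel = dirs == 0
    if np.any(parallel):
        inside = (origins >= lo) & (origins <= hi)
        entry = np.where(parallel, np.where(inside, -np.inf, np.inf), entry)
        leave = np.where(parallel, np.where(inside, np.inf, -np.inf), leave)
    t_min = entry.max(axis=-1)
    t_max = leave.min(axis=-1)
    hit = t_max >= np.maximum(t_min, 0.0)
    return t_min, t_max, hit


def composite_front_to_back(accumulated: np.ndarray, sample: np.ndarray) -> np.ndarray:
    """One premultiplied front-to-back *over* step.

    ``accumulated`` holds premultiplied RGB + alpha; ``sample`` holds straight
    color and alpha.  Returns the new accumulation.
    """
    acc = np.array(accumulated, dtype=np.float64, copy=True)
    sample = np.asarray(sample, dtype=np.float64)
    trans = 1.0 - acc[..., 3:4]
    acc[..., :3] += trans * sample[..., :3] * sample[..., 3:4]
    acc[..., 3:4] = acc[..., 3:4] + trans * sample[..., 3:4]
    return acc


def _transfer(norm_channels, colors, op, lo, global_opacity, points, dt, dt_ref, spacing):
    """Evaluate the transfer function at sample points.

    Returns premultiplied RGB (n, 3) and alpha (n,) merged over channels.
    """
    n = points.shape[0]
    rgb = np.zeros((n, 3))
    alpha = np.zeros(n)
    exponent = dt / dt_ref
    for values, color, ch_op, ch_lo in zip(norm_channels, colors, op, lo):
        i = sample_volume(values, spacing, points)
        a_raw = np.where(i >= ch_lo, i * ch_op * global_opacity, 0.0)
        a = 1.0 - np.power(1.0 - np.clip(a_raw, 0.0, 1.0), exponent)
        trans = 1.0 - alpha
        rgb += (trans * a)[:, None] * (i[:, None] * np.asarray(color))
        alpha = alpha + trans * a
    return rgb, alpha


def _prepare(stack: MultiChannelStack, settings: RenderSettings):
    norm = normalized_channels(stack)
    op, lo = settings.per_channel(stack.n_channels)
    lz, ly, lx = stack.extent_um
    bounds_lo = np.zeros(3)
    bounds_hi = np.array([lx, ly, lz])
    dt_ref = min(stack.spacing)
    return norm, op, lo, bounds_lo, bounds_hi, dt_ref


def _finish(rgb, alpha, settings, shape_hw):
    bg = np.asarray(settings.background, dtype=float)
    out = np.empty(shape_hw + (4,))
    out[..., :3] = (rgb + (1.0 - alpha)[..., None] * bg).reshape(shape_hw + (3,))
    out[..., 3] = alpha.reshape(shape_hw)
    return np.clip(out, 0.0, 1.0)


def render_raycast(
    stack: MultiChannelStack, camera: Camera, settings: RenderSettings
) -> np.ndarray:
    """Image-order ray casting; returns an (H, W, 4) RGBA image in [0, 1].

    Rays are launched from front-facing fragments of the bounding-box faces,
    so a camera inside the box sees only background (the visualization
    disappears as soon as the viewpoint enters the bounding box); the slice
    renderer keeps working there.
    """
    norm, op, lo, b_lo, b_hi, dt_ref = _prepare(stack, settings)
    dirs = camera.ray_directions().reshape(-1, 3)
    origin = np.asarray(camera.position, dtype=float)
    origins = np.broadcast_to(origin, dirs.shape)
    t_near, t_far, hit = _ray_box_batch(origins, dirs, b_lo, b_hi)
    hit &= t_near >= 0.0  # box-face contract: no front face visible from inside

    n_rays = dirs.shape[0]
    rgb = np.zeros((n_rays, 3))
    alpha = np.zeros(n_rays)
    dt = settings.step * dt_ref
    # sample strictly inside (t_near, t_far): the boundary itself is never
    # sampled, so results are exactly equivariant under volume/camera rotation
    span = np.where(hit, t_far - t_near, 0.0)
    n_steps = np.maximum(np.ceil(span / dt - 0.5), 0.0).astype(int)
    max_steps = int(n_steps.max(initial=0))
    for k in range(max_steps):
        active = hit & (k < n_steps) & (alpha < settings.early_stop_alpha)
        if not np.any(active):
            break
        t = t_near[active] + (k + 0.5) * dt
        pts = origins[active] + dirs[active] * t[:, None]
        s_rgb, s_a = _transfer(
            norm, stack.colors, op, lo, settings.global_opacity,
            pts, dt, dt_ref, stack.spacing,
        )
        trans = 1.0 - alpha[active]
        rgb[active] += trans[:, None] * s_rgb
        alpha[active] = alpha[active] + trans * s_a
    return _finish(rgb, alpha, settings, (camera.height, camera.width))


def render_slices(
    stack: MultiChannelStack, camera: Camera, settings: RenderSettings
) -> np.ndarray:
    """Object-order slice compositing; returns an (H, W, 4) RGBA image.

    ``slice_count`` view-perpendicular planes span the volume's camera-depth
    range and are composited back to front; planes at or behind the eye are
    skipped, so the camera may sit inside the volume.
    """
    norm, op, lo, b_lo, b_hi, dt_ref = _prepare(stack, settings)
    f, _, _ = camera.basis()
    origin = np.asarray(camera.position, dtype=float)
    corners = np.array(
        [[x, y, z] for x in (b_lo[0], b_hi[0]) for y in (b_lo[1], b_hi[1]) for z in (b_lo[2], b_hi[2])]
    )
    depths = (corners - origin) @ f
    d0, d1 = float(depths.min()), float(depths.max())
    shape_hw = (camera.height, camera.width)
    n_rays = camera.height * camera.width
    rgb = np.zeros((n_rays, 3))
    alpha = np.zeros(n_rays)
    if d1 <= 0:
        return _finish(rgb, alpha, settings, shape_hw)

    count = settings.slice_count or 2 * max(stack.shape)
    delta = (d1 - d0) / count
    dirs = camera.ray_directions().reshape(-1, 3)
    cos = dirs @ f  # > 0 for fov < 180
    for k in range(count - 1, -1, -1):  # back to front
        d = d0 + (k + 0.5) * delta
        if d <= 0:
            continue
        t = d / cos
        pts = origin + dirs * t[:, None]
        thickness = delta / cos
        s_rgb, s_a = _transfer(
            norm, stack.colors, op, lo, settings.global_opacity,
            pts, thickness, dt_ref, stack.spacing,
        )
        # back-to-front over: new sample goes in front of the accumulation
        rgb = s_rgb + (1.0 - s_a)[:, None] * rgb
        alpha = s_a + (1.0 - s_a) * alpha
    return _finish(rgb, alpha, settings, shape_hw)


def render_isosurface(
    stack: MultiChannelStack, camera: Camera, settings: RenderSettings
) -> np.ndarray:
    """Pseudo-isosurface ray casting with Lambertian headlight shading.

    Each ray stops at the first sample whose maximum-over-channels normalized
    intensity reaches ``iso_value``; the surface normal is the normalized
    central-difference gradient of the dominant channel and the pixel color is
    that channel's display color scaled by max(0, n . l).
    """
    if not 0.0 < settings.iso_value < 1.0:
        raise ValueError("iso_value must lie in (0, 1)")
    norm, op, lo, b_lo, b_hi, dt_ref = _prepare(stack, settings)
    dirs = camera.ray_directions().reshape(-1, 3)
    origin = np.asarray(camera.position, dtype=float)
    origins = np.broadcast_to(origin, dirs.shape)
    t_near, t_far, hit = _ray_box_batch(origins, dirs, b_lo, b_hi)
    hit &= t_near >= 0.0  # same box-face contract as standard ray casting
    dt = settings.step * dt_ref

    n_rays = dirs.shape[0]
    hit_t = np.full(n_rays, np.nan)
    hit_ch = np.full(n_rays, -1, dtype=int)
    pending = hit.copy()
    span = np.where(hit, t_far - t_near, 0.0)
    n_steps = np.maximum(np.ceil(span / dt - 0.5), 0.0).astype(int)
    max_steps = int(n_steps.max(initial=0))
    for k in range(max_steps):
        active = pending & (k < n_steps)
        if not np.any(active):
            break
        t = t_near[active] + (k + 0.5) * dt
        pts = origins[active] + dirs[active] * t[:, None]
        intensities = np.stack([sample_volume(v, stack.spacing, pts) for v in norm])
        best = intensities.argmax(axis=0)
        peak = intensities.max(axis=0)
        crossed = peak >= settings.iso_value
        idx = np.flatnonzero(active)[crossed]
        hit_t[idx] = t[crossed]
        hit_ch[idx] = best[crossed]
        pending[idx] = False

    rgb = np.zeros((n_rays, 3))
    alpha = np.zeros(n_rays)
    surf = hit_ch >= 0
    if np.any(surf):
        pts = origins[surf] + dirs[surf] * hit_t[surf, None]
        normal = np.zeros_like(pts)
        h = np.array([stack.spacing[2], stack.spacing[1], stack.spacing[0]])  # (dx, dy, dz)
        for ch in np.unique(hit_ch[surf]):
            sel = hit_ch[surf] == ch
            p = pts[sel]
            grad = np.empty_like(p)
            for axis in range(3):
                off = np.zeros(3)
                off[axis] = h[axis]
                grad[:, axis] = (
                    sample_volume(norm[ch], stack.spacing, p + off)
                    - sample_volume(norm[ch], stack.spacing, p - off)
                ) / (2.0 * h[axis])
            normal[sel] = -grad  # outward: away from increasing intensity
        mag = np.linalg.norm(normal, axis=1, keepdims=True)
        ok = mag[:, 0] > 0
        normal[ok] /= mag[ok]
        light = -dirs[surf]
        shade = np.maximum(0.0, np.einsum("ij,ij->i", normal, light))
        shade[~ok] = 1.0  # flat interior gradient: treat as facing the light
        colors = np.asarray(stack.colors)[hit_ch[surf]]
        rgb[surf] = colors * shade[:, None] * settings.global_opacity
        alpha[surf] = 1.0 * (settings.global_opacity > 0)
    return _finish(rgb, alpha, settings, (camera.height, camera.width))


def render(stack: MultiChannelStack, camera: Camera, settings: RenderSettings) -> np.ndarray:
    """Dispatch on ``settings.mode``."""
    if settings.mode == "raycast":
        return render_raycast(stack, camera, settings)
    if settings.mode == "slices":
        return render_slices(stack, camera, settings)
    return render_isosurface(stack, camera, settings)


def rgba_to_uint8(image: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] RGBA image to 8-bit for PNG export."""
    return (np.clip(image, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)
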