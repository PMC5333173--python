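"""Region-of-interest shapes, transforms, and rasterization.

Three selection tools are provided: box, cylinder and freehand polygon.  A
shape lives in world coordinates (um, left-handed, y up) and carries a
transform factored as per-axis scale -> rotation (axis-angle) -> translation,
applied about the shape center.

Rasterization produces the mask representation used throughout: a 2-D boolean
footprint over (y, x) plus inclusive front/back z slice indices — i.e. the
x-y footprint extruded over the shape's z extent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy.spatial.transform import Rotation

from .volume_io import MultiChannelStack, voxel_centers_1d

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class RoiMask:
    """2-D boolean footprint plus inclusive [z_front, z_back] slice interval."""

    footprint: np.ndarray
    z_front: int
    z_back: int
    is_empty: bool = False

    def __post_init__(self) -> None:
        fp = np.asarray(self.footprint, dtype=bool)
        object.__setattr__(self, "footprint", fp)
        if fp.ndim != 2:
            raise ValueError("footprint must be 2-D (y, x)")
        if not (0 <= self.z_front <= self.z_back):
            raise ValueError(f"need 0 <= z_front <= z_back, got [{self.z_front}, {self.z_back}]")
        if not self.is_empty and not fp.any():
            raise ValueError("footprint has no true cell; pass is_empty=True for an empty mask")
        if self.is_empty and fp.any():
            raise ValueError("an explicitly empty mask must have an all-false footprint")

    @property
    def z_span(self) -> int:
        return 0 if self.is_empty else self.z_back - self.z_front + 1

    @property
    def n_voxels(self) -> int:
        return int(self.footprint.sum()) * self.z_span

    def to_volume(self, n_slices: int) -> np.ndarray:
        """Expand to a 3-D boolean array over (z, y, x) with ``n_slices`` slices."""
        vol = np.zeros((n_slices,) + self.footprint.shape, dtype=bool)
        if not self.is_empty:
            vol[self.z_front : self.z_back + 1] = self.footprint
        return vol


@dataclass(frozen=True)
class RoiShape:
    """A selection shape with a factored scale->rotate->translate transform.

    ``params`` depends on ``kind``:

    * ``box``: ``half_extents`` (hx, hy, hz) in um.
    * ``cylinder``: ``radius`` and ``half_length`` in um; axis along local z.
    * ``freehand``: ``vertices`` — closed polygon, (n, 2) local (x, y) um —
      and ``half_depth`` in um.
    """

    kind: str
    params: dict
    center: tuple[float, float, float]
    scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    rotvec: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("box", "cylinder", "freehand"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if any(s <= 0 for s in self.scale):
            raise ValueError(f"scale factors must be > 0, got {self.scale}")
        for name in ("center", "scale", "rotvec", "translation"):
            object.__setattr__(self, name, tuple(float(v) for v in getattr(self, name)))
        if self.kind == "freehand":
            verts = np.asarray(self.params["vertices"], dtype=float)
            if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
                raise ValueError("freehand polygon needs >= 3 (x, y) vertices")

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_rotvec(self.rotvec).as_matrix()

    @property
    def world_center(self) -> np.ndarray:
        return np.asarray(self.center) + np.asarray(self.translation)

    def linear_map(self) -> np.ndarray:
        """The 3x3 matrix R @ diag(scale) mapping local to world offsets."""
        return self.rotation_matrix @ np.diag(self.scale)


def make_box_roi(stack: MultiChannelStack) -> RoiShape:
    """Axis-aligned box initially covering the entire volume."""
    lz, ly, lx = stack.extent_um
    return RoiShape(
        kind="box",
        params={"half_extents": (lx / 2.0, ly / 2.0, lz / 2.0)},
        center=(lx / 2.0, ly / 2.0, lz / 2.0),
    )


def make_cylinder_roi(stack: MultiChannelStack) -> RoiShape:
    """z-axis cylinder through the volume center spanning the full depth.

    Radius is half the smaller lateral extent; length is the full z extent.
    """
    lz, ly, lx = stack.extent_um
    return RoiShape(
        kind="cylinder",
        params={"radius": min(lx, ly) / 2.0, "half_length": lz / 2.0},
        center=(lx / 2.0, ly / 2.0, lz / 2.0),
    )


def make_freehand_roi(polyline: Iterable, stack: MultiChannelStack) -> RoiShape:
    """Closed polygon traced in the flattened x-y view, extruded over full depth.

    Vertices are (x, y) world um; the polygon is auto-closed (last vertex
    joined to the first).  The initial z range is the full stack depth and is
    adjusted afterwards with z scaling/translation.
    """
    verts = np.asarray(list(polyline), dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2:
        raise ValueError("polyline must be a sequence of (x, y) vertices")
    if verts.shape[0] > 1 and np.allclose(verts[0], verts[-1]):
        verts = verts[:-1]
    if verts.shape[0] < 3:
        raise ValueError(f"freehand polygon needs >= 3 vertices, got {verts.shape[0]}")
    edges = verts - verts[0]
    cross = edges[1:, 0] * edges[:-1, 1] - edges[1:, 1] * edges[:-1, 0]
    if np.allclose(cross, 0.0):
        raise ValueError("freehand polygon vertices are collinear")
    lz = stack.extent_um[0]
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    cx, cy = (lo + hi) / 2.0
    return RoiShape(
        kind="freehand",
        params={"vertices": verts - (cx, cy), "half_depth": lz / 2.0},
        center=(cx, cy, lz / 2.0),
    )


def transform_roi(
    shape: RoiShape,
    translation=(0.0, 0.0, 0.0),
    rotation=((0.0, 0.0, 1.0), 0.0),
    scale=(1.0, 1.0, 1.0),
) -> RoiShape:
    """Compose a further scale -> rotate -> translate about the shape center.

    ``rotation`` is ``(axis, angle_degrees)`` with a unit-length axis.
    """
    scale = np.asarray(scale, dtype=float)
    if np.any(scale <= 0):
        raise ValueError(f"scale factors must be > 0, got {tuple(scale)}")
    axis, angle_deg = rotation
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if not np.isclose(norm, 1.0):
        if norm == 0:
            raise ValueError("rotation axis must be unit length")
        axis = axis / norm
    r_new = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis)
    r_old = Rotation.from_rotvec(shape.rotvec)
    return replace(
        shape,
        scale=tuple(scale * shape.scale),
        rotvec=tuple((r_new * r_old).as_rotvec()),
        translation=tuple(np.asarray(shape.translation) + np.asarray(translation, dtype=float)),
    )


def scale_roi_axis(shape: RoiShape, axis: str, factor: float) -> RoiShape:
    """Multiply a single axis's scale factor; the other axes are untouched."""
    if factor <= 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    i = _AXES[axis]
    scale = list(shape.scale)
    scale[i] *= factor
    return replace(shape, scale=tuple(scale))


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd (crossing number) point-in-polygon test at the given points.

    ``points`` is (n, 2) and ``vertices`` (m, 2); the polygon is treated as
    closed.  Vectorized over points; edges are iterated.
    """
    points = np.asarray(points, dtype=float)
    vertices = np.asarray(vertices, dtype=float)
    px, py = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < x_at)
    return inside


def contains_points(shape: RoiShape, points_xyz: np.ndarray) -> np.ndarray:
    """Boolean containment of world points (n, 3) as (x, y, z) um."""
    points_xyz = np.atleast_2d(np.asarray(points_xyz, dtype=float))
    local = (points_xyz - shape.world_center) @ shape.rotation_matrix  # = R^T (p - c)
    local = local / np.asarray(shape.scale)
    if shape.kind == "box":
        h = np.asarray(shape.params["half_extents"], dtype=float)
        return np.all(np.abs(local) <= h, axis=1)
    if shape.kind == "cylinder":
        r = float(shape.params["radius"])
        hl = float(shape.params["half_length"])
        radial = local[:, 0] ** 2 + local[:, 1] ** 2
        return (radial <= r * r) & (np.abs(local[:, 2]) <= hl)
    verts = np.asarray(shape.params["vertices"], dtype=float)
    hd = float(shape.params["half_depth"])
    return points_in_polygon(local[:, :2], verts) & (np.abs(local[:, 2]) <= hd)


def _z_extent(shape: RoiShape) -> tuple[float, float]:
    """World-z support interval of the transformed shape."""
    m = shape.linear_map()[2]  # world-z row of R @ diag(s)
    cz = shape.world_center[2]
    if shape.kind == "box":
        h = np.asarray(shape.params["half_extents"], dtype=float)
        r = float(np.abs(m) @ h)
        return cz - r, cz + r
    if shape.kind == "cylinder":
        radius = float(shape.params["radius"])
        hl = float(shape.params["half_length"])
        r = hl * abs(m[2]) + radius * float(np.hypot(m[0], m[1]))
        return cz - r, cz + r
    verts = np.asarray(shape.params["vertices"], dtype=float)
    hd = float(shape.params["half_depth"])
    contrib = verts @ m[:2]
    pad = hd * abs(m[2])
    return cz + contrib.min() - pad, cz + contrib.max() + pad


def rasterize_roi(shape: RoiShape, stack: MultiChannelStack) -> RoiMask:
    """Rasterize a shape into the footprint-plus-z-interval mask.

    A footprint cell is true iff any voxel center in its (y, x) column lies
    inside the transformed shape; z_front/z_back come from the shape's world-z
    support clamped to the volume.  A shape entirely outside the volume yields
    an explicitly empty mask.
    """
    nz, ny, nx = stack.shape
    dz, dy, dx = stack.spacing
    xs = voxel_centers_1d(nx, dx)
    ys = voxel_centers_1d(ny, dy)
    zs = voxel_centers_1d(nz, dz)
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)
    footprint = np.zeros((ny, nx), dtype=bool)
    column = np.empty((ny * nx, 3))
    column[:, 0] = gx.ravel()
    column[:, 1] = gy.ravel()
    for z in zs:
        column[:, 2] = z
        footprint |= contains_points(shape, column).reshape(ny, nx)

    z_min, z_max = _z_extent(shape)
    eps = 1e-9
    z_front = max(0, int(np.ceil(z_min / dz - 0.5 - eps)))
    z_back = min(nz - 1, int(np.floor(z_max / dz - 0.5 + eps)))
    if not footprint.any() or z_front > z_back:
        return RoiMask(np.zeros((ny, nx), dtype=bool), 0, 0, is_empty=True)
    return RoiMask(footprint, z_front, z_back)


def roi_voxel_indices(mask: RoiMask) -> set[tuple[int, int, int]]:
    """All (z, y, x) indices covered by the mask."""
    if mask.is_empty:
        return set()
    ys, xs = np.nonzero(mask.footprint)
    return {
        (z, int(y), int(x))
        for z in range(mask.z_front, mask.z_back + 1)
        for y, x in zip(ys, xs)
    }


def roi_to_dict(shape: RoiShape) -> dict:
    """JSON-serializable representation {kind, params, transform}."""
    params = {
        k: (np.asarray(v).tolist() if isinstance(v, np.ndarray) else v)
        for k, v in shape.params.items()
    }
    return {
        "kind": shape.kind,
        "params": params,
        "center": list(shape.center),
        "transform": {
            "scale": list(shape.scale),
            "rotvec": list(shape.rotvec),
            "translation": list(shape.translation),
        },
    }


def roi_from_dict(doc: dict) -> RoiShape:
    t = doc.get("transform", {})
    params = dict(doc["params"])
    if "vertices" in params:
        params["vertices"] = np.asarray(params["vertices"], dtype=float)
    return RoiShape(
        kind=doc["kind"],
        params=params,
        center=tuple(doc["center"]),
        scale=tuple(t.get("scale", (1.0, 1.0, 1.0))),
        rotvec=tuple(t.get("rotvec", (0.0, 0.0, 0.0))),
        translation=tuple(t.get("translation", (0.0, 0.0, 0.0))),
    )


def full_volume_mask(stack: MultiChannelStack) -> RoiMask:
    """Convenience all-true mask covering the whole stack."""
    nz, ny, nx = stack.shape
    return RoiMask(np.ones((ny, nx), dtype=bool), 0, nz - 1)
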