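"""Reading, writing and normalizing multi-channel confocal z-stacks.

Conventions carried by every other module:

* Arrays are indexed ``(z, y, x)``.
* World coordinates are left-handed and in micrometres: x points along grid
  columns (rightward), y along grid rows (upward), z along the slice index
  (away from the viewer).  The centre of voxel ``(iz, iy, ix)`` sits at
  ``((ix + 0.5) dx, (iy + 0.5) dy, (iz + 0.5) dz)``.
* In-memory rows increase *upward* in world y.  TIFF pages store rows
  top-down, so rows are flipped exactly once, at I/O.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

#: Fallback voxel spacing (dz, dy, dx) in micrometres when a file carries no
#: metadata: the acquisition z increment of 0.4 um and a plausible lateral pitch.
DEFAULT_SPACING_UM = (0.4, 0.1, 0.1)

#: Display colors for up to four channels: blue nuclei, red mtDNA,
#: green tubulin, magenta actin.
DEFAULT_COLORS = (
    (0.0, 0.0, 1.0),
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (1.0, 0.0, 1.0),
)

_DESCRIPTION_KEY = "spacing_um"


@dataclass(frozen=True)
class VoxelGrid:
    """A single-channel 3-D intensity grid with physical voxel spacing.

    Parameters
    ----------
    values
        Non-negative intensities indexed ``(z, y, x)``.
    bit_depth
        8 or 16; intensities must not exceed ``2**bit_depth - 1``.
    spacing
        ``(dz, dy, dx)`` in micrometres, all positive.
    """

    values: np.ndarray
    bit_depth: int = 8
    spacing: tuple[float, float, float] = DEFAULT_SPACING_UM

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        object.__setattr__(self, "values", values)
        if values.ndim != 3 or min(values.shape) < 1:
            raise ValueError("values must be a 3-D (z, y, x) grid with >= 1 slice per axis")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if values.size and float(values.min()) < 0:
            raise ValueError("intensities must be non-negative")
        if values.size and float(values.max()) > self.max_intensity:
            raise ValueError(
                f"intensities exceed 2**{self.bit_depth} - 1 = {self.max_intensity}"
            )
        spacing = tuple(float(s) for s in self.spacing)
        object.__setattr__(self, "spacing", spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must all be > 0, got {spacing}")

    @property
    def max_intensity(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size (Lz, Ly, Lx) of the volume in micrometres."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass(frozen=True)
class MultiChannelStack:
    """Co-registered per-channel intensity grids with names and display colors."""

    channels: tuple[VoxelGrid, ...]
    names: tuple[str, ...] = ()
    colors: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        channels = tuple(self.channels)
        object.__setattr__(self, "channels", channels)
        if not channels:
            raise ValueError("stack must contain at least one channel")
        shape0, spacing0, depth0 = channels[0].shape, channels[0].spacing, channels[0].bit_depth
        for ch in channels[1:]:
            if ch.shape != shape0:
                raise ValueError("all channels must share an identical grid shape")
            if ch.spacing != spacing0:
                raise ValueError("all channels must share identical voxel spacing")
            if ch.bit_depth != depth0:
                raise ValueError("all channels must share one bit depth")
        names = tuple(self.names) or tuple(f"ch{i}" for i in range(len(channels)))
        colors = tuple(tuple(float(c) for c in col) for col in self.colors) or tuple(
            DEFAULT_COLORS[i % len(DEFAULT_COLORS)] for i in range(len(channels))
        )
        if len(names) != len(channels) or len(colors) != len(channels):
            raise ValueError("names and colors must each have one entry per channel")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "colors", colors)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.channels[0].shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.channels[0].spacing

    @property
    def bit_depth(self) -> int:
        return self.channels[0].bit_depth

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return self.channels[0].extent_um

    def intensity(self, channel: int) -> np.ndarray:
        return self.channels[channel].values


@dataclass(frozen=True)
class StackLayout:
    """Page-ordering descriptor for a multi-page TIFF.

    ``channel_major`` means all z pages of channel 0 come first, then channel 1,
    and so on; ``z_major`` means pages are interleaved slice by slice
    (c0z0, c1z0, c0z1, ...).
    """

    n_channels: int
    order: str = "channel_major"
    names: tuple[str, ...] = ()
    colors: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.order not in ("channel_major", "z_major"):
            raise ValueError(f"unknown page order {self.order!r}")


def voxel_centers_1d(n: int, spacing: float) -> np.ndarray:
    """World coordinates of the ``n`` voxel centers along one axis."""
    return (np.arange(n) + 0.5) * spacing


def world_to_index(point_xyz, spacing) -> tuple[int, int, int]:
    """Map a world point (x, y, z) in um to the (z, y, x) index of its voxel."""
    x, y, z = point_xyz
    dz, dy, dx = spacing
    return int(np.floor(z / dz)), int(np.floor(y / dy)), int(np.floor(x / dx))


def index_to_world(index_zyx, spacing) -> tuple[float, float, float]:
    """World position (x, y, z) of a voxel center given its (z, y, x) index."""
    iz, iy, ix = index_zyx
    dz, dy, dx = spacing
    return ((ix + 0.5) * dx, (iy + 0.5) * dy, (iz + 0.5) * dz)


def _interleave(pages: np.ndarray, n_channels: int, order: str) -> np.ndarray:
    """Split a (pages, y, x) array into (channel, z, y, x) per the layout."""
    n_pages = pages.shape[0]
    nz = n_pages // n_channels
    if order == "channel_major":
        return pages.reshape(n_channels, nz, *pages.shape[1:])
    # z-major: c0z0, c1z0, c0z1, ...
    return pages.reshape(nz, n_channels, *pages.shape[1:]).swapaxes(0, 1)


def _deinterleave(channels: np.ndarray, order: str) -> np.ndarray:
    """Inverse of :func:`_interleave`: (channel, z, y, x) -> (pages, y, x)."""
    if order == "channel_major":
        return channels.reshape(-1, *channels.shape[2:])
    return channels.swapaxes(0, 1).reshape(-1, *channels.shape[2:])


def read_zstack(
    path,
    layout: StackLayout,
    spacing: tuple[float, float, float] | None = None,
) -> MultiChannelStack:
    """Read a multi-page TIFF into a :class:`MultiChannelStack`.

    Parameters
    ----------
    path
        Multi-page grayscale TIFF, 8- or 16-bit.
    layout
        Channel count and page ordering; see :class:`StackLayout`.
    spacing
        Explicit ``(dz, dy, dx)`` in um; overrides file metadata.  When neither
        is available, :data:`DEFAULT_SPACING_UM` is used with a warning.

    Raises
    ------
    ValueError
        If the page count is not divisible by the channel count, or pages mix
        bit depths.
    """
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
        description = tif.pages[0].description or ""
    if not pages:
        raise ValueError(f"{path}: no pages found")
    dtypes = {p.dtype for p in pages}
    if len(dtypes) > 1:
        raise ValueError(f"{path}: mixed bit depths across pages: {sorted(map(str, dtypes))}")
    dtype = dtypes.pop()
    if dtype == np.uint8:
        bit_depth = 8
    elif dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"{path}: unsupported page dtype {dtype}; expected uint8 or uint16")
    if len(pages) % layout.n_channels != 0:
        raise ValueError(
            f"{path}: page count {len(pages)} not divisible by channel count {layout.n_channels}"
        )
    stack_pages = np.stack(pages)
    if spacing is None:
        spacing = _parse_spacing(description)
    if spacing is None:
        spacing = DEFAULT_SPACING_UM
        msg = f"{path}: no voxel spacing metadata; defaulting to {DEFAULT_SPACING_UM} um"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    per_channel = _interleave(stack_pages, layout.n_channels, layout.order)
    # TIFF rows are top-down; world y is up.  Flip rows here, once.
    per_channel = per_channel[:, :, ::-1, :]
    grids = tuple(
        VoxelGrid(values=np.ascontiguousarray(c), bit_depth=bit_depth, spacing=tuple(spacing))
        for c in per_channel
    )
    return MultiChannelStack(channels=grids, names=layout.names, colors=layout.colors)


def write_zstack(stack: MultiChannelStack, path) -> str:
    """Write a stack as a multi-page TIFF (z-major within channel-major blocks).

    Voxel spacing is stored in the ImageDescription as ``spacing_um=dz,dy,dx``
    so that :func:`read_zstack` inverts this operation exactly.
    """
    dtype = np.uint8 if stack.bit_depth == 8 else np.uint16
    data = np.stack([ch.values.astype(dtype) for ch in stack.channels])
    # invert the y-flip applied at read time
    pages = _deinterleave(data[:, :, ::-1, :], "channel_major")
    dz, dy, dx = stack.spacing
    description = f"{_DESCRIPTION_KEY}={dz!r},{dy!r},{dx!r}"
    tifffile.imwrite(str(path), pages, description=description, photometric="minisblack")
    return str(path)


def _parse_spacing(description: str) -> tuple[float, float, float] | None:
    for line in description.splitlines():
        line = line.strip()
        if line.startswith(_DESCRIPTION_KEY + "="):
            parts = line.split("=", 1)[1].split(",")
            if len(parts) == 3:
                return tuple(float(p) for p in parts)
    return None


def normalize_intensity(grid: VoxelGrid) -> VoxelGrid:
    """Rescale integer intensities to unit scale: values / (2**bit_depth - 1).

    Order-preserving; output values lie in [0, 1].
    """
    values = np.asarray(grid.values, dtype=np.float64) / grid.max_intensity
    return replace(grid, values=values)


def normalized_channels(stack: MultiChannelStack) -> list[np.ndarray]:
    """Unit-scale intensity arrays for every channel of a stack."""
    return [normalize_intensity(ch).values for ch in stack.channels]
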