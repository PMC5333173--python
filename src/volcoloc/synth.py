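"""Synthetic multi-channel z-stacks with known ground-truth colocalization.

Phantoms are built from additive Gaussian blobs.  A controllable fraction of
blob centers is shared between the two analysis channels, with channel-B
amplitudes linearly linked to channel-A amplitudes, so the expected
co-occurrence and intensity correlation are known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import DEFAULT_SPACING_UM, MultiChannelStack, VoxelGrid


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a blob phantom.

    ``overlap_fraction`` is the fraction of blob centers shared between the
    two channels; ``correlation`` is the slope linking shared-blob amplitudes
    (B = correlation * A + amplitude_noise); ``noise_sd`` is additive Gaussian
    voxel noise.  ``min_separation`` (voxels) enforces a minimum distance
    between non-shared centers of different channels (``None`` disables);
    ``n_extra_channels`` appends uncorrelated channels to emulate 3-4 channel
    acquisitions.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    n_blobs: int = 20
    sigma: float = 1.5
    amplitude_range: tuple[float, float] = (120.0, 255.0)
    overlap_fraction: float = 0.5
    correlation: float = 1.0
    amplitude_noise_sd: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    bit_depth: int = 8
    spacing: tuple[float, float, float] = DEFAULT_SPACING_UM
    min_separation: float | None = None
    n_extra_channels: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.sigma * 2 >= min(self.shape):
            raise ValueError("blobs do not fit: sigma too large for the grid")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth: blob centers per channel, shared centers, co-occurrence mask."""

    centers_a: np.ndarray
    centers_b: np.ndarray
    shared_centers: np.ndarray
    cooccurrence_mask: np.ndarray

    @property
    def n_shared(self) -> int:
        return len(self.shared_centers)


def _render_blobs(shape, centers, amplitudes, sigma):
    """Additively render Gaussian blobs, evaluated on +-4 sigma windows."""
    vol = np.zeros(shape, dtype=np.float64)
    half = max(1, int(np.ceil(4 * sigma)))
    for (cz, cy, cx), amp in zip(centers, amplitudes):
        z0, z1 = max(0, int(cz) - half), min(shape[0], int(cz) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(shape[1], int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(shape[2], int(cx) + half + 1)
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
        )
        r2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        vol[z0:z1, y0:y1, x0:x1] += amp * np.exp(-r2 / (2.0 * sigma ** 2))
    return vol


def _draw_centers(rng, n, shape, sigma, existing, min_sep, max_tries=2000):
    """Uniform centers in the interior; optionally repelled from ``existing``."""
    margin = 2.0 * sigma
    lo = np.full(3, margin)
    hi = np.asarray(shape, dtype=float) - margin
    centers = []
    others = np.asarray(existing, dtype=float).reshape(-1, 3)
    for _ in range(n):
        for attempt in range(max_tries):
            c = rng.uniform(lo, hi)
            if min_sep is None or len(others) == 0:
                break
            if np.min(np.linalg.norm(others - c, axis=1)) >= min_sep:
                break
        else:
            raise RuntimeError("could not place separated blob centers; relax min_separation")
        centers.append(c)
        if min_sep is not None:
            others = np.vstack([others, c]) if len(others) else c[None, :]
    return np.asarray(centers, dtype=float).reshape(-1, 3)


def generate_phantom(spec: PhantomSpec) -> tuple[MultiChannelStack, PhantomTruth]:
    """Render a two-channel blob phantom (plus optional extra channels).

    Shared blobs sit at identical centers in both channels with channel-B
    amplitude = correlation * A-amplitude + noise, clipped to the amplitude
    range.  Identical specs produce bit-identical stacks.
    """
    rng = np.random.default_rng(spec.seed)
    max_int = 2 ** spec.bit_depth - 1
    n_shared = int(round(spec.overlap_fraction * spec.n_blobs))
    n_solo = spec.n_blobs - n_shared

    shared = _draw_centers(rng, n_shared, spec.shape, spec.sigma, [], spec.min_separation)
    solo_a = _draw_centers(rng, n_solo, spec.shape, spec.sigma, shared, spec.min_separation)
    existing_for_b = np.vstack([shared, solo_a]) if len(shared) or len(solo_a) else []
    solo_b = _draw_centers(rng, n_solo, spec.shape, spec.sigma, existing_for_b, spec.min_separation)

    amp_lo, amp_hi = spec.amplitude_range
    amp_shared_a = rng.uniform(amp_lo, amp_hi, n_shared)
    amp_shared_b = np.clip(
        spec.correlation * amp_shared_a
        + (rng.normal(0.0, spec.amplitude_noise_sd, n_shared) if spec.amplitude_noise_sd else 0.0),
        amp_lo, amp_hi,
    )
    amp_solo_a = rng.uniform(amp_lo, amp_hi, n_solo)
    amp_solo_b = rng.uniform(amp_lo, amp_hi, n_solo)

    centers_a = np.vstack([shared, solo_a]) if spec.n_blobs else shared
    centers_b = np.vstack([shared, solo_b]) if spec.n_blobs else shared
    vol_a = _render_blobs(spec.shape, centers_a, np.concatenate([amp_shared_a, amp_solo_a]), spec.sigma)
    vol_b = _render_blobs(spec.shape, centers_b, np.concatenate([amp_shared_b, amp_solo_b]), spec.sigma)

    volumes = [vol_a, vol_b]
    for _ in range(spec.n_extra_channels):
        extra_centers = _draw_centers(rng, spec.n_blobs, spec.shape, spec.sigma, [], None)
        extra_amps = rng.uniform(amp_lo, amp_hi, spec.n_blobs)
        volumes.append(_render_blobs(spec.shape, extra_centers, extra_amps, spec.sigma))

    channels = []
    for vol in volumes:
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, spec.shape)
        quantized = np.clip(np.rint(vol), 0, max_int).astype(
            np.uint8 if spec.bit_depth == 8 else np.uint16
        )
        channels.append(VoxelGrid(quantized, bit_depth=spec.bit_depth, spacing=spec.spacing))

    # truth co-occurrence: voxels within 2 sigma of a shared center (windowed)
    mask = np.zeros(spec.shape, dtype=bool)
    reach = 2.0 * spec.sigma
    half = int(np.ceil(reach)) + 1
    for cz, cy, cx in shared:
        z0, z1 = max(0, int(cz) - half), min(spec.shape[0], int(cz) + half + 1)
        y0, y1 = max(0, int(cy) - half), min(spec.shape[1], int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(spec.shape[2], int(cx) + half + 1)
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
        )
        r2 = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
        mask[z0:z1, y0:y1, x0:x1] |= r2 <= reach ** 2

    stack = MultiChannelStack(channels=tuple(channels))
    truth = PhantomTruth(
        centers_a=centers_a, centers_b=centers_b,
        shared_centers=shared, cooccurrence_mask=mask,
    )
    return stack, truth


def generate_ramp_pair(
    shape: tuple[int, int, int],
    slope: float,
    intercept: float,
    bit_depth: int = 8,
    spacing=DEFAULT_SPACING_UM,
) -> MultiChannelStack:
    """Deterministic two-channel stack: A ramps along x, B = slope * A + intercept.

    B is clipped to the intensity range; A spans 0..max along x.
    """
    max_int = 2 ** bit_depth - 1
    nz, ny, nx = shape
    ramp = np.rint(np.linspace(0.0, max_int, nx))
    a = np.broadcast_to(ramp, shape).copy()
    b = np.clip(np.rint(slope * a + intercept), 0, max_int)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return MultiChannelStack(
        channels=(
            VoxelGrid(a.astype(dtype), bit_depth=bit_depth, spacing=spacing),
            VoxelGrid(b.astype(dtype), bit_depth=bit_depth, spacing=spacing),
        )
    )
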