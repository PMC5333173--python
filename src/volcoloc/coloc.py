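"""Threshold-based colocalization metrics and visualization volumes.

All quantities are computed over a pre-selected region of interest.  A voxel
is *colocalized* when both channels fall inside their [low, high] intensity
band.  The low threshold acts as a noise filter and is the only threshold
used by the intensity metrics (M1/M2, MOC, PCC); the high threshold
participates in the percentage colocalization and the visual masks.

The considered set S for MOC and PCC is the union: ROI voxels at or above the
low threshold in either channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import matplotlib

matplotlib.use("Agg")

from .roi import RoiMask
from .volume_io import MultiChannelStack, normalized_channels

RENDER_MODES = ("overlay_white", "coloc_only_original", "coloc_only_white", "none")


@dataclass(frozen=True)
class ColocParams:
    """Channel pair, intensity bands and visualization options."""

    ch_a: int
    ch_b: int
    low_a: float = 0.0
    high_a: float | None = None
    low_b: float = 0.0
    high_b: float | None = None
    render_mode: str = "overlay_white"
    coloc_opacity: float = 1.0

    def __post_init__(self) -> None:
        if self.ch_a == self.ch_b:
            raise ValueError("ch_a and ch_b must differ")
        if self.render_mode not in RENDER_MODES:
            raise ValueError(f"unknown render mode {self.render_mode!r}; expected {RENDER_MODES}")
        if not 0.0 <= self.coloc_opacity <= 1.0:
            raise ValueError("coloc_opacity must be in [0, 1]")

    def resolve(self, stack: MultiChannelStack) -> "ColocParams":
        """Fill missing high thresholds with the stack maximum and validate."""
        top = float(stack.channels[0].max_intensity)
        high_a = top if self.high_a is None else self.high_a
        high_b = top if self.high_b is None else self.high_b
        for lo, hi, name in ((self.low_a, high_a, "a"), (self.low_b, high_b, "b")):
            if not 0 <= lo <= hi <= top:
                raise ValueError(f"need 0 <= low_{name} <= high_{name} <= {top}")
        if not (0 <= self.ch_a < stack.n_channels and 0 <= self.ch_b < stack.n_channels):
            raise ValueError(f"channel indices must be < {stack.n_channels}")
        return ColocParams(
            self.ch_a, self.ch_b, self.low_a, high_a, self.low_b, high_b,
            self.render_mode, self.coloc_opacity,
        )


@dataclass(frozen=True)
class ColocResult:
    """Metric bundle; NaN entries are flagged undefined, never raised."""

    m1: float
    m2: float
    moc: float
    pcc: float
    pct_a: float
    pct_b: float
    n_coloc: int
    n_a: int
    n_b: int
    n_considered: int

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            name
            for name in ("m1", "m2", "moc", "pcc", "pct_a", "pct_b")
            if math.isnan(getattr(self, name))
        )

    def as_dict(self) -> dict:
        return {
            "m1": self.m1, "m2": self.m2, "moc": self.moc, "pcc": self.pcc,
            "pct_a": self.pct_a, "pct_b": self.pct_b,
            "n_coloc": self.n_coloc, "n_a": self.n_a, "n_b": self.n_b,
            "n_considered": self.n_considered,
        }


def _channel_pair(stack, params, roi):
    params = params.resolve(stack)
    a = stack.intensity(params.ch_a).astype(np.float64)
    b = stack.intensity(params.ch_b).astype(np.float64)
    roi_vol = roi.to_volume(stack.shape[0])
    if roi_vol.shape != a.shape:
        raise ValueError(f"ROI shape {roi_vol.shape} does not match stack shape {a.shape}")
    return a, b, roi_vol, params


def coloc_voxel_mask(stack: MultiChannelStack, params: ColocParams, roi: RoiMask) -> np.ndarray:
    """Boolean (z, y, x) mask: inside ROI and both channels in their band."""
    a, b, roi_vol, p = _channel_pair(stack, params, roi)
    return (
        roi_vol
        & (a >= p.low_a) & (a <= p.high_a)
        & (b >= p.low_b) & (b <= p.high_b)
    )


def considered_set_mask(stack: MultiChannelStack, params: ColocParams, roi: RoiMask) -> np.ndarray:
    """S = ROI voxels at/above the low threshold in either channel."""
    a, b, roi_vol, p = _channel_pair(stack, params, roi)
    return roi_vol & ((a >= p.low_a) | (b >= p.low_b))


def manders_mcc(stack: MultiChannelStack, params: ColocParams, roi: RoiMask) -> tuple[float, float]:
    """Manders' colocalization coefficients (M1, M2).

    M1 = sum of A over ROI voxels with A >= low_a and B >= low_b, divided by
    the sum of A over ROI voxels with A >= low_a; M2 is symmetric.  An empty
    denominator yields NaN.
    """
    a, b, roi_vol, p = _channel_pair(stack, params, roi)
    above_a = roi_vol & (a >= p.low_a)
    above_b = roi_vol & (b >= p.low_b)
    both = above_a & above_b
    denom_a = a[above_a].sum()
    denom_b = b[above_b].sum()
    m1 = float(a[both].sum() / denom_a) if denom_a > 0 else math.nan
    m2 = float(b[both].sum() / denom_b) if denom_b > 0 else math.nan
    return m1, m2


def manders_moc(stack: MultiChannelStack, params: ColocParams, roi: RoiMask) -> float:
    """Manders' overlap coefficient over the considered set S.

    MOC = sum(A B) / sqrt(sum(A^2) sum(B^2)); NaN when a denominator is zero.
    """
    a, b, roi_vol, p = _channel_pair(stack, params, roi)
    s = roi_vol & ((a >= p.low_a) | (b >= p.low_b))
    av, bv = a[s], b[s]
    denom = math.sqrt(float((av ** 2).sum()) * float((bv ** 2).sum()))
    if denom == 0:
        return math.nan
    return float((av * bv).sum() / denom)


def pearson_pcc(stack: MultiChannelStack, params: ColocParams, roi: RoiMask) -> float:
    """Pearson correlation of paired voxel intensities over the considered set.

    NaN when |S| < 2 or a channel is constant on S.
    """
    a, b, roi_vol, p = _channel_pair(stack, params, roi)
    s = roi_vol & ((a >= p.low_a) | (b >= p.low_b))
    av, bv = a[s], b[s]
    if av.size < 2:
        return math.nan
    da = av - av.mean()
    db = bv - bv.mean()
    denom = math.sqrt(float((da ** 2).sum()) * float((db ** 2).sum()))
    if denom == 0:
        return math.nan
    return float((da * db).sum() / denom)


def percent_colocalization(
    stack: MultiChannelStack, params: ColocParams, roi: RoiMask
) -> tuple[float, float]:
    """Voxel-count percentages: share of each channel's in-band ROI voxels
    that are colocalized.  0/0 yields NaN."""
    a, b, roi_vol, p = _channel_pair(stack, params, roi)
    in_a = roi_vol & (a >= p.low_a) & (a <= p.high_a)
    in_b = roi_vol & (b >= p.low_b) & (b <= p.high_b)
    n_a = int(in_a.sum())
    n_b = int(in_b.sum())
    n_coloc = int((in_a & in_b).sum())
    pct_a = 100.0 * n_coloc / n_a if n_a else math.nan
    pct_b = 100.0 * n_coloc / n_b if n_b else math.nan
    return pct_a, pct_b


def coloc_report(stack: MultiChannelStack, params: ColocParams, roi: RoiMask) -> ColocResult:
    """Compute the full metric bundle in one pass."""
    a, b, roi_vol, p = _channel_pair(stack, params, roi)
    m1, m2 = manders_mcc(stack, p, roi)
    moc = manders_moc(stack, p, roi)
    pcc = pearson_pcc(stack, p, roi)
    pct_a, pct_b = percent_colocalization(stack, p, roi)
    in_a = roi_vol & (a >= p.low_a) & (a <= p.high_a)
    in_b = roi_vol & (b >= p.low_b) & (b <= p.high_b)
    s = roi_vol & ((a >= p.low_a) | (b >= p.low_b))
    return ColocResult(
        m1=m1, m2=m2, moc=moc, pcc=pcc, pct_a=pct_a, pct_b=pct_b,
        n_coloc=int((in_a & in_b).sum()), n_a=int(in_a.sum()), n_b=int(in_b.sum()),
        n_considered=int(s.sum()),
    )


def stack_to_rgba(stack: MultiChannelStack) -> np.ndarray:
    """Additive RGBA projection of a stack: color_c * intensity summed, clipped.

    Alpha is the maximum normalized intensity across channels.
    """
    norm = normalized_channels(stack)
    rgba = np.zeros(stack.shape + (4,), dtype=np.float64)
    for values, color in zip(norm, stack.colors):
        rgba[..., :3] += values[..., None] * np.asarray(color)
        rgba[..., 3] = np.maximum(rgba[..., 3], values)
    rgba[..., :3] = np.clip(rgba[..., :3], 0.0, 1.0)
    return rgba


def colocalization_volume(
    stack: MultiChannelStack, params: ColocParams, roi: RoiMask
) -> np.ndarray:
    """RGBA (z, y, x, 4) volume for one of the four colocalization render modes.

    * ``overlay_white``     — original volume with colocalized voxels blended
      toward white at ``coloc_opacity``.
    * ``coloc_only_original`` — only colocalized voxels, original colors.
    * ``coloc_only_white``  — only colocalized voxels, white.
    * ``none``              — the unmodified original volume.
    """
    p = params.resolve(stack)
    base = stack_to_rgba(stack)
    if p.render_mode == "none":
        return base
    mask = coloc_voxel_mask(stack, p, roi)
    white = np.array([1.0, 1.0, 1.0, 1.0])
    if p.render_mode == "overlay_white":
        out = base.copy()
        out[mask] = (1.0 - p.coloc_opacity) * base[mask] + p.coloc_opacity * white
        return out
    out = np.zeros_like(base)
    if p.render_mode == "coloc_only_original":
        out[mask] = base[mask]
        out[mask, 3] = np.maximum(out[mask, 3], p.coloc_opacity)
    elif p.render_mode == "coloc_only_white":
        out[mask, :3] = 1.0
        out[mask, 3] = p.coloc_opacity
    return out


def scatter_histogram(
    stack: MultiChannelStack, params: ColocParams, roi: RoiMask, bins: int
) -> np.ndarray:
    """2-D count grid of (A, B) intensity pairs over the considered set.

    ``bins`` equal-width bins per axis over [0, 2**bit_depth - 1]; the total
    count equals |S|.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    a, b, roi_vol, p = _channel_pair(stack, params, roi)
    s = roi_vol & ((a >= p.low_a) | (b >= p.low_b))
    top = float(stack.channels[0].max_intensity)
    hist, _, _ = np.histogram2d(
        a[s], b[s], bins=bins, range=[[0.0, top], [0.0, top]]
    )
    return hist.astype(np.int64)


def pseudocolor_scatter(
    hist: np.ndarray,
    colormap: str = "viridis",
    log_scale: bool = False,
    background=(0.0, 0.0, 0.0),
) -> np.ndarray:
    """Map a count grid through a colormap to an RGB image.

    Counts are normalized by their maximum (after optional log1p); zero-count
    bins map to the background color.
    """
    hist = np.asarray(hist, dtype=np.float64)
    if np.any(hist < 0):
        raise ValueError("counts must be non-negative")
    try:
        cmap = matplotlib.colormaps[colormap]
    except KeyError as exc:
        raise ValueError(f"unknown colormap {colormap!r}") from exc
    values = np.log1p(hist) if log_scale else hist
    top = values.max()
    norm = values / top if top > 0 else values
    rgb = np.asarray(cmap(norm))[..., :3]
    rgb[hist == 0] = np.asarray(background, dtype=float)
    return rgb
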