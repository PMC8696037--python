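"""Flattening of curved retinal cross-sections.

The nuclear stain marks the ganglion cell layer (GCL) and inner nuclear
layer (INL); the inner edges of those two bands bound the inner
plexiform layer (IPL). A bilinearly blended Coons patch spanned by the
two detected boundary curves (and straight lateral edges joining their
endpoints) maps the curved IPL onto a rectangle whose rows run from 0%
depth (GCL border) to 100% (INL border).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d, map_coordinates
from skimage.filters import threshold_otsu

from .profiles import DEFAULT_LAYER_EDGES, StratificationProfile

__all__ = [
    "SectionImage",
    "BoundaryCurves",
    "StraightenedSection",
    "StraighteningError",
    "detect_boundaries",
    "coons_straighten",
    "depth_profile",
]

log = logging.getLogger(__name__)


class StraighteningError(RuntimeError):
    """A section that cannot be straightened; callers should skip it."""


@dataclass
class SectionImage:
    """Multi-channel cross-section raster.

    ``channels`` maps channel name → 2-D array (row 0 at the GCL side);
    ``channel_roles`` marks each channel nuclear / marker / cell_fill.
    """

    channels: Dict[str, np.ndarray]
    pixel_size: float = 1.0  # μm/px
    channel_roles: Mapping[str, str] = field(default_factory=dict)
    ground_truth: object = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("section has no channels")
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape


@dataclass
class BoundaryCurves:
    """The two IPL boundary curves, single-valued in x on a shared domain."""

    x: np.ndarray  # column coordinates, px
    top: np.ndarray  # GCL/IPL border, y px per column
    bottom: np.ndarray  # IPL/INL border, y px per column

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.top = np.asarray(self.top, dtype=float)
        self.bottom = np.asarray(self.bottom, dtype=float)
        if not (self.x.shape == self.top.shape == self.bottom.shape):
            raise ValueError("curve arrays must share the domain")
        if len(self.x) < 2:
            raise ValueError("curves need at least two samples")
        gap = self.bottom - self.top
        if not ((gap > 0).all() or (gap < 0).all()):
            raise ValueError("boundary curves cross")


@dataclass
class StraightenedSection:
    """Channels resampled onto a rectangular (depth × position) grid.

    Row 0 corresponds to the GCL border (0% IPL depth), the last row to
    the INL border (100%).
    """

    channels: Dict[str, np.ndarray]
    depth_resolution: float  # % IPL depth per row step
    out_of_bounds_samples: int = 0

    @property
    def n_rows(self) -> int:
        return next(iter(self.channels.values())).shape[0]


def _column_band_edges(mask_col: np.ndarray):
    """Inner edges of the top and bottom nuclear bands in one column.

    Returns (top_edge, bottom_edge) as sub-pixel y, or None if the column
    lacks two distinct bands.
    """
    idx = np.flatnonzero(mask_col)
    if idx.size == 0:
        return None
    # split into runs of consecutive rows
    breaks = np.flatnonzero(np.diff(idx) > 1)
    runs = np.split(idx, breaks + 1)
    if len(runs) < 2:
        return None
    top_run, bottom_run = runs[0], runs[-1]
    return float(top_run[-1]) + 0.5, float(bottom_run[0]) - 0.5


def detect_boundaries(
    section: SectionImage,
    nuclear_channel: str = "nuclear",
    smooth_sigma: float = 5.0,
    threshold_mode: str = "otsu",
    max_missing_fraction: float = 0.2,
    presmooth_sigma: float = 1.0,
) -> BoundaryCurves:
    """Detect the GCL/IPL and IPL/INL borders from the nuclear channel.

    The channel is lightly smoothed, thresholded (Otsu by default), and
    each column's top and bottom above-threshold bands located; the inner
    edge of the top band and the inner edge of the bottom band bound the
    IPL. Columns lacking both bands are linearly interpolated if they are
    at most ``max_missing_fraction`` of all columns; otherwise the
    section is rejected (mirroring the discard-on-failure policy). The
    resulting curves are smoothed with a 1-D Gaussian.
    """
    if nuclear_channel not in section.channels:
        raise ValueError(f"nuclear channel {nuclear_channel!r} not in section")
    if threshold_mode != "otsu":
        raise ValueError(f"unknown threshold mode {threshold_mode!r}")
    img = np.asarray(section.channels[nuclear_channel], dtype=float)
    if img.max() <= 0:
        raise StraighteningError("nuclear channel is blank")
    smoothed = gaussian_filter(img, presmooth_sigma) if presmooth_sigma > 0 else img
    thr = threshold_otsu(smoothed)
    mask = smoothed > thr

    n_cols = img.shape[1]
    top = np.full(n_cols, np.nan)
    bottom = np.full(n_cols, np.nan)
    for j in range(n_cols):
        edges = _column_band_edges(mask[:, j])
        if edges is not None and edges[1] > edges[0]:
            top[j], bottom[j] = edges
    missing = np.isnan(top)
    frac = missing.mean()
    if frac > max_missing_fraction:
        raise StraighteningError(
            f"{frac:.0%} of columns lack two nuclear bands "
            f"(limit {max_missing_fraction:.0%}); section discarded")
    if missing.any():
        log.info("interpolating boundaries across %d/%d columns", missing.sum(), n_cols)
        cols = np.arange(n_cols, dtype=float)
        good = ~missing
        top[missing] = np.interp(cols[missing], cols[good], top[good])
        bottom[missing] = np.interp(cols[missing], cols[good], bottom[good])
    if smooth_sigma > 0:
        top = gaussian_filter1d(top, smooth_sigma, mode="nearest")
        bottom = gaussian_filter1d(bottom, smooth_sigma, mode="nearest")
    if not (bottom > top).all():
        raise StraighteningError("detected boundary curves cross; section discarded")
    return BoundaryCurves(x=np.arange(n_cols, dtype=float), top=top, bottom=bottom)


def coons_straighten(
    section: SectionImage,
    curves: BoundaryCurves,
    out_rows: int = 100,
) -> StraightenedSection:
    """Resample every channel onto the rectangle spanned by the Coons patch.

    The patch interpolates the two detected boundary curves and the
    straight lateral segments joining their endpoints; with straight
    lateral edges the construction reduces to a vertical blend between
    the two curves. Intensities are bilinearly interpolated; samples
    falling outside the raster are zero-filled and counted.
    """
    if out_rows < 2:
        raise ValueError("out_rows must be at least 2")
    nx = len(curves.x)
    s = (curves.x - curves.x[0]) / (curves.x[-1] - curves.x[0])  # (nx,)
    t = np.linspace(0.0, 1.0, out_rows)[:, None]  # (out_rows, 1)

    top_xy = np.stack([curves.x, curves.top])  # (2, nx)
    bot_xy = np.stack([curves.x, curves.bottom])
    p00, p10 = top_xy[:, 0], top_xy[:, -1]
    p01, p11 = bot_xy[:, 0], bot_xy[:, -1]

    # bilinearly blended Coons patch; the ruled lateral edges make the
    # edge and corner terms cancel, but the full construction is kept
    surf = (
        (1 - t)[None] * top_xy[:, None, :] + t[None] * bot_xy[:, None, :]
        + (1 - s)[None, None, :] * ((1 - t)[None] * p00[:, None, None] + t[None] * p01[:, None, None])
        + s[None, None, :] * ((1 - t)[None] * p10[:, None, None] + t[None] * p11[:, None, None])
        - ((1 - s)[None, None, :] * (1 - t)[None] * p00[:, None, None]
           + s[None, None, :] * (1 - t)[None] * p10[:, None, None]
           + (1 - s)[None, None, :] * t[None] * p01[:, None, None]
           + s[None, None, :] * t[None] * p11[:, None, None])
    )  # (2, out_rows, nx): x and y source coordinates

    src_x, src_y = surf[0], surf[1]
    h, w = section.shape
    oob = int(((src_x < 0) | (src_x > w - 1) | (src_y < 0) | (src_y > h - 1)).sum())
    if oob:
        log.info("%d samples fall outside the raster; zero-filled", oob)
    out = {}
    for name, chan in section.channels.items():
        out[name] = map_coordinates(
            np.asarray(chan, dtype=float), [src_y, src_x], order=1, mode="constant", cval=0.0)
    return StraightenedSection(
        channels=out,
        depth_resolution=100.0 / (out_rows - 1),
        out_of_bounds_samples=oob,
    )


def depth_profile(straight: StraightenedSection, channel: str) -> StratificationProfile:
    """Mean intensity per depth row, normalized to peak 1."""
    if channel not in straight.channels:
        raise ValueError(f"channel {channel!r} not in straightened section")
    img = straight.channels[channel]
    signal = img.mean(axis=1)
    peak = signal.max()
    if peak <= 0:
        raise ValueError(f"channel {channel!r} is all zero")
    depths = np.linspace(0.0, 100.0, len(signal))
    return StratificationProfile(
        depth_bins=depths,
        signal=signal / peak,
        layer_edges=DEFAULT_LAYER_EDGES,
        raw=signal,
    )
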