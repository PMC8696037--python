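"""Generator for curved cross-section fixtures with known boundary truth.

Channel 0 ("nuclear") mimics a nuclear stain: two bright slabs flanking
the IPL (the GCL band above the top boundary, the INL band below the
bottom boundary). Channels "band0", "band1", … are Gaussian marker bands
planted at known IPL depths measured along the curved frame.
"""

from __future__ import annotations

import numpy as np

from ..straighten import BoundaryCurves, SectionImage
from .truth import GroundTruth

__all__ = ["gen_curved_section"]


def gen_curved_section(
    width: int = 256,
    height: int = 160,
    boundary_amplitude: float = 0.0,
    band_depths=(),
    band_sigma: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    ipl_top_frac: float = 0.3,
    ipl_bottom_frac: float = 0.7,
    nuclear_band_px: int = 14,
    wavelengths: float = 1.5,
) -> tuple:
    """Generate a curved section plus its true boundary curves.

    The two IPL boundaries are sinusoids of the given amplitude (px);
    zero amplitude yields an already-straight section. ``band_depths``
    are IPL-% positions of planted marker bands. Returns
    ``(SectionImage, BoundaryCurves)``.
    """
    band_depths = tuple(float(d) for d in band_depths)
    for d in band_depths:
        if not 0.0 <= d <= 100.0:
            raise ValueError(f"band depth {d}% outside [0, 100]")
    rng = np.random.default_rng(seed)
    x = np.arange(width, dtype=float)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    wave = boundary_amplitude * np.sin(2.0 * np.pi * wavelengths * x / width + phase)
    top = ipl_top_frac * height + wave
    bottom = ipl_bottom_frac * height + wave
    if not (bottom > top).all():
        raise ValueError("boundary curves cross; reduce boundary_amplitude")
    if top.min() - nuclear_band_px < 0 or bottom.max() + nuclear_band_px > height - 1:
        raise ValueError("boundaries too close to the image edge for the nuclear bands")

    rows = np.arange(height, dtype=float)[:, None]  # (height, 1)
    nuclear = (((rows >= top[None, :] - nuclear_band_px) & (rows < top[None, :]))
               | ((rows >= bottom[None, :]) & (rows < bottom[None, :] + nuclear_band_px))
               ).astype(float) * 200.0

    channels = {"nuclear": nuclear}
    roles = {"nuclear": "nuclear"}
    for i, d in enumerate(band_depths):
        center = top + d / 100.0 * (bottom - top)  # (width,)
        band = 200.0 * np.exp(-0.5 * ((rows - center[None, :]) / band_sigma) ** 2)
        channels[f"band{i}"] = band
        roles[f"band{i}"] = "marker"
    if noise_sd > 0:
        for name in channels:
            channels[name] = np.clip(
                channels[name] + rng.normal(0.0, noise_sd, channels[name].shape),
                0.0, None)

    truth = GroundTruth(
        "section",
        {"width_px": width, "height_px": height,
         "boundary_amplitude_px": boundary_amplitude,
         "band_depths_pct": band_depths, "band_sigma_px": band_sigma,
         "noise_sd": noise_sd},
        seed)
    section = SectionImage(channels=channels, pixel_size=1.0, channel_roles=roles,
                           ground_truth=truth)
    curves = BoundaryCurves(x=x, top=top.copy(), bottom=bottom.copy())
    return section, curves
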