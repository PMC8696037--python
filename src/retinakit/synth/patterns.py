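"""Point-pattern generators: Poisson, hard-core and jittered-lattice mosaics.

All generators are pure functions of their parameters and seed.
Densities are in cells/mm², coordinates and distances in μm.
"""

from __future__ import annotations

import numpy as np

from ..mosaic import PointPattern, Window
from .truth import GroundTruth

__all__ = ["gen_poisson_pattern", "gen_hardcore_pattern", "gen_jittered_lattice",
           "PackingError"]


class PackingError(RuntimeError):
    """Requested hard-core density could not be realized."""


def _as_window(window) -> Window:
    if isinstance(window, Window):
        return window
    return Window(*window)


def gen_poisson_pattern(density: float, window, seed: int) -> PointPattern:
    """Homogeneous Poisson (complete spatial randomness) pattern.

    The point count is Poisson with mean ``density × area``; coordinates
    are uniform in the window.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    win = _as_window(window)
    rng = np.random.default_rng(seed)
    n = rng.poisson(density * win.area_mm2)
    pts = np.column_stack([
        rng.uniform(win.x0, win.x1, n),
        rng.uniform(win.y0, win.y1, n),
    ])
    return PointPattern(
        points=pts, window=win, label="poisson",
        ground_truth=GroundTruth("mosaic", {"model": "poisson", "density_per_mm2": density},
                                 seed),
    )


def hexagonal_packing_limit(dmin: float, window) -> int:
    """Maximum point count for minimum spacing ``dmin`` (hexagonal packing)."""
    win = _as_window(window)
    if dmin <= 0:
        return np.iinfo(np.int64).max
    return int(np.floor(win.area_um2 * 2.0 / (np.sqrt(3.0) * dmin**2)))


def gen_hardcore_pattern(
    density: float,
    dmin: float,
    window,
    seed: int,
    max_attempts: int = 200_000,
) -> PointPattern:
    """Hard-core (regular) mosaic by dart-throwing rejection sampling.

    Every accepted point is at least ``dmin`` from every other, so the
    minimum spacing is exact by construction. Requests beyond the
    hexagonal packing bound are rejected up front; sampling that stalls
    before reaching the target count fails explicitly, naming the density
    achieved.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    if dmin < 0:
        raise ValueError("dmin must be non-negative")
    win = _as_window(window)
    n_target = int(round(density * win.area_mm2))
    limit = hexagonal_packing_limit(dmin, win)
    if n_target > limit:
        raise PackingError(
            f"{n_target} points at dmin={dmin} μm exceed the hexagonal packing "
            f"bound of {limit} for this window")
    rng = np.random.default_rng(seed)
    accepted = np.empty((n_target, 2))
    n_acc = 0
    dmin2 = dmin * dmin
    for _ in range(max_attempts):
        if n_acc >= n_target:
            break
        cand = np.array([rng.uniform(win.x0, win.x1), rng.uniform(win.y0, win.y1)])
        if n_acc and dmin > 0:
            d2 = np.sum((accepted[:n_acc] - cand) ** 2, axis=1)
            if d2.min() < dmin2:
                continue
        accepted[n_acc] = cand
        n_acc += 1
    if n_acc < n_target:
        raise PackingError(
            f"dart throwing stalled at {n_acc}/{n_target} points after "
            f"{max_attempts} attempts; achieved density "
            f"{n_acc / win.area_mm2:.1f} cells/mm² (requested {density})")
    return PointPattern(
        points=accepted, window=win, label="hardcore",
        ground_truth=GroundTruth(
            "mosaic",
            {"model": "hardcore", "density_per_mm2": density, "dmin_um": dmin},
            seed),
    )


def gen_jittered_lattice(
    spacing: float,
    jitter_sd: float,
    window,
    seed: int,
) -> PointPattern:
    """Hexagonal lattice with isotropic Gaussian jitter, clipped to the window.

    With zero jitter the output is an exact hexagonal lattice whose
    interior points all have nearest-neighbor distance ``spacing``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    win = _as_window(window)
    rng = np.random.default_rng(seed)
    row_h = spacing * np.sqrt(3.0) / 2.0
    margin = 3.0 * jitter_sd + spacing
    ys = np.arange(win.y0 - margin, win.y1 + margin, row_h)
    pts = []
    for i, y in enumerate(ys):
        offset = (spacing / 2.0) if i % 2 else 0.0
        xs = np.arange(win.x0 - margin + offset, win.x1 + margin, spacing)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    pts = np.concatenate(pts)
    if jitter_sd > 0:
        pts = pts + rng.normal(0.0, jitter_sd, pts.shape)
    pts = pts[(pts[:, 0] >= win.x0) & (pts[:, 0] <= win.x1)
              & (pts[:, 1] >= win.y0) & (pts[:, 1] <= win.y1)]
    return PointPattern(
        points=pts, window=win, label="jittered_lattice",
        ground_truth=GroundTruth(
            "mosaic",
            {"model": "jittered_lattice", "spacing_um": spacing, "jitter_sd_um": jitter_sd},
            seed),
    )
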