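"""Normalized depth profiles across the inner plexiform layer (IPL).

Depth runs from 0% at the inner limiting border of the ganglion cell
layer (GCL) to 100% at the inner nuclear layer (INL). The IPL is divided
into five contiguous strata; S5 abuts the GCL side and S1 the INL side,
so the ON strata (S4, S5) lie at low depth and the OFF strata (S1, S2)
at high depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["StratificationProfile", "DEFAULT_LAYER_EDGES", "stratum_of"]

#: stratum edges in % IPL depth (equal quintiles by default)
DEFAULT_LAYER_EDGES = (0.0, 20.0, 40.0, 60.0, 80.0, 100.0)

#: stratum names ordered from the GCL border (0%) to the INL border (100%)
STRATA_GCL_TO_INL = ("S5", "S4", "S3", "S2", "S1")


def stratum_of(depth_pct: float, edges=DEFAULT_LAYER_EDGES) -> str:
    """Map an IPL depth (%) to its stratum name (S1–S5)."""
    if not 0.0 <= depth_pct <= 100.0:
        raise ValueError(f"depth {depth_pct}% outside [0, 100]")
    idx = min(int(np.searchsorted(edges, depth_pct, side="right")) - 1,
              len(STRATA_GCL_TO_INL) - 1)
    return STRATA_GCL_TO_INL[idx]


@dataclass
class StratificationProfile:
    """Signal (dendritic length or intensity) density versus IPL depth.

    ``signal`` is peak-normalized to 1; ``raw`` keeps the unnormalized
    per-bin mass for conservation checks.
    """

    depth_bins: np.ndarray  # bin centers, % IPL depth, covering [0, 100]
    signal: np.ndarray  # normalized to peak 1
    layer_edges: tuple = DEFAULT_LAYER_EDGES
    raw: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.depth_bins = np.asarray(self.depth_bins, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.depth_bins.shape != self.signal.shape:
            raise ValueError("depth_bins and signal must have the same shape")
        if self.signal.size and (self.signal.min() < -1e-12 or self.signal.max() > 1 + 1e-9):
            raise ValueError("normalized signal must lie in [0, 1]")

    @property
    def peak_depth(self) -> float:
        return float(self.depth_bins[int(np.argmax(self.signal))])
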