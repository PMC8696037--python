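"""Morphometry of traced neurons (SWC trees).

Computes total neurite length, branch-point counts and the distribution
of dendritic length across IPL depth, and classifies cells into the four
stratification subtypes (bistratified S2+S4, monostratified ON S4,
ON S5, OFF S1).

Axons (SWC type 2) and soma segments are excluded from length and
stratification by default; the analyses target dendrites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .profiles import DEFAULT_LAYER_EDGES, StratificationProfile, stratum_of

__all__ = [
    "Morphology",
    "IplFrame",
    "SubtypeCall",
    "SwcValidationError",
    "read_swc",
    "write_swc",
    "total_neurite_length",
    "branch_points",
    "stratification_distribution",
    "classify_subtype",
]

log = logging.getLogger(__name__)

SOMA_TYPE = 1
AXON_TYPE = 2

#: node types excluded from neurite length / stratification by default
DEFAULT_EXCLUDED_TYPES = frozenset({SOMA_TYPE, AXON_TYPE})


class SwcValidationError(ValueError):
    """Raised for structurally invalid SWC data (cycles, orphans, dup ids)."""


@dataclass
class Morphology:
    """Rooted tree of 3-D neurite points with SWC semantics.

    ``ids``, ``types``, ``parents`` are integer arrays; ``xyz`` is
    ``(n, 3)`` μm; ``radii`` μm. Roots have parent ``-1``.
    """

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray
    radii: np.ndarray
    parents: np.ndarray
    ground_truth: object = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=int)
        self.types = np.asarray(self.types, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.radii = np.asarray(self.radii, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        self._validate()

    def _validate(self) -> None:
        n = len(self.ids)
        if not (len(self.types) == len(self.xyz) == len(self.radii) == len(self.parents) == n):
            raise SwcValidationError("column length mismatch")
        if n == 0:
            raise SwcValidationError("empty morphology")
        uniq, counts = np.unique(self.ids, return_counts=True)
        if (counts > 1).any():
            raise SwcValidationError(f"duplicate node ids: {uniq[counts > 1].tolist()}")
        if not np.isfinite(self.xyz).all():
            raise SwcValidationError("non-finite coordinates")
        id_index = {int(i): k for k, i in enumerate(self.ids)}
        roots = 0
        for k, p in enumerate(self.parents):
            if p == -1:
                roots += 1
                continue
            if int(p) not in id_index:
                raise SwcValidationError(
                    f"orphan node {int(self.ids[k])}: parent {int(p)} missing")
            if id_index[int(p)] >= k:
                raise SwcValidationError(
                    f"parent {int(p)} does not precede child {int(self.ids[k])}")
        if roots != 1:
            raise SwcValidationError(f"expected exactly one root, found {roots}")
        # parent-precedes-child ordering over a single root rules out cycles
        # and guarantees connectivity

    @property
    def n(self) -> int:
        return len(self.ids)

    def parent_index(self) -> np.ndarray:
        """Row index of each node's parent (-1 for the root)."""
        id_index = {int(i): k for k, i in enumerate(self.ids)}
        return np.array([id_index[int(p)] if p != -1 else -1 for p in self.parents])

    def child_counts(self) -> np.ndarray:
        pidx = self.parent_index()
        counts = np.zeros(self.n, dtype=int)
        for p in pidx:
            if p >= 0:
                counts[p] += 1
        return counts


@dataclass(frozen=True)
class IplFrame:
    """Maps z coordinates (μm) to IPL depth: GCL border → 0%, INL → 100%."""

    gcl_border_z: float
    inl_border_z: float

    def __post_init__(self) -> None:
        if self.gcl_border_z == self.inl_border_z:
            raise ValueError("IPL frame borders must be distinct")

    def depth(self, z) -> np.ndarray:
        return 100.0 * (np.asarray(z, dtype=float) - self.gcl_border_z) / (
            self.inl_border_z - self.gcl_border_z)


@dataclass(frozen=True)
class SubtypeCall:
    call: str  # bistratified_S2S4 | mono_ON_S4 | mono_ON_S5 | mono_OFF_S1 | unclassified
    peak_depths: tuple  # % IPL depth, sorted ascending
    peak_fractions: tuple  # share of dendritic mass per peak


# ---------------------------------------------------------------------------
# SWC I/O

def read_swc(path) -> Morphology:
    """Read a standard 7-column SWC file, validating tree structure."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcValidationError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
        try:
            rows.append((int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                         float(parts[4]), float(parts[5]), int(parts[6])))
        except ValueError as exc:
            raise SwcValidationError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise SwcValidationError(f"{path}: no data rows")
    arr = np.array(rows, dtype=float)
    return Morphology(
        ids=arr[:, 0].astype(int),
        types=arr[:, 1].astype(int),
        xyz=arr[:, 2:5],
        radii=arr[:, 5],
        parents=arr[:, 6].astype(int),
    )


def write_swc(m: Morphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for k in range(m.n):
            x, y, z = m.xyz[k]
            fh.write(f"{int(m.ids[k])} {int(m.types[k])} {x:.6f} {y:.6f} {z:.6f} "
                     f"{m.radii[k]:.6f} {int(m.parents[k])}\n")


# ---------------------------------------------------------------------------
# Morphometry

def _segment_mask(m: Morphology, excluded_types) -> np.ndarray:
    """Nodes whose incoming (parent) segment counts as neurite."""
    return (m.parents != -1) & ~np.isin(m.types, list(excluded_types))


def total_neurite_length(m: Morphology, excluded_types=DEFAULT_EXCLUDED_TYPES) -> float:
    """Sum of Euclidean parent–child segment lengths, in μm.

    A segment belongs to its child node; segments whose child is a soma
    or axon node are excluded by default.
    """
    pidx = m.parent_index()
    mask = _segment_mask(m, excluded_types)
    if not mask.any():
        return 0.0
    seg = m.xyz[mask] - m.xyz[pidx[mask]]
    return float(np.linalg.norm(seg, axis=1).sum())


def branch_points(m: Morphology) -> int:
    """Number of non-soma nodes with two or more children."""
    counts = m.child_counts()
    return int(((counts >= 2) & (m.types != SOMA_TYPE)).sum())


def stratification_distribution(
    m: Morphology,
    frame: IplFrame,
    bin: float = 2.0,
    excluded_types=DEFAULT_EXCLUDED_TYPES,
    depth_tolerance: float = 10.0,
) -> StratificationProfile:
    """Dendritic length per IPL-depth bin, peak-normalized.

    Each segment's length is apportioned across the depth bins it spans by
    linear interpolation. Nodes up to ``depth_tolerance`` % outside
    [0, 100] are tolerated (logged) and their mass is clipped into the
    edge bins; nodes beyond that are an error.
    """
    if bin <= 0:
        raise ValueError("bin must be positive")
    pidx = m.parent_index()
    mask = _segment_mask(m, excluded_types)
    if not mask.any():
        raise ValueError("no dendritic segments to profile")
    depths = frame.depth(m.xyz[:, 2])
    d_child = depths[mask]
    d_parent = depths[pidx[mask]]
    out_lo, out_hi = -depth_tolerance, 100.0 + depth_tolerance
    dmin, dmax = min(d_child.min(), d_parent.min()), max(d_child.max(), d_parent.max())
    if dmin < out_lo or dmax > out_hi:
        raise ValueError(
            f"dendritic depths span [{dmin:.1f}, {dmax:.1f}]%, beyond the "
            f"[{out_lo:.0f}, {out_hi:.0f}]% tolerance")
    if dmin < 0 or dmax > 100:
        log.info("dendritic depths slightly outside [0, 100]%% "
                 "([%.1f, %.1f]%%); clipping into edge bins", dmin, dmax)

    seg_len = np.linalg.norm(m.xyz[mask] - m.xyz[pidx[mask]], axis=1)
    n_bins = int(np.ceil(100.0 / bin))
    edges = np.minimum(np.arange(n_bins + 1) * bin, 100.0)
    massed = np.zeros(n_bins)
    lo = np.clip(np.minimum(d_child, d_parent), 0.0, 100.0)
    hi = np.clip(np.maximum(d_child, d_parent), 0.0, 100.0)
    for L, a, b in zip(seg_len, lo, hi):
        if b - a < 1e-12:
            k = min(int(a // bin), n_bins - 1)
            massed[k] += L
            continue
        # fraction of the segment's depth extent overlapping each bin
        overlap = np.clip(np.minimum(edges[1:], b) - np.maximum(edges[:-1], a), 0.0, None)
        massed += L * overlap / (b - a)
    centers = (edges[:-1] + edges[1:]) / 2.0
    peak = massed.max()
    return StratificationProfile(
        depth_bins=centers,
        signal=massed / peak if peak > 0 else massed,
        raw=massed,
    )


def classify_subtype(
    profile: StratificationProfile,
    prominence: float = 0.2,
    min_peak_fraction: float = 0.15,
) -> SubtypeCall:
    """Call the stratification subtype from a dendritic depth profile.

    Peaks are detected on the peak-normalized profile (zero-padded so
    boundary maxima count) at the given prominence; each peak must carry
    at least ``min_peak_fraction`` of the total dendritic mass, where a
    peak's mass is the profile mass between the minima separating it from
    neighboring peaks. Peak depths map onto S1–S5; one or two qualifying
    peaks yield one of the four subtype labels, anything else is
    ``unclassified``.
    """
    sig = profile.signal
    mass = profile.raw if profile.raw is not None else sig
    total = mass.sum()
    if total <= 0:
        return SubtypeCall("unclassified", (), ())
    padded = np.r_[0.0, sig, 0.0]
    peak_idx, _ = find_peaks(padded, prominence=prominence)
    peak_idx = peak_idx - 1  # undo padding shift

    if len(peak_idx) == 0:
        return SubtypeCall("unclassified", (), ())

    # region boundaries at the minimum between adjacent peaks
    bounds = [0]
    for a, b in zip(peak_idx[:-1], peak_idx[1:]):
        bounds.append(a + int(np.argmin(sig[a:b + 1])))
    bounds.append(len(sig))
    fractions = np.array([mass[bounds[i]:bounds[i + 1]].sum() / total
                          for i in range(len(peak_idx))])
    keep = fractions >= min_peak_fraction
    depths = profile.depth_bins[peak_idx][keep]
    fracs = fractions[keep]
    order = np.argsort(depths)
    depths, fracs = depths[order], fracs[order]

    strata = [stratum_of(d, profile.layer_edges) for d in depths]
    call = "unclassified"
    if len(depths) == 2 and set(strata) == {"S2", "S4"}:
        call = "bistratified_S2S4"
    elif len(depths) == 1:
        call = {"S4": "mono_ON_S4", "S5": "mono_ON_S5", "S1": "mono_OFF_S1"}.get(
            strata[0], "unclassified")
    return SubtypeCall(call, tuple(float(d) for d in depths),
                       tuple(float(f) for f in fracs))
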