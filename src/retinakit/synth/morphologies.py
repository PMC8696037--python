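"""Generator for mono- and bistratified model neuron morphologies.

Builds a rooted binary-branching tree whose dendritic length is
concentrated in Gaussian slabs at the requested IPL depths. The implied
IPL frame places the GCL border at z = 0 μm and the INL border at
``ipl_thickness_um``; the frame parameters are recorded in the
GroundTruth so downstream depth analyses can reconstruct it.
"""

from __future__ import annotations

import numpy as np

from ..morphology import IplFrame, Morphology
from .truth import GroundTruth

__all__ = ["gen_morphology", "frame_from_truth"]

DEFAULT_IPL_THICKNESS_UM = 50.0


def frame_from_truth(truth: GroundTruth) -> IplFrame:
    """Reconstruct the IPL frame a generated morphology was built in."""
    p = truth.params
    return IplFrame(gcl_border_z=p["gcl_border_z_um"], inl_border_z=p["inl_border_z_um"])


def _grow_binary(rng, nodes, parent_idx, hub_xy, plane_z, sigma_z,
                 arbor_radius, branch_order, thickness):
    """Recursively add a radial binary arbor around ``hub_xy`` at ``plane_z``."""
    def add_node(xyz, parent):
        nodes.append((3, xyz, 0.5, parent))
        return len(nodes) - 1

    def grow(parent, level, angle_lo, angle_hi):
        if level > branch_order:
            return
        r = arbor_radius * level / branch_order
        for frac in (0.25, 0.75):
            ang = angle_lo + frac * (angle_hi - angle_lo)
            z = float(np.clip(plane_z + rng.normal(0.0, sigma_z), 0.0, thickness))
            xyz = (hub_xy[0] + r * np.cos(ang), hub_xy[1] + r * np.sin(ang), z)
            child = add_node(xyz, parent)
            mid = angle_lo + frac * (angle_hi - angle_lo)
            half = (angle_hi - angle_lo) / 4.0
            grow(child, level + 1, mid - half, mid + half)

    grow(parent_idx, 1, 0.0, 2.0 * np.pi)


def gen_morphology(
    soma_depth: float = 5.0,
    strat_depths=(40.0,),
    arbor_radius: float = 150.0,
    branch_order: int = 5,
    seed: int = 0,
    strat_sigma_pct: float = 5.0,
    ipl_thickness_um: float = DEFAULT_IPL_THICKNESS_UM,
) -> Morphology:
    """Generate a mono- (1 plane) or bistratified (2 planes) morphology.

    ``strat_depths`` are IPL-% values in [0, 100]; the soma sits
    ``soma_depth`` μm on the GCL side of the 0% border, with a thin stalk
    rising to each stratification plane where a radial binary arbor of
    the given order spreads, its z spread set by ``strat_sigma_pct``.
    """
    strat_depths = tuple(float(d) for d in strat_depths)
    if not 1 <= len(strat_depths) <= 2:
        raise ValueError("strat_depths must contain 1 or 2 planes")
    for d in strat_depths:
        if not 0.0 <= d <= 100.0:
            raise ValueError(f"stratification depth {d}% outside [0, 100]")
    if soma_depth < 0 or arbor_radius <= 0 or branch_order < 1:
        raise ValueError("invalid geometry parameters")
    rng = np.random.default_rng(seed)
    thickness = ipl_thickness_um
    sigma_z = strat_sigma_pct / 100.0 * thickness

    # (type, xyz, radius, parent-row) with the soma at row 0
    nodes = [(1, (0.0, 0.0, -soma_depth), 5.0, -1)]
    for i, depth in enumerate(strat_depths):
        plane_z = depth / 100.0 * thickness
        # stalk from the soma to the plane, slightly offset per plane
        hub_xy = (2.0 * i, 0.0)
        nodes.append((3, (hub_xy[0], hub_xy[1], plane_z), 0.8, 0))
        _grow_binary(rng, nodes, len(nodes) - 1, hub_xy, plane_z, sigma_z,
                     arbor_radius, branch_order, thickness)

    types = np.array([t for t, _, _, _ in nodes])
    xyz = np.array([p for _, p, _, _ in nodes])
    radii = np.array([r for _, _, r, _ in nodes])
    parent_rows = np.array([p for _, _, _, p in nodes])
    ids = np.arange(1, len(nodes) + 1)
    parents = np.where(parent_rows >= 0, ids[parent_rows], -1)
    return Morphology(
        ids=ids, types=types, xyz=xyz, radii=radii, parents=parents,
        ground_truth=GroundTruth(
            "morphology",
            {"soma_depth_um": soma_depth, "strat_depths_pct": strat_depths,
             "arbor_radius_um": arbor_radius, "branch_order": branch_order,
             "strat_sigma_pct": strat_sigma_pct,
             "gcl_border_z_um": 0.0, "inl_border_z_um": thickness},
            seed),
    )
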