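"""Readers and writers for the package's text and image formats.

Conventions: CSVs carry explicit headers with units in the column names
(μm for coordinates, seconds for times); TIFF stacks are channel-first
with a YAML sidecar manifest naming channels, roles and pixel size;
ground-truth records are YAML sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ephys import SpikeTrain, StimulusTrial
from .mosaic import PointPattern, Window
from .straighten import SectionImage
from .synth.truth import GroundTruth

__all__ = [
    "FormatError",
    "read_point_table", "write_point_table",
    "read_spike_table", "write_spike_table",
    "read_section_tiff", "write_section_tiff",
    "write_ground_truth", "read_ground_truth",
    "load_yaml", "dump_yaml",
]

POINT_COLUMNS = ["x_um", "y_um", "label"]
SPIKE_COLUMNS = ["cell_id", "trial", "condition_kind", "condition_value", "t_s"]


class FormatError(ValueError):
    """Malformed input file."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def write_point_table(pattern: PointPattern, path) -> None:
    df = pd.DataFrame({
        "x_um": pattern.points[:, 0],
        "y_um": pattern.points[:, 1],
        "label": pattern.label,
    })
    df.to_csv(path, index=False)


def read_point_table(path, window: Optional[Window] = None) -> PointPattern:
    """Read a point table CSV (columns x_um, y_um, label).

    If no window is given, the points' bounding box (padded by 10⁻⁶ μm)
    is used.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from None
    _require_columns(df, ["x_um", "y_um"], path)
    pts = df[["x_um", "y_um"]].to_numpy(dtype=float)
    if window is None:
        pad = 1e-6
        window = Window(pts[:, 0].min() - pad, pts[:, 1].min() - pad,
                        pts[:, 0].max() + pad, pts[:, 1].max() + pad)
    label = str(df["label"].iloc[0]) if "label" in df.columns and len(df) else ""
    return PointPattern(points=pts, window=window, label=label)


def write_spike_table(trials: Mapping[str, Sequence[StimulusTrial]], path) -> None:
    """Write trials keyed by cell id as a long-format spike table."""
    rows = []
    for cell_id, cell_trials in trials.items():
        for k, trial in enumerate(cell_trials):
            kind = trial.condition.get("kind", "")
            value = (trial.condition.get("diameter_um")
                     or trial.condition.get("direction_deg")
                     or trial.condition.get("current_pA") or 0.0)
            for t in trial.train.spikes:
                rows.append((cell_id, k, kind, value, t))
    pd.DataFrame(rows, columns=SPIKE_COLUMNS).to_csv(path, index=False)


def read_spike_table(path, epochs: Mapping[str, tuple], t0: float = 0.0,
                     t1: Optional[float] = None) -> dict:
    """Read a spike table into ``{cell_id: [StimulusTrial, ...]}``.

    The epoch structure is not stored in the table and must be supplied
    (from the stimulus configuration).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from None
    _require_columns(df, SPIKE_COLUMNS, path)
    value_key = {"flash": "diameter_um", "grating": "direction_deg",
                 "current_step": "current_pA"}
    out: dict = {}
    for (cell, trial_no, kind, value), grp in df.groupby(
            ["cell_id", "trial", "condition_kind", "condition_value"]):
        times = np.sort(grp["t_s"].to_numpy(dtype=float))
        end = t1 if t1 is not None else max((e for _, e in epochs.values()),
                                            default=times[-1] if len(times) else 0.0)
        condition = {"kind": kind, value_key.get(kind, "value"): value}
        out.setdefault(cell, []).append(StimulusTrial(
            train=SpikeTrain(spikes=times, t0=t0, t1=end),
            condition=condition, epochs=dict(epochs)))
    return out


def write_section_tiff(section: SectionImage, path) -> None:
    """Write a channel-first TIFF stack plus a YAML channel manifest."""
    path = Path(path)
    names = list(section.channels)
    stack = np.stack([np.asarray(section.channels[n], dtype=np.float32) for n in names])
    tifffile.imwrite(path, stack)
    manifest = {
        "channels": names,
        "channel_roles": {n: section.channel_roles.get(n, "marker") for n in names},
        "pixel_size_um": float(section.pixel_size),
    }
    path.with_suffix(".manifest.yaml").write_text(yaml.safe_dump(manifest))


def read_section_tiff(path) -> SectionImage:
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    manifest_path = path.with_suffix(".manifest.yaml")
    if manifest_path.exists():
        manifest = yaml.safe_load(manifest_path.read_text())
        names = manifest["channels"]
        if len(names) != stack.shape[0]:
            raise FormatError(
                f"{path}: manifest names {len(names)} channels "
                f"({names}) but stack has {stack.shape[0]} pages")
        roles = manifest.get("channel_roles", {})
        pixel_size = float(manifest.get("pixel_size_um", 1.0))
    else:
        names = [f"ch{i}" for i in range(stack.shape[0])]
        roles, pixel_size = {}, 1.0
    return SectionImage(
        channels={n: stack[i].astype(float) for i, n in enumerate(names)},
        pixel_size=pixel_size, channel_roles=roles)


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(truth.as_dict())))


def read_ground_truth(path) -> GroundTruth:
    d = yaml.safe_load(Path(path).read_text())
    return GroundTruth(kind=d["kind"], params=d["params"], seed=int(d["seed"]))


def _plain(obj):
    """Recursively coerce numpy scalars/sequences to plain Python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_yaml(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a mapping at top level")
    return data


def dump_yaml(data: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(data)))
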