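"""Spike-train physiology metrics.

Covers firing-adaptation indices from current-step responses, F-I curves,
flash-response classification (ON / OFF / ON-OFF / unresponsive),
spot-size tuning tables, and direction tuning with a direction
selectivity index (DSI).

All times are seconds; rates are Hz; stimulus geometry is μm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "StimulusTrial",
    "DirectionTuning",
    "FlashClassification",
    "adaptation_index",
    "fi_curve",
    "classify_flash_response",
    "spot_size_tuning",
    "direction_tuning",
]

#: window used for transient (edge) response rates, seconds
TRANSIENT_WINDOW_S = 0.3


@dataclass
class SpikeTrain:
    """Sorted spike times within a recording window ``[t0, t1]``."""

    spikes: np.ndarray  # seconds
    t0: float = 0.0
    t1: Optional[float] = None
    ground_truth: object = None

    def __post_init__(self) -> None:
        s = np.asarray(self.spikes, dtype=float).ravel()
        if self.t1 is None:
            self.t1 = float(s[-1]) if s.size else self.t0
        if s.size:
            if np.any(np.diff(s) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if s[0] < self.t0 or s[-1] > self.t1:
                raise ValueError("spike times outside the recording window")
        self.spikes = s

    @property
    def n(self) -> int:
        return len(self.spikes)

    def count_in(self, start: float, end: float) -> int:
        """Spikes with ``start <= t < end``."""
        return int(np.searchsorted(self.spikes, end) - np.searchsorted(self.spikes, start))

    def rate_in(self, start: float, end: float) -> float:
        if end <= start:
            raise ValueError("empty interval")
        return self.count_in(start, end) / (end - start)


@dataclass
class StimulusTrial:
    """One spike train aligned to a stimulus epoch description.

    ``condition`` carries the stimulus kind and its value, e.g.
    ``{"kind": "flash", "diameter_um": 300}`` or
    ``{"kind": "grating", "direction_deg": 90}`` or
    ``{"kind": "current_step", "current_pA": 50}``.
    ``epochs`` maps epoch names (``baseline``, ``stim_on``, ``stim_off``)
    to ``(start, end)`` intervals in seconds.
    """

    train: SpikeTrain
    condition: Mapping[str, object]
    epochs: Mapping[str, tuple]
    ground_truth: object = None

    def __post_init__(self) -> None:
        for name, (a, b) in self.epochs.items():
            if not (self.train.t0 <= a < b <= self.train.t1):
                raise ValueError(f"epoch {name!r}=({a}, {b}) outside recording window")


@dataclass(frozen=True)
class DirectionTuning:
    directions: np.ndarray  # degrees
    mean_counts: np.ndarray  # spikes per direction
    dsi: float
    pref_dir: float  # degrees in [0, 360)
    mode: str = "vector_sum"
    undefined: bool = False


@dataclass(frozen=True)
class FlashClassification:
    call: str  # "ON" | "OFF" | "ON-OFF" | "unresponsive"
    on_index: float
    off_index: float
    z_thresh: float
    used_poisson_fallback: bool = False


def adaptation_index(train: SpikeTrain, variant: str = "literal") -> float:
    """Firing adaptation index from the first and last inter-spike intervals.

    With ``T_initial`` the interval between the first two spikes and
    ``T_last`` the interval between the last two:

    - ``variant="literal"``: ``1 - T_last / T_initial``. Zero for a
      perfectly regular train; negative when firing decays (intervals
      lengthen).
    - ``variant="decay_positive"``: ``1 - T_initial / T_last``. Zero for a
      regular train; positive when firing decays.

    Requires at least three spikes (two intervals).
    """
    if variant not in ("literal", "decay_positive"):
        raise ValueError(f"unknown adaptation variant {variant!r}")
    if train.n < 3:
        raise ValueError(f"adaptation index undefined for {train.n} < 3 spikes")
    isis = np.diff(train.spikes)
    t_initial, t_last = isis[0], isis[-1]
    if variant == "literal":
        return float(1.0 - t_last / t_initial)
    return float(1.0 - t_initial / t_last)


def fi_curve(trials: Sequence[StimulusTrial]) -> pd.DataFrame:
    """Firing rate versus injected current.

    Rate is the spike count within the ``stim_on`` epoch divided by its
    duration, averaged over trials sharing the same current step. Empty
    windows contribute 0 Hz.
    """
    if not trials:
        raise ValueError("no trials")
    rows = []
    for t in trials:
        if "current_pA" not in t.condition:
            raise ValueError("fi_curve requires current_step trials with 'current_pA'")
        a, b = t.epochs["stim_on"]
        rows.append({"current_pA": float(t.condition["current_pA"]),
                     "rate_hz": t.train.rate_in(a, b)})
    df = pd.DataFrame(rows).groupby("current_pA", as_index=False)["rate_hz"].mean()
    return df.sort_values("current_pA", ignore_index=True)


def _epoch_rates(trials, epoch, window=None):
    rates = []
    for t in trials:
        a, b = t.epochs[epoch]
        if window is not None:
            b = min(b, a + window)
        rates.append(t.train.rate_in(a, b))
    return np.asarray(rates)


def classify_flash_response(
    trials: Sequence[StimulusTrial],
    z_thresh: float = 3.0,
    transient_window: float = TRANSIENT_WINDOW_S,
) -> FlashClassification:
    """Classify a cell's flash response as ON, OFF, ON-OFF or unresponsive.

    The ON (OFF) index is the elevation of the mean rate in the first
    ``transient_window`` seconds after stimulus onset (offset) over the
    mean baseline rate, in units of the across-trial baseline-rate SD.
    The call is ON if only the ON index exceeds ``z_thresh``, OFF if only
    the OFF index does, ON-OFF if both, unresponsive if neither.

    With zero baseline SD the indices fall back to a Poisson-rate z-score
    (elevation over the expected count scaled by its Poisson SD), flagged
    in the result.
    """
    if not trials:
        raise ValueError("no trials")
    for t in trials:
        if "baseline" not in t.epochs:
            raise ValueError("flash trials require a 'baseline' epoch")

    base = _epoch_rates(trials, "baseline")
    on = _epoch_rates(trials, "stim_on", transient_window)
    off = _epoch_rates(trials, "stim_off", transient_window)
    base_mean = base.mean()
    base_sd = base.std(ddof=1) if len(base) > 1 else 0.0

    fallback = base_sd == 0.0
    if not fallback:
        on_idx = (on.mean() - base_mean) / base_sd
        off_idx = (off.mean() - base_mean) / base_sd
    else:
        # Poisson test on pooled counts: SD of the pooled rate estimate is
        # sqrt(expected count)/total window
        def z(rates):
            w = transient_window * len(trials)
            expected = base_mean * w
            observed = rates.mean() * w
            if expected == 0.0:
                return float("inf") if observed > 0 else 0.0
            return (observed - expected) / np.sqrt(expected)

        on_idx, off_idx = z(on), z(off)

    on_hit, off_hit = on_idx > z_thresh, off_idx > z_thresh
    if on_hit and off_hit:
        call = "ON-OFF"
    elif on_hit:
        call = "ON"
    elif off_hit:
        call = "OFF"
    else:
        call = "unresponsive"
    return FlashClassification(
        call=call,
        on_index=float(on_idx),
        off_index=float(off_idx),
        z_thresh=z_thresh,
        used_poisson_fallback=fallback,
    )


def spot_size_tuning(trials: Sequence[StimulusTrial]) -> pd.DataFrame:
    """Mean stimulus-window rate per flashed-spot diameter.

    Returns a table with ``diameter_um``, ``rate_hz`` and ``norm_rate``
    (rate scaled so the row maximum is 1, for heatmap display); rows are
    sorted by diameter.
    """
    if not trials:
        raise ValueError("no trials")
    rows = []
    for t in trials:
        if "diameter_um" not in t.condition:
            raise ValueError("spot_size_tuning requires flash trials with 'diameter_um'")
        a, b = t.epochs["stim_on"]
        rows.append({"diameter_um": float(t.condition["diameter_um"]),
                     "rate_hz": t.train.rate_in(a, b)})
    df = pd.DataFrame(rows).groupby("diameter_um", as_index=False)["rate_hz"].mean()
    df = df.sort_values("diameter_um", ignore_index=True)
    peak = df["rate_hz"].max()
    df["norm_rate"] = df["rate_hz"] / peak if peak > 0 else 0.0
    return df


def direction_tuning(
    trials: Sequence[StimulusTrial],
    mode: str = "vector_sum",
) -> DirectionTuning:
    """Directional tuning and selectivity from moving-stimulus trials.

    Spike counts in the ``stim_on`` epoch are averaged per direction
    (directions must be evenly spaced over 360°). With
    ``mode="vector_sum"`` (default),

        DSI = |Σ_d n_d exp(iθ_d)| / Σ_d n_d

    and the preferred direction is the argument of the vector sum. With
    ``mode="pref_null"``, DSI = (pref − null)/(pref + null) using the
    peak direction and its opposite.

    All-zero counts leave the DSI undefined (``undefined=True``,
    ``dsi=nan``).
    """
    if mode not in ("vector_sum", "pref_null"):
        raise ValueError(f"unknown DSI mode {mode!r}")
    if not trials:
        raise ValueError("no trials")
    counts: dict[float, list[int]] = {}
    for t in trials:
        if "direction_deg" not in t.condition:
            raise ValueError("direction_tuning requires trials with 'direction_deg'")
        d = float(t.condition["direction_deg"]) % 360.0
        a, b = t.epochs.get("stim_on", (t.train.t0, t.train.t1))
        counts.setdefault(d, []).append(t.train.count_in(a, b))
    directions = np.array(sorted(counts))
    spacing = np.diff(np.concatenate([directions, [directions[0] + 360.0]]))
    if len(directions) < 2 or not np.allclose(spacing, 360.0 / len(directions)):
        raise ValueError("directions must be evenly spaced over 360°")
    mean_counts = np.array([np.mean(counts[d]) for d in directions])

    total = mean_counts.sum()
    if total == 0:
        return DirectionTuning(directions, mean_counts, float("nan"),
                               float("nan"), mode, undefined=True)

    theta = np.deg2rad(directions)
    vec = np.sum(mean_counts * np.exp(1j * theta))
    pref_dir = float(np.rad2deg(np.angle(vec)) % 360.0)
    if mode == "vector_sum":
        dsi = float(np.abs(vec) / total)
    else:
        i_pref = int(np.argmax(mean_counts))
        i_null = int(np.argmin(np.abs(
            (directions - (directions[i_pref] + 180.0) + 180.0) % 360.0 - 180.0)))
        p, q = mean_counts[i_pref], mean_counts[i_null]
        dsi = float((p - q) / (p + q)) if (p + q) > 0 else 0.0
        pref_dir = float(directions[i_pref])
    return DirectionTuning(directions, mean_counts, dsi, pref_dir, mode)
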