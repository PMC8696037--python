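"""Spike-train and stimulus-trial generators.

Trials use a shared timeline: ``baseline`` (1 s), ``stim_on`` (the
stimulus epoch, 2 s by default), then ``stim_off`` (1 s). Times are in
seconds.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..ephys import SpikeTrain, StimulusTrial, TRANSIENT_WINDOW_S
from .truth import GroundTruth

__all__ = ["gen_spike_train", "gen_direction_trials", "gen_flash_trials",
           "DEFAULT_DIRECTIONS", "size_tuning_profile"]

DEFAULT_DIRECTIONS = tuple(float(d) for d in range(0, 360, 45))

BASELINE_S = 1.0
POST_S = 1.0

#: default center-size tuning: log-Gaussian peaked at this diameter (μm).
#: This profile is a free generator choice recorded in GroundTruth, not a
#: claim about real data.
DEFAULT_PREF_DIAMETER_UM = 300.0
DEFAULT_SIZE_WIDTH_LOG = 1.0


def _poisson_times(rng, rate, a, b):
    """Homogeneous Poisson spike times in [a, b)."""
    n = rng.poisson(max(rate, 0.0) * (b - a))
    return rng.uniform(a, b, n)


def _to_train(times, t0, t1):
    times = np.sort(np.asarray(times, dtype=float))
    # break exact ties (measure-zero but possible in float) minimally
    for k in range(1, len(times)):
        if times[k] <= times[k - 1]:
            times[k] = np.nextafter(times[k - 1], np.inf)
    return SpikeTrain(spikes=times, t0=t0, t1=t1)


def gen_spike_train(
    n_spikes: int,
    first_isi: float,
    isi_ratio: float,
    seed: int = 0,
    jitter_sd: float = 0.0,
) -> SpikeTrain:
    """Spike train with geometrically progressing inter-spike intervals.

    The intervals follow a geometric progression such that the ratio of
    the last interval to the first equals ``isi_ratio``;
    ``isi_ratio=1`` gives a perfectly regular train. Optional Gaussian
    jitter is off by default.

    Spike times are snapped to a dyadic 2⁻³⁰ s (~1 ns) grid so that
    inter-spike intervals survive float summation exactly: a regular
    train's measured intervals are bitwise identical.
    """
    if n_spikes < 3:
        raise ValueError("need at least 3 spikes (adaptation index undefined below)")
    if first_isi <= 0 or isi_ratio <= 0:
        raise ValueError("first_isi and isi_ratio must be positive")
    k = n_spikes - 1  # number of intervals
    r = isi_ratio ** (1.0 / (k - 1))
    isis = first_isi * r ** np.arange(k)
    isis[-1] = first_isi * isi_ratio  # endpoints exact
    grid = 2.0 ** -30
    isis_int = np.maximum(np.rint(isis / grid).astype(np.int64), 1)
    times = np.concatenate([[0], np.cumsum(isis_int)]).astype(float) * grid
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        times = np.sort(times + rng.normal(0.0, jitter_sd, times.shape))
    train = _to_train(times, 0.0, float(times[-1]))
    train.ground_truth = GroundTruth(
        "train",
        {"n_spikes": n_spikes, "first_isi_s": first_isi, "isi_ratio": isi_ratio,
         "jitter_sd_s": jitter_sd},
        seed)
    return train


def gen_direction_trials(
    pref_dir: float,
    kappa: float,
    base_count: float,
    n_trials: int,
    directions=DEFAULT_DIRECTIONS,
    seed: int = 0,
    sweep_s: float = 2.0,
) -> list:
    """Direction-tuned moving-stimulus trials.

    Per-trial spike counts are Poisson with mean
    ``base_count * exp(kappa * (cos(θ - pref_dir) - 1))`` — a von Mises
    profile normalized to peak 1 — and spike times are uniform within the
    sweep. ``kappa=0`` gives equal expected counts in every direction.
    """
    directions = tuple(float(d) for d in directions)
    if not directions:
        raise ValueError("directions must be non-empty")
    if base_count <= 0:
        raise ValueError("base_count must be positive")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    rng = np.random.default_rng(seed)
    truth = GroundTruth(
        "train",
        {"model": "direction", "pref_dir_deg": pref_dir, "kappa": kappa,
         "base_count": base_count, "n_trials": n_trials, "directions": directions,
         "sweep_s": sweep_s},
        seed)
    trials = []
    for d in directions:
        mean = base_count * np.exp(kappa * (np.cos(np.deg2rad(d - pref_dir)) - 1.0))
        for _ in range(n_trials):
            n = rng.poisson(mean)
            train = _to_train(rng.uniform(0.0, sweep_s, n), 0.0, sweep_s)
            trials.append(StimulusTrial(
                train=train,
                condition={"kind": "grating", "direction_deg": d},
                epochs={"stim_on": (0.0, sweep_s)},
            ))
            trials[-1].ground_truth = truth
    return trials


def size_tuning_profile(diameter_um, pref_diameter_um=DEFAULT_PREF_DIAMETER_UM,
                        width_log=DEFAULT_SIZE_WIDTH_LOG):
    """Log-Gaussian center-size rate multiplier, peak 1 at the preferred size."""
    return float(np.exp(-0.5 * (np.log(diameter_um / pref_diameter_um) / width_log) ** 2))


def gen_flash_trials(
    cell_class: str,
    diameters,
    on_rate: float,
    baseline_rate: float,
    epoch: float = 2.0,
    seed: int = 0,
    n_trials: int = 10,
    pref_diameter_um: float = DEFAULT_PREF_DIAMETER_UM,
    size_width_log: float = DEFAULT_SIZE_WIDTH_LOG,
) -> list:
    """Flashing-spot trials for an ON, OFF or ON-OFF cell.

    Spiking is piecewise-homogeneous Poisson: the response rate applies
    during the class-appropriate window(s) — the whole stimulus epoch for
    ON cells, the whole post-stimulus epoch for OFF cells, and the 300 ms
    windows after each edge for ON-OFF cells — and the baseline rate
    elsewhere. Diameters modulate the response elevation by a log-Gaussian
    center-size profile recorded in the trials' GroundTruth.
    """
    if cell_class not in ("ON", "OFF", "ON-OFF"):
        raise ValueError(f"unknown cell class {cell_class!r}")
    if baseline_rate < 0 or on_rate < baseline_rate:
        raise ValueError("require on_rate >= baseline_rate >= 0")
    if on_rate == baseline_rate:
        warnings.warn("on_rate equals baseline_rate: cell class is unrecoverable",
                      stacklevel=2)
    if epoch <= 0:
        raise ValueError("epoch must be positive")
    diameters = tuple(float(d) for d in diameters)
    rng = np.random.default_rng(seed)
    t_on = BASELINE_S
    t_off = BASELINE_S + epoch
    t_end = t_off + POST_S
    epochs = {"baseline": (0.0, t_on), "stim_on": (t_on, t_off),
              "stim_off": (t_off, t_end)}
    truth = GroundTruth(
        "train",
        {"model": "flash", "cell_class": cell_class, "diameters_um": diameters,
         "on_rate_hz": on_rate, "baseline_rate_hz": baseline_rate, "epoch_s": epoch,
         "n_trials": n_trials, "size_profile": "log_gaussian",
         "pref_diameter_um": pref_diameter_um, "size_width_log": size_width_log,
         "transient_window_s": TRANSIENT_WINDOW_S},
        seed)
    trials = []
    for d in diameters:
        mult = size_tuning_profile(d, pref_diameter_um, size_width_log)
        resp = baseline_rate + (on_rate - baseline_rate) * mult
        if cell_class == "ON":
            segments = [(0.0, t_on, baseline_rate), (t_on, t_off, resp),
                        (t_off, t_end, baseline_rate)]
        elif cell_class == "OFF":
            segments = [(0.0, t_off, baseline_rate), (t_off, t_end, resp)]
        else:  # ON-OFF: transients at both stimulus edges
            w = TRANSIENT_WINDOW_S
            segments = [(0.0, t_on, baseline_rate), (t_on, t_on + w, resp),
                        (t_on + w, t_off, baseline_rate), (t_off, t_off + w, resp),
                        (t_off + w, t_end, baseline_rate)]
        for _ in range(n_trials):
            times = np.concatenate([_poisson_times(rng, r, a, b) for a, b, r in segments])
            trial = StimulusTrial(
                train=_to_train(times, 0.0, t_end),
                condition={"kind": "flash", "diameter_um": d, "cell_class": cell_class},
                epochs=epochs,
            )
            trial.ground_truth = truth
            trials.append(trial)
    return trials
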