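import numpy as np
import pytest

from retinakit import synth
from retinakit.ephys import (
    SpikeTrain,
    StimulusTrial,
    adaptation_index,
    classify_flash_response,
    direction_tuning,
    fi_curve,
    spot_size_tuning,
)


def make_trial(times, condition, epochs, t1=4.0):
    return StimulusTrial(train=SpikeTrain(np.asarray(times, float), 0.0, t1),
                         condition=condition, epochs=epochs)


class TestAdaptationIndex:
    def test_regular_train_zero_both_variants(self):
        t = SpikeTrain(np.arange(10) * 0.125)
        assert adaptation_index(t, "literal") == 0.0
        assert adaptation_index(t, "decay_positive") == 0.0

    def test_printed_formula_example(self):
        t = SpikeTrain([0.0, 0.1, 0.2, 0.3, 0.5])
        assert adaptation_index(t, "literal") == pytest.approx(-1.0)
        assert adaptation_index(t, "decay_positive") == pytest.approx(0.5)

    def test_too_few_spikes(self):
        with pytest.raises(ValueError):
            adaptation_index(SpikeTrain([0.0, 0.1]))

    def test_generator_roundtrip(self):
        for rho in (0.25, 0.8, 1.0, 2.0, 4.0):
            t = synth.gen_spike_train(15, 0.02, rho, seed=0)
            assert adaptation_index(t, "literal") == pytest.approx(1 - rho, abs=1e-6)

    def test_variant_algebraic_relation(self):
        # literal = 1 - 1/(1 - decay_positive)
        rng = np.random.default_rng(0)
        for _ in range(20):
            times = np.cumsum(rng.uniform(0.01, 0.3, size=8))
            t = SpikeTrain(times)
            lit = adaptation_index(t, "literal")
            dec = adaptation_index(t, "decay_positive")
            assert lit == pytest.approx(1 - 1 / (1 - dec), rel=1e-9)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            adaptation_index(SpikeTrain([0.0, 0.1, 0.2]), "other")


class TestFiCurve:
    EPOCHS = {"stim_on": (1.0, 1.5)}

    def test_no_spikes_zero_rate(self):
        trials = [make_trial([], {"kind": "current_step", "current_pA": 50},
                             self.EPOCHS, t1=2.0)]
        assert fi_curve(trials)["rate_hz"].iloc[0] == 0.0

    def test_count_over_duration(self):
        times = np.linspace(1.01, 1.49, 10)
        trials = [make_trial(times, {"kind": "current_step", "current_pA": 100},
                             self.EPOCHS, t1=2.0)]
        assert fi_curve(trials)["rate_hz"].iloc[0] == pytest.approx(20.0)

    def test_poisson_rate_recovery(self):
        rng = np.random.default_rng(1)
        lam, dur, n = 40.0, 0.5, 100
        trials = []
        for _ in range(n):
            k = rng.poisson(lam * dur)
            times = np.sort(rng.uniform(1.0, 1.5, k))
            times = np.unique(times)
            trials.append(make_trial(times, {"kind": "current_step",
                                             "current_pA": 80}, self.EPOCHS, t1=2.0))
        rate = fi_curve(trials)["rate_hz"].iloc[0]
        assert abs(rate - lam) <= 3 * np.sqrt(lam / (dur * n))

    def test_additive_over_concatenation(self):
        # pooled trials give the weighted mean of the sub-group rates
        t1 = [make_trial(np.linspace(1.01, 1.49, 4),
                         {"kind": "current_step", "current_pA": 50},
                         self.EPOCHS, t1=2.0)] * 3
        t2 = [make_trial(np.linspace(1.01, 1.49, 8),
                         {"kind": "current_step", "current_pA": 50},
                         self.EPOCHS, t1=2.0)] * 1
        r1 = fi_curve(t1)["rate_hz"].iloc[0]
        r2 = fi_curve(t2)["rate_hz"].iloc[0]
        pooled = fi_curve(t1 + t2)["rate_hz"].iloc[0]
        assert pooled == pytest.approx((3 * r1 + 1 * r2) / 4)


class TestClassifyFlashResponse:
    def test_generator_on_cell(self):
        trials = synth.gen_flash_trials("ON", [300], 40.0, 2.0, seed=0)
        assert classify_flash_response(trials).call == "ON"

    def test_generator_off_cell(self):
        trials = synth.gen_flash_trials("OFF", [300], 40.0, 2.0, seed=1)
        assert classify_flash_response(trials).call == "OFF"

    def test_generator_onoff_cell(self):
        trials = synth.gen_flash_trials("ON-OFF", [300], 40.0, 2.0, seed=2)
        assert classify_flash_response(trials).call == "ON-OFF"

    def test_baseline_only_unresponsive(self):
        epochs = {"baseline": (0.0, 1.0), "stim_on": (1.0, 3.0),
                  "stim_off": (3.0, 4.0)}
        rng = np.random.default_rng(3)
        trials = []
        for _ in range(10):
            times = np.sort(rng.uniform(0.0, 4.0, rng.poisson(8)))
            trials.append(make_trial(np.unique(times), {"kind": "flash",
                                                        "diameter_um": 300}, epochs))
        assert classify_flash_response(trials).call == "unresponsive"

    def test_zero_baseline_sd_poisson_fallback(self):
        epochs = {"baseline": (0.0, 1.0), "stim_on": (1.0, 3.0),
                  "stim_off": (3.0, 4.0)}
        trials = [make_trial(np.linspace(1.01, 1.29, 12),
                             {"kind": "flash", "diameter_um": 300}, epochs)
                  for _ in range(5)]
        res = classify_flash_response(trials)
        assert res.used_poisson_fallback
        assert res.call == "ON"

    def test_missing_baseline_rejected(self):
        trials = [make_trial([1.5], {"kind": "flash", "diameter_um": 300},
                             {"stim_on": (1.0, 3.0), "stim_off": (3.0, 4.0)})]
        with pytest.raises(ValueError, match="baseline"):
            classify_flash_response(trials)


class TestSpotSizeTuning:
    def test_flat_for_identical_responses(self):
        epochs = {"baseline": (0.0, 1.0), "stim_on": (1.0, 3.0),
                  "stim_off": (3.0, 4.0)}
        trials = [make_trial(np.linspace(1.1, 2.9, 6),
                             {"kind": "flash", "diameter_um": d}, epochs)
                  for d in (50, 300, 1200)]
        df = spot_size_tuning(trials)
        assert df["rate_hz"].nunique() == 1
        np.testing.assert_allclose(df["norm_rate"], 1.0)

    def test_peak_recovered_at_preferred_size(self):
        diameters = [50, 100, 200, 300, 600, 1200]
        trials = synth.gen_flash_trials("ON", diameters, 60.0, 2.0, seed=4,
                                        n_trials=20)
        df = spot_size_tuning(trials)
        assert df.loc[df["rate_hz"].idxmax(), "diameter_um"] == 300

    def test_norm_max_is_one(self):
        trials = synth.gen_flash_trials("ON", [100, 300], 40.0, 2.0, seed=5)
        assert spot_size_tuning(trials)["norm_rate"].max() == pytest.approx(1.0)


class TestDirectionTuning:
    EPOCHS = {"stim_on": (0.0, 2.0)}

    def _trials_with_counts(self, counts, directions=None):
        directions = directions or [45.0 * k for k in range(8)]
        trials = []
        for d, c in zip(directions, counts):
            times = np.linspace(0.1, 1.9, c) if c else []
            trials.append(make_trial(times, {"kind": "grating", "direction_deg": d},
                                     self.EPOCHS, t1=2.0))
        return trials

    def test_uniform_counts_zero_dsi(self):
        tuning = direction_tuning(self._trials_with_counts([7] * 8))
        assert tuning.dsi <= 1e-12

    def test_single_direction_full_dsi(self):
        tuning = direction_tuning(self._trials_with_counts([0, 0, 9, 0, 0, 0, 0, 0]))
        assert tuning.dsi == pytest.approx(1.0)
        assert tuning.pref_dir == pytest.approx(90.0)

    def test_all_zero_flagged_undefined(self):
        tuning = direction_tuning(self._trials_with_counts([0] * 8))
        assert tuning.undefined and np.isnan(tuning.dsi)

    def test_rotation_equivariance(self):
        counts = [2, 5, 11, 5, 2, 1, 0, 1]
        base = direction_tuning(self._trials_with_counts(counts))
        rotated_dirs = [(45.0 * k + 90.0) % 360 for k in range(8)]
        rot = direction_tuning(self._trials_with_counts(counts, rotated_dirs))
        assert rot.pref_dir == pytest.approx((base.pref_dir + 90.0) % 360, abs=1e-9)
        assert rot.dsi == pytest.approx(base.dsi, rel=1e-12)

    def test_relabeling_invariance(self):
        counts = [2, 5, 11, 5, 2, 1, 0, 1]
        trials = self._trials_with_counts(counts)
        shuffled = list(reversed(trials))
        a, b = direction_tuning(trials), direction_tuning(shuffled)
        assert a.dsi == b.dsi and a.pref_dir == b.pref_dir

    def test_dsi_bounds_random_counts(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            counts = rng.integers(0, 30, 8).tolist()
            if sum(counts) == 0:
                continue
            tuning = direction_tuning(self._trials_with_counts(counts))
            assert 0.0 <= tuning.dsi <= 1.0

    def test_pref_null_mode(self):
        tuning = direction_tuning(self._trials_with_counts([0, 0, 12, 0, 0, 0, 4, 0]),
                                  mode="pref_null")
        assert tuning.pref_dir == pytest.approx(90.0)
        assert tuning.dsi == pytest.approx((12 - 4) / (12 + 4))

    def test_uneven_directions_rejected(self):
        trials = self._trials_with_counts([3, 3, 3], directions=[0.0, 30.0, 90.0])
        with pytest.raises(ValueError, match="evenly spaced"):
            direction_tuning(trials)

    def test_generator_recovery(self):
        trials = synth.gen_direction_trials(135.0, 8.0, 50.0, 10, seed=9)
        tuning = direction_tuning(trials)
        err = abs((tuning.pref_dir - 135.0 + 180) % 360 - 180)
        assert err <= 45.0


class TestSpikeTrainValidation:
    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrain([0.2, 0.1])

    def test_outside_window_rejected(self):
        with pytest.raises(ValueError):
            SpikeTrain([0.5, 2.5], t0=0.0, t1=2.0)

    def test_epoch_outside_window_rejected(self):
        with pytest.raises(ValueError):
            StimulusTrial(train=SpikeTrain([0.5], 0.0, 1.0),
                          condition={"kind": "flash"},
                          epochs={"stim_on": (0.5, 2.0)})
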