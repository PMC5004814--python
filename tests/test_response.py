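"""PSTHs, the temporal-modulation test, evoked metrics, choice analyses."""

import numpy as np
import pandas as pd
import pytest

from vibroseq.response import (
    adaptation_ratio,
    adaptation_summary,
    choice_bias,
    compute_psth,
    divergence_time,
    evoked_response,
    temporal_modulation_test,
)
from vibroseq.synthetic import default_archetype, simulate_unit


def poisson_trains(rng, rate_hz, n_trials, epoch=(-25.0, 250.0)):
    span_s = (epoch[1] - epoch[0]) / 1000.0
    return [
        np.sort(rng.uniform(epoch[0], epoch[1], rng.poisson(rate_hz * span_s)))
        for _ in range(n_trials)
    ]


class TestPsth:
    def test_single_spike_rate(self):
        trains = [np.array([7.4])] + [np.empty(0)] * 9
        psth = compute_psth(trains, epoch_ms=(0.0, 20.0), bin_ms=1.0)
        assert psth.rate_hz[7] == pytest.approx(100.0)
        assert psth.rate_hz.sum() == pytest.approx(100.0)

    def test_boxcar_preserves_rate_integral(self):
        rng = np.random.default_rng(0)
        trains = poisson_trains(rng, 20.0, 50, epoch=(0.0, 200.0))
        raw = compute_psth(trains, (0.0, 200.0), 1.0)
        sm = compute_psth(trains, (0.0, 200.0), 1.0, smoothing_ms=10.0)
        # integrals agree away from edge effects
        assert sm.rate_hz[20:-20].sum() == pytest.approx(
            raw.rate_hz[20:-20].sum(), rel=0.05
        )

    def test_empty_trial_set_rejected(self):
        with pytest.raises(ValueError):
            compute_psth([])


class TestModulationTest:
    def test_preconditions(self):
        with pytest.raises(ValueError):
            temporal_modulation_test([np.array([5.0])], n_perm=0)
        assert temporal_modulation_test([np.empty(0)] * 10, n_perm=100) == 1.0

    def test_transient_unit_is_detected(self, library):
        arch = default_archetype("Fast", baseline_hz=5.0)
        trials = pd.DataFrame(
            {"trial_id": np.arange(100), "stimulus": ["FFF"] * 100,
             "choice": ["left"] * 100}
        )
        sp = simulate_unit(arch, trials, seed=0, sequences=library)
        trains = [g["time_ms"].to_numpy() for _, g in sp.groupby("trial_id")]
        assert temporal_modulation_test(trains, n_perm=2000, seed=1) < 0.001

    def test_type_one_error_controlled_under_stationary_null(self):
        rng = np.random.default_rng(12)
        n_units = 300
        pvals = np.array(
            [
                temporal_modulation_test(
                    poisson_trains(rng, 10.0, 50), n_perm=500, seed=rng
                )
                for _ in range(n_units)
            ]
        )
        rate = np.mean(pvals < 0.05)
        se = np.sqrt(0.05 * 0.95 / n_units)
        assert rate <= 0.05 + 3 * se
        # p-values roughly uniform under the null
        assert np.mean(pvals < 0.5) == pytest.approx(0.5, abs=0.1)


class TestEvoked:
    def test_flat_unit_has_zero_modulation(self):
        trains = [np.arange(-20.0, 240.0, 40.0)] * 20  # same train every trial
        ev = evoked_response(trains, 100.0)
        assert abs(ev.mean_evoked_hz) < 10.0
        assert not ev.significant

    def test_peak_latency_matches_construction(self):
        rng = np.random.default_rng(4)
        trains = []
        for _ in range(200):
            base = rng.uniform(0.0, 250.0, rng.poisson(1.0))
            transient = rng.normal(62.0, 1.5, rng.poisson(3.0))  # peak 12 ms post
            trains.append(np.sort(np.concatenate([base, transient])))
        ev = evoked_response(trains, 50.0)
        assert ev.peak_latency_ms == pytest.approx(12.0, abs=5.0)  # 10-ms smoothing
        assert ev.significant and ev.mean_evoked_hz > 0

    def test_windows_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            evoked_response([np.array([1.0])], 240.0)


class TestAdaptation:
    def test_ratio_arithmetic(self):
        assert np.allclose(adaptation_ratio([20.0, 20.0, 20.0]), [1.0, 1.0])
        assert np.allclose(adaptation_ratio([20.0, 16.0, 14.0]), [0.80, 0.70])
        assert adaptation_ratio([0.0, 5.0]) is None

    def test_recovers_imposed_multipliers(self, library):
        # generator imposes per-pulse multipliers (1, 0.8, 0.7); the evoked
        # -rate estimator should recover them within 2 SEM across units
        rng = np.random.default_rng(8)
        trials = pd.DataFrame(
            {"trial_id": np.arange(60), "stimulus": ["FFF"] * 60,
             "choice": ["left"] * 60}
        )
        onsets = library["FFF"].pulse_onsets_ms
        per_unit = []
        for u in range(40):
            arch = default_archetype("Fast", baseline_hz=float(rng.uniform(4, 10)))
            sp = simulate_unit(arch, trials, seed=100 + u, sequences=library)
            grouped = {t: g["time_ms"].to_numpy() for t, g in sp.groupby("trial_id")}
            trains = [grouped.get(t, np.empty(0)) for t in trials["trial_id"]]
            per_unit.append(
                [evoked_response(trains, o).mean_evoked_hz for o in onsets]
            )
        summary = adaptation_summary(per_unit)
        for target, row in zip((0.8, 0.7), summary.itertuples()):
            assert abs(row.ratio_mean - target) < 2 * row.ratio_sem + 0.02


class TestChoiceBias:
    def test_swapping_choice_labels_negates_bias(self):
        rng = np.random.default_rng(1)
        choices = np.array(["right", "left"] * 30)
        units = [poisson_trains(rng, 10.0, 60) for _ in range(5)]
        a = choice_bias(units, choices, 100.0)
        swapped = np.where(choices == "right", "left", "right")
        b = choice_bias(units, swapped, 100.0)
        assert np.allclose(a["per_unit_bias_hz"], -b["per_unit_bias_hz"])

    def test_slowpos_population_bias_detected(self, slowpos_session):
        s = slowpos_session
        final_onset = 100.0  # third pulse onset for the FFF train
        units = [s.spikes_by_trial(u) for u in s.unit_ids()]
        res = choice_bias(units, s.trials["choice"].to_numpy(), final_onset)
        assert res["mean_bias_hz"] > 0
        assert res["p_value"] < 0.01
        assert res["baseline_p_value"] > 0.05

    def test_type_one_calibration_on_choice_blind_units(self):
        rng = np.random.default_rng(21)
        n_runs = 150
        nonsig = 0
        for _ in range(n_runs):
            choices = np.array(["right", "left"] * 30)
            units = [poisson_trains(rng, 12.0, 60) for _ in range(10)]
            res = choice_bias(units, choices, 100.0)
            nonsig += res["p_value"] >= 0.05
        se = np.sqrt(0.05 * 0.95 / n_runs)
        assert nonsig / n_runs >= 0.95 - 3 * se


class TestDivergence:
    def test_identical_traces_never_diverge(self):
        rates = np.tile(np.linspace(5, 15, 250), (4, 1))
        assert divergence_time(rates, rates) is None

    def test_offset_from_120ms_detected(self):
        rng = np.random.default_rng(5)
        base = rng.uniform(5, 15, size=(8, 1)) + rng.normal(0, 0.3, size=(8, 250))
        right = base.copy()
        right[:, 120:] += 4.0
        t = divergence_time(right, base, t0_ms=0.0)
        assert t is not None
        assert abs(t - 120.0) <= 10.0

    def test_persistence_one_reduces_to_first_significant_window(self):
        rng = np.random.default_rng(6)
        base = rng.uniform(5, 15, size=(8, 1)) + rng.normal(0, 0.3, size=(8, 250))
        right = base.copy()
        right[:, 120:] += 4.0
        t1 = divergence_time(right, base, persistence=1)
        t3 = divergence_time(right, base, persistence=3)
        assert t1 is not None and t1 <= t3
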