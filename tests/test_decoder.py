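"""Population decoders: binning, OVA fits, controls, chance behavior."""

import numpy as np
import pytest

from vibroseq.decoder import (
    BinSpec,
    bin_spike_train,
    binned_counts,
    evaluate_choice_decoder,
    evaluate_stimulus_decoder,
    fit_unit_ova,
    predict_population,
    rate_normalize,
    rate_normalize_counts,
    time_scramble,
)


class TestBinning:
    def test_empty_train_gives_zero_vector(self):
        v = bin_spike_train(np.empty(0), BinSpec())
        assert v.shape == (15,) and not v.any()

    def test_spike_lands_in_second_bin(self):
        v = bin_spike_train(np.array([12.0]), BinSpec())
        assert v[1] == 1 and v.sum() == 1

    def test_single_bin_is_total_count(self):
        times = np.array([-5.0, 3.0, 50.0, 149.0, 200.0])
        v = bin_spike_train(times, BinSpec(kind="single"))
        assert v == pytest.approx([3.0])  # spikes outside 0-150 ignored

    def test_pre_withdrawal_window(self):
        spec = BinSpec(kind="pre_withdrawal")
        times = np.array([40.0, 95.0, 180.0])
        v = bin_spike_train(times, spec, withdrawal_ms=190.0)
        assert v == pytest.approx([2.0])  # [90, 190)
        with pytest.raises(ValueError):
            bin_spike_train(times, spec)


class TestControls:
    def test_rate_normalize_unit_norm(self):
        assert rate_normalize(np.array([3.0, 4.0])) == pytest.approx([0.6, 0.8])
        zero = np.zeros(4)
        assert rate_normalize(zero) == pytest.approx(zero)
        X = np.arange(24, dtype=float).reshape(2, 3, 4)
        norms = np.linalg.norm(rate_normalize_counts(X), axis=-1)
        assert np.allclose(norms[norms > 0], 1.0)

    def test_time_scramble_preserves_counts(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 150, 40))
        scrambled = time_scramble(times, rng)
        assert len(scrambled) == len(times)
        assert np.all(np.diff(scrambled) >= 0)
        assert not np.allclose(scrambled, times)


class TestUnitOva:
    def test_separable_counts_reach_perfect_training_accuracy(self):
        labels = np.repeat(["a", "b", "c", "d"], 20)
        X = (np.repeat(np.arange(4), 20) * 5.0)[:, None] + np.random.default_rng(
            0
        ).normal(0, 0.1, (80, 1))
        dec = fit_unit_ova(X, labels)
        pred = np.argmax(dec.predict_proba(X), axis=1)
        assert np.mean(np.array(dec.classes)[pred] == labels) == 1.0
        assert dec.coefficients.shape == (4, 2)  # one bin + bias per class

    def test_probabilities_normalized_per_trial(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(1.0, (60, 5)).astype(float)
        labels = np.tile(["a", "b", "c", "d"], 15)
        dec = fit_unit_ova(X, labels)
        probs = dec.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_fit_is_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(1.0, (80, 5)).astype(float)
        labels = np.repeat(["a", "b", "c", "d"], 20)
        a = fit_unit_ova(X, labels, cv_folds=3, seed=7)
        b = fit_unit_ova(X, labels, cv_folds=3, seed=7)
        assert np.allclose(a.coefficients, b.coefficients)


class TestPopulationPrediction:
    def test_single_unit_population_equals_its_argmax(self):
        probs = np.array([0.1, 0.6, 0.2, 0.1])
        idx, summed = predict_population([probs])
        assert idx == 1 and np.allclose(summed, probs)

    def test_confidence_weighted_vote(self):
        # opposing votes of unequal confidence: the stronger one wins
        u1 = np.array([0.70, 0.30])
        u2 = np.array([0.45, 0.55])
        idx, _ = predict_population([u1, u2])
        assert idx == 0

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            predict_population([])


class TestStimulusDecoding:
    def test_confusion_rows_sum_to_one(self, fast_stim_report):
        assert np.allclose(fast_stim_report.confusion.sum(axis=1), 1.0, atol=1e-9)
        assert 0.0 <= fast_stim_report.overall_accuracy <= 1.0

    def test_fast_population_decodes_stimuli(self, fast_stim_report):
        assert fast_stim_report.overall_accuracy > 0.45
        # the two same-mean-speed sequences are themselves distinguished
        diag = dict(zip(fast_stim_report.classes, np.diag(fast_stim_report.confusion)))
        assert diag["FMS"] > 0.30 and diag["SMF"] > 0.30

    def test_single_bin_loses_temporal_information(self, fast_session, fast_stim_report):
        labels = fast_session.trials["stimulus"].to_numpy()
        X1 = binned_counts(fast_session, BinSpec(kind="single"))
        rep1 = evaluate_stimulus_decoder(X1, labels, n_repeats=15, seed=0)
        assert rep1.overall_accuracy < fast_stim_report.overall_accuracy - 0.1

    def test_rate_normalization_keeps_and_scrambling_destroys_decoding(
        self, fast_session, fast_binned, fast_stim_report
    ):
        labels = fast_session.trials["stimulus"].to_numpy()
        rep_norm = evaluate_stimulus_decoder(
            rate_normalize_counts(fast_binned), labels, n_repeats=15, seed=0
        )
        rng = np.random.default_rng(7)
        spec = BinSpec()
        Xs = np.zeros_like(fast_binned)
        for u, uid in enumerate(fast_session.unit_ids()):
            for i, t in enumerate(fast_session.spikes_by_trial(uid)):
                Xs[u, i] = bin_spike_train(time_scramble(t, rng), spec)
        rep_scr = evaluate_stimulus_decoder(Xs, labels, n_repeats=15, seed=0)
        assert rep_norm.overall_accuracy > fast_stim_report.overall_accuracy - 0.12
        assert rep_scr.overall_accuracy < 0.35  # collapses toward 25% chance
        assert rep_scr.overall_accuracy < rep_norm.overall_accuracy - 0.15

    def test_uninformative_units_have_bounded_influence(self, fast_session, fast_binned):
        # equal-weight normalization: adding chance-level units must not
        # change expected accuracy by much
        labels = fast_session.trials["stimulus"].to_numpy()
        rng = np.random.default_rng(11)
        noise = rng.poisson(0.1, size=(8,) + fast_binned.shape[1:]).astype(float)
        Xaug = np.concatenate([fast_binned, noise], axis=0)
        base = evaluate_stimulus_decoder(fast_binned, labels, n_repeats=15, seed=4)
        aug = evaluate_stimulus_decoder(Xaug, labels, n_repeats=15, seed=4)
        assert abs(aug.overall_accuracy - base.overall_accuracy) < 0.10
        assert aug.overall_accuracy > 0.40


class TestChoiceDecoding:
    def test_slowpos_population_predicts_choice(self, slowpos_session):
        s = slowpos_session
        X = binned_counts(s, BinSpec(kind="single"))
        res = evaluate_choice_decoder(
            X,
            s.trials["stimulus"].to_numpy(),
            s.trials["choice"].to_numpy(),
            n_repeats=20,
            seed=0,
        )
        for stim, rep in res["per_stimulus"].items():
            assert rep.overall_accuracy > 0.5, stim
            assert np.allclose(rep.confusion.sum(axis=1), 1.0, atol=1e-9)
        assert res["mean_accuracy"] > 0.6

    def test_fast_population_cannot_predict_choice(self, fast_session):
        # no choice signal in Fast units: per-stimulus accuracy near 50%
        X = binned_counts(fast_session, BinSpec(kind="single"))
        res = evaluate_choice_decoder(
            X,
            fast_session.trials["stimulus"].to_numpy(),
            fast_session.trials["choice"].to_numpy(),
            n_repeats=20,
            seed=0,
        )
        assert abs(res["mean_accuracy"] - 0.5) < 0.12
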