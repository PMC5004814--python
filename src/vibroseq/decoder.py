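"""Population decoding of stimulus identity and behavioral choice.

Each unit is represented by an independent classifier over its binned
single-trial spike counts: a one-versus-all (OVA) set of logistic functions
for the four-way stimulus decoder, or a single logistic function for the
binary choice decoder.  Per-unit class probabilities are renormalized to sum
to one so that every unit carries the same vote mass; the population
prediction is the class with the maximal summed probability, ties broken
uniformly at random under the run seed.

Evaluation repeats the whole procedure on fresh stratified 70/30 splits of
the trials: units are fit on the training split, and each held-out test
event receives, from every unit, the probabilities of one spike train drawn
without replacement from that unit's held-out trials of the queried class.
Confusion matrices are averaged over repeats with rows normalized to one.

Two controls probe what the decoder uses: rate normalization (dividing each
binned train by its Euclidean norm, removing overall rate while preserving
temporal shape) and time scrambling (re-drawing spike times uniformly within
the trial, preserving counts while destroying timing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "BinSpec",
    "UnitDecoder",
    "DecoderReport",
    "bin_spike_train",
    "binned_counts",
    "fit_unit_ova",
    "predict_population",
    "evaluate_stimulus_decoder",
    "evaluate_choice_decoder",
    "rate_normalize",
    "rate_normalize_counts",
    "time_scramble",
]

DECODING_EPOCH_MS = (0.0, 150.0)


@dataclass(frozen=True)
class BinSpec:
    """How single-trial spike trains are turned into count vectors.

    ``kind`` is one of:

    * ``"uniform"`` — ``bin_ms`` bins across ``epoch_ms`` (default 10-ms
      bins over 0-150 ms, 15 features);
    * ``"single"`` — one bin covering the whole epoch (total count);
    * ``"pre_withdrawal"`` — one bin covering the last ``pre_ms`` before the
      trial's nose-poke withdrawal.
    """

    kind: str = "uniform"
    bin_ms: float = 10.0
    epoch_ms: tuple[float, float] = DECODING_EPOCH_MS
    pre_ms: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "single", "pre_withdrawal"):
            raise ValueError(f"unknown bin spec kind {self.kind!r}")

    @property
    def n_bins(self) -> int:
        if self.kind == "uniform":
            return int(round((self.epoch_ms[1] - self.epoch_ms[0]) / self.bin_ms))
        return 1


def bin_spike_train(
    times_ms: np.ndarray, spec: BinSpec, withdrawal_ms: float | None = None
) -> np.ndarray:
    """Count vector for one spike train; spikes outside the window are ignored."""
    times_ms = np.asarray(times_ms, dtype=float)
    if spec.kind == "uniform":
        edges = np.arange(
            spec.epoch_ms[0], spec.epoch_ms[1] + spec.bin_ms / 2, spec.bin_ms
        )
        return np.histogram(times_ms, bins=edges)[0].astype(float)
    if spec.kind == "single":
        lo, hi = spec.epoch_ms
    else:  # pre_withdrawal
        if withdrawal_ms is None:
            raise ValueError("pre_withdrawal binning needs the withdrawal time")
        lo, hi = withdrawal_ms - spec.pre_ms, withdrawal_ms
    return np.array([np.sum((times_ms >= lo) & (times_ms < hi))], dtype=float)


def binned_counts(session, spec: BinSpec) -> np.ndarray:
    """(n_units, n_trials, n_bins) count array for a whole session."""
    withdrawal = session.trials["withdrawal_ms"].to_numpy()
    unit_ids = session.unit_ids()
    n_trials = len(session.trials)
    X = np.zeros((len(unit_ids), n_trials, spec.n_bins))
    for u, uid in enumerate(unit_ids):
        for i, times in enumerate(session.spikes_by_trial(uid)):
            X[u, i] = bin_spike_train(times, spec, withdrawal_ms=withdrawal[i])
    return X


def rate_normalize(counts: np.ndarray) -> np.ndarray:
    """Divide a count vector by its Euclidean norm (zero vectors unchanged)."""
    counts = np.asarray(counts, dtype=float)
    norm = np.linalg.norm(counts)
    return counts / norm if norm > 0 else counts


def rate_normalize_counts(X: np.ndarray) -> np.ndarray:
    """Rate-normalize every spike-count vector along the last axis."""
    norms = np.linalg.norm(X, axis=-1, keepdims=True)
    return np.where(norms > 0, X / np.where(norms > 0, norms, 1.0), X)


def time_scramble(
    times_ms: np.ndarray,
    rng: np.random.Generator,
    epoch_ms: tuple[float, float] = DECODING_EPOCH_MS,
) -> np.ndarray:
    """Re-draw each spike time uniformly within the epoch (counts preserved)."""
    times_ms = np.asarray(times_ms, dtype=float)
    inside = (times_ms >= epoch_ms[0]) & (times_ms < epoch_ms[1])
    new = times_ms.copy()
    new[inside] = rng.uniform(epoch_ms[0], epoch_ms[1], size=int(inside.sum()))
    return np.sort(new)


@dataclass
class UnitDecoder:
    """Per-class logistic functions for one unit, with normalized outputs."""

    classes: tuple
    models: list  # fitted LogisticRegression (or float fallback prob) per class
    spec: BinSpec | None = None
    C: float = 1.0

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Normalized class probabilities, rows summing to 1."""
        X = np.atleast_2d(X)
        probs = np.empty((len(X), len(self.classes)))
        for j, model in enumerate(self.models):
            if isinstance(model, float):
                probs[:, j] = model
            else:
                probs[:, j] = model.predict_proba(X)[:, 1]
        probs = np.clip(probs, 1e-12, None)
        return probs / probs.sum(axis=1, keepdims=True)

    @property
    def coefficients(self) -> np.ndarray:
        """(n_classes, n_bins + 1) coefficient matrix, bias last."""
        rows = []
        for model in self.models:
            if isinstance(model, float):
                rows.append(np.zeros(self._n_features + 1))
            else:
                rows.append(np.concatenate([model.coef_[0], model.intercept_]))
        return np.vstack(rows)

    @property
    def _n_features(self) -> int:
        for model in self.models:
            if not isinstance(model, float):
                return model.coef_.shape[1]
        return 0


def _fit_binary(X: np.ndarray, y01: np.ndarray, C: float):
    if y01.min() == y01.max():  # degenerate: class absent or universal
        return float(np.clip(y01.mean(), 1e-6, 1 - 1e-6))
    model = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
    model.fit(X, y01)
    return model


def fit_unit_ova(
    X: np.ndarray,
    labels: Sequence,
    classes: Sequence | None = None,
    C: float = 1.0,
    cv_folds: int = 0,
    Cs: Sequence[float] = (0.1, 1.0, 10.0),
    seed: int = 0,
) -> UnitDecoder:
    """One-vs-all L2 logistic classifier for one unit's binned trains.

    With ``cv_folds > 0`` the regularization strength is chosen from ``Cs``
    by stratified k-fold cross-validated accuracy of the assembled OVA
    classifier within the training data; otherwise the fixed ``C`` is used.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if classes is None:
        classes = tuple(np.unique(labels))
    else:
        classes = tuple(classes)
    present = set(np.unique(labels))
    if len(present & set(classes)) < 2:
        raise ValueError("need at least two classes present in training trials")

    if cv_folds > 0 and len(Cs) > 1:
        kf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        best_C, best_acc = Cs[0], -1.0
        for Ci in Cs:
            correct = 0
            for tr, va in kf.split(X, labels):
                models = [
                    _fit_binary(X[tr], (labels[tr] == c).astype(int), Ci)
                    for c in classes
                ]
                dec = UnitDecoder(classes=classes, models=models, C=Ci)
                pred = np.argmax(dec.predict_proba(X[va]), axis=1)
                correct += np.sum(np.array(classes)[pred] == labels[va])
            acc = correct / len(labels)
            if acc > best_acc + 1e-12:
                best_acc, best_C = acc, Ci
        C = best_C

    models = [_fit_binary(X, (labels == c).astype(int), C) for c in classes]
    return UnitDecoder(classes=classes, models=models, C=C)


def _argmax_random_ties(values: np.ndarray, rng: np.random.Generator) -> int:
    m = values.max()
    cand = np.flatnonzero(values >= m - 1e-12)
    return int(cand[0] if len(cand) == 1 else rng.choice(cand))


def predict_population(
    unit_probs: Sequence[np.ndarray], rng: np.random.Generator | None = None
):
    """Population prediction: argmax of summed per-unit class probabilities."""
    if len(unit_probs) == 0:
        raise ValueError("need at least one unit decoder output")
    rng = rng if rng is not None else np.random.default_rng(0)
    summed = np.sum(np.vstack(unit_probs), axis=0)
    return _argmax_random_ties(summed, rng), summed


@dataclass
class DecoderReport:
    """Averaged decoding outcome over repeated fit/evaluate cycles."""

    classes: tuple
    confusion: np.ndarray  # rows (true class) normalized to sum to 1
    overall_accuracy: float
    per_unit_accuracy: np.ndarray
    n_repeats: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.confusion, index=list(self.classes), columns=list(self.classes)
        )


def _stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def evaluate_stimulus_decoder(
    X: np.ndarray,
    stimulus_labels: Sequence,
    n_repeats: int = 300,
    seed: int = 0,
    train_fraction: float = 0.7,
    C: float = 1.0,
    cv_folds: int = 0,
    Cs: Sequence[float] = (0.1, 1.0, 10.0),
) -> DecoderReport:
    """Repeated-split evaluation of the four-way population stimulus decoder.

    ``X`` is the (n_units, n_trials, n_bins) count array and
    ``stimulus_labels`` the per-trial sequence names.  Each repeat draws a
    fresh stratified 70/30 split, fits every unit's OVA classifier on the
    training trials, and scores population predictions on the held-out
    trials, pairing each test event with one held-out train per unit sampled
    without replacement from the queried class.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(stimulus_labels)
    classes = tuple(np.unique(labels))
    n_units = X.shape[0]
    for c in classes:
        if np.sum(labels == c) < 2:
            raise ValueError(f"need at least two trials of class {c!r}")

    root = np.random.SeedSequence(seed)
    confusion = np.zeros((len(classes), len(classes)))
    unit_correct = np.zeros(n_units)
    unit_events = 0
    overall_num = 0.0
    overall_den = 0
    for rep_ss in root.spawn(n_repeats):
        rng = np.random.default_rng(rep_ss)
        train_idx, test_idx = _stratified_split(labels, train_fraction, rng)
        decoders = [
            fit_unit_ova(
                X[u, train_idx],
                labels[train_idx],
                classes=classes,
                C=C,
                cv_folds=cv_folds,
                Cs=Cs,
                seed=int(rng.integers(2**31 - 1)),
            )
            for u in range(n_units)
        ]
        rep_conf = np.zeros_like(confusion)
        for ci, c in enumerate(classes):
            idx_c = test_idx[labels[test_idx] == c]
            m = len(idx_c)
            if m == 0:
                continue
            summed = np.zeros((m, len(classes)))
            for u, dec in enumerate(decoders):
                perm = rng.permutation(m)  # one train per event, no replacement
                probs = dec.predict_proba(X[u, idx_c])[perm]
                summed += probs
                own = np.array(
                    [_argmax_random_ties(p, rng) for p in probs]
                )
                unit_correct[u] += np.sum(own == ci)
            preds = np.array([_argmax_random_ties(s, rng) for s in summed])
            for p in preds:
                rep_conf[ci, p] += 1.0
            overall_num += np.sum(preds == ci)
            overall_den += m
            unit_events += m
            rep_conf[ci] /= m
        confusion += rep_conf
    confusion /= n_repeats
    return DecoderReport(
        classes=classes,
        confusion=confusion,
        overall_accuracy=float(overall_num / overall_den),
        per_unit_accuracy=unit_correct / max(unit_events, 1),
        n_repeats=n_repeats,
        seed=seed,
    )


def evaluate_choice_decoder(
    X: np.ndarray,
    stimulus_labels: Sequence,
    choice_labels: Sequence,
    n_repeats: int = 300,
    seed: int = 0,
    train_fraction: float = 0.7,
    C: float = 1.0,
    cv_folds: int = 0,
    Cs: Sequence[float] = (0.1, 1.0, 10.0),
) -> dict:
    """Binary population choice decoder, evaluated separately per stimulus.

    One logistic function per unit is trained on trials of all stimuli
    pooled; accuracy is assessed per stimulus on choice-balanced held-out
    sets so that 50% is a meaningful chance level despite behavioral side
    bias.  Returns ``{"per_stimulus": {stim: DecoderReport}, "mean_accuracy":
    float}``; a stimulus whose held-out trials contain a single choice class
    is skipped.
    """
    X = np.asarray(X, dtype=float)
    stim = np.asarray(stimulus_labels)
    choice = np.asarray(choice_labels)
    classes = ("left", "right")
    if len(np.unique(choice)) < 2:
        raise ValueError("both choices must be present")
    n_units = X.shape[0]
    stim_names = tuple(np.unique(stim))
    combo = np.char.add(np.char.add(stim.astype(str), "|"), choice.astype(str))

    root = np.random.SeedSequence(seed)
    conf = {s: np.zeros((2, 2)) for s in stim_names}
    conf_n = {s: 0 for s in stim_names}
    acc_sum = {s: 0.0 for s in stim_names}
    unit_correct = np.zeros(n_units)
    unit_events = 0
    for rep_ss in root.spawn(n_repeats):
        rng = np.random.default_rng(rep_ss)
        train_idx, test_idx = _stratified_split(combo, train_fraction, rng)
        decoders = [
            fit_unit_ova(
                X[u, train_idx],
                choice[train_idx],
                classes=classes,
                C=C,
                cv_folds=cv_folds,
                Cs=Cs,
                seed=int(rng.integers(2**31 - 1)),
            )
            for u in range(n_units)
        ]
        for s in stim_names:
            held = test_idx[stim[test_idx] == s]
            idx_by_choice = [held[choice[held] == c] for c in classes]
            n_bal = min(len(i) for i in idx_by_choice)
            if n_bal == 0:
                continue
            rep_conf = np.zeros((2, 2))
            correct = 0
            for ci, idx_c in enumerate(idx_by_choice):
                sel = rng.choice(idx_c, size=n_bal, replace=False)
                summed = np.zeros((n_bal, 2))
                for u, dec in enumerate(decoders):
                    perm = rng.permutation(n_bal)
                    probs = dec.predict_proba(X[u, sel])[perm]
                    summed += probs
                    own = np.array([_argmax_random_ties(p, rng) for p in probs])
                    unit_correct[u] += np.sum(own == ci)
                preds = np.array([_argmax_random_ties(v, rng) for v in summed])
                for p in preds:
                    rep_conf[ci, p] += 1.0
                correct += np.sum(preds == ci)
                unit_events += n_bal
            conf[s] += rep_conf / n_bal
            conf_n[s] += 1
            acc_sum[s] += correct / (2 * n_bal)

    per_stim = {}
    for s in stim_names:
        if conf_n[s] == 0:
            continue
        per_stim[s] = DecoderReport(
            classes=classes,
            confusion=conf[s] / conf_n[s],
            overall_accuracy=acc_sum[s] / conf_n[s],
            per_unit_accuracy=unit_correct / max(unit_events, 1),
            n_repeats=conf_n[s],
            seed=seed,
        )
    if not per_stim:
        raise ValueError("no stimulus had both choices in held-out trials")
    mean_acc = float(np.mean([r.overall_accuracy for r in per_stim.values()]))
    return {"per_stimulus": per_stim, "mean_accuracy": mean_acc}
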