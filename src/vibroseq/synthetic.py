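"""Synthetic behavioral sessions with ground-truth spike-train structure.

This module generates trial tables and trial-aligned spike trains with the
statistical structure the downstream analyses assume, so that every stage of
the pipeline can be exercised and validated against known ground truth.

Behavioral model
    The probability of a right drink-port choice is a lapse-adjusted logistic
    function of the stimulus's mean panel speed — the integrated cue the
    animals' behavior tracks.  Nose-poke withdrawal times follow a shifted
    gamma distribution truncated at the task's minimum poke duration.

Neural model
    Each unit belongs to one of five response archetypes:

    ``Fast``
        baseline plus a brief transient after each pulse, scaled by that
        pulse's peak velocity and a per-pulse-position adaptation multiplier.
    ``Medium``
        baseline minus a broader pulse-triggered suppression.
    ``SlowPos``
        baseline plus small sustained responses to pulses 2-3 (fixed
        amplitude, not velocity-scaled) and a choice-dependent firing-rate
        ramp that begins after the second pulse and plateaus during the
        third (right-choice trials only).
    ``SlowNeg``
        baseline with a steady linear rate decline through the trial, not
        locked to pulses.
    ``Unmodulated``
        constant baseline.

    Rates are clipped at zero and spikes are drawn from an inhomogeneous
    Poisson process by thinning, at 0.1-ms resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stimulus import SequenceSpec, build_sequence, load_sequence_library, mean_speed

__all__ = [
    "UnitArchetype",
    "SessionConfig",
    "SessionData",
    "default_archetype",
    "simulate_behavior",
    "unit_rate_function",
    "simulate_unit",
    "generate_session",
    "TRIAL_EPOCH_MS",
    "RATE_DT_MS",
]

#: trial-aligned spike window relative to stimulus onset
TRIAL_EPOCH_MS = (-25.0, 250.0)
#: time resolution of rate functions and the thinning sampler
RATE_DT_MS = 0.1

#: laminar depth ranges (um), lower-closed
LAYER_DEPTHS = {
    "L2/3": (200.0, 650.0),
    "L4": (650.0, 975.0),
    "L5A": (975.0, 1285.0),
    "L5B": (1285.0, 1575.0),
    "L6": (1575.0, 2200.0),
}


@dataclass(frozen=True)
class UnitArchetype:
    """Generative parameters for one synthetic unit."""

    class_label: str  # Fast | Medium | SlowPos | SlowNeg | Unmodulated
    baseline_hz: float = 10.0
    velocity_gain: float = 0.0  # Hz per (mm/s) of pulse peak velocity
    kernel_latency_ms: float = 10.0  # transient peak time after pulse onset
    kernel_width_ms: float = 4.0  # gaussian s.d. of the transient
    adaptation_ratios: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    sustained_hz: float = 0.0  # fixed-amplitude late-pulse response (SlowPos)
    choice_gain_hz: float = 0.0  # added on right-choice trials (SlowPos)
    decay_hz_per_s: float = 0.0  # within-trial linear decline (SlowNeg)
    suppression_hz: float = 0.0  # pulse-triggered decrement (Medium)
    layer: str = "L4"
    spike_class: str = "RS"
    sort_class: str = "single"

    def __post_init__(self) -> None:
        if self.baseline_hz < 0:
            raise ValueError("baseline_hz must be non-negative")
        if self.kernel_width_ms <= 0 or self.kernel_latency_ms < 0:
            raise ValueError("kernel latency/width must be non-negative/positive")
        if len(self.adaptation_ratios) and self.adaptation_ratios[0] != 1.0:
            raise ValueError("adaptation_ratios must start at 1 for pulse 1")


# Default archetypes.  Transient gains give fast units peak evoked responses
# of tens of Hz; the Medium suppression kernel is broad (tens of ms) so its
# rate dynamics live on an intermediate time scale; slow units carry either a
# late choice ramp or a steady decline.  Typical laminar homes follow the
# observed distribution (fast/medium superficial + L5B, slow units deep).
_DEFAULTS: dict[str, UnitArchetype] = {
    "Fast": UnitArchetype(
        class_label="Fast",
        baseline_hz=8.0,
        velocity_gain=0.30,
        kernel_latency_ms=10.0,
        kernel_width_ms=3.5,
        adaptation_ratios=(1.0, 0.8, 0.7, 0.7),
        layer="L4",
    ),
    "Medium": UnitArchetype(
        class_label="Medium",
        baseline_hz=14.0,
        suppression_hz=10.0,
        kernel_latency_ms=28.0,
        kernel_width_ms=16.0,
        layer="L5B",
    ),
    "SlowPos": UnitArchetype(
        class_label="SlowPos",
        baseline_hz=10.0,
        sustained_hz=8.0,
        kernel_latency_ms=15.0,
        kernel_width_ms=10.0,
        choice_gain_hz=12.0,
        layer="L5B",
    ),
    "SlowNeg": UnitArchetype(
        class_label="SlowNeg",
        baseline_hz=16.0,
        decay_hz_per_s=50.0,
        layer="L6",
    ),
    "Unmodulated": UnitArchetype(
        class_label="Unmodulated",
        baseline_hz=10.0,
        layer="L2/3",
    ),
}

_ARCHETYPE_LAYERS = {
    "Fast": ("L2/3", "L4", "L5B"),
    "Medium": ("L4", "L5B"),
    "SlowPos": ("L5A", "L5B"),
    "SlowNeg": ("L5B", "L6"),
    "Unmodulated": ("L2/3", "L4", "L5A", "L5B", "L6"),
}


def default_archetype(class_label: str, **overrides) -> UnitArchetype:
    """A copy of the default parameterization of one archetype."""
    if class_label not in _DEFAULTS:
        raise ValueError(f"unknown archetype {class_label!r}")
    return replace(_DEFAULTS[class_label], **overrides)


@dataclass(frozen=True)
class Psychometric:
    """Lapse-adjusted logistic of mean panel speed."""

    slope: float = 0.2  # logit units per mm/s
    midpoint_mm_s: float | None = None  # None -> mean of stimulus-set speeds
    lapse: float = 0.05
    right_bias: float = 0.0  # additive logit offset

    def __post_init__(self) -> None:
        if not (0.0 <= self.lapse <= 0.5):
            raise ValueError("lapse must lie in [0, 0.5]")


@dataclass(frozen=True)
class WithdrawalModel:
    """Shifted gamma, truncated at the task's minimum nose-poke time."""

    minimum_ms: float = 150.0
    mean_ms: float = 190.0
    dispersion: float = 2.0  # gamma shape

    def __post_init__(self) -> None:
        if self.mean_ms <= self.minimum_ms:
            raise ValueError("mean withdrawal must exceed the minimum")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class SessionConfig:
    """Everything needed to generate one synthetic session."""

    stimulus_set: tuple[str, ...] = ("FFF", "FMS", "SMF", "SSS")
    n_trials_per_stimulus: int = 50
    unit_counts: tuple[tuple[str, int], ...] = (
        ("Fast", 10),
        ("Medium", 4),
        ("SlowPos", 4),
        ("SlowNeg", 3),
        ("Unmodulated", 9),
    )
    psychometric: Psychometric = field(default_factory=Psychometric)
    withdrawal: WithdrawalModel = field(default_factory=WithdrawalModel)
    seed: int = 0
    sequences: Mapping[str, SequenceSpec] | None = None  # None -> packaged library

    def __post_init__(self) -> None:
        if self.n_trials_per_stimulus <= 0:
            raise ValueError("n_trials_per_stimulus must be positive")
        for name, count in self.unit_counts:
            if count <= 0:
                raise ValueError(f"unit count for {name} must be positive")

    def resolve_sequences(self) -> dict[str, SequenceSpec]:
        lib = dict(self.sequences) if self.sequences is not None else load_sequence_library()
        return {name: lib[name] for name in self.stimulus_set}


@dataclass
class SessionData:
    """Trial table, per-unit trial-aligned spikes, and unit metadata.

    ``spikes`` has columns (unit_id, trial_id, time_ms) with times relative
    to stimulus onset and restricted to the trial epoch.  ``units`` carries
    metadata (depth, width, SNR, ISI-violation fraction, sort class) plus the
    ground-truth archetype label for synthetic sessions.
    """

    trials: pd.DataFrame
    spikes: pd.DataFrame
    units: pd.DataFrame
    epoch_ms: tuple[float, float] = TRIAL_EPOCH_MS

    def validate(self) -> None:
        need_trials = {"trial_id", "stimulus", "choice", "correct", "withdrawal_ms"}
        missing = need_trials - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        need_spikes = {"unit_id", "trial_id", "time_ms"}
        missing = need_spikes - set(self.spikes.columns)
        if missing:
            raise ValueError(f"spike table missing columns: {sorted(missing)}")
        if not self.trials["choice"].isin(["left", "right"]).all():
            raise ValueError("every trial must have a left/right choice")
        t = self.spikes["time_ms"].to_numpy()
        if len(t) and (t.min() < self.epoch_ms[0] or t.max() > self.epoch_ms[1]):
            raise ValueError("spike times outside the trial epoch")
        for _, grp in self.spikes.groupby(["unit_id", "trial_id"], sort=False):
            if not np.all(np.diff(grp["time_ms"].to_numpy()) >= 0):
                raise ValueError("spike times must be sorted within trials")
        if set(self.spikes["unit_id"]) - set(self.units["unit_id"]):
            raise ValueError("spike table references unknown units")

    def unit_ids(self) -> list:
        return list(self.units["unit_id"])

    def spikes_by_trial(self, unit_id) -> list[np.ndarray]:
        """Spike-time arrays per trial, ordered as the trial table rows."""
        sub = self.spikes[self.spikes["unit_id"] == unit_id]
        grouped = {tid: g["time_ms"].to_numpy() for tid, g in sub.groupby("trial_id")}
        empty = np.empty(0)
        return [grouped.get(tid, empty) for tid in self.trials["trial_id"]]


def _stimulus_speeds(sequences: Mapping[str, SequenceSpec]) -> dict[str, float]:
    return {
        name: mean_speed(build_sequence(spec)) for name, spec in sequences.items()
    }


def right_choice_probabilities(
    cfg: SessionConfig, sequences: Mapping[str, SequenceSpec] | None = None
) -> dict[str, float]:
    """P(right | stimulus) under the configured psychometric."""
    sequences = sequences or cfg.resolve_sequences()
    speeds = _stimulus_speeds(sequences)
    psy = cfg.psychometric
    mid = psy.midpoint_mm_s
    if mid is None:
        mid = float(np.mean(list(speeds.values())))
    out = {}
    for name, v in speeds.items():
        logit = psy.slope * (v - mid) + psy.right_bias
        p = 1.0 / (1.0 + np.exp(-logit))
        out[name] = psy.lapse + (1.0 - 2.0 * psy.lapse) * p
    return out


def simulate_behavior(
    cfg: SessionConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate the trial table: stimulus order, choices, withdrawal times."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sequences = cfg.resolve_sequences()
    p_right = right_choice_probabilities(cfg, sequences)

    stim = np.repeat(list(cfg.stimulus_set), cfg.n_trials_per_stimulus)
    rng.shuffle(stim)
    pr = np.array([p_right[s] for s in stim])
    choice = np.where(rng.uniform(size=len(stim)) < pr, "right", "left")
    reward = np.array([sequences[s].reward_side for s in stim])

    wd = cfg.withdrawal
    scale = (wd.mean_ms - wd.minimum_ms) / wd.dispersion
    withdrawal = wd.minimum_ms + rng.gamma(wd.dispersion, scale, size=len(stim))

    return pd.DataFrame(
        {
            "trial_id": np.arange(len(stim)),
            "stimulus": stim,
            "choice": choice,
            "correct": choice == reward,
            "withdrawal_ms": withdrawal,
        }
    )


def unit_rate_function(
    arch: UnitArchetype,
    seq: SequenceSpec,
    choice: str = "left",
    epoch_ms: tuple[float, float] = TRIAL_EPOCH_MS,
    dt_ms: float = RATE_DT_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Firing-rate trace lambda(t) in Hz for one archetype/stimulus/choice.

    Returns ``(t_ms, rate_hz)`` on a ``dt_ms`` grid spanning the trial epoch.
    """
    t = np.arange(epoch_ms[0], epoch_ms[1] + dt_ms / 2, dt_ms)
    lam = np.full_like(t, arch.baseline_hz)
    onsets = seq.pulse_onsets_ms
    peak_v = np.array([p.peak_velocity_mm_s for p in seq.pulses])

    def bump(center_ms: float) -> np.ndarray:
        return np.exp(-0.5 * ((t - center_ms) / arch.kernel_width_ms) ** 2)

    if arch.class_label == "Fast":
        for i, onset in enumerate(onsets):
            ratio = (
                arch.adaptation_ratios[i]
                if i < len(arch.adaptation_ratios)
                else arch.adaptation_ratios[-1]
            )
            lam += arch.velocity_gain * peak_v[i] * ratio * bump(
                onset + arch.kernel_latency_ms
            )
    elif arch.class_label == "Medium":
        for onset in onsets:
            lam -= arch.suppression_hz * bump(onset + arch.kernel_latency_ms)
    elif arch.class_label == "SlowPos":
        # weak sustained responses, absent for the first pulse and not
        # scaled by pulse velocity (slow units do not track kinematics)
        for onset in onsets[1:]:
            lam += arch.sustained_hz * bump(onset + arch.kernel_latency_ms)
        if choice == "right" and len(onsets) >= 2:
            p2 = seq.pulses[1]
            ramp_start = onsets[1] + p2.duration_ms  # offset of pulse 2
            if len(onsets) >= 3:
                plateau = onsets[2] + seq.pulses[2].duration_ms / 2.0
            else:
                plateau = ramp_start + 30.0
            ramp = np.clip((t - ramp_start) / max(plateau - ramp_start, 1e-9), 0.0, 1.0)
            lam += arch.choice_gain_hz * ramp
    elif arch.class_label == "SlowNeg":
        lam -= arch.decay_hz_per_s * np.clip(t, 0.0, None) / 1000.0
    elif arch.class_label == "Unmodulated":
        pass
    else:
        raise ValueError(f"unknown archetype {arch.class_label!r}")

    return t, np.clip(lam, 0.0, None)


def _thinning_sample(
    t: np.ndarray, lam: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One inhomogeneous-Poisson spike train by thinning; sorted times in ms."""
    lam_max = float(lam.max())
    if not np.isfinite(lam_max):
        raise ValueError("rate function must be bounded")
    if lam_max <= 0:
        return np.empty(0)
    span_s = (t[-1] - t[0]) / 1000.0
    n = rng.poisson(lam_max * span_s)
    cand = rng.uniform(t[0], t[-1], size=n)
    keep = rng.uniform(0.0, 1.0, size=n) < np.interp(cand, t, lam) / lam_max
    return np.sort(cand[keep])


def simulate_unit(
    arch: UnitArchetype,
    trials: pd.DataFrame,
    seed: int,
    sequences: Mapping[str, SequenceSpec],
    epoch_ms: tuple[float, float] = TRIAL_EPOCH_MS,
) -> pd.DataFrame:
    """Spike trains for every trial; DataFrame (trial_id, time_ms)."""
    rng = np.random.default_rng(seed)
    cache: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    rows_t, rows_s = [], []
    for tid, stim, choice in zip(
        trials["trial_id"], trials["stimulus"], trials["choice"]
    ):
        key = (stim, choice)
        if key not in cache:
            cache[key] = unit_rate_function(
                arch, sequences[stim], choice, epoch_ms=epoch_ms
            )
        t, lam = cache[key]
        times = _thinning_sample(t, lam, rng)
        rows_t.append(np.full(len(times), tid))
        rows_s.append(times)
    return pd.DataFrame(
        {
            "trial_id": np.concatenate(rows_t).astype(int) if rows_t else [],
            "time_ms": np.concatenate(rows_s) if rows_s else [],
        }
    )


def _sample_unit_metadata(
    arch: UnitArchetype, unit_id: int, rng: np.random.Generator
) -> dict:
    layer = rng.choice(_ARCHETYPE_LAYERS[arch.class_label])
    lo, hi = LAYER_DEPTHS[layer]
    depth = rng.uniform(lo, hi)
    if arch.spike_class == "FS":
        width = rng.uniform(0.15, 0.35)
    else:
        width = rng.uniform(0.45, 0.75)
    snr = float(np.exp(rng.normal(np.log(4.0), 0.3)))
    isi_violation = float(rng.uniform(0.0, 0.004))
    return {
        "unit_id": unit_id,
        "depth_um": depth,
        "width_ms": width,
        "snr": snr,
        "isi_violation": isi_violation,
        "sort_class": arch.sort_class,
        "spike_class": arch.spike_class,
        "layer": layer,
        "true_class": arch.class_label,
        "baseline_hz": arch.baseline_hz,
    }


def generate_session(cfg: SessionConfig) -> SessionData:
    """Generate a complete synthetic session with ground-truth labels.

    Per-unit baselines are drawn from a positively skewed (log-normal)
    distribution around the archetype default, mirroring the skewed firing
    rate distributions of cortical populations.
    """
    ss = np.random.SeedSequence(cfg.seed)
    behav_seed, meta_seed, *unit_seeds_pool = ss.spawn(
        2 + sum(c for _, c in cfg.unit_counts)
    )
    rng_meta = np.random.default_rng(meta_seed)
    sequences = cfg.resolve_sequences()
    trials = simulate_behavior(cfg, np.random.default_rng(behav_seed))

    unit_rows = []
    spike_frames = []
    unit_id = 0
    pool = iter(unit_seeds_pool)
    for class_label, count in cfg.unit_counts:
        proto = _DEFAULTS[class_label]
        for _ in range(count):
            baseline = float(np.exp(rng_meta.normal(np.log(proto.baseline_hz), 0.4)))
            # response gains scale with the drawn baseline so that response
            # magnitude relative to baseline is homogeneous across the
            # skewed baseline distribution
            scale = baseline / proto.baseline_hz
            arch = default_archetype(
                class_label,
                baseline_hz=baseline,
                velocity_gain=proto.velocity_gain * scale,
                sustained_hz=proto.sustained_hz * scale,
                suppression_hz=proto.suppression_hz * scale,
                choice_gain_hz=proto.choice_gain_hz * scale,
                decay_hz_per_s=proto.decay_hz_per_s * scale,
            )
            meta = _sample_unit_metadata(arch, unit_id, rng_meta)
            unit_rows.append(meta)
            child = next(pool)
            sp = simulate_unit(
                arch, trials, child.generate_state(1)[0] & 0x7FFFFFFF, sequences
            )
            sp.insert(0, "unit_id", unit_id)
            spike_frames.append(sp)
            unit_id += 1

    spikes = (
        pd.concat(spike_frames, ignore_index=True)
        if spike_frames
        else pd.DataFrame(columns=["unit_id", "trial_id", "time_ms"])
    )
    session = SessionData(
        trials=trials, spikes=spikes, units=pd.DataFrame(unit_rows)
    )
    session.validate()
    return session
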