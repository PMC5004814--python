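"""Whisker stimulus kinematics.

The stimulus panel delivers trains of brief up-down "ramp-return" deflections
(pulses).  Each pulse is parameterized by its rise time, fall time and peak
amplitude; pulses are concatenated with a fixed quiet gap between the end of
one pulse and the onset of the next.  Position ramps are modeled as raised
cosines, so velocity is smooth, peaks mid-ramp, and is zero at pulse onset and
offset.  For a raised-cosine ramp of amplitude ``A`` (mm) and rise time ``T``
(s) the peak velocity is ``pi * A / (2 * T)`` mm/s and the total travel of a
full pulse is exactly ``2 * A`` mm.

All times are milliseconds, positions millimeters, velocities mm/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PulseSpec",
    "SequenceSpec",
    "Waveform",
    "build_pulse",
    "build_sequence",
    "mean_speed",
    "integrated_speed_regressor",
    "speed_regressors",
    "load_sequence_library",
    "export_waveform_csv",
    "DEFAULT_DT_MS",
    "REGRESSION_EPOCH_MS",
    "REGRESSION_BIN_MS",
]

DEFAULT_DT_MS = 0.5
#: analysis epoch and rate-bin width used by the integration-window regression
REGRESSION_EPOCH_MS = (0.0, 180.0)
REGRESSION_BIN_MS = 5.0


@dataclass(frozen=True)
class PulseSpec:
    """One ramp-return panel deflection.

    ``nominal_peak_velocity_mm_s`` is the value quoted for the hardware
    stimulus and is informational only; the model's own peak velocity follows
    from amplitude and rise time (see :attr:`peak_velocity_mm_s`).
    """

    label: str
    rise_ms: float
    fall_ms: float
    amplitude_mm: float
    nominal_peak_velocity_mm_s: float | None = None

    def __post_init__(self) -> None:
        if self.rise_ms <= 0 or self.fall_ms <= 0:
            raise ValueError("rise_ms and fall_ms must be positive")
        if self.amplitude_mm <= 0:
            raise ValueError("amplitude_mm must be positive")

    @property
    def duration_ms(self) -> float:
        return self.rise_ms + self.fall_ms

    @property
    def peak_velocity_mm_s(self) -> float:
        """Peak |velocity| of the raised-cosine ramp, pi*A/(2*T)."""
        t_fast = min(self.rise_ms, self.fall_ms) / 1000.0
        return np.pi * self.amplitude_mm / (2.0 * t_fast)


@dataclass(frozen=True)
class SequenceSpec:
    """An ordered train of pulses with a fixed end-to-onset gap."""

    name: str
    pulses: tuple[PulseSpec, ...]
    gap_ms: float
    reward_side: str = "right"

    def __post_init__(self) -> None:
        if len(self.pulses) == 0:
            raise ValueError("a sequence needs at least one pulse")
        if self.gap_ms < 0:
            raise ValueError("gap_ms must be non-negative")
        if self.reward_side not in ("left", "right"):
            raise ValueError("reward_side must be 'left' or 'right'")
        object.__setattr__(self, "pulses", tuple(self.pulses))

    @property
    def duration_ms(self) -> float:
        """First pulse onset to last pulse offset."""
        return sum(p.duration_ms for p in self.pulses) + self.gap_ms * (
            len(self.pulses) - 1
        )

    @property
    def pulse_onsets_ms(self) -> np.ndarray:
        onsets = np.empty(len(self.pulses))
        t = 0.0
        for i, p in enumerate(self.pulses):
            onsets[i] = t
            t += p.duration_ms + self.gap_ms
        return onsets


@dataclass(frozen=True)
class Waveform:
    """Sampled panel trajectory; samples at ``t0_ms + i * dt_ms``."""

    dt_ms: float
    position_mm: np.ndarray
    velocity_mm_s: np.ndarray
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        if len(self.position_mm) != len(self.velocity_mm_s):
            raise ValueError("position and velocity must have equal length")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + self.dt_ms * np.arange(len(self.position_mm))

    @property
    def duration_ms(self) -> float:
        return self.dt_ms * (len(self.position_mm) - 1)


def _n_samples(interval_ms: float, dt_ms: float) -> int:
    n = interval_ms / dt_ms
    n_round = round(n)
    if abs(n - n_round) > 1e-9 or n_round < 1:
        raise ValueError(
            f"dt_ms={dt_ms} does not evenly divide interval of {interval_ms} ms"
        )
    return int(n_round)


def build_pulse(spec: PulseSpec, dt_ms: float = DEFAULT_DT_MS) -> Waveform:
    """Sample one raised-cosine ramp-return pulse on a ``dt_ms`` grid.

    ``dt_ms`` must evenly divide both the rise and the fall time so that the
    ramp endpoints fall on grid samples.
    """
    n_rise = _n_samples(spec.rise_ms, dt_ms)
    n_fall = _n_samples(spec.fall_ms, dt_ms)
    a = spec.amplitude_mm

    t_up = np.arange(n_rise + 1) * dt_ms
    pos_up = a / 2.0 * (1.0 - np.cos(np.pi * t_up / spec.rise_ms))
    # velocity in mm/s: d/dt of the ramp with T in seconds
    vel_up = (
        a * np.pi / (2.0 * spec.rise_ms / 1000.0) * np.sin(np.pi * t_up / spec.rise_ms)
    )

    t_dn = np.arange(1, n_fall + 1) * dt_ms
    pos_dn = a / 2.0 * (1.0 + np.cos(np.pi * t_dn / spec.fall_ms))
    vel_dn = (
        -a * np.pi / (2.0 * spec.fall_ms / 1000.0) * np.sin(np.pi * t_dn / spec.fall_ms)
    )

    pos = np.concatenate([pos_up, pos_dn])
    vel = np.concatenate([vel_up, vel_dn])
    pos[0] = pos[-1] = 0.0
    return Waveform(dt_ms=dt_ms, position_mm=pos, velocity_mm_s=vel)


def build_sequence(spec: SequenceSpec, dt_ms: float = DEFAULT_DT_MS) -> Waveform:
    """Concatenate the pulses of a sequence with quiet gaps between them."""
    if spec.gap_ms > 0:
        _n_samples(spec.gap_ms, dt_ms)  # grid check
    total = spec.duration_ms
    n_total = _n_samples(total, dt_ms)
    pos = np.zeros(n_total + 1)
    vel = np.zeros(n_total + 1)
    for onset, pulse in zip(spec.pulse_onsets_ms, spec.pulses):
        w = build_pulse(pulse, dt_ms)
        i0 = _n_samples(onset, dt_ms) if onset > 0 else 0
        pos[i0 : i0 + len(w.position_mm)] = w.position_mm
        vel[i0 : i0 + len(w.position_mm)] = w.velocity_mm_s
    return Waveform(dt_ms=dt_ms, position_mm=pos, velocity_mm_s=vel)


def _speed_integral_mm(w: Waveform, start_ms: float, stop_ms: float) -> float:
    """Integral of |velocity| over [start, stop], zero-padded outside support."""
    t = w.times_ms
    speed = np.abs(w.velocity_mm_s)
    cum = np.concatenate([[0.0], np.cumsum((speed[1:] + speed[:-1]) / 2.0 * w.dt_ms)])
    lo = float(np.interp(start_ms, t, cum, left=0.0, right=cum[-1]))
    hi = float(np.interp(stop_ms, t, cum, left=0.0, right=cum[-1]))
    return (hi - lo) / 1000.0  # mm/s * ms -> mm


def mean_speed(w: Waveform, window_ms: tuple[float, float] | None = None) -> float:
    """Time-averaged |panel velocity| in mm/s over ``window_ms``.

    With ``window_ms=None`` the average runs over the waveform's own support
    (first to last sample).  The waveform is treated as motionless outside its
    support, so a window extending past it dilutes the average.
    """
    if window_ms is None:
        window_ms = (float(w.times_ms[0]), float(w.times_ms[-1]))
    start, stop = window_ms
    if stop <= start:
        raise ValueError("mean_speed window must have positive length")
    travel_mm = _speed_integral_mm(w, start, stop)
    return travel_mm / ((stop - start) / 1000.0)


def integrated_speed_regressor(
    w: Waveform,
    window_W_ms: float,
    bin_ms: float = REGRESSION_BIN_MS,
    epoch_ms: tuple[float, float] = REGRESSION_EPOCH_MS,
) -> np.ndarray:
    """Trailing-window integrated panel speed, one value per rate bin.

    The value for the rate bin ``[t, t + bin_ms)`` is the integral of |panel
    velocity| (in mm of travel) over the preceding window ``[t - W, t)``,
    zero-padding panel speed before sequence onset.  ``window_W_ms`` must lie
    on the 5-ms grid from 5 to 180 ms.
    """
    if window_W_ms < 5.0 or window_W_ms > 180.0 or (window_W_ms % 5.0) != 0.0:
        raise ValueError("integration window must be on the 5-ms grid in [5, 180]")
    starts = np.arange(epoch_ms[0], epoch_ms[1], bin_ms)
    return np.array(
        [_speed_integral_mm(w, t - window_W_ms, t) for t in starts]
    )


def speed_regressors(
    w: Waveform,
    windows_ms: Sequence[float] = tuple(range(5, 185, 5)),
    bin_ms: float = REGRESSION_BIN_MS,
    epoch_ms: tuple[float, float] = REGRESSION_EPOCH_MS,
) -> dict[float, np.ndarray]:
    """Regressors for all integration windows of one waveform."""
    return {
        float(W): integrated_speed_regressor(w, W, bin_ms=bin_ms, epoch_ms=epoch_ms)
        for W in windows_ms
    }


def load_sequence_library(path: str | None = None) -> dict[str, SequenceSpec]:
    """Load the stimulus library (packaged YAML by default).

    The packaged library contains the three-pulse discrimination set
    (FFF/FMS/SMF/SSS) and the four-pulse FSFS/SFFS set, including the
    amplitude-rescaled "different-intensity" variants of the latter.
    """
    if path is None:
        text = (
            resources.files("vibroseq").joinpath("data/sequences.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    pulses = {
        name: PulseSpec(label=name, **params) for name, params in raw["pulses"].items()
    }
    library: dict[str, SequenceSpec] = {}
    for name, entry in raw["sequences"].items():
        scale = entry.get("amplitude_scale", 1.0)
        seq_pulses = []
        for lbl in entry["pulses"]:
            p = pulses[lbl]
            if scale != 1.0:
                p = PulseSpec(
                    label=p.label,
                    rise_ms=p.rise_ms,
                    fall_ms=p.fall_ms,
                    amplitude_mm=p.amplitude_mm * scale,
                    nominal_peak_velocity_mm_s=None,
                )
            seq_pulses.append(p)
        library[name] = SequenceSpec(
            name=name,
            pulses=tuple(seq_pulses),
            gap_ms=entry["gap_ms"],
            reward_side=entry["reward_side"],
        )
    return library


def export_waveform_csv(w: Waveform, path: str) -> None:
    """Write a waveform as two-column CSV (time_ms, position_mm)."""
    arr = np.column_stack([w.times_ms, w.position_mm])
    np.savetxt(path, arr, delimiter=",", header="time_ms,position_mm", comments="")
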