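"""PSTHs, temporal-modulation testing, evoked-response and choice analyses.

The temporal-modulation test compares the observed binned firing rate during
the stimulus epoch against spike trains whose spike times are randomly
re-drawn uniformly within the epoch (preserving per-trial spike counts while
destroying all timing).  The test statistic is the sum over bins of squared
deviations of the trial-averaged rate from the epoch-mean rate.  Because the
re-drawn times are i.i.d. uniform, the pooled null bin counts are
multinomial, which is how the null distribution is sampled.  p-values use
the add-one rule p = (1 + #{null >= observed}) / (1 + n_perm), so the test
is valid (never anti-conservative) at any permutation count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PSTH",
    "EvokedResponse",
    "compute_psth",
    "temporal_modulation_test",
    "evoked_response",
    "adaptation_ratio",
    "adaptation_summary",
    "choice_bias",
    "divergence_time",
    "window_rate",
]

MODULATION_EPOCH_MS = (0.0, 180.0)
MODULATION_BIN_MS = 10.0


@dataclass(frozen=True)
class PSTH:
    """Trial-averaged firing rate on a fixed bin grid."""

    bin_edges_ms: np.ndarray
    rate_hz: np.ndarray
    n_trials: int
    smoothing_ms: float = 0.0

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:]) / 2.0

    @property
    def bin_ms(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0])


@dataclass(frozen=True)
class EvokedResponse:
    """Impulse-evoked response metrics for one unit and pulse."""

    baseline_hz: float
    peak_modulation_hz: float  # signed extremal deviation from baseline
    peak_latency_ms: float  # time of the extremum relative to pulse onset
    mean_evoked_hz: float  # 5-35 ms window rate minus baseline
    significant: bool
    p_value: float


def compute_psth(
    trial_spikes: Sequence[np.ndarray],
    epoch_ms: tuple[float, float] = (-25.0, 250.0),
    bin_ms: float = 1.0,
    smoothing_ms: float = 0.0,
) -> PSTH:
    """PSTH from per-trial spike-time arrays.

    Smoothing is a unit-mass boxcar applied to the binned rate (for display;
    it preserves the rate integral away from the epoch edges).
    """
    if len(trial_spikes) == 0:
        raise ValueError("need at least one trial")
    edges = np.arange(epoch_ms[0], epoch_ms[1] + bin_ms / 2, bin_ms)
    counts = np.zeros(len(edges) - 1)
    for times in trial_spikes:
        counts += np.histogram(times, bins=edges)[0]
    rate = counts / (len(trial_spikes) * bin_ms / 1000.0)
    if smoothing_ms > 0:
        k = max(int(round(smoothing_ms / bin_ms)), 1)
        rate = np.convolve(rate, np.ones(k) / k, mode="same")
    return PSTH(
        bin_edges_ms=edges,
        rate_hz=rate,
        n_trials=len(trial_spikes),
        smoothing_ms=smoothing_ms,
    )


def _modulation_statistic(counts: np.ndarray, n_trials: int, bin_ms: float) -> float:
    rate = counts / (n_trials * bin_ms / 1000.0)
    return float(np.sum((rate - rate.mean()) ** 2))


def temporal_modulation_test(
    trial_spikes: Sequence[np.ndarray],
    epoch_ms: tuple[float, float] = MODULATION_EPOCH_MS,
    bin_ms: float = MODULATION_BIN_MS,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for temporal modulation of the firing rate.

    Returns 1.0 for units with no spikes in the epoch.  A unit is considered
    temporally modulated when p < 0.05.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    edges = np.arange(epoch_ms[0], epoch_ms[1] + bin_ms / 2, bin_ms)
    n_bins = len(edges) - 1
    n_trials = len(trial_spikes)
    counts = np.zeros(n_bins)
    total = 0
    for times in trial_spikes:
        inside = times[(times >= epoch_ms[0]) & (times < epoch_ms[1])]
        counts += np.histogram(inside, bins=edges)[0]
        total += len(inside)
    if total == 0:
        return 1.0
    observed = _modulation_statistic(counts, n_trials, bin_ms)
    # uniform re-draw of each spike's time => pooled null counts multinomial
    null_counts = rng.multinomial(total, np.full(n_bins, 1.0 / n_bins), size=n_perm)
    scale = 1.0 / (n_trials * bin_ms / 1000.0)
    null_rates = null_counts * scale
    null_stats = np.sum(
        (null_rates - null_rates.mean(axis=1, keepdims=True)) ** 2, axis=1
    )
    return float((1 + np.sum(null_stats >= observed)) / (1 + n_perm))


def window_rate(
    trial_spikes: Sequence[np.ndarray], window_ms: tuple[float, float]
) -> np.ndarray:
    """Per-trial firing rate (Hz) in a window."""
    lo, hi = window_ms
    span_s = (hi - lo) / 1000.0
    return np.array(
        [np.sum((t >= lo) & (t < hi)) / span_s for t in trial_spikes]
    )


def evoked_response(
    trial_spikes: Sequence[np.ndarray],
    pulse_onset_ms: float,
    epoch_ms: tuple[float, float] = (-25.0, 250.0),
    smoothing_ms: float = 10.0,
    search_ms: float = 40.0,
) -> EvokedResponse:
    """Impulse-evoked response metrics relative to a pulse onset.

    Baseline is the mean rate 0-10 ms before pulse onset.  The peak
    modulation is the extremal deviation (max or min, whichever is larger in
    magnitude) of the boxcar-smoothed 1-ms PSTH within ``search_ms`` after
    onset; its time is the peak latency.  Mean evoked rate is measured 5-35
    ms after onset, minus baseline; significance is a paired t-test of the
    per-trial evoked-window versus baseline-window rates.
    """
    if pulse_onset_ms - 10.0 < epoch_ms[0] or pulse_onset_ms + search_ms > epoch_ms[1]:
        raise ValueError("analysis windows fall outside the trial epoch")
    psth = compute_psth(trial_spikes, epoch_ms, bin_ms=1.0, smoothing_ms=smoothing_ms)
    centers = psth.bin_centers_ms
    base_mask = (centers >= pulse_onset_ms - 10.0) & (centers < pulse_onset_ms)
    baseline = float(psth.rate_hz[base_mask].mean())
    search = (centers >= pulse_onset_ms) & (centers < pulse_onset_ms + search_ms)
    dev = psth.rate_hz[search] - baseline
    i_ext = int(np.argmax(np.abs(dev)))
    peak_mod = float(dev[i_ext])
    latency = float(centers[search][i_ext] - pulse_onset_ms)

    base_rates = window_rate(trial_spikes, (pulse_onset_ms - 10.0, pulse_onset_ms))
    ev_rates = window_rate(
        trial_spikes, (pulse_onset_ms + 5.0, pulse_onset_ms + 35.0)
    )
    mean_evoked = float(ev_rates.mean() - base_rates.mean())
    diffs = ev_rates - base_rates
    if np.allclose(diffs, diffs[0]):
        p = 1.0
    else:
        p = float(stats.ttest_rel(ev_rates, base_rates).pvalue)
    return EvokedResponse(
        baseline_hz=baseline,
        peak_modulation_hz=peak_mod,
        peak_latency_ms=latency,
        mean_evoked_hz=mean_evoked,
        significant=p < 0.05,
        p_value=p,
    )


def adaptation_ratio(evoked_by_pulse: Sequence[float]) -> np.ndarray | None:
    """Per-pulse adaptation ratios: evoked rate to pulse N over pulse 1.

    Returns ``None`` when the pulse-1 evoked rate is non-positive (the unit
    is excluded from population adaptation summaries).
    """
    ev = np.asarray(evoked_by_pulse, dtype=float)
    if len(ev) < 2:
        raise ValueError("need evoked rates for at least two pulses")
    if ev[0] <= 0:
        return None
    return ev[1:] / ev[0]


def adaptation_summary(
    per_unit_evoked: Sequence[Sequence[float]],
) -> pd.DataFrame:
    """Population mean +/- SEM of adaptation ratios across units."""
    ratios = [adaptation_ratio(ev) for ev in per_unit_evoked]
    ratios = [r for r in ratios if r is not None]
    if not ratios:
        raise ValueError("no units with positive pulse-1 response")
    mat = np.vstack(ratios)
    return pd.DataFrame(
        {
            "pulse": np.arange(2, mat.shape[1] + 2),
            "ratio_mean": mat.mean(axis=0),
            "ratio_sem": stats.sem(mat, axis=0),
            "n_units": mat.shape[0],
        }
    )


def choice_bias(
    per_unit_trial_spikes: Sequence[Sequence[np.ndarray]],
    choices: Sequence[str],
    final_pulse_onset_ms: float,
    window_ms: tuple[float, float] = (5.0, 50.0),
    baseline_window_ms: tuple[float, float] = (-25.0, 0.0),
) -> dict:
    """Right-minus-left choice bias in firing rate across units.

    For each unit the bias is its mean rate in ``window_ms`` after the final
    pulse onset on right-choice trials minus left-choice trials.  Population
    significance is a paired t-test across units; the same statistic on a
    pre-sequence baseline window serves as the control comparison.  Units
    lacking either choice class are skipped.
    """
    choices = np.asarray(choices)
    right = choices == "right"
    left = choices == "left"
    if not right.any() or not left.any():
        raise ValueError("both choices must be present")
    lo = final_pulse_onset_ms + window_ms[0]
    hi = final_pulse_onset_ms + window_ms[1]
    bias, base_bias = [], []
    for trial_spikes in per_unit_trial_spikes:
        rates = window_rate(trial_spikes, (lo, hi))
        base = window_rate(trial_spikes, baseline_window_ms)
        bias.append(rates[right].mean() - rates[left].mean())
        base_bias.append(base[right].mean() - base[left].mean())
    bias_arr = np.array(bias)
    base_arr = np.array(base_bias)

    def _p(arr: np.ndarray) -> float:
        if len(arr) < 2 or np.allclose(arr, arr[0]):
            return 1.0
        return float(stats.ttest_1samp(arr, 0.0).pvalue)

    return {
        "per_unit_bias_hz": bias_arr,
        "mean_bias_hz": float(bias_arr.mean()),
        "p_value": _p(bias_arr),
        "baseline_mean_bias_hz": float(base_arr.mean()),
        "baseline_p_value": _p(base_arr),
    }


def divergence_time(
    rates_right: np.ndarray,
    rates_left: np.ndarray,
    bin_ms: float = 1.0,
    t0_ms: float = 0.0,
    window_ms: float = 10.0,
    step_ms: float = 5.0,
    alpha: float = 0.05,
    persistence: int = 3,
) -> float | None:
    """Earliest sustained right/left PSTH divergence by sliding paired t-test.

    ``rates_right``/``rates_left`` are (n_units, n_bins) PSTH matrices on a
    common grid starting at ``t0_ms``.  A sliding window of ``window_ms``
    advances by ``step_ms``; at each position the windowed mean rates are
    compared across units by paired t-test.  The divergence time is the start
    of the earliest window from which p < alpha holds for ``persistence``
    consecutive windows; ``None`` if no such run exists.
    """
    rates_right = np.atleast_2d(rates_right)
    rates_left = np.atleast_2d(rates_left)
    if rates_right.shape != rates_left.shape or rates_right.shape[0] < 2:
        raise ValueError("need matched PSTH matrices for at least two units")
    n_bins = rates_right.shape[1]
    w = max(int(round(window_ms / bin_ms)), 1)
    s = max(int(round(step_ms / bin_ms)), 1)
    starts = list(range(0, n_bins - w + 1, s))
    pvals = []
    for i in starts:
        r = rates_right[:, i : i + w].mean(axis=1)
        l = rates_left[:, i : i + w].mean(axis=1)
        if np.allclose(r - l, (r - l)[0]) and np.isclose((r - l)[0], 0.0):
            pvals.append(1.0)
        else:
            res = stats.ttest_rel(r, l)
            pvals.append(1.0 if np.isnan(res.pvalue) else float(res.pvalue))
    sig = np.array(pvals) < alpha
    run = 0
    for idx, flag in enumerate(sig):
        run = run + 1 if flag else 0
        if run >= persistence:
            first = idx - persistence + 1
            return t0_ms + starts[first] * bin_ms
    return None
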