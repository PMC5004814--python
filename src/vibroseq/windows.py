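"""Integration-window regression and unit time-scale classification.

For each unit, the trial-averaged firing rate in 5-ms bins over the 0-180 ms
stimulus epoch (stacked across the four sequences: 4 x 36 = 144 observations)
is regressed on the panel speed integrated over a trailing window W, for W on
the 5-ms grid from 5 to 180 ms (36 regressions).  Windows whose ordinary
least-squares fit is significant after Bonferroni correction (p < 0.05/36 =
0.0014) are candidates; the best window is the candidate with the highest
R^2.  Units are classed by best window and slope sign:

* Fast: best W in 5-20 ms
* Medium: best W in 25-50 ms
* Slow: best W in 55-180 ms, split into SlowPos / SlowNeg by slope sign
* Unclassified: no significant window
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .stimulus import (
    REGRESSION_BIN_MS,
    REGRESSION_EPOCH_MS,
    SequenceSpec,
    Waveform,
    build_sequence,
    speed_regressors,
)

__all__ = [
    "WINDOWS_MS",
    "ALPHA_FAMILY",
    "WindowRegressionResult",
    "fit_window_regressions",
    "select_best_window",
    "classify_unit",
    "classify_session",
    "binned_rates_by_stimulus",
]

WINDOWS_MS = tuple(float(w) for w in range(5, 185, 5))
ALPHA_FAMILY = 0.05

#: class boundaries on the best integration window (ms); the 55-ms window
#: belongs to the Slow range (configurable via classify_unit)
FAST_RANGE = (5.0, 20.0)
MEDIUM_RANGE = (25.0, 50.0)
SLOW_RANGE = (55.0, 180.0)


@dataclass
class WindowRegressionResult:
    """Per-window OLS outcomes and the derived classification for one unit."""

    table: pd.DataFrame  # columns: window_ms, slope, intercept, r2, p, valid
    best_window_ms: float | None = None
    slope_sign: int | None = None
    unit_class: str = "Unclassified"


def fit_window_regressions(
    rates_by_stimulus: Mapping[str, np.ndarray],
    regressors: Mapping[str, Mapping[float, np.ndarray]],
    windows_ms: Sequence[float] = WINDOWS_MS,
) -> WindowRegressionResult:
    """OLS of stacked 5-ms firing rates on integrated speed, per window.

    ``rates_by_stimulus`` maps sequence name to the unit's 36-bin
    trial-averaged rate; ``regressors`` maps sequence name to the per-window
    integrated-speed regressors (see :func:`vibroseq.stimulus.speed_regressors`).
    Slopes are in Hz per mm of integrated panel travel.  A window whose
    regressor is constant (no panel motion) is marked invalid.
    """
    stims = sorted(rates_by_stimulus)
    y = np.concatenate([np.asarray(rates_by_stimulus[s], dtype=float) for s in stims])
    rows = []
    for W in windows_ms:
        x = np.concatenate([np.asarray(regressors[s][W], dtype=float) for s in stims])
        if len(x) != len(y):
            raise ValueError("regressor and rate lengths differ")
        if np.ptp(x) == 0.0:
            rows.append(
                dict(window_ms=W, slope=np.nan, intercept=np.nan, r2=np.nan,
                     p=np.nan, valid=False)
            )
            continue
        fit = stats.linregress(x, y)
        rows.append(
            dict(
                window_ms=W,
                slope=fit.slope,
                intercept=fit.intercept,
                r2=fit.rvalue**2,
                p=fit.pvalue,
                valid=True,
            )
        )
    return WindowRegressionResult(table=pd.DataFrame(rows))


def select_best_window(
    result: WindowRegressionResult, alpha_family: float = ALPHA_FAMILY
) -> float | None:
    """Best integration window: max R^2 among Bonferroni-significant fits.

    The per-window threshold is ``alpha_family / n_windows`` (0.05/36 =
    0.0014 on the default grid).  Ties in R^2 break toward the smallest
    window.  Returns None when no window is significant.
    """
    tab = result.table
    n = len(tab)
    cand = tab[tab["valid"] & (tab["p"] < alpha_family / n)]
    if cand.empty:
        return None
    best_r2 = cand["r2"].max()
    # tie-break toward the smallest window at machine precision
    ties = cand[np.isclose(cand["r2"], best_r2, rtol=0.0, atol=1e-12)]
    return float(ties["window_ms"].min())


def classify_unit(
    best_window_ms: float | None,
    slope_sign: int | None,
    fast_range: tuple[float, float] = FAST_RANGE,
    medium_range: tuple[float, float] = MEDIUM_RANGE,
    slow_range: tuple[float, float] = SLOW_RANGE,
) -> str:
    """Fast/Medium/SlowPos/SlowNeg class from best window and slope sign."""
    if best_window_ms is None:
        return "Unclassified"
    w = best_window_ms
    if fast_range[0] <= w <= fast_range[1]:
        return "Fast"
    if medium_range[0] <= w <= medium_range[1]:
        return "Medium"
    if slow_range[0] <= w <= slow_range[1]:
        return "SlowPos" if (slope_sign or 0) > 0 else "SlowNeg"
    return "Unclassified"


def binned_rates_by_stimulus(
    session,
    unit_id,
    bin_ms: float = REGRESSION_BIN_MS,
    epoch_ms: tuple[float, float] = REGRESSION_EPOCH_MS,
) -> dict[str, np.ndarray]:
    """Trial-averaged rate in 5-ms bins over the epoch, per stimulus."""
    edges = np.arange(epoch_ms[0], epoch_ms[1] + bin_ms / 2, bin_ms)
    trial_spikes = session.spikes_by_trial(unit_id)
    stim = session.trials["stimulus"].to_numpy()
    out = {}
    for s in np.unique(stim):
        idx = np.flatnonzero(stim == s)
        counts = np.zeros(len(edges) - 1)
        for i in idx:
            counts += np.histogram(trial_spikes[i], bins=edges)[0]
        out[s] = counts / (len(idx) * bin_ms / 1000.0)
    return out


def classify_session(
    session,
    sequences: Mapping[str, SequenceSpec],
    alpha_family: float = ALPHA_FAMILY,
    windows_ms: Sequence[float] = WINDOWS_MS,
    unit_ids: Sequence | None = None,
) -> pd.DataFrame:
    """Per-unit window regression and classification for a whole session.

    Returns a table with unit_id, best_window_ms, slope, r2, p and
    unit_class; the per-window regressors are computed once per stimulus.
    ``unit_ids`` restricts the analysis (typically to temporally modulated
    units); default is every unit in the session.
    """
    regressors = {
        name: speed_regressors(build_sequence(spec), windows_ms)
        for name, spec in sequences.items()
    }
    rows = []
    for unit_id in (unit_ids if unit_ids is not None else session.unit_ids()):
        rates = binned_rates_by_stimulus(session, unit_id)
        res = fit_window_regressions(rates, regressors, windows_ms)
        best = select_best_window(res, alpha_family)
        if best is None:
            rows.append(
                dict(unit_id=unit_id, best_window_ms=np.nan, slope=np.nan,
                     r2=np.nan, p=np.nan, unit_class="Unclassified")
            )
            continue
        row = res.table[res.table["window_ms"] == best].iloc[0]
        sign = 1 if row["slope"] > 0 else -1
        rows.append(
            dict(
                unit_id=unit_id,
                best_window_ms=best,
                slope=row["slope"],
                r2=row["r2"],
                p=row["p"],
                unit_class=classify_unit(best, sign),
            )
        )
    return pd.DataFrame(rows)
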