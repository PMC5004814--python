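"""Behavioral summaries: choice fractions, d-prime, and proportion tests.

Relative right choice — the fraction of right drink-port choices for each
stimulus minus the unweighted mean fraction across stimuli — removes
individual side bias before relating behavior to stimulus mean speed.
Discriminability between the extreme stimuli is summarized by the
equal-variance signal-detection index d' = z(hit) - z(false alarm), with
extreme rates clipped to [1/(2n), 1 - 1/(2n)] before the normal quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportions_ztest

__all__ = [
    "BehaviorSummary",
    "summarize_behavior",
    "dprime",
    "fms_smf_proportion_test",
    "simple_discrimination",
    "fixed_panel_comparison",
]


@dataclass
class BehaviorSummary:
    """Per-stimulus choice statistics and the derived discrimination measures."""

    per_stimulus: pd.DataFrame  # stimulus, n_trials, n_right, fraction_right
    relative_right: dict[str, float]
    dprime: float | None = None  # FFF-vs-SSS (or FSFS-vs-SFFS) discriminability
    fms_smf_p: float | None = None
    simple_discrimination: float | None = None


def _fractions(trials: pd.DataFrame) -> pd.DataFrame:
    grp = trials.groupby("stimulus", sort=True)
    out = grp.agg(
        n_trials=("choice", "size"),
        n_right=("choice", lambda c: int((c == "right").sum())),
    ).reset_index()
    out["fraction_right"] = out["n_right"] / out["n_trials"]
    return out


def dprime(hit_rate: float, fa_rate: float, n_hit: int, n_fa: int) -> float:
    """Signal-detection d' with 1/(2n) extreme-rate correction."""
    if n_hit <= 0 or n_fa <= 0:
        raise ValueError("trial counts must be positive")
    h = float(np.clip(hit_rate, 1.0 / (2 * n_hit), 1.0 - 1.0 / (2 * n_hit)))
    f = float(np.clip(fa_rate, 1.0 / (2 * n_fa), 1.0 - 1.0 / (2 * n_fa)))
    return float(norm.ppf(h) - norm.ppf(f))


def fms_smf_proportion_test(
    trials: pd.DataFrame,
    n_comparisons: int = 8,
    pair: tuple[str, str] = ("FMS", "SMF"),
) -> tuple[float, bool]:
    """Two-sample proportion z-test of right-choice fractions for a pair.

    Significance uses the Bonferroni-corrected threshold
    ``0.05 / n_comparisons`` (0.00625 for the default eight comparisons, one
    per animal).  Returns ``(p, significant)``.
    """
    counts, nobs = [], []
    for s in pair:
        sub = trials[trials["stimulus"] == s]
        if len(sub) == 0:
            raise ValueError(f"no trials for stimulus {s!r}")
        counts.append(int((sub["choice"] == "right").sum()))
        nobs.append(len(sub))
    if counts[0] * nobs[1] == counts[1] * nobs[0]:  # identical fractions
        return 1.0, False
    _, p = proportions_ztest(counts, nobs)
    return float(p), bool(p < 0.05 / n_comparisons)


def simple_discrimination(
    trials: pd.DataFrame, pair: tuple[str, str] = ("FFF", "SSS")
) -> float:
    """Fraction right for the first stimulus minus fraction right for the second."""
    frac = _fractions(trials).set_index("stimulus")["fraction_right"]
    return float(frac[pair[0]] - frac[pair[1]])


def fixed_panel_comparison(
    normal_trials: pd.DataFrame,
    fixed_trials: pd.DataFrame,
    pair: tuple[str, str] = ("FFF", "SSS"),
) -> dict[str, float]:
    """Simple-difference discrimination in two condition blocks.

    Intended for the moving-panel versus fixed-panel comparison: the measure
    is (fraction right to the first stimulus) - (fraction right to the
    second) in each block, plus their difference.
    """
    d_normal = simple_discrimination(normal_trials, pair)
    d_fixed = simple_discrimination(fixed_trials, pair)
    return {
        "normal": d_normal,
        "fixed": d_fixed,
        "impairment": d_normal - d_fixed,
    }


def summarize_behavior(
    trials: pd.DataFrame,
    dprime_pair: tuple[str, str] = ("FFF", "SSS"),
    fms_smf_pair: tuple[str, str] = ("FMS", "SMF"),
    n_comparisons: int = 8,
) -> BehaviorSummary:
    """Per-stimulus choice fractions plus the derived summary measures.

    Measures needing stimuli absent from the session are left ``None``.
    """
    per_stim = _fractions(trials)
    mean_right = per_stim["fraction_right"].mean()
    relative = {
        row.stimulus: float(row.fraction_right - mean_right)
        for row in per_stim.itertuples()
    }
    have = set(per_stim["stimulus"])

    d = None
    simple = None
    if set(dprime_pair) <= have:
        idx = per_stim.set_index("stimulus")
        d = dprime(
            idx.loc[dprime_pair[0], "fraction_right"],
            idx.loc[dprime_pair[1], "fraction_right"],
            int(idx.loc[dprime_pair[0], "n_trials"]),
            int(idx.loc[dprime_pair[1], "n_trials"]),
        )
        simple = simple_discrimination(trials, dprime_pair)
    p = None
    if set(fms_smf_pair) <= have:
        p, _ = fms_smf_proportion_test(trials, n_comparisons, fms_smf_pair)
    return BehaviorSummary(
        per_stimulus=per_stim,
        relative_right=relative,
        dprime=d,
        fms_smf_p=p,
        simple_discrimination=simple,
    )
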