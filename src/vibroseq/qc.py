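"""Post-sorting unit inclusion and classification criteria.

Single-unit eligibility requires an inter-spike-interval criterion (fewer
than 0.5% of consecutive intervals under 1.5 ms) and a spike-height
signal-to-noise ratio above 2.  Units are split into fast-spiking (FS) and
regular-spiking (RS) classes by waveform trough-to-peak width, and assigned
to cortical layers by recording depth.  All thresholds are applied as strict
inequalities; laminar bins are half-open, lower-closed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ISI_THRESHOLD_MS",
    "ISI_MAX_FRACTION",
    "FS_WIDTH_MS",
    "SNR_MIN",
    "LAYER_BOUNDS_UM",
    "isi_violation_fraction",
    "classify_rs_fs",
    "assign_layer",
    "snr",
    "qc_unit",
    "qc_report",
]

ISI_THRESHOLD_MS = 1.5
ISI_MAX_FRACTION = 0.005
FS_WIDTH_MS = 0.375
SNR_MIN = 2.0

#: half-open [lower, upper) depth bins in um
LAYER_BOUNDS_UM = (
    ("L2/3", 200.0, 650.0),
    ("L4", 650.0, 975.0),
    ("L5A", 975.0, 1285.0),
    ("L5B", 1285.0, 1575.0),
    ("L6", 1575.0, 2200.0),
)


def isi_violation_fraction(spike_times_ms: np.ndarray) -> float:
    """Fraction of consecutive inter-spike intervals below 1.5 ms.

    ``spike_times_ms`` is the pooled, sorted spike train of one unit.
    Raises on fewer than two spikes (the fraction is undefined; such units
    are treated as multi-unit clusters by the caller).
    """
    times = np.asarray(spike_times_ms, dtype=float)
    if times.size < 2:
        raise ValueError("need at least two spikes to compute ISI violations")
    isis = np.diff(times)
    return float(np.mean(isis < ISI_THRESHOLD_MS))


def classify_rs_fs(width_ms: float) -> str:
    """FS iff trough-to-peak width is strictly below 0.375 ms, else RS."""
    if width_ms <= 0:
        raise ValueError("waveform width must be positive")
    return "FS" if width_ms < FS_WIDTH_MS else "RS"


def assign_layer(depth_um: float) -> str:
    """Laminar label for a recording depth; 'out' outside 200-2200 um."""
    if depth_um < 0:
        raise ValueError("depth must be non-negative")
    for layer, lo, hi in LAYER_BOUNDS_UM:
        if lo <= depth_um < hi:
            return layer
    return "out"


def snr(trough_to_peak: float, mean_noise_sd: float) -> float:
    """Spike height divided by mean noise standard deviation."""
    if mean_noise_sd <= 0:
        raise ValueError("mean noise s.d. must be positive")
    return trough_to_peak / mean_noise_sd


def qc_unit(
    isi_fraction: float | None, snr_value: float, width_ms: float, depth_um: float
) -> dict:
    """QC verdict for one unit; pure function of its metadata.

    ``isi_fraction=None`` (undefined, e.g. too few spikes) forces the
    multi-unit verdict.
    """
    isi_pass = isi_fraction is not None and isi_fraction < ISI_MAX_FRACTION
    snr_pass = snr_value > SNR_MIN
    verdict = "single" if (isi_pass and snr_pass) else "multi"
    reasons = []
    if not isi_pass:
        reasons.append("isi")
    if not snr_pass:
        reasons.append("snr")
    return {
        "isi_pass": isi_pass,
        "snr_pass": snr_pass,
        "verdict": verdict,
        "reasons": ",".join(reasons),
        "spike_class": classify_rs_fs(width_ms),
        "layer": assign_layer(depth_um),
    }


def qc_report(units: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`qc_unit` to a unit-metadata table.

    Expects columns unit_id, isi_violation, snr, width_ms, depth_um; returns
    one row per unit with pass flags, verdict and derived labels.
    """
    rows = []
    for rec in units.to_dict("records"):
        isi = rec.get("isi_violation")
        isi = None if isi is None or (isinstance(isi, float) and np.isnan(isi)) else isi
        res = qc_unit(isi, rec["snr"], rec["width_ms"], rec["depth_um"])
        res["unit_id"] = rec["unit_id"]
        rows.append(res)
    cols = ["unit_id", "isi_pass", "snr_pass", "verdict", "reasons", "spike_class", "layer"]
    return pd.DataFrame(rows)[cols]
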