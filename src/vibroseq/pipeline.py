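"""End-to-end orchestration: simulate -> QC -> analyses -> report.

``run_pipeline`` executes the stages in dependency order on either a
generated synthetic session or a session directory on disk, writes every
intermediate table, and records a manifest (package version, configuration,
stage seeds) sufficient to regenerate all outputs.  Stage seeds are spawned
deterministically from the run seed, so reruns with the same configuration
are reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import summarize_behavior
from .decoder import (
    BinSpec,
    binned_counts,
    evaluate_choice_decoder,
    evaluate_stimulus_decoder,
)
from .io import read_session, write_session
from .qc import qc_report
from .response import temporal_modulation_test
from .synthetic import SessionConfig, SessionData, generate_session
from .windows import classify_session

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    out_dir: str
    session: SessionConfig = field(default_factory=SessionConfig)
    input_dir: str | None = None  # read an existing session instead of simulating
    seed: int = 0
    run_qc: bool = True
    run_modulation: bool = True
    run_classification: bool = True
    run_decoding: bool = True
    run_behavior: bool = True
    modulation_n_perm: int = 10_000
    modulation_alpha: float = 0.05
    decoder_repeats: int = 50
    decoder_bin: BinSpec = field(default_factory=BinSpec)
    choice_bin: BinSpec = field(default_factory=lambda: BinSpec(kind="single"))


def _config_dict(cfg: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        return obj

    d = enc(cfg)
    d.pop("sequences", None)
    return d


def run_pipeline(cfg: RunConfig) -> Path:
    """Run all enabled stages; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    ss = np.random.SeedSequence(cfg.seed)
    seed_mod, seed_dec, seed_choice = (
        int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(3)
    )

    t0 = time.perf_counter()
    if cfg.input_dir is not None:
        session = read_session(cfg.input_dir)
    else:
        session = generate_session(cfg.session)
    write_session(session, out / "session")
    timings["session"] = time.perf_counter() - t0

    results: dict = {}
    if cfg.run_qc:
        t0 = time.perf_counter()
        report = qc_report(session.units)
        report.to_csv(out / "qc_report.csv", index=False)
        results["n_single_units"] = int((report["verdict"] == "single").sum())
        timings["qc"] = time.perf_counter() - t0

    if cfg.run_modulation:
        t0 = time.perf_counter()
        rng = np.random.default_rng(seed_mod)
        rows = []
        for uid in session.unit_ids():
            p = temporal_modulation_test(
                session.spikes_by_trial(uid), n_perm=cfg.modulation_n_perm, seed=rng
            )
            rows.append({"unit_id": uid, "p": p, "modulated": p < cfg.modulation_alpha})
        mod = pd.DataFrame(rows)
        mod.to_csv(out / "modulation.csv", index=False)
        results["fraction_modulated"] = float(mod["modulated"].mean())
        timings["modulation"] = time.perf_counter() - t0

    if cfg.run_classification:
        t0 = time.perf_counter()
        sequences = cfg.session.resolve_sequences()
        # classification is restricted to temporally modulated units when
        # the modulation stage ran (the analysis cohort)
        unit_ids = None
        if cfg.run_modulation:
            unit_ids = mod.loc[mod["modulated"], "unit_id"].tolist()
        cls = classify_session(session, sequences, unit_ids=unit_ids)
        cls.to_csv(out / "classification.csv", index=False)
        results["class_counts"] = cls["unit_class"].value_counts().to_dict()
        timings["classification"] = time.perf_counter() - t0

    if cfg.run_decoding:
        t0 = time.perf_counter()
        X = binned_counts(session, cfg.decoder_bin)
        stim_labels = session.trials["stimulus"].to_numpy()
        stim_report = evaluate_stimulus_decoder(
            X, stim_labels, n_repeats=cfg.decoder_repeats, seed=seed_dec
        )
        stim_report.to_frame().to_csv(out / "stimulus_confusion.csv")
        results["stimulus_decoder_accuracy"] = stim_report.overall_accuracy
        Xc = binned_counts(session, cfg.choice_bin)
        choice_out = evaluate_choice_decoder(
            Xc,
            stim_labels,
            session.trials["choice"].to_numpy(),
            n_repeats=cfg.decoder_repeats,
            seed=seed_choice,
        )
        results["choice_decoder_accuracy"] = choice_out["mean_accuracy"]
        timings["decoding"] = time.perf_counter() - t0

    if cfg.run_behavior:
        t0 = time.perf_counter()
        summary = summarize_behavior(session.trials)
        payload = {
            "relative_right": summary.relative_right,
            "dprime": summary.dprime,
            "fms_smf_p": summary.fms_smf_p,
            "simple_discrimination": summary.simple_discrimination,
        }
        (out / "behavior_summary.json").write_text(json.dumps(payload, indent=2))
        summary.per_stimulus.to_csv(out / "behavior_per_stimulus.csv", index=False)
        results["dprime"] = summary.dprime
        timings["behavior"] = time.perf_counter() - t0

    config = _config_dict(cfg)
    manifest = {
        "package_version": __version__,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "stage_seeds": {
            "modulation": seed_mod,
            "stimulus_decoder": seed_dec,
            "choice_decoder": seed_choice,
        },
        "results": results,
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
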