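"""End-to-end orchestration: preprocess -> embed -> cycles -> HAVOK ->
detection/forecast -> statistics, with artifacts and a run manifest."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cycles import extract_cycle_features
from .embedding import delay_embed, dominant_period
from .havok import fit_havok, predict_test_span, prediction_accuracy, sweep_forcing_accuracy
from .io import PipelineConfig, read_timeseries_csv, write_matrix_csv
from .preprocess import preprocess_series
from .risk import sweep_coordinates
from .synthetic import SyntheticPatientConfig, generate_patient
from .timeseries import EventSeries, HourlyCountSeries

__all__ = ["run_pipeline", "config_hash"]

log = logging.getLogger("havokrisk")

STAGES = ["load", "preprocess", "embed", "cycles", "havok", "risk", "stats"]


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    input_path: str | Path | None = None,
    synthetic_config: SyntheticPatientConfig | None = None,
    outdir: str | Path = "havokrisk_out",
) -> dict:
    """Run the full analysis on a CSV record or a synthetic patient.

    Writes embedding matrices, the fitted system, evaluation tables and a
    manifest into ``outdir``; returns the manifest dict. Numeric outputs
    are fully determined by the config hash and seed.
    """
    if (input_path is None) == (synthetic_config is None):
        raise ValueError("pass exactly one of input_path or synthetic_config")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
    }
    timings: dict[str, float] = {}

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s started", name)

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc_type is None:
                    manifest["stages"].append(name)
                    log.info("stage %s done (%.2fs)", name, timings[name])
                else:
                    manifest["failed_stage"] = name
                    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                    log.error("stage %s failed: %s", name, exc)
                return False

        return _Timer()

    with stage("load"):
        if input_path is not None:
            series, events = read_timeseries_csv(input_path)
        else:
            series, events = generate_patient(synthetic_config)

    with stage("preprocess"):
        pp = preprocess_series(
            series,
            trim_months=config.trim_months,
            cutoff_hours=config.lowpass_cutoff_hours,
            fir_order=config.fir_order,
        )
        events = EventSeries(
            events.le_counts[pp.trimmed_hours :],
            events.seizure_flags[pp.trimmed_hours :],
        )

    with stage("embed"):
        emb = delay_embed(pp.filtered.values, d=config.d, k=config.k)
        write_matrix_csv(out / "U.csv", emb.U)
        write_matrix_csv(out / "S.csv", emb.S)
        write_matrix_csv(
            out / "V.csv",
            emb.V,
            meta={
                "d": emb.d,
                "k": emb.k,
                "time_offset": emb.time_offset,
                "sign_convention": "largest |u_r| element positive",
                "dominant_period_hours": [
                    dominant_period(emb.U[:, j]) for j in range(emb.k)
                ],
            },
        )

    with stage("cycles"):
        cyc = extract_cycle_features(pp.series.values, causal=False)
        pd.DataFrame(
            {
                "period_days": cyc.periodogram.period_days,
                "power": cyc.periodogram.power,
            }
        ).to_csv(out / "periodogram.csv", index=False)
        log.info(
            "selected peaks: fast %.2f d (power %.3g), slow %.2f d (power %.3g)",
            cyc.peaks.fast_peak_days,
            cyc.peaks.fast_power,
            cyc.peaks.slow_peak_days,
            cyc.peaks.slow_power,
        )

    with stage("havok"):
        span = (0, min(config.train_hours, emb.V.shape[0] - 24))
        sys = fit_havok(emb.V, config.r, span)
        sim, truth = predict_test_span(sys, emb.V)
        acc = prediction_accuracy(sim.V_pred, truth)
        write_matrix_csv(
            out / "havok_A.csv",
            sys.A,
            meta={
                "r": sys.r,
                "train_span": list(sys.train_span),
                "fit_residual": sys.fit_residual.tolist(),
                "condition_number": sys.condition_number,
                "initial_condition": sys.initial_condition,
                "test_accuracy_inv_mse": acc.tolist(),
            },
        )
        write_matrix_csv(out / "havok_B.csv", sys.B)
        lo, hi = config.sweep_r
        sweep = sweep_forcing_accuracy(emb, range(lo, hi + 1), span)
        pd.DataFrame(
            [
                {"r": r, **{f"inv_mse_V{j + 1}": a[j] for j in range(len(a))}}
                for r, a in sweep.items()
            ]
        ).to_csv(out / "forcing_sweep.csv", index=False)

    with stage("risk"):
        ev_aligned = EventSeries(
            events.le_counts[: emb.V.shape[0]], events.seizure_flags[: emb.V.shape[0]]
        )
        table, _ = sweep_coordinates(
            emb,
            ev_aligned,
            horizons=config.horizons,
            models=config.models,
            coordinates=config.coordinates,
            resolution=config.resolution,
            train_hours=config.train_hours,
            n_reps=config.repetitions,
            n_null=config.n_null,
            alpha=config.alpha,
            seed=config.seed,
            multidien=cyc,
        )
        table.to_csv(out / "risk_evaluations.csv", index=False)

    with stage("stats"):
        summary = {
            "n_significant": int(table["significant"].sum()),
            "best_detection_auc": float(
                table.loc[table["horizon_days"] == 0, "mean_auc"].max()
            )
            if (table["horizon_days"] == 0).any()
            else None,
            "correction": config.correction,
        }
        (out / "stats_summary.json").write_text(json.dumps(summary, indent=2))

    manifest["timings_s"] = timings
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
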