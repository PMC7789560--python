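"""Pipeline orchestration: the five-phase protocol per synthetic subject.

Per subject: a familiarization block (simulated, nothing recorded), an
acquisition phase on a whole-set order at the strict tolerance, C+/C−
training on the in-zone acquisition data, two hybrid test phases on a
subset order at the relaxed tolerance (order counterbalanced across
subjects), and a natural baseline phase on the same subset order at the
test tolerance. Metrics, synergy analysis and statistics follow.

All randomness is namespaced from the config's master seed and the
per-subject seeds, so a rerun with the same config reproduces every file
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .datasets import build_dataset
from .kinematics import ArmGeometry
from .metrics import average_reaching_postures, phase_metrics, tidy_metrics
from .predictors import Hyperparameters, PredictorModel, offline_rmse, train
from .recording import MotionRecording, read_recording, write_recording
from .stats import compare_conditions, paired_rmse_test, render_report
from .subject import simulate_phase_hybrid, simulate_phase_natural
from .synergy import (
    cumulative_ev,
    pairwise_distances,
    run_pca,
    subspace_distance,
    synergy_to_json,
)
from .tasks import (
    Tolerance,
    build_target_grid,
    build_target_set,
    generate_target_order,
)

__all__ = [
    "run_experiment",
    "run_subject",
    "SubjectResult",
    "read_recording",
    "write_recording",
]


@dataclass
class SubjectResult:
    """Everything the analysis needs for one subject."""

    index: int
    recordings: dict[str, MotionRecording]
    outcomes: dict[str, list]
    models: dict[str, PredictorModel]
    rmse: dict[str, float]  # e.g. "C+_train", "C-_baseline"
    metrics: dict[str, dict]  # per condition N / C+ / C-
    synergy: dict[str, object] = field(default_factory=dict)


def _hyper(config: ExperimentConfig) -> Hyperparameters:
    return Hyperparameters(
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        max_train_rows=config.max_train_rows,
    )


def run_subject(config: ExperimentConfig, index: int) -> SubjectResult:
    """The five-phase protocol for one synthetic subject."""
    geometry = config.geometry()
    subject = config.subject(index)
    grid = build_target_grid(geometry, config.grid_spacing, config.grid_near_face)
    whole = build_target_set(grid, "whole")
    subset = build_target_set(grid, "subset")
    acq_tol = Tolerance(*config.acquisition_tolerance)
    test_tol = Tolerance(*config.test_tolerance)

    ss = np.random.SeedSequence([config.master_seed, subject.seed])
    seeds = ss.generate_state(8)
    order_whole = generate_target_order(
        whole, config.min_order_whole, int(seeds[0] % 2**31)
    )
    order_subset = generate_target_order(
        subset, config.min_order_subset, int(seeds[1] % 2**31)
    )
    if config.order_cap_whole:
        order_whole = type(order_whole)(
            order_whole.sequence[: config.order_cap_whole], order_whole.seed
        )
    if config.order_cap_subset:
        order_subset = type(order_subset)(
            order_subset.sequence[: config.order_cap_subset], order_subset.seed
        )

    # familiarization: simulated but not recorded
    recordings: dict[str, MotionRecording] = {}
    outcomes: dict[str, list] = {}

    rec, outs = simulate_phase_natural(
        order_whole, acq_tol, subject, geometry,
        np.random.default_rng(seeds[2]), phase="acquisition",
    )
    recordings["acquisition"], outcomes["acquisition"] = rec, outs

    hyper = _hyper(config)
    ds = {m: build_dataset(rec, m) for m in ("C+", "C-")}
    models = {
        m: train(ds[m], hyper, seed=int(seeds[3] % 2**31)) for m in ("C+", "C-")
    }

    first = ("C+", "C-") if config.cplus_first(index) else ("C-", "C+")
    for k, mode in enumerate(first):
        phase = f"test{mode}"
        rec_h, outs_h = simulate_phase_hybrid(
            order_subset, models[mode], test_tol, subject, geometry,
            np.random.default_rng(seeds[4 + k]), phase=phase,
        )
        recordings[phase], outcomes[phase] = rec_h, outs_h

    rec_b, outs_b = simulate_phase_natural(
        order_subset, test_tol, subject, geometry,
        np.random.default_rng(seeds[6]), phase="baseline",
    )
    recordings["baseline"], outcomes["baseline"] = rec_b, outs_b

    ds_base = {m: build_dataset(rec_b, m) for m in ("C+", "C-")}
    rmse = {}
    for m in ("C+", "C-"):
        rmse[f"{m}_train"] = offline_rmse(models[m], ds[m]).pooled
        rmse[f"{m}_baseline"] = offline_rmse(models[m], ds_base[m]).pooled

    metrics = {
        "N": phase_metrics(outs_b, rec_b.shoulder_positions, "N"),
        "C+": phase_metrics(
            outcomes["testC+"], recordings["testC+"].shoulder_positions, "C+"
        ),
        "C-": phase_metrics(
            outcomes["testC-"], recordings["testC-"].shoulder_positions, "C-"
        ),
    }

    synergy = {}
    postures = {
        "N": average_reaching_postures(rec_b, outs_b, "N"),
        "C+": average_reaching_postures(
            recordings["testC+"], outcomes["testC+"], "C+"
        ),
        "C-": average_reaching_postures(
            recordings["testC-"], outcomes["testC-"], "C-"
        ),
        "MC+": average_reaching_postures(
            recordings["testC+"], outcomes["testC+"], "MC+", mimicked=True
        ),
        "MC-": average_reaching_postures(
            recordings["testC-"], outcomes["testC-"], "MC-", mimicked=True
        ),
    }
    synergy["postures"] = postures
    if all(len(p) >= 8 for p in postures.values()):
        pca = {g: run_pca(p, g) for g, p in postures.items()}
        synergy["pca"] = pca
        synergy["cum_ev3"] = {g: cumulative_ev(r, 3) for g, r in pca.items()}
        synergy["dist_to_N_3"] = {
            g: subspace_distance(pca[g], pca["N"], 3) for g in ("C+", "C-")
        }

    return SubjectResult(
        index=index,
        recordings=recordings,
        outcomes=outcomes,
        models=models,
        rmse=rmse,
        metrics=metrics,
        synergy=synergy,
    )


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Run all subjects, write recordings/metrics/reports, return the manifest."""
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {
        "config_hash": _file_hash(out / "config.yaml"),
        "subjects": {},
        "files": {},
        "partial": [],
    }

    results: list[SubjectResult] = []
    for i in range(config.n_subjects):
        sdir = out / f"subject{i}"
        sdir.mkdir(exist_ok=True)
        try:
            res = run_subject(config, i)
        except Exception as ex:  # record partial completion
            manifest["partial"].append({"subject": i, "error": str(ex)})
            continue
        results.append(res)
        for phase, rec in res.recordings.items():
            p = sdir / f"{phase}.csv"
            write_recording(rec, p)
            manifest["files"][f"s{i}/{phase}"] = _file_hash(p)
        tidy = tidy_metrics(res.metrics, subject=i)
        p = sdir / "metrics.csv"
        tidy.to_csv(p, index=False, float_format="%.10g")
        manifest["files"][f"s{i}/metrics"] = _file_hash(p)
        if "pca" in res.synergy:
            p = sdir / "synergy.json"
            p.write_text(synergy_to_json(res.synergy["pca"]))
            manifest["files"][f"s{i}/synergy"] = _file_hash(p)
            p = sdir / "subspace_distances.csv"
            pairwise_distances(res.synergy["pca"]).to_csv(
                p, index=False, float_format="%.10g"
            )
            manifest["files"][f"s{i}/subspace_distances"] = _file_hash(p)
        summary = {
            "rmse": res.rmse,
            "metrics": {
                k: {kk: vv for kk, vv in v.items() if not kk.startswith("per_trial")}
                for k, v in res.metrics.items()
            },
            "cum_ev3": res.synergy.get("cum_ev3"),
            "dist_to_N_3": res.synergy.get("dist_to_N_3"),
        }
        p = sdir / "summary.json"
        p.write_text(json.dumps(summary, indent=1, sort_keys=True))
        manifest["files"][f"s{i}/summary"] = _file_hash(p)
        manifest["subjects"][i] = summary

    # group statistics (need >= 3 completed subjects)
    if len(results) >= 3:
        stats_results = {}
        stats_results["rmse"] = [
            paired_rmse_test(
                np.array([r.rmse["C+_train"] for r in results]),
                np.array([r.rmse["C-_train"] for r in results]),
                metric="rmse_training",
            ),
            paired_rmse_test(
                np.array([r.rmse["C+_baseline"] for r in results]),
                np.array([r.rmse["C-_baseline"] for r in results]),
                metric="rmse_baseline",
            ),
        ]
        online = []
        plots = {}
        for metric_key, name in [("mean_as_cm_s", "AS"), ("mean_at_s", "AT"),
                                 ("sv_cm3", "SV")]:
            samples = {
                cond: np.array([r.metrics[cond][metric_key] for r in results])
                for cond in ("C+", "C-", "N")
            }
            online.append(compare_conditions(samples, metric=name))
            plots[name] = samples
        stats_results["online"] = online
        render_report(stats_results, out / "report", plots=plots)
        manifest["files"]["report/manifest"] = _file_hash(
            out / "report" / "manifest.json"
        )
    else:
        manifest["partial"].append(
        {"stage": "stats", "reason": f"{len(results)} subject(s) < 3"}
        )

    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["manifest_hash"] = _file_hash(mpath)
    return manifest
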