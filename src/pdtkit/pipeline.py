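"""Pipeline stages and report writers: simulate -> extract -> select -> evaluate.

Every stage writes comma-delimited text (plus JSON for structured reports)
into an output directory, together with a manifest recording the
configuration hash, seed and library versions so a run is reconstructible
from its artifacts alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classifiers import ClassifierSpec
from .config import RunConfig
from .errors import DataError
from .evaluation import (
    EvalReport,
    compare_groups,
    evaluate_pipeline,
    mean_relative_improvement,
    relative_improvement,
)
from .feature_selection import FeatureSubset, best_first_select, selection_report
from .features import (
    WindowConfig,
    features_frame,
    frame_to_dataset,
    read_feature_matrix,
    write_feature_matrix,
)
from .sensor_signal import load_stream, stream_to_angles
from .synthetic_data import SimulationParams, simulate_cohort
from .features import extract_features

log = logging.getLogger(__name__)

FAMILIES = ("svm", "rbfn", "rf")


def _window(cfg: RunConfig) -> WindowConfig:
    return WindowConfig(
        test_duration_s=cfg.window.test_duration_s,
        analysis_start_s=cfg.window.analysis_start_s,
        analysis_end_s=cfg.window.analysis_end_s,
    )


def _sim_params(cfg: RunConfig) -> SimulationParams:
    return SimulationParams(**cfg.simulation.model_dump())


def classifier_spec(cfg: RunConfig, family: str, *, selected: bool) -> ClassifierSpec:
    """Spec for one family; the RBFN uses fewer prototypes once features are selected."""
    c = cfg.classifiers
    return ClassifierSpec(
        family=family,
        degree=c.svm_degree,
        C=c.svm_C,
        n_clusters=c.rbfn_clusters_selected if selected else c.rbfn_clusters_full,
        n_trees=c.rf_trees,
        seed=cfg.seed,
    )


def simulate_stage(cfg: RunConfig, out_dir: Path) -> list[Path]:
    """Write per-subject sensor files, the roster, and ground-truth angles."""
    out_dir.mkdir(parents=True, exist_ok=True)
    sensors = out_dir / "sensors"
    sensors.mkdir(exist_ok=True)
    subjects = simulate_cohort(
        cfg.cohort.n_patients,
        cfg.cohort.n_controls,
        severity=(cfg.cohort.severity_lo, cfg.cohort.severity_hi),
        params=_sim_params(cfg),
        seed=cfg.seed,
    )
    written: list[Path] = []
    roster_rows, truth_rows = [], []
    for subj in subjects:
        for stream in (subj.weak_stream, subj.counter_stream):
            path = sensors / f"{stream.subject_id}_{stream.side}.csv"
            pd.DataFrame(
                {"t": stream.t, "ax": stream.acc[:, 0], "ay": stream.acc[:, 1], "az": stream.acc[:, 2]}
            ).to_csv(path, index=False)
            written.append(path)
        rec = subj.record
        roster_rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "mrc": rec.mrc_grade,
                "weak_label": rec.weak_label,
                "severity": subj.severity,
            }
        )
        for truth in (subj.weak_truth, subj.counter_truth):
            truth_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": truth.subject_id,
                        "side": truth.side,
                        "t": truth.t,
                        "drift_deg": truth.drift_deg,
                        "pron_deg": truth.pron_deg,
                    }
                )
            )
    roster_path = out_dir / "roster.csv"
    pd.DataFrame(roster_rows).to_csv(roster_path, index=False)
    truth_path = out_dir / "ground_truth_angles.csv"
    pd.concat(truth_rows, ignore_index=True).to_csv(truth_path, index=False)
    written += [roster_path, truth_path]
    return written


def extract_stage(cfg: RunConfig, in_dir: Path, out_dir: Path) -> Path:
    """Sensor files + roster -> canonical feature matrix CSV."""
    out_dir.mkdir(parents=True, exist_ok=True)
    roster = pd.read_csv(in_dir / "roster.csv", dtype={"mrc": str})
    from .features import SubjectRecord

    records = []
    for _, row in roster.iterrows():
        sid = str(row["subject_id"])
        streams = {}
        for side in ("weak", "counter"):
            path = in_dir / "sensors" / f"{sid}_{side}.csv"
            if not path.exists():
                raise DataError(f"subject {sid}: missing {side}-side sensor file {path}")
            streams[side] = stream_to_angles(
                load_stream(path, units=cfg.units), cutoff_hz=cfg.filter_cutoff_hz
            )
        rec = SubjectRecord(
            subject_id=sid,
            group=str(row["group"]),
            mrc_grade=str(row["mrc"]),
            weak_label=str(row.get("weak_label", "paretic")),
            features=extract_features(
                streams["weak"], streams["counter"], _window(cfg), osc_method=cfg.osc_method
            ),
        )
        records.append(rec)
    path = out_dir / "features.csv"
    write_feature_matrix(features_frame(records), path)
    return path


def select_stage(cfg: RunConfig, features_path: Path, out_dir: Path) -> Path:
    """Pooled wrapper selection per classifier family, with a summary table
    of which features each classifier chose."""
    out_dir.mkdir(parents=True, exist_ok=True)
    data = frame_to_dataset(read_feature_matrix(features_path))
    selections: dict[str, FeatureSubset] = {}
    payload = {}
    for family in FAMILIES:
        spec = classifier_spec(cfg, family, selected=True)
        chosen, trace = best_first_select(
            data,
            spec,
            patience=cfg.selection.patience,
            direction=cfg.selection.direction,
            merit=cfg.selection.merit,
        )
        selections[family] = chosen
        payload[family] = {
            "features": list(chosen.names),
            "indices": list(chosen.indices),
            "merit": chosen.merit,
            "n_evaluated": trace.n_evaluated,
            "stopping_reason": trace.stopping_reason,
        }
    (out_dir / "selection.json").write_text(json.dumps(payload, indent=2))
    report_path = out_dir / "selection_report.csv"
    selection_report(selections).to_csv(report_path, index=False)
    return report_path


def evaluate_stage(cfg: RunConfig, features_path: Path, out_dir: Path) -> list[EvalReport]:
    """LOOCV evaluation of the three families with and without feature selection."""
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = read_feature_matrix(features_path)
    data = frame_to_dataset(frame)
    reports: list[EvalReport] = []
    for family in FAMILIES:
        for fs_mode, selected in (("none", False), (cfg.selection.placement, True)):
            spec = classifier_spec(cfg, family, selected=selected)
            reports.append(
                evaluate_pipeline(
                    data,
                    spec,
                    fs_mode=fs_mode,
                    patience=cfg.selection.patience,
                    merit=cfg.selection.merit,
                )
            )
    write_report(reports, out_dir)
    compare_groups(frame).to_csv(out_dir / "group_comparison.csv", index=False)
    return reports


def write_report(reports: Sequence[EvalReport], out_dir: Path) -> pd.DataFrame:
    """Metrics table, ROC point files and the relative-improvement summary."""
    if len(reports) == 0:
        raise DataError("no evaluation reports to write")
    sizes = {r.n for r in reports}
    if len(sizes) != 1:
        raise DataError(f"reports mix cohorts of different sizes: {sorted(sizes)}")
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in reports:
        mode = "exFS" if r.fs_mode == "none" else "inFS"
        rows.append(
            {
                "classifier": r.classifier,
                "fs": mode,
                "accuracy": r.accuracy,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "f_measure": r.f_measure,
                "auc": r.auc,
            }
        )
        pd.DataFrame(r.roc, columns=["fpr", "tpr"]).to_csv(
            out_dir / f"roc_{r.classifier}_{mode}.csv", index=False
        )
        (out_dir / f"report_{r.classifier}_{mode}.json").write_text(
            json.dumps(r.to_dict(), indent=2)
        )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "metrics.csv", index=False)

    by_key = {(r["classifier"], r["fs"]): r for r in rows}
    improvements, auc_pairs = [], []
    for family in sorted({r.classifier for r in reports}):
        ex, inc = by_key.get((family, "exFS")), by_key.get((family, "inFS"))
        if ex is None or inc is None:
            continue
        improvements.append(
            {
                "classifier": family,
                "accuracy_exFS": ex["accuracy"],
                "accuracy_inFS": inc["accuracy"],
                "accuracy_improvement_pct": relative_improvement(ex["accuracy"], inc["accuracy"]),
                "auc_exFS": ex["auc"],
                "auc_inFS": inc["auc"],
                "auc_improvement_pct": relative_improvement(ex["auc"], inc["auc"]),
            }
        )
        auc_pairs.append((ex["auc"], inc["auc"]))
    if improvements:
        imp = pd.DataFrame(improvements)
        imp.to_csv(out_dir / "improvements.csv", index=False)
        summary = {"mean_auc_improvement_pct": mean_relative_improvement(auc_pairs)}
        (out_dir / "improvement_summary.json").write_text(json.dumps(summary, indent=2))
    return table


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> int:
    """Execute all stages in order and write a run manifest.  Returns 0 on success."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = []
    try:
        stage = "simulate"
        simulate_stage(cfg, out_dir / "cohort")
        stages.append(stage)
        stage = "extract"
        features_path = extract_stage(cfg, out_dir / "cohort", out_dir)
        stages.append(stage)
        stage = "select"
        select_stage(cfg, features_path, out_dir)
        stages.append(stage)
        stage = "evaluate"
        evaluate_stage(cfg, features_path, out_dir)
        stages.append(stage)
    except Exception:
        log.exception("pipeline failed in stage %r", stage)
        raise
    manifest = {
        "package_version": __version__,
        "config_hash": cfg.config_hash(),
        "config": cfg.model_dump(),
        "seed": cfg.seed,
        "stages": stages,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": __import__("sklearn").__version__,
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return 0
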