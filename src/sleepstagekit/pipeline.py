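"""End-to-end orchestration: simulate -> preprocess -> windows -> train ->
summarize -> evaluate -> wear simulation.

A single structured configuration (plain dict, typically loaded from YAML)
drives the run; every stage records its outputs and wall-clock in a run
manifest, stamped with a hash of the configuration so reruns are
attributable.  Stage toggles allow partial runs; a stage failure halts all
downstream stages with a structured error entry.  With fixed seeds, reruns
reproduce all CSV outputs byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, parameters, preprocess, synthetic, wearsim, windows
from .core import Hypnogram, TimeInBedWindow, read_hypnogram_csv
from .sleepnet import SleepNet, SleepNetConfig, SSLTaskConfig, pretrain_ssl, tiny_config, train_sleepnet

DEFAULT_STAGES = ("simulate", "preprocess", "windows", "pretrain", "train", "summarize", "evaluate", "wearsim")

SLEEP_PARAMETERS = (
    "total_sleep_duration_h",
    "sleep_efficiency_pct",
    "waso_min",
    "rem_duration_h",
    "nrem_duration_h",
    "rem_ratio_pct",
    "nrem_ratio_pct",
)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _sleepnet_config(cfg: dict) -> SleepNetConfig:
    block = dict(cfg.get("sleepnet", {}))
    preset = block.pop("preset", "tiny")
    if preset == "tiny":
        return tiny_config(**block)
    return SleepNetConfig(**block)


def run_pipeline(cfg: dict, out_dir=None) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    out = Path(out_dir or cfg.get("out_dir", "sleepstagekit_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stages = {s: bool(cfg.get("stages", {}).get(s, False)) for s in DEFAULT_STAGES}
    manifest = {
        "run_id": str(cfg.get("run_id", "run")),
        "config_hash": config_hash(cfg),
        "seed": seed,
        "stages": [],
        "outputs": [],
        "errors": [],
    }
    state: dict = {}

    order = [s for s in DEFAULT_STAGES if stages[s]]
    for stage in order:
        t0 = time.perf_counter()
        try:
            _STAGE_FUNCS[stage](cfg, out, seed, state, manifest)
        except Exception as exc:
            manifest["errors"].append({"stage": stage, "error": f"{type(exc).__name__}: {exc}"})
            manifest["stages"].append({"stage": stage, "status": "failed"})
            break
        manifest["stages"].append(
            {"stage": stage, "status": "ok", "wall_seconds": round(time.perf_counter() - t0, 2)}
        )
    _write_manifest(manifest, out / "run_manifest.txt")
    return manifest


def _write_manifest(manifest: dict, path: Path) -> None:
    with open(path, "w") as fh:
        for key in ("run_id", "config_hash", "seed"):
            fh.write(f"{key}: {manifest[key]}\n")
        for s in manifest["stages"]:
            fh.write(f"stage: {json.dumps(s, sort_keys=True)}\n")
        for o in manifest["outputs"]:
            fh.write(f"output: {o}\n")
        for e in manifest["errors"]:
            fh.write(f"error: {json.dumps(e, sort_keys=True)}\n")


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg, out, seed, state, manifest):
    cc = synthetic.CohortConfig(seed=seed, **cfg.get("cohort", {}))
    cohort_dir = out / "cohort"
    m = synthetic.simulate_cohort(cc, cohort_dir)
    state["cohort_dir"] = cohort_dir
    state["cohort_manifest"] = m
    manifest["outputs"].append(str(cohort_dir / "manifest.txt"))


def _stage_preprocess(cfg, out, seed, state, manifest):
    cohort_dir = Path(cfg.get("cohort_dir", state.get("cohort_dir", out / "cohort")))
    pcfg = preprocess.PreprocessConfig(**cfg.get("preprocess", {}))
    subjects: dict = {}
    qc_rows = []
    for sdir in sorted(d for d in cohort_dir.iterdir() if d.is_dir()):
        sid = sdir.name
        entry = {"tensors": [], "hypnograms": [], "features": [], "times": []}
        for rpath in sorted(sdir.glob("recording_*.csv")):
            rec, qc = preprocess.read_recording(rpath, subject_id=sid)
            if rec is not None:
                rec = preprocess.resample_clip(rec, pcfg)
                qc2 = preprocess.quality_check(rec, pcfg)
                qc.mean_acc_mg, qc.calibration_error_mg = qc2.mean_acc_mg, qc2.calibration_error_mg
                if qc2.excluded:
                    for r in qc2.reasons:
                        qc.exclude(r)
            qc_rows.append(vars(qc) | {"file": rpath.name})
            if rec is None or qc.excluded:
                continue
            tensor = preprocess.epochize(rec, pcfg)
            X, times = windows.extract_features(tensor, pcfg.target_rate)
            entry["tensors"].append(tensor)
            entry["features"].append(X)
            entry["times"].append(times)
        for hpath in sorted(sdir.glob("hypnogram_*.csv")):
            entry["hypnograms"].append(read_hypnogram_csv(hpath))
        if entry["tensors"]:
            subjects[sid] = entry
    state["subjects"] = subjects
    qc_df = pd.DataFrame(qc_rows)
    qc_df["reasons"] = qc_df["reasons"].apply("; ".join)
    qc_df.to_csv(out / "qc_report.csv", index=False, float_format="%.3f")
    manifest["outputs"].append(str(out / "qc_report.csv"))


def _stage_windows(cfg, out, seed, state, manifest):
    subjects = state["subjects"]
    diary = pd.read_csv(Path(state.get("cohort_dir", out / "cohort")) / "diary.csv",
                        parse_dates=["fell_asleep", "woke_up"])
    feats, labels = [], []
    for sid, entry in subjects.items():
        d = diary[diary["subject_id"] == sid]
        for X, times in zip(entry["features"], entry["times"]):
            in_bed = np.zeros(len(times), dtype=bool)
            for _, row in d.iterrows():
                in_bed |= (times >= row["fell_asleep"]) & (times < row["woke_up"])
            feats.append(X)
            labels.append(in_bed)
    model = windows.fit_window_model(np.vstack(feats), np.concatenate(labels), seed=seed)
    rows = []
    for sid, entry in subjects.items():
        entry["windows"] = {}
        for X, times in zip(entry["features"], entry["times"]):
            ws = windows.predict_time_in_bed(model, X, times)
            ws = windows.merge_windows(ws, model.merge_gap_minutes)
            for night_date, w in windows.select_overnight_window(ws).items():
                entry["windows"][night_date] = w
                rows.append(
                    {"subject_id": sid, "night_date": night_date,
                     "start": w.start.isoformat(), "end": w.end.isoformat(), "source": w.source}
                )
    pd.DataFrame(rows).to_csv(out / "windows.csv", index=False)
    manifest["outputs"].append(str(out / "windows.csv"))


def _stage_pretrain(cfg, out, seed, state, manifest):
    subjects = state["subjects"]
    block = cfg.get("ssl", {})
    X = np.concatenate(
        [t.epochs[t.wear_mask] for e in subjects.values() for t in e["tensors"]]
    ).astype(float)
    max_windows = int(block.get("max_windows", 2000))
    if len(X) > max_windows:
        sel = np.random.default_rng(seed).choice(len(X), max_windows, replace=False)
        X = X[sel]
    ncfg = _sleepnet_config(cfg)
    model = SleepNet(ncfg)
    ssl_cfg = SSLTaskConfig(
        tasks=tuple(block.get("tasks", ("time_reversal", "segment_permutation", "time_warp"))),
        seed=seed,
    )
    res = pretrain_ssl(model, X, ssl_cfg, epochs=int(block.get("epochs", 3)))
    state["pretrained_state"] = res.extractor_state
    auc_df = pd.DataFrame(
        [{"task": t, "holdout_auc": a} for t, a in res.task_auc.items()]
    )
    auc_df.to_csv(out / "ssl_report.csv", index=False, float_format="%.4f")
    manifest["outputs"].append(str(out / "ssl_report.csv"))


def _stage_train(cfg, out, seed, state, manifest):
    subjects = state["subjects"]
    ncfg = _sleepnet_config(cfg)
    nights = []
    for sid, entry in subjects.items():
        for tensor, hyp in zip(entry["tensors"], entry["hypnograms"]):
            nights.append((tensor, hyp, sid))
    k = int(cfg.get("folds", 5))
    cv = train_sleepnet(nights, ncfg, k=k, seed=seed,
                        pretrained_state=state.get("pretrained_state"))
    state["cv"] = cv
    rows = []
    for sid, pred in cv.predictions.items():
        df = pred.to_frame()
        df.insert(0, "subject_id", sid)
        rows.append(df)
    pred_df = pd.concat(rows, ignore_index=True)
    pred_df["epoch_start"] = pd.to_datetime(pred_df["epoch_start"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S"
    )
    pred_df.to_csv(out / "stage_predictions.csv", index=False, float_format="%.5f")
    manifest["outputs"].append(str(out / "stage_predictions.csv"))


def _stage_summarize(cfg, out, seed, state, manifest):
    subjects = state["subjects"]
    cv = state.get("cv")
    rows = []
    for sid, entry in subjects.items():
        pred = cv.predictions.get(sid) if cv else None
        for hyp in entry["hypnograms"]:
            window = TimeInBedWindow(hyp.epoch_start_times[0], hyp.end_time, "truth")
            truth_sum = parameters.summarize_night(hyp, window)
            truth_sum.subject_id = sid
            row = {"source": "truth"} | truth_sum.as_dict()
            rows.append(row)
            if pred is not None:
                sel = (pred.epoch_times >= window.start) & (pred.epoch_times < window.end)
                if sel.any():
                    ph = Hypnogram(pred.epoch_times[sel], pred.labels[sel])
                    psum = parameters.summarize_night(ph, window)
                    psum.subject_id = sid
                    rows.append({"source": "predicted"} | psum.as_dict())
    df = pd.DataFrame(rows)
    df.to_csv(out / "night_summaries.csv", index=False, float_format="%.4f")
    manifest["outputs"].append(str(out / "night_summaries.csv"))
    state["night_summaries"] = df

    if cv is not None:
        ba_rows = []
        for param in SLEEP_PARAMETERS:
            t = df[df["source"] == "truth"].reset_index()
            p = df[df["source"] == "predicted"].reset_index()
            n = min(len(t), len(p))
            if n >= 2:
                res = agreement.bland_altman(t[param][:n], p[param][:n], param)
                ba_rows.append(vars(res))
        if ba_rows:
            pd.DataFrame(ba_rows).to_csv(out / "bland_altman.csv", index=False,
                                         float_format="%.4f")
            manifest["outputs"].append(str(out / "bland_altman.csv"))


def _stage_evaluate(cfg, out, seed, state, manifest):
    cv = state["cv"]
    truths, preds = cv.truths, {s: p.labels for s, p in cv.predictions.items()}
    frames = []
    for scheme in ("five_class", "three_class", "two_class"):
        t = {s: _collapse_labels(v, scheme) for s, v in truths.items()}
        p = {s: _collapse_labels(v, scheme) for s, v in preds.items()}
        summary, per_subject = agreement.subject_level_report(t, p, scheme)
        summary = summary.reset_index(names="level")
        summary.insert(0, "scheme", scheme)
        frames.append(summary)
    report = pd.concat(frames, ignore_index=True)
    report.to_csv(out / "agreement_report.csv", index=False, float_format="%.4f")
    manifest["outputs"].append(str(out / "agreement_report.csv"))
    state["agreement_report"] = report


def _collapse_labels(labels, scheme):
    if scheme == "five_class":
        return np.asarray(labels, dtype=object)
    from .core import THREE_CLASS_MAP, TWO_CLASS_MAP

    mapping = THREE_CLASS_MAP if scheme == "three_class" else TWO_CLASS_MAP
    return np.array([mapping[l] for l in labels], dtype=object)


def _stage_wearsim(cfg, out, seed, state, manifest):
    block = cfg.get("wearsim", {})
    n_subjects = int(block.get("n_subjects", 30))
    stage_model = synthetic.default_stage_model()
    weeks = [
        synthetic.simulate_week_sleep(f"W{i:03d}", stage_model, seed=seed + i)
        for i in range(n_subjects)
    ]
    best, grid = wearsim.wear_grid_search(
        weeks,
        hours_grid=block.get("hours_grid", (16, 20, 22, 24)),
        days_grid=block.get("days_grid", (1, 3, 5, 7)),
        icc_threshold=float(block.get("icc_threshold", 0.75)),
        reps=int(block.get("reps", 3)),
        seed=seed,
    )
    grid.to_csv(out / "wear_grid.csv", index=False, float_format="%.4f")
    manifest["outputs"].append(str(out / "wear_grid.csv"))
    state["wear_best"] = best


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "pretrain": _stage_pretrain,
    "preprocess": _stage_preprocess,
    "windows": _stage_windows,
    "train": _stage_train,
    "summarize": _stage_summarize,
    "evaluate": _stage_evaluate,
    "wearsim": _stage_wearsim,
}
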