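"""End-to-end orchestration: denoise -> window/stack -> dual feature banks
-> recursive elimination -> genetic augmentation -> parallel forests.

Activity and location are classified by two independent deep neural
decision forests fed from their respective feature banks ("parallel" means
task-parallel, not weight-sharing).  Evaluation is stratified k-fold
cross-validation; folds are grouped by recording so stacks cut from one
recording never straddle the train/test boundary, and feature selection
and augmentation are fitted inside each training fold only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .config import PipelineConfig
from .dndf import DNDFClassifier, evaluate
from .har_features import HARFeatureExtractor, HarFeatureConfig
from .loc_features import LOCFeatureExtractor, LocFeatureConfig
from .preprocessing import denoise_recording, segment_windows, stack_windows
from .selection_augmentation import GeneticAugmenter, RecursiveBankSelector
from .sensor_io import MultiSensorRecording, align_and_resample, read_recording_dir

__all__ = [
    "FeatureTable",
    "preprocess_recording",
    "stacks_from_recording",
    "extract_feature_tables",
    "cross_validate_task",
    "run_pipeline",
    "run_pipeline_in_memory",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """One bank's feature matrix with labels and recording grouping."""

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    layout: list[str] = field(default_factory=list)


def _har_cfg(cfg: PipelineConfig) -> HarFeatureConfig:
    h = cfg.features.har
    return HarFeatureConfig(n_mfcc=h.n_mfcc, n_filters=h.n_filters,
                            frame_s=h.frame_s, hop_s=h.hop_s,
                            fnn_max_dim=h.fnn_max_dim, fnn_rtol=h.fnn_rtol,
                            fnn_atol=h.fnn_atol, higuchi_k_max=h.higuchi_k_max,
                            per_window=h.per_window)


def _loc_cfg(cfg: PipelineConfig) -> LocFeatureConfig:
    l = cfg.features.loc
    return LocFeatureConfig(min_separation_s=l.min_separation_s,
                            threshold_mode=l.threshold_mode,
                            threshold_quantile=l.threshold_quantile,
                            audio_n_mfcc=l.audio_n_mfcc,
                            audio_n_filters=l.audio_n_filters,
                            audio_frame_s=l.audio_frame_s,
                            audio_hop_s=l.audio_hop_s)


def preprocess_recording(rec: MultiSensorRecording,
                         cfg: PipelineConfig) -> MultiSensorRecording:
    """Align/resample to the common rate, then low-pass each IMU channel."""
    if rec.fs is None or rec.fs != cfg.fs:
        rec = align_and_resample(rec, cfg.fs)
    return denoise_recording(rec, order=cfg.filter.order,
                             cutoff=cfg.filter.cutoff,
                             cutoff_units=cfg.filter.cutoff_units)


def stacks_from_recording(rec: MultiSensorRecording, cfg: PipelineConfig):
    windows = segment_windows(rec, cfg.window.seconds)
    return stack_windows(windows, cfg.stack.size, cfg.stack.stride, rec=rec)


def extract_feature_tables(recordings: list[MultiSensorRecording],
                           cfg: PipelineConfig,
                           preprocess: bool = True
                           ) -> tuple[FeatureTable, FeatureTable]:
    """Both banks for a corpus: (activity table, localization table)."""
    har_ext = HARFeatureExtractor(cfg=_har_cfg(cfg))
    loc_ext = LOCFeatureExtractor(cfg=_loc_cfg(cfg))
    X_har, X_loc, y_act, y_loc, groups = [], [], [], [], []
    for i, rec in enumerate(recordings):
        if preprocess:
            rec = preprocess_recording(rec, cfg)
        stacks = stacks_from_recording(rec, cfg)
        if not stacks:
            logger.warning("recording %d too short for a stack: skipped", i)
            continue
        X_har.append(har_ext.fit_transform(stacks))
        X_loc.append(loc_ext.fit_transform(stacks))
        gid = rec.subject_id or f"rec{i}"
        for _ in stacks:
            y_act.append(rec.activity_label)
            y_loc.append(rec.location_label)
            groups.append(gid)
    har = FeatureTable(X=np.vstack(X_har), y=np.asarray(y_act),
                       groups=np.asarray(groups),
                       layout=list(har_ext.feature_names_))
    loc = FeatureTable(X=np.vstack(X_loc), y=np.asarray(y_loc),
                       groups=np.asarray(groups),
                       layout=list(loc_ext.feature_names_))
    return har, loc


def _make_classifier(cfg: PipelineConfig, seed: int) -> DNDFClassifier:
    d = cfg.dndf
    return DNDFClassifier(hidden_layers=tuple(d.hidden_layers),
                          embed_dim=d.embed_dim, n_trees=d.n_trees,
                          tree_depth=d.tree_depth, epochs=d.epochs,
                          batch_size=d.batch_size,
                          learning_rate=d.learning_rate, l2=d.l2,
                          class_weight=d.class_weight, random_state=seed)


def cross_validate_task(table: FeatureTable, cfg: PipelineConfig,
                        seed: int | None = None) -> dict:
    """Stratified (recording-grouped) k-fold CV of one bank's classifier.

    Selection and augmentation happen inside each training fold; the test
    fold sees only the transform.  Returns per-fold metrics plus pooled
    macro scores and the pooled confusion matrix.
    """
    seed = cfg.seed if seed is None else seed
    folds = cfg.eval.folds
    if cfg.eval.group_by_recording and len(np.unique(table.groups)) >= folds:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True,
                                        random_state=seed)
        split_iter = splitter.split(table.X, table.y, groups=table.groups)
    else:
        splitter = StratifiedKFold(n_splits=folds, shuffle=True,
                                   random_state=seed)
        split_iter = splitter.split(table.X, table.y)
    fold_metrics = []
    y_true_all, y_pred_all = [], []
    for k, (tr, te) in enumerate(split_iter):
        t0 = time.time()
        X_tr, y_tr = table.X[tr], table.y[tr]
        X_te, y_te = table.X[te], table.y[te]
        if cfg.select.enabled:
            selector = RecursiveBankSelector(
                keep_fraction=cfg.select.keep_fraction,
                step_fraction=cfg.select.step_fraction)
            X_tr = selector.fit_transform(X_tr, y_tr)
            X_te = selector.transform(X_te)
        if cfg.ga.enabled:
            aug = GeneticAugmenter(n_generations=cfg.ga.n_generations,
                                   same_class=cfg.ga.same_class,
                                   chained=cfg.ga.chained,
                                   random_state=seed + 1000 + k)
            ds = aug.fit_resample(X_tr, y_tr)
            X_tr, y_tr = ds.vectors, ds.labels
        clf = _make_classifier(cfg, seed + k).fit(X_tr, y_tr)
        m = evaluate(clf, X_te, y_te)
        y_true_all.append(y_te)
        y_pred_all.append(clf.predict(X_te))
        fold_metrics.append({
            "fold": k,
            "accuracy": m["accuracy"],
            "macro_f1": m["macro_f1"],
            "macro_recall": m["macro_recall"],
            "macro_precision": m["macro_precision"],
            "n_train": int(len(tr)), "n_test": int(len(te)),
            "seconds": round(time.time() - t0, 2),
        })
        logger.info("fold %d: acc %.3f macro-F1 %.3f (%.1fs)", k,
                    m["accuracy"], m["macro_f1"], fold_metrics[-1]["seconds"])
    from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    labels = sorted(np.unique(table.y).tolist())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0)
    return {
        "folds": fold_metrics,
        "labels": labels,
        "confusion": confusion_matrix(y_true, y_pred, labels=labels).tolist(),
        "accuracy": float((y_true == y_pred).mean()),
        "macro_precision": float(prec.mean()),
        "macro_recall": float(rec.mean()),
        "macro_f1": float(f1.mean()),
    }


def run_pipeline_in_memory(recordings: list[MultiSensorRecording],
                           cfg: PipelineConfig) -> dict:
    """Full pipeline on an in-memory corpus; returns both tasks' metrics."""
    har, loc = extract_feature_tables(recordings, cfg)
    results = {}
    if not np.any(har.y == None):  # noqa: E711  - labels may be absent
        results["activity"] = cross_validate_task(har, cfg)
    if not np.any(loc.y == None):  # noqa: E711
        results["location"] = cross_validate_task(loc, cfg)
    return results


def _corpus_hash(recordings: list[MultiSensorRecording]) -> str:
    h = hashlib.sha256()
    for rec in recordings:
        h.update(str(rec.subject_id).encode())
        h.update(str(rec.activity_label).encode())
        h.update(str(rec.location_label).encode())
        for name in sorted(rec.channels):
            h.update(np.ascontiguousarray(rec.channels[name].axes).tobytes())
    return h.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig, input_dir, out_dir) -> dict:
    """Disk-to-disk run: read recording directories, write stage artifacts
    (feature CSVs, metrics JSON) and a manifest sufficient to reproduce the
    run (config + seed + input hash)."""
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.model_dump(), "stages": {}}
    try:
        rec_dirs = sorted(p for p in input_dir.iterdir()
                          if p.is_dir() and (p / "labels.json").exists())
        recordings = [read_recording_dir(p) for p in rec_dirs]
        manifest["input_hash"] = _corpus_hash(recordings)
        manifest["n_recordings"] = len(recordings)

        t0 = time.time()
        har, loc = extract_feature_tables(recordings, cfg)
        manifest["stages"]["features"] = {"seconds": round(time.time() - t0, 1),
                                          "har_dim": har.X.shape[1],
                                          "loc_dim": loc.X.shape[1]}
        _write_features_csv(har, out_dir / "features_har.csv")
        _write_features_csv(loc, out_dir / "features_loc.csv")

        results = {}
        for task, table in (("activity", har), ("location", loc)):
            if np.any(table.y == None):  # noqa: E711
                logger.warning("task %s skipped: unlabeled recordings", task)
                continue
            t0 = time.time()
            results[task] = cross_validate_task(table, cfg)
            manifest["stages"][f"cv_{task}"] = {
                "seconds": round(time.time() - t0, 1)}
        (out_dir / "metrics.json").write_text(json.dumps(results, indent=1))
        manifest["ok"] = True
    except Exception as exc:
        manifest["ok"] = False
        manifest["failed_stage"] = manifest["stages"].keys().__len__()
        manifest["error"] = repr(exc)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results


def _write_features_csv(table: FeatureTable, path) -> None:
    import pandas as pd
    df = pd.DataFrame(table.X, columns=table.layout)
    df.insert(0, "label", table.y)
    df.insert(1, "group", table.groups)
    df.to_csv(path, index=False, float_format="%.8g")
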