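"""End-to-end orchestration: simulate -> fit -> features -> classify -> evaluate.

Every stage reads and writes plain files (NIfTI / CSV / JSON) under a run
directory, so stages can be re-run or resumed independently; a manifest
records every artifact with a checksum and the configuration hash.  All
randomness descends from the single ``seed`` in the configuration, making
two runs with equal configs numerically identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .classification import (
    CLASSIFIER_KINDS,
    ClassifierSpec,
    CohortSplit,
    feature_importance,
    predict_scores,
    stratified_split,
    train_classifier,
)
from .evaluation import (
    bonferroni_alpha,
    evaluate_scores,
    image_quality,
    mcnemar_paired,
    roc_auc,
    youden_threshold,
)
from .fitting import MAP_NAMES, generate_map_suite, qc_filter_lesion
from .radiomics import feature_row, mean_metric_vector
from .signal_models import DEFAULT_BVALUES, BValueScheme
from .synthetic import CohortSpec, iter_cohort

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("mbdwi")

STAGES = ("simulate", "fit", "features", "classify", "evaluate")


@dataclass(frozen=True)
class PipelineConfig:
    """Single declarative configuration for a full pipeline run."""

    seed: int = 0
    # cohort
    n_subjects: int = 20
    n_malignant: int = 12
    snr: float = 30.0
    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    # fitting
    fwhm_mm: float = 3.0
    ivim_mode: str = "segmented"
    ivim_b_max: float = 1000.0
    qc_threshold: float = 0.8
    qc_model: str = "BE_IVIM"
    # classification / evaluation
    classifiers: tuple[str, ...] = ("rf", "l1r", "pca", "svm")
    maps: tuple[str, ...] = MAP_NAMES
    split_fraction: float = 0.5
    cv_folds: int = 10
    cv_repeats: int = 100
    n_boot: int = 2000
    mcnemar_repeats: int = 100
    m_comparisons: int = 23

    def __post_init__(self):
        unknown = set(self.classifiers) - set(CLASSIFIER_KINDS)
        if unknown:
            raise ValueError(f"unknown classifiers: {sorted(unknown)}")
        unknown = set(self.maps) - set(MAP_NAMES)
        if unknown:
            raise ValueError(f"unknown maps: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("bvalues", "classifiers", "maps"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Manifest:
    def __init__(self, run_dir: Path, config: PipelineConfig):
        self.path = run_dir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
            if self.data.get("config_hash") != config.hash():
                raise ValueError(
                    "run directory holds a different configuration; "
                    "use a fresh directory")
        else:
            self.data = {"config_hash": config.hash(),
                         "config": config.to_dict(),
                         "stages": {}, "artifacts": {}}

    def done(self, stage: str) -> bool:
        return stage in self.data["stages"]

    def record(self, stage: str, artifacts: list[Path], wall_s: float,
               info: dict | None = None):
        for p in artifacts:
            self.data["artifacts"][str(p)] = _checksum(p)
        self.data["stages"][stage] = {
            "wall_seconds": round(wall_s, 2), **(info or {})}
        self.path.write_text(json.dumps(self.data, indent=2))


def _background_box(shape) -> np.ndarray:
    """A corner air box used as the noise-reference region."""
    box = np.zeros(shape, dtype=bool)
    nx, ny, nz = shape
    box[: max(nx // 8, 2), : max(ny // 8, 2), :] = True
    return box


def _stage_simulate(cfg, run_dir, manifest):
    t0 = time.time()
    sub_dir = run_dir / "subjects"
    sub_dir.mkdir(exist_ok=True)
    scheme = BValueScheme(cfg.bvalues)
    spec = CohortSpec(n_subjects=cfg.n_subjects,
                      n_malignant=cfg.n_malignant,
                      snr=cfg.snr, seed=cfg.seed)
    rows, artifacts = [], []
    for subject in iter_cohort(spec, scheme):
        prefix = sub_dir / subject.subject_id
        mio.save_dwi(subject.volume, prefix)
        mio.save_mask(subject.mask, subject.volume.spacing,
                      f"{prefix}_mask.nii.gz")
        rows.append({"subject_id": subject.subject_id,
                     "label": subject.label,
                     "dwi": f"subjects/{subject.subject_id}",
                     "mask": f"subjects/{subject.subject_id}_mask.nii.gz"})
        log.info("simulated %s (%s)", subject.subject_id, subject.label)
    cohort = pd.DataFrame(rows)
    cohort_path = run_dir / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    manifest.record("simulate", [cohort_path], time.time() - t0,
                    {"n_subjects": len(rows)})


def _stage_fit(cfg, run_dir, manifest):
    t0 = time.time()
    cohort = pd.read_csv(run_dir / "cohort.csv")
    maps_dir = run_dir / "maps"
    maps_dir.mkdir(exist_ok=True)
    qc_rows = []
    for _, row in cohort.iterrows():
        vol = mio.load_dwi(run_dir / row.dwi)
        mask = mio.load_mask(run_dir / row["mask"])
        maps, quality = generate_map_suite(
            vol, mask, fwhm_mm=cfg.fwhm_mm, ivim_mode=cfg.ivim_mode,
            ivim_b_max=cfg.ivim_b_max)
        sdir = maps_dir / row.subject_id
        sdir.mkdir(exist_ok=True)
        for name, pmap in maps.items():
            safe = name.replace("*", "star")
            mio.save_map(pmap, vol.spacing, sdir / f"{safe}.nii.gz")
        qc = {"subject_id": row.subject_id}
        for model, fq in quality.items():
            mr2 = fq.mean_r2(mask)
            qc[f"mean_r2_{model}"] = mr2
        qc["keep"] = bool(qc_filter_lesion(
            quality[cfg.qc_model], mask, cfg.qc_threshold))
        # image quality of the highest-b volume against an air corner box
        b_high = vol.scheme.values[-1]
        iq = image_quality(vol.volume_at(b_high), mask,
                           _background_box(vol.shape) & ~mask)
        qc[f"snr_b{b_high:g}"] = iq["snr"]
        qc[f"cnr_b{b_high:g}"] = iq["cnr"]
        qc[f"contrast_b{b_high:g}"] = iq["contrast"]
        qc_rows.append(qc)
        log.info("fitted %s (keep=%s)", row.subject_id, qc["keep"])
    qc_path = run_dir / "qc.csv"
    pd.DataFrame(qc_rows).to_csv(qc_path, index=False)
    excluded = sum(not r["keep"] for r in qc_rows)
    manifest.record("fit", [qc_path], time.time() - t0,
                    {"n_excluded_qc": excluded})


def _stage_features(cfg, run_dir, manifest):
    t0 = time.time()
    cohort = pd.read_csv(run_dir / "cohort.csv")
    qc = pd.read_csv(run_dir / "qc.csv").set_index("subject_id")
    feat_rows, mean_rows = {}, {}
    labels = {}
    for _, row in cohort.iterrows():
        if not qc.loc[row.subject_id, "keep"]:
            log.info("skipping %s (QC excluded)", row.subject_id)
            continue
        mask = mio.load_mask(run_dir / row["mask"])
        sdir = run_dir / "maps" / row.subject_id
        maps = {}
        for name in MAP_NAMES:
            safe = name.replace("*", "star")
            maps[name] = mio.load_map(sdir / f"{safe}.nii.gz")
        spacing = mio.load_dwi(run_dir / row.dwi).spacing
        feat_rows[row.subject_id] = feature_row(maps, mask, spacing)
        mean_rows[row.subject_id] = mean_metric_vector(maps, mask)
        labels[row.subject_id] = row.label
    features = pd.DataFrame(feat_rows).T
    features.index.name = "subject_id"
    features["label"] = pd.Series(labels)
    features.to_csv(run_dir / "features.csv")
    means = pd.DataFrame(mean_rows).T
    means.index.name = "subject_id"
    means["label"] = pd.Series(labels)
    means.to_csv(run_dir / "means.csv")
    manifest.record("features", [run_dir / "features.csv",
                                 run_dir / "means.csv"], time.time() - t0,
                    {"n_features": features.shape[1] - 1})


def _map_columns(features: pd.DataFrame, map_name: str) -> list[str]:
    return [c for c in features.columns if c.startswith(f"{map_name}__")]


def _stage_classify(cfg, run_dir, manifest):
    t0 = time.time()
    features = pd.read_csv(run_dir / "features.csv", index_col=0)
    labels = features.pop("label")
    split = stratified_split(labels, cfg.split_fraction, cfg.seed)
    (run_dir / "split.json").write_text(json.dumps(
        {"train": list(split.train_ids), "test": list(split.test_ids),
         "seed": cfg.seed}, indent=2))
    score_rows = []
    importances = {}
    for map_name in cfg.maps:
        cols = _map_columns(features, map_name)
        X_tr = features.loc[list(split.train_ids), cols]
        y_tr = labels.loc[list(split.train_ids)]
        X_te = features.loc[list(split.test_ids), cols]
        for kind in cfg.classifiers:
            spec = ClassifierSpec(kind, seed=cfg.seed)
            model = train_classifier(spec, X_tr, y_tr)
            scores = predict_scores(model, X_te)
            for sid, sc in zip(split.test_ids, scores):
                score_rows.append({"subject_id": sid, "map": map_name,
                                   "classifier": kind, "score": float(sc),
                                   "label": labels.loc[sid]})
            if kind == "rf":
                importances[map_name] = feature_importance(
                    model, cols).head(20)
            log.info("trained %s on %s", kind, map_name)
    scores = pd.DataFrame(score_rows)
    scores.to_csv(run_dir / "scores.csv", index=False)
    imp = pd.concat(importances, names=["map", "feature"]).rename("importance")
    imp.to_csv(run_dir / "rf_importance_top20.csv")
    manifest.record("classify", [run_dir / "scores.csv",
                                 run_dir / "rf_importance_top20.csv"],
                    time.time() - t0)


def _oriented_metric_scores(means, labels, split, metric):
    """Orient a mean metric so higher = malignant, using training data."""
    tr = list(split.train_ids)
    sign = 1.0
    if roc_auc(means.loc[tr, metric], labels.loc[tr]) < 0.5:
        sign = -1.0
    te = list(split.test_ids)
    return sign * means.loc[te, metric].to_numpy()


def _stage_evaluate(cfg, run_dir, manifest):
    t0 = time.time()
    scores = pd.read_csv(run_dir / "scores.csv")
    means = pd.read_csv(run_dir / "means.csv", index_col=0)
    mean_labels = means.pop("label")
    split_info = json.loads((run_dir / "split.json").read_text())
    split = CohortSplit(tuple(split_info["train"]), tuple(split_info["test"]),
                        split_info["seed"])
    te = list(split.test_ids)
    report_rows, roc_frames = [], []
    rng = np.random.default_rng(cfg.seed + 1)
    for map_name in cfg.maps:
        per_method_scores = {}
        for kind in cfg.classifiers:
            sub = scores[(scores["map"] == map_name)
                         & (scores.classifier == kind)].set_index("subject_id")
            s = sub.loc[te, "score"].to_numpy()
            y = sub.loc[te, "label"].to_numpy()
            ev = evaluate_scores(s, y, map_name, kind, n_boot=cfg.n_boot,
                                 seed=int(rng.integers(2**31 - 1)))
            report_rows.append({**dataclasses.asdict(ev),
                                "p_value": float("nan")})
            per_method_scores[kind] = (s, y)
        metric = f"m{map_name}"
        s_mean = _oriented_metric_scores(means, mean_labels, split, metric)
        y_mean = mean_labels.loc[te].to_numpy()
        ev = evaluate_scores(s_mean, y_mean, map_name, "mean_metric",
                             n_boot=cfg.n_boot,
                             seed=int(rng.integers(2**31 - 1)))
        report_rows.append({**dataclasses.asdict(ev),
                            "p_value": float("nan")})
        # paired comparison radiomics RF vs mean metric at Youden cutpoints
        if "rf" in per_method_scores:
            s_rf, y_rf = per_method_scores["rf"]
            pvals = []
            for _ in range(cfg.mcnemar_repeats):
                boot = rng.integers(0, len(te), len(te))
                if len(np.unique(y_rf[boot])) < 2:
                    continue
                pa = (s_rf[boot] >= youden_threshold(s_rf, y_rf)).astype(int)
                pb = (s_mean[boot] >= youden_threshold(s_mean, y_mean)).astype(int)
                pvals.append(mcnemar_paired(pa, pb, y_rf[boot]))
            report_rows.append({
                "image_set": map_name, "method": "rf_vs_mean_mcnemar",
                "auc": float("nan"), "ci_low": float("nan"),
                "ci_high": float("nan"),
                "sensitivity": float("nan"), "specificity": float("nan"),
                "ppv": float("nan"), "npv": float("nan"),
                "p_value": float(np.mean(pvals)) if pvals else float("nan")})
    report = pd.DataFrame(report_rows)
    report_path = run_dir / "report.csv"
    report.to_csv(report_path, index=False)
    qc = pd.read_csv(run_dir / "qc.csv")
    iq_cols = [c for c in qc.columns
               if c.split("_")[0] in ("snr", "cnr", "contrast")]
    summary = {
        "bonferroni_alpha": bonferroni_alpha(0.05, cfg.m_comparisons),
        "m_comparisons": cfg.m_comparisons,
        "n_test_subjects": len(te),
        "image_quality_high_b": {c: float(qc[c].mean()) for c in iq_cols},
    }
    (run_dir / "report.json").write_text(json.dumps(summary, indent=2))
    manifest.record("evaluate", [report_path, run_dir / "report.json"],
                    time.time() - t0)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "features": _stage_features,
    "classify": _stage_classify,
    "evaluate": _stage_evaluate,
}


def run_pipeline(config: PipelineConfig, run_dir,
                 stages=STAGES, resume: bool = True) -> Path:
    """Execute the pipeline stages in order under ``run_dir``.

    With ``resume=True`` stages already recorded in the manifest are
    skipped, so a run can be continued after interruption or a single
    stage re-executed into an existing directory.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(run_dir, config)
    for stage in stages:
        if stage not in _STAGE_FN:
            raise ValueError(f"unknown stage {stage!r}")
        if resume and manifest.done(stage):
            log.info("stage %s already complete; skipping", stage)
            continue
        log.info("running stage %s", stage)
        _STAGE_FN[stage](config, run_dir, manifest)
    return run_dir
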