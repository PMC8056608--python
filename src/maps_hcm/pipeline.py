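"""Pipeline orchestration: QC -> detection -> ROI extraction ->
discovery or classification -> scoring -> correlation.

Stages communicate through files (TIFF/CSV/JSON) under the run's output
root, so any stage can be re-run or substituted by external tools.  A
run manifest records the config snapshot, per-stage output hashes and
library versions; deterministic stages reproduce hash-identical outputs
when re-run with the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, validate_config
from .detection import DetectorConfig, detect_cells, iou
from .discovery import (
    ReducedEmbedding,
    centroid_exemplars,
    crop_rois,
    embedding_table,
    reduce_features,
    silhouette_sweep,
    split_noise_cluster,
    subcluster,
)
from .features import ExtractorConfig, build_extractor, extract_features
from .qc import QCConfig, calibrate_threshold, qc_batch
from .scoring import (
    classify_rois,
    correlate_lof,
    score_variant,
    scores_table,
    train_classifier,
)
from .synthetic import SyntheticSpec, generate_dataset, read_dataset
from .types import BBox, FieldImage, ROI, stable_seed

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    stages: dict = field(default_factory=dict)  # stage -> {file: sha256}
    versions: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def record(self, stage: str, paths: Sequence[Path]) -> None:
        self.stages[stage] = {
            str(p.name): _sha256(p) for p in sorted(paths, key=str)
        }
        self.timestamps[stage] = time.time()

    def save(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def label_rois_from_truth(
    rois: Sequence[ROI],
    truth_boxes: dict[str, list[BBox]],
    truth_labels: dict[str, list[str]],
    iou_threshold: float = 0.5,
) -> list[Optional[str]]:
    """Transfer ground-truth phenotype labels to detected ROIs by best
    IoU match (the synthetic stand-in for human exemplar labeling)."""
    out: list[Optional[str]] = []
    for roi in rois:
        boxes = truth_boxes.get(roi.source_image, [])
        labels = truth_labels.get(roi.source_image, [])
        best, best_iou = None, iou_threshold
        for b, lab in zip(boxes, labels):
            v = iou(roi.bbox, b)
            if v >= best_iou:
                best, best_iou = lab, v
        out.append(best)
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full pipeline on a synthetic study.

    Stage order: generate -> QC -> detection -> ROI/feature extraction
    -> discovery (``mode="discover"``) or classification + per-variant
    scoring + LOF correlation (``mode="score"``).  A stage failure
    raises :class:`StageError` naming the stage.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid pipeline config: " + "; ".join(issues))
    out = Path(config.out_root)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(),
        versions={"maps_hcm": __version__, "numpy": np.__version__},
    )

    # ---- stage: generate -------------------------------------------------
    stage = "generate"
    try:
        data_root = out / "data"
        variant_dirs = {}
        lof_rows = []
        for v in config.synthetic.variants:
            spec = SyntheticSpec(
                **{
                    **config.synthetic.spec,
                    "phenotype_mix": v.resolve_mix(),
                    "seed": stable_seed(config.seed, "generate", v.name),
                }
            )
            vdir = data_root / v.name
            generate_dataset(spec, config.synthetic.fields_per_variant, vdir,
                             overwrite=True)
            variant_dirs[v.name] = vdir
            if v.lof_score is not None:
                lof_rows.append(dict(variant=v.name, lof_score=v.lof_score))
        lof_path = out / "lof.csv"
        pd.DataFrame(lof_rows, columns=["variant", "lof_score"]).to_csv(
            lof_path, index=False
        )
        manifest.record(stage, [lof_path] + sorted(data_root.rglob("*.csv")))
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: qc -------------------------------------------------------
    stage = "qc"
    try:
        qc_config = QCConfig(focus_channel=config.qc.channel,
                             threshold=config.qc.threshold)
        if qc_config.threshold is None:
            qc_config.threshold = _calibrate_qc(config, qc_config)
            logger.info("calibrated QC threshold: %g", qc_config.threshold)
        kept_fields: dict[str, list[FieldImage]] = {}
        truths: dict[str, tuple[dict, dict]] = {}
        qc_paths = []
        n_removed = 0
        for name, vdir in variant_dirs.items():
            fields, man, ann, labels = read_dataset(vdir)
            boxes_by_image: dict[str, list[BBox]] = {}
            labels_by_image: dict[str, list[str]] = {}
            for (row_a, row_l) in zip(ann.itertuples(), labels.itertuples()):
                fid = Path(row_a.image).stem
                boxes_by_image.setdefault(fid, []).append(
                    BBox(row_a.left, row_a.top, row_a.width, row_a.height)
                )
                labels_by_image.setdefault(fid, []).append(row_l.label)
            report_path = out / "qc" / f"{name}.csv"
            report_path.parent.mkdir(parents=True, exist_ok=True)
            kept, table = qc_batch(fields, qc_config, report_path)
            n_removed += len(fields) - len(kept)
            kept_fields[name] = kept
            truths[name] = (boxes_by_image, labels_by_image)
            qc_paths.append(report_path)
        logger.info("QC removed %d fields", n_removed)
        manifest.record(stage, qc_paths)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: detect ---------------------------------------------------
    stage = "detect"
    try:
        det_config = DetectorConfig(
            min_area=config.detect.min_area,
            max_area=config.detect.max_area,
            smooth_sigma=config.detect.smooth_sigma,
            pad_frac=config.detect.pad_frac,
            reporter_min_frac=config.detect.reporter_min_frac,
            iou_threshold=config.detect.iou_threshold,
        )
        detections = {
            name: {f.field_id: detect_cells(f, det_config) for f in fields}
            for name, fields in kept_fields.items()
        }
        det_paths = []
        for name, by_image in detections.items():
            rows = [
                dict(image=fid, score=d.score, left=d.bbox.left, top=d.bbox.top,
                     width=d.bbox.width, height=d.bbox.height)
                for fid, dets in by_image.items()
                for d in dets
            ]
            p = out / "detections" / f"{name}.csv"
            p.parent.mkdir(parents=True, exist_ok=True)
            pd.DataFrame(
                rows, columns=["image", "score", "left", "top", "width", "height"]
            ).to_csv(p, index=False)
            det_paths.append(p)
        manifest.record(stage, det_paths)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: features -------------------------------------------------
    stage = "features"
    try:
        if config.features.extractor == "vgg":
            extractor = build_extractor(
                ExtractorConfig(
                    weights_source=config.features.weights_source,
                    seed=stable_seed(config.seed, "extractor"),
                    input_size=config.features.input_size,
                    pool_grid=config.features.pool_grid,
                ),
                kind="vgg",
            )
            roi_size = config.features.input_size
        else:
            extractor = build_extractor(kind="radial")
            roi_size = 64
        rois_by_variant: dict[str, list[ROI]] = {}
        feats_by_variant: dict[str, np.ndarray] = {}
        for name, fields in kept_fields.items():
            rois = crop_rois(fields, detections[name], output_size=roi_size)
            rois_by_variant[name] = rois
            feats_by_variant[name] = extract_features(rois, extractor)
        manifest.record(stage, [])
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    if config.mode == "discover":
        _run_discovery(config, manifest, out, rois_by_variant, feats_by_variant)
        manifest.save(out / "manifest.json")
        return manifest

    # ---- stage: classify -------------------------------------------------
    stage = "classify"
    try:
        train_names = config.score.train_variants or list(variant_dirs)
        X_parts, y_parts, id_parts = [], [], []
        for name in train_names:
            boxes_by_image, labels_by_image = truths[name]
            labels = label_rois_from_truth(
                rois_by_variant[name], boxes_by_image, labels_by_image,
                config.detect.iou_threshold,
            )
            keep = [i for i, l in enumerate(labels) if l is not None]
            X_parts.append(feats_by_variant[name][keep])
            y_parts.extend(labels[i] for i in keep)
            id_parts.extend(f"{name}:{rois_by_variant[name][i].roi_id}" for i in keep)
        X = np.vstack(X_parts)
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message=".*examples.*")
            model, report = train_classifier(
                X, y_parts, ids=id_parts,
                feature_fingerprint=extractor.fingerprint,
                seed=stable_seed(config.seed, "classifier"),
            )
        report_path = out / "classifier_report.json"
        with open(report_path, "w") as fh:
            json.dump(
                {
                    "classes": list(report.classes),
                    "confusion": report.confusion.tolist(),
                    "precision": {k: float(v) for k, v in report.precision.items()},
                    "recall": {k: float(v) for k, v in report.recall.items()},
                    "n_per_class": report.n_per_class,
                },
                fh, indent=2,
            )
        manifest.record(stage, [report_path])
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: score ----------------------------------------------------
    stage = "score"
    try:
        scores = []
        for name in variant_dirs:
            feats = feats_by_variant[name]
            if len(feats) == 0:
                logger.warning("variant %s has no ROIs; skipped", name)
                continue
            labels, _ = classify_rois(model, feats, extractor.fingerprint)
            scores.append(score_variant(name, labels, class_set=model.classes))
        scores_path = out / "scores.csv"
        scores_table(scores).to_csv(scores_path, index=False)
        manifest.record(stage, [scores_path])
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # ---- stage: correlate ------------------------------------------------
    stage = "correlate"
    try:
        lof_csv = Path(config.score.lof_csv) if config.score.lof_csv else lof_path
        lof_df = pd.read_csv(lof_csv)
        corr_paths = []
        if len(lof_df) >= 3:
            result = correlate_lof(
                scores, lof_df,
                pairs_path=out / "correlation_pairs.csv",
                plot_path=out / "correlation.png",
            )
            corr_json = out / "correlation.json"
            with open(corr_json, "w") as fh:
                json.dump(
                    {"r": result.pearson_r, "p": result.p_value, "n": result.n,
                     "slope": result.slope, "intercept": result.intercept},
                    fh, indent=2,
                )
            corr_paths = [corr_json, out / "correlation_pairs.csv"]
        else:
            logger.info("fewer than 3 LOF-scored variants; correlation skipped")
        manifest.record(stage, corr_paths)
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    manifest.save(out / "manifest.json")
    return manifest


def _calibrate_qc(config: PipelineConfig, qc_config: QCConfig) -> float:
    """Generate a sharp+blurred calibration set and fit the threshold."""
    from .synthetic import generate_field

    n = config.synthetic.calibration_fields_per_class
    labeled = []
    for i in range(n):
        for blur, tag in ((0.0, "sharp"), (config.synthetic.calibration_blur_sigma, "blurry")):
            spec = SyntheticSpec(
                **{
                    **config.synthetic.spec,
                    "blur_sigma": blur,
                    "seed": stable_seed(config.seed, "qc-calib", tag, i),
                }
            )
            f, gt = generate_field(spec, field_id=f"calib_{tag}_{i}")
            labeled.append((f, gt.focus_label))
    return calibrate_threshold(labeled, qc_config)


def _run_discovery(
    config: PipelineConfig,
    manifest: RunManifest,
    out: Path,
    rois_by_variant: dict[str, list[ROI]],
    feats_by_variant: dict[str, np.ndarray],
) -> None:
    stage = "discover"
    try:
        all_rois = [r for name in sorted(rois_by_variant) for r in rois_by_variant[name]]
        X = np.vstack([feats_by_variant[name] for name in sorted(feats_by_variant)])
        seed = stable_seed(config.seed, "discover")
        embedding = reduce_features(X, seed=seed)
        retained = split_noise_cluster(
            embedding, noise_max_frac=config.discover.noise_max_frac, seed=seed
        )
        coords = embedding.coords30[retained]
        sweep = silhouette_sweep(
            coords, range(config.discover.k_min, config.discover.k_max + 1),
            seed=seed,
        )
        sub = np.full(embedding.n, -1)
        sub[retained] = subcluster(coords, sweep.chosen_k, seed=seed)
        embedding.subcluster = sub
        disc_dir = out / "discovery"
        disc_dir.mkdir(parents=True, exist_ok=True)
        embedding_table(embedding, all_rois).to_csv(
            disc_dir / "embedding.csv", index=False
        )
        centroid_exemplars(embedding, all_rois,
                           n_neighbors=config.discover.n_exemplars,
                           out_dir=disc_dir)
        with open(disc_dir / "sweep.json", "w") as fh:
            json.dump(
                {"k_values": sweep.k_values, "silhouettes": sweep.silhouettes,
                 "chosen_k": sweep.chosen_k,
                 "n_noise": int((~retained).sum())},
                fh, indent=2,
            )
        manifest.record(
            stage, [disc_dir / "embedding.csv", disc_dir / "sweep.json",
                    disc_dir / "exemplars.csv"]
        )
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc
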