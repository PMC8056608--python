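"""Cell detection, detection metrics, and training-data augmentation.

The detection stage places bounding boxes around transfected cells
(reporter-positive), ignoring nucleus-only distractors.  The original
pipeline delegated this to a trainable cloud model; here the detector is
a *contract* — field in, ranked detections out — realized by a classical
reference implementation (Otsu threshold on the brighter of the reporter
and target channels, connected components, area and reporter-support
filters).  A pluggable trainable backend can be substituted via
:class:`DetectorBackend`.

Evaluation is PASCAL-style: greedy score-ordered matching at an IoU
threshold, precision/recall, and all-points-interpolated average
precision (area under the precision-recall envelope).
"""

from __future__ import annotations

import abc
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from skimage import filters, measure

from .qc import add_gaussian_noise, compute_snr
from .types import Annotation, BBox, Detection, FieldImage, stable_seed


@dataclass
class DetectorConfig:
    """Reference-detector tunables (pixel areas at the native field scale)."""

    min_area: int = 150
    max_area: int = 30000
    smooth_sigma: float = 0.7  # pre-threshold Gaussian smoothing
    pad_frac: float = 0.15
    reporter_min_frac: float = 0.5
    reporter_offset: float = 0.08  # reporter support = reporter > median + offset
    score_scale: float = 0.15
    iou_threshold: float = 0.5


class DetectorBackend(abc.ABC):
    """Contract mirroring the role of a trainable detection endpoint."""

    @abc.abstractmethod
    def train(self, fields: Sequence[FieldImage], annotations: Sequence[Annotation]) -> "DetectorBackend":
        ...

    @abc.abstractmethod
    def predict(self, field: FieldImage) -> list[Detection]:
        ...


def detect_cells(field: FieldImage, config: Optional[DetectorConfig] = None) -> list[Detection]:
    """Reference detector: ranked detections of transfected cells.

    Candidate mask = Otsu threshold on max(reporter, target); connected
    components filtered by area and by reporter support (fraction of
    component pixels clearly above the reporter background), so
    nucleus-only distractors are excluded.  Deterministic.
    """
    config = config or DetectorConfig()
    reporter = field.channel("reporter").astype(np.float64)
    target = field.channel("target").astype(np.float64)
    h, w = reporter.shape
    signal = np.maximum(reporter, target)
    if config.smooth_sigma > 0:
        from scipy import ndimage

        signal = ndimage.gaussian_filter(signal, config.smooth_sigma)

    try:
        thresh = filters.threshold_otsu(signal)
    except ValueError:  # constant image
        return []
    mask = signal > thresh
    labeled = measure.label(mask, connectivity=2)

    reporter_support = reporter > (np.median(reporter) + config.reporter_offset)
    background = float(np.median(signal))

    detections: list[Detection] = []
    for region in measure.regionprops(labeled):
        if not (config.min_area <= region.area <= config.max_area):
            continue
        coords = region.coords
        support = float(reporter_support[coords[:, 0], coords[:, 1]].mean())
        if support < config.reporter_min_frac:
            continue
        r0, c0, r1, c1 = region.bbox
        pad_r = config.pad_frac * (r1 - r0)
        pad_c = config.pad_frac * (c1 - c0)
        top = max((r0 - pad_r) / h, 0.0)
        left = max((c0 - pad_c) / w, 0.0)
        bottom = min((r1 + pad_r) / h, 1.0)
        right = min((c1 + pad_c) / w, 1.0)
        contrast = float(signal[coords[:, 0], coords[:, 1]].mean()) - background
        score = float(np.clip(1.0 - np.exp(-max(contrast, 0.0) / config.score_scale), 0.0, 1.0))
        detections.append(
            Detection(
                bbox=BBox(left, top, right - left, bottom - top),
                score=score,
                image=field.field_id,
            )
        )
    detections.sort(key=lambda d: (-d.score, d.bbox.left, d.bbox.top))
    return detections


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two normalized boxes."""
    ix = max(0.0, min(a.right, b.right) - max(a.left, b.left))
    iy = max(0.0, min(a.bottom, b.bottom) - max(a.top, b.top))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def match_detections(
    preds: Sequence[Detection],
    truths: Sequence[BBox],
    iou_threshold: float = 0.5,
) -> tuple[list[bool], int]:
    """Greedy score-ordered matching of predictions to ground truth.

    Each truth box matches at most one prediction; a prediction is a TP
    iff its best available IoU >= ``iou_threshold``.  Score ties break
    toward the larger IoU.  Returns per-prediction TP flags (in the
    score-sorted order) and the count of unmatched truths.
    """
    order = sorted(range(len(preds)), key=lambda i: -preds[i].score)
    unmatched = set(range(len(truths)))
    flags: list[bool] = []
    for i in order:
        best_j, best_iou = None, 0.0
        for j in unmatched:
            v = iou(preds[i].bbox, truths[j])
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j is not None and best_iou >= iou_threshold:
            unmatched.discard(best_j)
            flags.append(True)
        else:
            flags.append(False)
    return flags, len(unmatched)


def precision_recall(flags: Sequence[bool], n_truth: int) -> tuple[float, float]:
    """Precision = TP/(TP+FP); recall = TP/n_truth; 0 with a warning when
    a denominator is 0."""
    if n_truth < 0:
        raise ValueError("n_truth must be >= 0")
    flags = list(flags)
    tp = sum(flags)
    if len(flags) == 0:
        warnings.warn("no detections: precision reported as 0")
        precision = 0.0
    else:
        precision = tp / len(flags)
    if n_truth == 0:
        warnings.warn("no ground truth: recall reported as 0")
        recall = 0.0
    else:
        recall = tp / n_truth
    return precision, recall


def average_precision(flags: Sequence[bool], n_truth: int) -> float:
    """All-points-interpolated area under the precision-recall curve.

    For each recall level reached, precision is replaced by the maximum
    precision at any recall >= that level (the PR envelope), and the
    envelope is integrated over recall.
    """
    if n_truth < 1:
        raise ValueError("average_precision requires n_truth >= 1")
    flags = np.asarray(list(flags), dtype=bool)
    if flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_truth
    # Envelope: running max of precision from the right.
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_recall = 0.0
    ap = 0.0
    for p, r in zip(envelope, recall):
        if r > prev_recall:
            ap += (r - prev_recall) * p
            prev_recall = r
    return float(ap)


def evaluate_detections(
    preds_by_image: dict[str, list[Detection]],
    truths_by_image: dict[str, list[BBox]],
    iou_threshold: float = 0.5,
) -> "DetectionMetrics":
    """Pool matches across fields (ranked globally by score) and compute
    precision, recall and average precision."""
    scored_flags: list[tuple[float, bool]] = []
    n_truth = 0
    for image, truths in truths_by_image.items():
        preds = preds_by_image.get(image, [])
        flags, _ = match_detections(preds, truths, iou_threshold)
        order = sorted(preds, key=lambda d: -d.score)
        scored_flags.extend((d.score, f) for d, f in zip(order, flags))
        n_truth += len(truths)
    scored_flags.sort(key=lambda t: -t[0])
    flags = [f for _, f in scored_flags]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall = precision_recall(flags, n_truth)
    ap = average_precision(flags, n_truth) if n_truth else 0.0
    return DetectionMetrics(
        precision=precision,
        recall=recall,
        average_precision=ap,
        iou_threshold=iou_threshold,
        n_truth=n_truth,
        n_pred=len(flags),
    )


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    average_precision: float
    iou_threshold: float
    n_truth: int
    n_pred: int


# ---------------------------------------------------------------------------
# Training augmentation: the fixed 14-transform scheme.
# ---------------------------------------------------------------------------

TRANSFORM_IDS = (
    "identity", "rot90", "rot180", "rot270", "flip_h", "flip_v",
    "rot90_flip_h", "brightness_up", "brightness_down", "contrast_up",
    "contrast_down", "invert", "noise_low", "noise_high",
)

_GEOMETRIC = {"identity", "rot90", "rot180", "rot270", "flip_h", "flip_v",
              "rot90_flip_h"}


def _transform_box(bbox: BBox, transform_id: str) -> BBox:
    l, t, w, h = bbox.left, bbox.top, bbox.width, bbox.height
    if transform_id == "rot90":  # counter-clockwise
        return BBox(t, 1 - l - w, h, w)
    if transform_id == "rot180":
        return BBox(1 - l - w, 1 - t - h, w, h)
    if transform_id == "rot270":
        return BBox(1 - t - h, l, h, w)
    if transform_id == "flip_h":
        return BBox(1 - l - w, t, w, h)
    if transform_id == "flip_v":
        return BBox(l, 1 - t - h, w, h)
    if transform_id == "rot90_flip_h":
        return _transform_box(_transform_box(bbox, "rot90"), "flip_h")
    return bbox


def augment_image(
    image: np.ndarray,
    annotations: Sequence[Annotation],
    transform_id: str,
    seed: int = 0,
) -> tuple[np.ndarray, list[Annotation]]:
    """Apply one registered transform to a (C, H, W) image and its boxes.

    Geometric transforms map boxes exactly; photometric transforms leave
    them untouched.  Noise transforms are deterministic given ``seed``.
    """
    if transform_id not in TRANSFORM_IDS:
        raise ValueError(
            f"unknown transform {transform_id!r}; valid ids: {TRANSFORM_IDS}"
        )
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = img[None]

    if transform_id == "identity":
        out = img.copy()
    elif transform_id == "rot90":
        out = np.rot90(img, 1, axes=(1, 2)).copy()
    elif transform_id == "rot180":
        out = np.rot90(img, 2, axes=(1, 2)).copy()
    elif transform_id == "rot270":
        out = np.rot90(img, 3, axes=(1, 2)).copy()
    elif transform_id == "flip_h":
        out = img[:, :, ::-1].copy()
    elif transform_id == "flip_v":
        out = img[:, ::-1, :].copy()
    elif transform_id == "rot90_flip_h":
        out = np.rot90(img, 1, axes=(1, 2))[:, :, ::-1].copy()
    elif transform_id == "brightness_up":
        out = np.clip(img + 0.15, 0.0, 1.0)
    elif transform_id == "brightness_down":
        out = np.clip(img - 0.15, 0.0, 1.0)
    elif transform_id == "contrast_up":
        out = np.clip((img - 0.5) * 1.5 + 0.5, 0.0, 1.0)
    elif transform_id == "contrast_down":
        out = np.clip((img - 0.5) * 0.6 + 0.5, 0.0, 1.0)
    elif transform_id == "invert":
        out = 1.0 - img
    elif transform_id == "noise_low":
        out = add_gaussian_noise(img, multiplier=1.0, base_sigma=0.02, seed=seed)
    else:  # noise_high
        out = add_gaussian_noise(img, multiplier=1.0, base_sigma=0.05, seed=seed)

    if transform_id in _GEOMETRIC:
        new_anns = [
            Annotation(a.image, a.tag, _transform_box(a.bbox, transform_id))
            for a in annotations
        ]
    else:
        new_anns = list(annotations)
    return out.astype(np.float32), new_anns


def augment_dataset(dataset_dir: str | Path, out_dir: str | Path,
                    seed: int = 0, overwrite: bool = False) -> dict:
    """Expand a dataset by the 14-transform scheme (identity included):
    every source image yields exactly 14 outputs, and the annotation CSV
    is regenerated with transformed boxes."""
    from .synthetic import read_field_tiff, write_field_tiff
    from .types import FieldImage

    dataset_dir = Path(dataset_dir)
    out = Path(out_dir)
    ann_path = dataset_dir / "annotations.csv"
    if not ann_path.exists():
        raise FileNotFoundError(f"annotation CSV not found: {ann_path}")
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty")
    out.mkdir(parents=True, exist_ok=True)

    df = pd.read_csv(ann_path)
    images = sorted(p.name for p in dataset_dir.glob("*.tif"))
    rows = []
    n_out = 0
    for idx, fname in enumerate(images):
        field = read_field_tiff(dataset_dir / fname)
        anns = [
            Annotation(fname, r.tag, BBox(r.left, r.top, r.width, r.height))
            for r in df[df["image"] == fname].itertuples()
        ]
        for tid in TRANSFORM_IDS:
            timg, tanns = augment_image(
                field.image, anns, tid, seed=stable_seed(seed, fname, tid)
            )
            out_name = f"{Path(fname).stem}__{tid}.tif"
            write_field_tiff(out / out_name, FieldImage(timg, field.channels, out_name))
            n_out += 1
            for a in tanns:
                rows.append(
                    dict(image=out_name, tag=a.tag, left=a.bbox.left,
                         top=a.bbox.top, width=a.bbox.width, height=a.bbox.height)
                )
    pd.DataFrame(
        rows, columns=["image", "tag", "left", "top", "width", "height"]
    ).to_csv(out / "annotations.csv", index=False, float_format="%.17g")
    return {"n_source": len(images), "n_output": n_out,
            "transforms": list(TRANSFORM_IDS)}


def noise_sweep(
    fields: Sequence[FieldImage],
    truths_by_image: dict[str, list[BBox]],
    multipliers: Sequence[float] = (0.0, 1.0, 2.0, 3.0),
    config: Optional[DetectorConfig] = None,
    base_sigma: float = 0.06,
    seed: int = 0,
) -> pd.DataFrame:
    """Detector robustness sweep over noise multipliers.

    For each multiplier, every field is corrupted with additive Gaussian
    noise (fixed per-field seeds), detections are evaluated against the
    clean ground truth, and the mean whole-image SNR is recorded.
    """
    if len(multipliers) == 0:
        raise ValueError("noise_sweep requires at least one multiplier")
    config = config or DetectorConfig()
    rows = []
    for m in multipliers:
        preds = {}
        snrs = []
        for f in fields:
            noisy = add_gaussian_noise(
                f.image, multiplier=m, base_sigma=base_sigma,
                seed=stable_seed(seed, f.field_id, "noise"),
            )
            noisy_field = FieldImage(noisy, f.channels, f.field_id)
            preds[f.field_id] = detect_cells(noisy_field, config)
            snrs.append(compute_snr(noisy).snr)
        metrics = evaluate_detections(preds, truths_by_image, config.iou_threshold)
        rows.append(
            dict(multiplier=m, mean_snr=float(np.mean(snrs)),
                 precision=metrics.precision, recall=metrics.recall,
                 average_precision=metrics.average_precision)
        )
    return pd.DataFrame(rows)
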