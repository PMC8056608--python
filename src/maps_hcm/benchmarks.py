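"""Standard synthetic benchmarks for the QC and detection stages.

These drive the validation experiments end to end: generate fields at
the study conditions, run the stage under test, and measure performance
against the generator's ground truth.  Both the test suite and the
reproduction script call these functions.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import pandas as pd

from .detection import (
    DetectionMetrics,
    DetectorConfig,
    detect_cells,
    evaluate_detections,
    noise_sweep,
)
from .qc import QCConfig, QCMetrics, calibrate_threshold, qc_batch, qc_metrics
from .synthetic import SyntheticSpec, generate_field
from .types import BBox, FieldImage, stable_seed


def _field_pairs(spec: SyntheticSpec, n: int, blur_sigma: float, seed: int,
                 tag: str) -> list[tuple[FieldImage, bool]]:
    """n sharp + n blurred fields with their focus labels."""
    out = []
    for i in range(n):
        for blur, sub in ((0.0, "sharp"), (blur_sigma, "blurry")):
            fspec = dataclasses.replace(
                spec, blur_sigma=blur, seed=stable_seed(seed, tag, sub, i)
            )
            field, truth = generate_field(fspec, field_id=f"{tag}_{sub}_{i:03d}")
            out.append((field, truth.focus_label))
    return out


def qc_focus_benchmark(
    seed: int,
    n_eval: int = 50,
    n_calib: int = 20,
    blur_sigma: float = 5.0,
    spec: SyntheticSpec | None = None,
) -> QCMetrics:
    """Focus-QC discrimination benchmark.

    Calibrates the threshold on a disjoint ``n_calib``+``n_calib`` set,
    then scores ``n_eval`` in-focus and ``n_eval`` blurred fields;
    returns the confusion metrics (positives = in-focus retained).
    """
    spec = spec or SyntheticSpec()
    config = QCConfig()
    calib = _field_pairs(spec, n_calib, blur_sigma, seed, "calib")
    config.threshold = calibrate_threshold(calib, config)
    eval_set = _field_pairs(spec, n_eval, blur_sigma, seed, "eval")
    _, table = qc_batch([f for f, _ in eval_set], config)
    return qc_metrics(list(table["keep"]), [lab for _, lab in eval_set])


def detection_test_set(
    seed: int, n_fields: int = 20, spec: SyntheticSpec | None = None
) -> tuple[list[FieldImage], dict[str, list[BBox]]]:
    """Noise-free fields with ground-truth boxes (transfected cells plus
    non-transfected distractors)."""
    spec = spec or SyntheticSpec()
    fields, truths = [], {}
    for i in range(n_fields):
        fspec = dataclasses.replace(
            spec, noise_multiplier=0.0, seed=stable_seed(seed, "det", i)
        )
        field, truth = generate_field(fspec, field_id=f"det_{i:03d}")
        fields.append(field)
        truths[field.field_id] = [a.bbox for a in truth.boxes]
    return fields, truths


def detection_benchmark(
    seed: int,
    n_fields: int = 20,
    config: DetectorConfig | None = None,
) -> DetectionMetrics:
    """Clean-field detection benchmark: run the reference detector and
    evaluate precision/recall/AP at IoU 0.5 against ground truth."""
    config = config or DetectorConfig()
    fields, truths = detection_test_set(seed, n_fields)
    preds = {f.field_id: detect_cells(f, config) for f in fields}
    return evaluate_detections(preds, truths, config.iou_threshold)


def noise_robustness_benchmark(
    seed: int,
    n_fields: int = 10,
    multipliers: Sequence[float] = (0.0, 1.0, 2.0, 3.0),
) -> pd.DataFrame:
    """Detection robustness sweep on the standard clean test set."""
    fields, truths = detection_test_set(seed, n_fields)
    return noise_sweep(fields, truths, multipliers, seed=seed)
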