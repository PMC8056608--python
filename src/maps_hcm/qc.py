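"""Image quality control: variance-of-Laplacian focus measures.

Automated microscopes occasionally acquire out-of-focus fields, and
aberrations such as air bubbles, foreign fibers or grossly overexposed
cells carry strong artificial edges that corrupt edge-based focus
statistics.  This module scores each field with the variance of its
Laplacian response — high for sharp fields, low for blurry ones — after
suppressing artifact edges (grayscale dilation against bubble rings;
mask-and-blur in-fill against saturated blobs), then keeps or removes
fields against a calibrated threshold.

Metric orientation follows the screening convention: *positives are
in-focus fields that were retained*; true negatives are blurry fields
correctly removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology

from .types import FieldImage, SATURATION_VALUE

#: 4-neighbour Laplacian kernel.
LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)


@dataclass
class QCConfig:
    """Tunables for the focus-QC stage."""

    focus_channel: str = "nucleus"
    threshold: Optional[float] = None
    suppress_bubbles: bool = True
    suppress_overexposed: bool = True
    bubble_selem_size: int = 3
    bubble_iterations: int = 1
    saturation_fraction: float = 0.98
    overexposed_dilation: int = 7
    overexposed_blur_sigma: float = 15.0
    suppression_order: tuple[str, ...] = ("bubbles", "overexposed")


@dataclass
class FocusReport:
    field_id: str
    raw_variance: float
    focus_measure: float
    bubbles_suppressed: bool
    overexposure_suppressed: bool
    threshold: float
    keep: bool


@dataclass
class SNRStats:
    mean_pixel: float
    std_pixel: float
    snr: float
    noise_multiplier: float = float("nan")


@dataclass
class QCMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float


def laplacian_variance(image: np.ndarray) -> float:
    """Variance of the 4-neighbour Laplacian response over the valid
    (border-free) interior of a single-channel image.

    Population variance; a constant image scores exactly 0.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] < 3 or image.shape[1] < 3:
        raise ValueError(f"image must be 2-D and at least 3x3, got {image.shape}")
    full = ndimage.convolve(image, LAPLACIAN_KERNEL, mode="constant")
    valid = full[1:-1, 1:-1]
    return float(valid.var())


def suppress_bubbles(
    image: np.ndarray, selem_size: int = 3, iterations: int = 1
) -> np.ndarray:
    """Grayscale dilation that collapses thin bright rings (air-bubble
    edges) into blobs with low interior gradient."""
    if selem_size < 1 or iterations < 0:
        raise ValueError("selem_size must be >= 1 and iterations >= 0")
    out = np.asarray(image, dtype=np.float64)
    footprint = morphology.footprint_rectangle((selem_size, selem_size))
    for _ in range(iterations):
        out = morphology.dilation(out, footprint)
    return out


def suppress_overexposed(
    image: np.ndarray,
    saturation_value: float = SATURATION_VALUE,
    saturation_fraction: float = 0.98,
    dilation: int = 7,
    blur_sigma: float = 15.0,
) -> np.ndarray:
    """Replace saturated regions with a heavily blurred in-fill.

    Pixels at or above ``saturation_fraction * saturation_value`` are
    masked, the mask is dilated, and masked pixels are replaced by a
    Gaussian-blurred copy of the image.  Images without saturated pixels
    come back bit-identical.
    """
    img = np.asarray(image, dtype=np.float64)
    mask = img >= saturation_fraction * saturation_value
    if not mask.any():
        return img.copy()
    mask = morphology.dilation(mask, morphology.disk(dilation))
    blurred = ndimage.gaussian_filter(img, blur_sigma)
    out = img.copy()
    out[mask] = blurred[mask]
    return out


def focus_score(field: FieldImage, config: QCConfig) -> FocusReport:
    """Score one field: extract the focus channel, suppress artifact
    edges, compute the focus measure and decide keep/remove."""
    plane = field.channel(config.focus_channel)
    raw = laplacian_variance(plane)
    processed = np.asarray(plane, dtype=np.float64)
    overexposure_changed = False
    for step in config.suppression_order:
        if step == "bubbles" and config.suppress_bubbles:
            processed = suppress_bubbles(
                processed, config.bubble_selem_size, config.bubble_iterations
            )
        elif step == "overexposed" and config.suppress_overexposed:
            before = processed
            processed = suppress_overexposed(
                processed,
                saturation_fraction=config.saturation_fraction,
                dilation=config.overexposed_dilation,
                blur_sigma=config.overexposed_blur_sigma,
            )
            overexposure_changed = not np.array_equal(before, processed)
    measure = laplacian_variance(processed)
    threshold = config.threshold if config.threshold is not None else float("nan")
    keep = bool(measure >= threshold) if np.isfinite(threshold) else False
    return FocusReport(
        field_id=field.field_id,
        raw_variance=raw,
        focus_measure=measure,
        bubbles_suppressed=config.suppress_bubbles,
        overexposure_suppressed=overexposure_changed,
        threshold=threshold,
        keep=keep,
    )


def choose_threshold(measures: Sequence[float], labels: Sequence[bool]) -> float:
    """Exhaustive scan for the cut maximizing accuracy (keep iff measure
    >= threshold); accuracy ties break toward the larger (stricter)
    threshold.  Candidates are the observed measures themselves."""
    measures = np.asarray(measures, dtype=float)
    labels = np.asarray([bool(l) for l in labels])
    if labels.all() or not labels.any():
        raise ValueError("calibration requires both in-focus and blurry fields")
    best_t, best_acc = None, -1.0
    for t in np.unique(measures):
        keep = measures >= t
        acc = float((keep == labels).mean())
        if acc > best_acc or (acc == best_acc and t > best_t):
            best_t, best_acc = float(t), acc
    if len(np.unique(measures)) == 1:
        warnings.warn(
            "focus measures are identical across classes; threshold is degenerate"
        )
    return best_t


def calibrate_threshold(
    labeled_fields: Sequence[tuple[FieldImage, bool]],
    config: Optional[QCConfig] = None,
) -> float:
    """Choose the focus-measure cut maximizing accuracy on labeled fields.

    ``labeled_fields`` pairs each field with its focus label (True =
    in focus).
    """
    config = config or QCConfig()
    measures = [focus_score(f, config).focus_measure for f, _ in labeled_fields]
    return choose_threshold(measures, [lab for _, lab in labeled_fields])


def qc_metrics(decisions: Sequence[bool], truth: Sequence[bool]) -> QCMetrics:
    """Confusion-matrix metrics with in-focus-retained as the positive
    class: TP = in-focus kept, TN = blurry removed."""
    decisions = np.asarray(decisions, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if decisions.size == 0:
        raise ValueError("qc_metrics requires at least one decision")
    if decisions.shape != truth.shape:
        raise ValueError("decisions and truth must have equal length")
    tp = int((decisions & truth).sum())
    fp = int((decisions & ~truth).sum())
    tn = int((~decisions & ~truth).sum())
    fn = int((~decisions & truth).sum())
    total = tp + fp + tn + fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return QCMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / total,
        precision=precision,
        recall=recall,
    )


def compute_snr(image: np.ndarray, noise_multiplier: float = float("nan")) -> SNRStats:
    """Mean pixel value over population standard deviation of pixel values.

    A constant image has zero standard deviation; its SNR is reported as
    +inf with a warning.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot compute SNR of an empty image")
    mean = float(arr.mean())
    std = float(arr.std())
    if std == 0.0:
        warnings.warn("constant image: SNR reported as +inf")
        snr = float("inf")
    else:
        snr = mean / std
    return SNRStats(mean_pixel=mean, std_pixel=std, snr=snr,
                    noise_multiplier=noise_multiplier)


def add_gaussian_noise(
    image: np.ndarray,
    multiplier: float,
    base_sigma: float = 0.06,
    seed: int = 0,
) -> np.ndarray:
    """Add i.i.d. Gaussian noise of sigma = multiplier * base_sigma,
    clipped to the dtype range; deterministic given the seed."""
    if multiplier < 0:
        raise ValueError(f"multiplier must be >= 0, got {multiplier}")
    arr = np.asarray(image)
    if multiplier == 0:
        return arr.copy()
    rng = np.random.default_rng(seed)
    noisy = arr.astype(np.float64) + rng.normal(0.0, multiplier * base_sigma, arr.shape)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return np.clip(np.rint(noisy), info.min, info.max).astype(arr.dtype)
    return np.clip(noisy, 0.0, SATURATION_VALUE).astype(arr.dtype)


def qc_batch(
    fields: Sequence[FieldImage],
    config: QCConfig,
    report_path: Optional[str | Path] = None,
) -> tuple[list[FieldImage], pd.DataFrame]:
    """Apply ``focus_score`` to each field; return kept fields (input
    order preserved) and the per-field report table."""
    if len(fields) == 0:
        raise ValueError("qc_batch requires at least one field")
    if config.threshold is None:
        raise ValueError(
            "QC threshold is not set: calibrate with calibrate_threshold "
            "or provide an explicit threshold"
        )
    reports = []
    for f in fields:
        try:
            reports.append(focus_score(f, config))
        except Exception as exc:
            raise RuntimeError(f"QC failed on field {f.field_id!r}: {exc}") from exc
    table = pd.DataFrame(
        [
            dict(
                image=r.field_id,
                raw_variance=r.raw_variance,
                focus_measure=r.focus_measure,
                threshold=r.threshold,
                keep=r.keep,
                bubbles_suppressed=r.bubbles_suppressed,
                overexposure_suppressed=r.overexposure_suppressed,
            )
            for r in reports
        ]
    )
    if report_path is not None:
        table.to_csv(report_path, index=False)
    kept = [f for f, r in zip(fields, reports) if r.keep]
    return kept, table
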