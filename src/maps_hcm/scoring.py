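"""Supervised phenotype scoring and variant-level analytics.

A phenotype classifier is trained on human-labeled exemplar classes
(here: feature vectors of labeled ROIs), every detected cell is scored,
per-variant localization distributions are aggregated, and the nuclear
fraction — the proportion of a variant's cells classified "nuclear",
used as the loss-of-function proxy — is correlated against an
orthogonal per-variant LOF score table (Pearson r with a two-sided
t-transform p-value).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

#: Advisory floor on per-class training examples.
MIN_CLASS_EXAMPLES = 100


@dataclass
class ClassifierConfig:
    holdout_fraction: float = 0.2
    max_iter: int = 2000
    C: float = 1.0


@dataclass
class PhenotypeModel:
    """A trained classifier handle with its provenance fingerprint."""

    estimator: LogisticRegression
    classes: tuple[str, ...]
    feature_fingerprint: dict
    train_ids: tuple[str, ...]
    holdout_ids: tuple[str, ...]
    seed: int

    @property
    def fingerprint(self) -> dict:
        return {
            "classes": list(self.classes),
            "n_train": len(self.train_ids),
            "n_holdout": len(self.holdout_ids),
            "seed": self.seed,
            "features": self.feature_fingerprint,
        }


@dataclass
class ClassifierReport:
    classes: tuple[str, ...]
    confusion: np.ndarray  # rows = truth, cols = predicted
    precision: dict[str, float]
    recall: dict[str, float]
    n_per_class: dict[str, int]


@dataclass
class VariantScore:
    variant: str
    n_cells: int
    class_distribution: dict[str, float]
    nuclear_fraction: float


@dataclass
class CorrelationResult:
    pearson_r: float
    p_value: float
    n: int
    slope: float = float("nan")
    intercept: float = float("nan")


def train_classifier(
    features: np.ndarray,
    labels: Sequence[str],
    ids: Optional[Sequence[str]] = None,
    feature_fingerprint: Optional[dict] = None,
    config: Optional[ClassifierConfig] = None,
    seed: int = 0,
) -> tuple[PhenotypeModel, "ClassifierReport"]:
    """Train the reference phenotype classifier.

    A multinomial logistic-regression model fit on feature vectors with
    a stratified, seeded holdout split.  Classes are kept in sorted
    (alphabetical) order so prediction ties resolve deterministically.
    Warns when a class has fewer than 100 examples.  Returns the model
    handle and its holdout evaluation report.
    """
    config = config or ClassifierConfig()
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray([str(l) for l in labels])
    if ids is None:
        ids = [str(i) for i in range(len(labels))]
    ids = np.asarray([str(i) for i in ids])
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"training requires >= 2 classes, got {list(classes)}")
    for cls, cnt in zip(classes, counts):
        if cnt == 0:  # pragma: no cover - unique() cannot yield 0
            raise ValueError(f"class {cls!r} has no examples")
        if cnt < MIN_CLASS_EXAMPLES:
            warnings.warn(
                f"class {cls!r} has {cnt} examples (< {MIN_CLASS_EXAMPLES})"
            )
    idx = np.arange(len(labels))
    train_idx, hold_idx = train_test_split(
        idx, test_size=config.holdout_fraction, stratify=labels,
        random_state=seed,
    )
    est = LogisticRegression(C=config.C, max_iter=config.max_iter,
                             random_state=seed)
    est.fit(features[train_idx], labels[train_idx])
    model = PhenotypeModel(
        estimator=est,
        classes=tuple(str(c) for c in est.classes_),
        feature_fingerprint=feature_fingerprint or {},
        train_ids=tuple(ids[train_idx]),
        holdout_ids=tuple(ids[hold_idx]),
        seed=seed,
    )
    report = evaluate_classifier(
        model, features[hold_idx], labels[hold_idx], ids[hold_idx]
    )
    return model, report


def evaluate_classifier(
    model: PhenotypeModel,
    features: np.ndarray,
    labels: Sequence[str],
    ids: Optional[Sequence[str]] = None,
) -> ClassifierReport:
    """Per-class precision/recall from the holdout confusion matrix.

    Holdout identity is enforced: an id that also appears in the model's
    training set is an error.
    """
    if ids is not None:
        overlap = set(map(str, ids)) & set(model.train_ids)
        if overlap:
            raise ValueError(
                f"holdout overlaps training set: {sorted(overlap)[:5]}"
            )
    preds = model.estimator.predict(np.asarray(features, dtype=np.float64))
    labels = np.asarray([str(l) for l in labels])
    cm = confusion_matrix(labels, preds, labels=list(model.classes))
    return report_from_confusion(cm, model.classes)


def report_from_confusion(cm: np.ndarray, classes: Sequence[str]) -> ClassifierReport:
    """Per-class precision/recall from a confusion matrix whose rows are
    truth and columns predictions."""
    cm = np.asarray(cm)
    classes = tuple(str(c) for c in classes)
    precision, recall, n_per_class = {}, {}, {}
    for i, cls in enumerate(classes):
        col = cm[:, i].sum()
        row = cm[i, :].sum()
        precision[cls] = cm[i, i] / col if col else 0.0
        recall[cls] = cm[i, i] / row if row else 0.0
        n_per_class[cls] = int(row)
    return ClassifierReport(
        classes=classes, confusion=cm,
        precision=precision, recall=recall, n_per_class=n_per_class,
    )


def classify_rois(
    model: PhenotypeModel,
    features: np.ndarray,
    feature_fingerprint: Optional[dict] = None,
) -> tuple[list[str], np.ndarray]:
    """Predict a label and probability vector per ROI.

    The feature fingerprint must match the one the model was trained
    with.  The argmax label breaks exact probability ties toward the
    alphabetically first class (classes are stored sorted).
    """
    if feature_fingerprint is not None and model.feature_fingerprint:
        if feature_fingerprint != model.feature_fingerprint:
            raise ValueError(
                "feature fingerprint mismatch between model and input: "
                f"{feature_fingerprint} vs {model.feature_fingerprint}"
            )
    probs = model.estimator.predict_proba(np.asarray(features, dtype=np.float64))
    # np.argmax takes the first maximum; classes are alphabetically sorted.
    labels = [model.classes[i] for i in np.argmax(probs, axis=1)]
    return labels, probs


def score_variant(variant: str, labels: Sequence[str],
                  class_set: Optional[Sequence[str]] = None) -> VariantScore:
    """Empirical distribution of phenotype labels for one variant."""
    labels = [str(l) for l in labels]
    if not labels:
        raise ValueError(f"variant {variant!r} has no labeled cells")
    classes = sorted(class_set) if class_set is not None else sorted(set(labels))
    n = len(labels)
    dist = {c: labels.count(c) / n for c in classes}
    return VariantScore(
        variant=variant,
        n_cells=n,
        class_distribution=dist,
        nuclear_fraction=dist.get("nuclear", 0.0),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("pearson requires n >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        raise ValueError("zero variance in x or y")
    return float((xd * yd).sum() / denom)


def pearson_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation via the exact
    t-transform: t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom."""
    if n < 3:
        raise ValueError("pearson_pvalue requires n >= 3")
    if abs(r) >= 1.0:
        warnings.warn("|r| = 1: p-value reported as 0")
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def correlate_lof(
    scores: Sequence[VariantScore],
    lof_table: dict[str, float] | pd.DataFrame,
    pairs_path: Optional[str | Path] = None,
    plot_path: Optional[str | Path] = None,
) -> CorrelationResult:
    """Correlate per-variant nuclear fraction against LOF scores.

    Inner join on variant id (case-sensitive exact match); unjoined ids
    are logged, never silently dropped.  Emits the joined pairs CSV and
    an optional scatter plot with the ordinary-least-squares best-fit
    line.
    """
    if isinstance(lof_table, pd.DataFrame):
        if not {"variant", "lof_score"} <= set(lof_table.columns):
            raise ValueError("LOF table needs columns variant, lof_score")
        lof = dict(zip(lof_table["variant"].astype(str), lof_table["lof_score"]))
    else:
        lof = {str(k): float(v) for k, v in lof_table.items()}
    if len(lof) != len(set(lof)):  # pragma: no cover - dict keys unique
        raise ValueError("duplicate variant ids in LOF table")

    score_ids = [s.variant for s in scores]
    joined = [(s.variant, s.nuclear_fraction, lof[s.variant])
              for s in scores if s.variant in lof]
    missing_scores = sorted(set(score_ids) - set(lof))
    missing_lof = sorted(set(lof) - set(score_ids))
    for name, items in [("LOF table", missing_scores), ("scores", missing_lof)]:
        if items:
            logger.warning("variants missing from %s dropped from join: %s",
                           name, items)
    if len(joined) < 3:
        raise ValueError(
            f"need >= 3 joined variants, got {len(joined)}; "
            f"unjoined: scores={missing_scores}, lof={missing_lof}"
        )
    frac = np.array([j[1] for j in joined])
    lofv = np.array([j[2] for j in joined])
    r = pearson(frac, lofv)
    p = pearson_pvalue(r, len(joined))
    slope, intercept = np.polyfit(lofv, frac, 1)

    pairs = pd.DataFrame(joined, columns=["variant", "nuclear_fraction", "lof_score"])
    if pairs_path is not None:
        pairs.to_csv(pairs_path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(lofv, frac)
        xs = np.linspace(lofv.min(), lofv.max(), 50)
        ax.plot(xs, slope * xs + intercept, "r-",
                label=f"r={r:.3f}, p={p:.3g}")
        for v, xi, yi in zip(pairs["variant"], lofv, frac):
            ax.annotate(v, (xi, yi), fontsize=6)
        ax.set_xlabel("LOF score")
        ax.set_ylabel("fraction of cells with nuclear localization")
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return CorrelationResult(pearson_r=r, p_value=p, n=len(joined),
                             slope=float(slope), intercept=float(intercept))


def scores_table(scores: Sequence[VariantScore]) -> pd.DataFrame:
    """Export `variant,n_cells,frac_nuclear,frac_nuclear_excluded,frac_diffuse`."""
    return pd.DataFrame(
        [
            dict(
                variant=s.variant,
                n_cells=s.n_cells,
                frac_nuclear=s.class_distribution.get("nuclear", 0.0),
                frac_nuclear_excluded=s.class_distribution.get("nuclear_excluded", 0.0),
                frac_diffuse=s.class_distribution.get("diffuse", 0.0),
            )
            for s in scores
        ]
    )
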