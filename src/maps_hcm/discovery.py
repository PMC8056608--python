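"""Unsupervised phenotype discovery.

Detected cells are cropped to ROIs, embedded as feature vectors
(:mod:`maps_hcm.features`), reduced with PCA followed by UMAP (30
dimensions for clustering, a separate 2-D run for visualization), split
into a retained cluster and a small noise cluster, subclustered with
spectral clustering at the cluster count chosen by the mean silhouette
coefficient, and summarized by per-cluster centroid exemplars for human
labeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import SpectralClustering
from sklearn.decomposition import PCA

from .types import BBox, Detection, FieldImage, ROI


@dataclass
class ReduceConfig:
    """Dimensionality-reduction hyperparameters.

    Defaults follow the preservation-of-global-structure recipe:
    PCA pre-reduction to 500 components, then UMAP with
    ``n_neighbors=100``, ``min_dist=0.1`` and the Chebyshev metric.
    """

    pca_components: int = 500
    umap_components: int = 30
    n_neighbors: int = 100
    min_dist: float = 0.1
    metric: str = "chebyshev"


@dataclass
class ReducedEmbedding:
    """Per-ROI reduced coordinates plus cluster/noise assignments."""

    coords30: np.ndarray
    coords2: np.ndarray
    top_cluster: Optional[np.ndarray] = None  # True = retained, False = noise
    subcluster: Optional[np.ndarray] = None  # -1 for noise rows

    def __post_init__(self) -> None:
        if self.coords2 is not None and len(self.coords2) != len(self.coords30):
            raise ValueError("coords30 and coords2 must have equal row counts")

    @property
    def n(self) -> int:
        return len(self.coords30)


@dataclass
class ClusterSweep:
    k_values: list[int]
    silhouettes: list[float]
    chosen_k: int


def crop_rois(
    fields: Sequence[FieldImage],
    detections_by_image: dict[str, list[Detection]],
    pad: float = 0.0,
    output_size: Optional[int] = None,
) -> list[ROI]:
    """Crop padded detection boxes into ROIs.

    Boxes are expanded by ``pad`` (fraction of box size), clipped at the
    image border, and optionally resized to ``output_size``; zero-area
    boxes after clipping are skipped with a warning.
    """
    from skimage.transform import resize

    by_id = {f.field_id: f for f in fields}
    rois: list[ROI] = []
    for image_id, dets in detections_by_image.items():
        if image_id not in by_id:
            raise KeyError(f"detections reference unknown field {image_id!r}")
        f = by_id[image_id]
        h, w = f.shape
        for k, det in enumerate(dets):
            b = det.bbox
            l = max(b.left - pad * b.width, 0.0)
            t = max(b.top - pad * b.height, 0.0)
            r = min(b.right + pad * b.width, 1.0)
            bot = min(b.bottom + pad * b.height, 1.0)
            r0, r1 = int(np.floor(t * h)), int(np.ceil(bot * h))
            c0, c1 = int(np.floor(l * w)), int(np.ceil(r * w))
            patch = f.image[:, max(r0, 0) : r1, max(c0, 0) : c1]
            if patch.shape[1] == 0 or patch.shape[2] == 0:
                warnings.warn(f"skipping zero-area ROI {image_id}:{k}")
                continue
            if output_size is not None:
                patch = resize(
                    patch, (patch.shape[0], output_size, output_size),
                    order=1, mode="edge", anti_aliasing=False, preserve_range=True,
                ).astype(np.float32)
            rois.append(
                ROI(pixels=patch, source_image=image_id, bbox=b,
                    roi_id=f"{image_id}:{k}")
            )
    return rois


def reduce_features(
    matrix: np.ndarray,
    config: Optional[ReduceConfig] = None,
    seed: int = 0,
) -> ReducedEmbedding:
    """PCA to <=500 components, then UMAP to 30 dimensions for clustering
    and an independent 2-D UMAP run (same hyperparameters) for plots.

    ``n_neighbors`` is clamped to n-1 with a warning for small inputs.
    """
    import umap

    config = config or ReduceConfig()
    matrix = np.asarray(matrix, dtype=np.float32)
    n, f = matrix.shape
    if n < 3:
        raise ValueError(f"need at least 3 samples to reduce, got {n}")

    n_pca = min(config.pca_components, n - 1, f)
    reduced = PCA(n_components=n_pca, random_state=seed).fit_transform(matrix)

    n_neighbors = config.n_neighbors
    if n_neighbors > n - 1:
        warnings.warn(
            f"n_neighbors={n_neighbors} exceeds n-1={n - 1}; clamping"
        )
        n_neighbors = n - 1

    def _run(n_components: int) -> np.ndarray:
        return umap.UMAP(
            n_components=min(n_components, max(n - 2, 1)),
            n_neighbors=n_neighbors,
            min_dist=config.min_dist,
            metric=config.metric,
            random_state=seed,
            init="random" if n <= config.umap_components + 2 else "spectral",
        ).fit_transform(reduced)

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", message=".*n_jobs.*")
        coords30 = _run(config.umap_components)
        coords2 = _run(2)
    return ReducedEmbedding(coords30=np.asarray(coords30, np.float32),
                            coords2=np.asarray(coords2, np.float32))


def subcluster(coords: np.ndarray, k: int, seed: int = 0,
               n_neighbors: int = 10) -> np.ndarray:
    """Spectral clustering with a nearest-neighbors affinity; label ids
    are remapped to descending cluster size for stability."""
    coords = np.asarray(coords)
    n = len(coords)
    if not 2 <= k <= n - 1:
        raise ValueError(f"k must lie in [2, {n - 1}], got {k}")
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*not fully connected.*")
        labels = SpectralClustering(
            n_clusters=k,
            affinity="nearest_neighbors",
            n_neighbors=min(n_neighbors, n - 1),
            assign_labels="kmeans",
            random_state=seed,
        ).fit_predict(coords)
    # Stable relabeling: 0 = largest cluster; ties by original label id.
    sizes = np.bincount(labels, minlength=k)
    order = sorted(range(k), key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels], dtype=int)


def split_noise_cluster(
    embedding: ReducedEmbedding,
    noise_max_frac: float = 0.2,
    seed: int = 0,
) -> np.ndarray:
    """Split the embedding into two spectral clusters and flag the
    smaller as candidate noise.

    The smaller cluster is auto-discarded (flag False) only when its
    fraction is below ``noise_max_frac``; otherwise both groups are
    retained with a warning so a human can review the split.  Returns
    the retained mask and stores it on the embedding.
    """
    n = embedding.n
    if n < 4:
        raise ValueError("need at least 4 points to split a noise cluster")
    labels = subcluster(embedding.coords30, 2, seed=seed)
    minor = labels == 1  # label 1 is the smaller cluster after remapping
    frac = float(minor.mean())
    retained = np.ones(n, dtype=bool)
    if frac < noise_max_frac:
        retained = ~minor
    else:
        warnings.warn(
            f"candidate noise cluster holds {frac:.0%} of ROIs "
            f"(> {noise_max_frac:.0%}); nothing discarded — review exemplars"
        )
    embedding.top_cluster = retained
    return retained


def mean_silhouette(coords: np.ndarray, labels: Sequence[int]) -> float:
    """Mean silhouette coefficient s = (b - a) / max(a, b) with Euclidean
    distances; singleton clusters score 0."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 1:
        coords = coords[:, None]
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("mean_silhouette requires at least 2 clusters")
    if any((labels == u).sum() == 0 for u in uniq):  # pragma: no cover
        raise ValueError("empty cluster")
    dists = cdist(coords, coords)
    n = len(coords)
    scores = np.zeros(n)
    members = {u: np.flatnonzero(labels == u) for u in uniq}
    for i in range(n):
        own = members[labels[i]]
        if len(own) == 1:
            scores[i] = 0.0
            continue
        a = dists[i, own].sum() / (len(own) - 1)
        b = min(dists[i, members[u]].mean() for u in uniq if u != labels[i])
        scores[i] = (b - a) / max(a, b)
    return float(scores.mean())


def silhouette_sweep(
    coords: np.ndarray,
    k_range: Sequence[int],
    seed: int = 0,
    n_neighbors: int = 10,
) -> ClusterSweep:
    """Run ``subcluster`` over ``k_range`` and pick the k maximizing the
    mean silhouette (ties break toward smaller k)."""
    k_values = list(k_range)
    if not k_values:
        raise ValueError("k_range must be non-empty")
    n = len(coords)
    for k in k_values:
        if not 2 <= k <= n - 1:
            raise ValueError(f"k={k} outside [2, {n - 1}]")
    sils = []
    for k in k_values:
        labels = subcluster(coords, k, seed=seed, n_neighbors=n_neighbors)
        sils.append(mean_silhouette(coords, labels))
    best = int(np.argmax(sils))  # argmax returns the first (smallest k) on ties
    return ClusterSweep(k_values=k_values, silhouettes=sils,
                        chosen_k=k_values[best])


def centroid_exemplars(
    embedding: ReducedEmbedding,
    rois: Sequence[ROI],
    n_neighbors: int = 20,
    out_dir: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Per-subcluster centroid exemplars for human labeling.

    For each subcluster the centroid of the 30-D coordinates is taken
    and the ``n_neighbors`` nearest retained points (Euclidean) are
    listed in order of increasing distance.  Optionally writes one
    montage PNG per cluster and an exemplar CSV.
    """
    if embedding.subcluster is None:
        raise ValueError("embedding has no subcluster labels")
    if len(rois) != embedding.n:
        raise ValueError("rois and embedding rows must correspond 1:1")
    retained = (embedding.top_cluster if embedding.top_cluster is not None
                else np.ones(embedding.n, dtype=bool))
    rows = []
    for c in sorted(set(embedding.subcluster[retained])):
        idx = np.flatnonzero(retained & (embedding.subcluster == c))
        centroid = embedding.coords30[idx].mean(axis=0)
        d = np.linalg.norm(embedding.coords30[idx] - centroid, axis=1)
        if len(idx) < n_neighbors:
            warnings.warn(
                f"cluster {c} has only {len(idx)} members (< {n_neighbors}); "
                "returning all"
            )
        order = np.argsort(d, kind="stable")[:n_neighbors]
        for rank, o in enumerate(order):
            rows.append(
                dict(cluster=int(c), rank=rank, roi=rois[idx[o]].roi_id,
                     source_image=rois[idx[o]].source_image,
                     distance=float(d[o]))
            )
    table = pd.DataFrame(rows, columns=["cluster", "rank", "roi",
                                        "source_image", "distance"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "exemplars.csv", index=False)
        _write_exemplar_montages(table, rois, out)
    return table


def _write_exemplar_montages(table: pd.DataFrame, rois: Sequence[ROI],
                             out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    by_id = {r.roi_id: r for r in rois}
    for c, group in table.groupby("cluster"):
        n = len(group)
        ncols = min(n, 5)
        nrows = int(np.ceil(n / ncols))
        fig, axes = plt.subplots(nrows, ncols, figsize=(2 * ncols, 2 * nrows),
                                 squeeze=False)
        for ax in axes.ravel():
            ax.axis("off")
        for ax, roi_id in zip(axes.ravel(), group["roi"]):
            patch = by_id[roi_id].pixels
            rgb = np.stack([patch[2], patch[1], patch[0]], axis=-1)
            ax.imshow(np.clip(rgb, 0, 1))
            ax.set_title(roi_id, fontsize=5)
        fig.savefig(out / f"cluster_{c}_exemplars.png", dpi=100)
        plt.close(fig)


def embedding_table(embedding: ReducedEmbedding, rois: Sequence[ROI]) -> pd.DataFrame:
    """Export `roi,source_image,umap1,umap2,noise,subcluster` rows."""
    retained = (embedding.top_cluster if embedding.top_cluster is not None
                else np.ones(embedding.n, dtype=bool))
    sub = (embedding.subcluster if embedding.subcluster is not None
           else np.full(embedding.n, -1))
    return pd.DataFrame(
        dict(
            roi=[r.roi_id for r in rois],
            source_image=[r.source_image for r in rois],
            umap1=embedding.coords2[:, 0],
            umap2=embedding.coords2[:, 1],
            noise=~retained,
            subcluster=[int(s) if keep else -1 for s, keep in zip(sub, retained)],
        )
    )
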