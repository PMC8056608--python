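"""Per-ROI feature extraction for phenotype discovery.

The discovery stage represents each single-cell crop by a fixed-length
feature vector produced by the first four convolutional blocks of a
VGG-16-style network (channel widths 64-64 / 128-128 / 256-256-256 /
512-512-512, 3x3 kernels, 2x2 max-pools), followed by adaptive average
pooling of the block-4 output to a 4x4 spatial grid over 512 channels
and flattening to 8,192 features.

The convolutional stack is implemented directly on NumPy (im2col +
matmul), so it runs anywhere, deterministically, with no deep-learning
runtime.  Weights come either from a seeded He-normal initialization
(``weights_source="random"``, the offline default — random convolutional
projections preserve the coarse spatial-intensity layout that separates
localization phenotypes) or from a user-supplied ``.npz`` checkpoint
(``weights_source="pretrained"``) for users who export pretrained VGG-16
block weights themselves.

A weight-free classical alternative (``RadialProfileExtractor``) encodes
the target-channel intensity as a radial profile relative to the cell
center, which is the geometry that distinguishes nuclear /
nuclear-excluded / diffuse localization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import ROI

#: VGG-16 convolutional blocks 1-4 (output channel widths per conv layer).
VGG_BLOCKS: tuple[tuple[int, ...], ...] = (
    (64, 64),
    (128, 128),
    (256, 256, 256),
    (512, 512, 512),
)


@dataclass
class ExtractorConfig:
    """Configuration of the convolutional feature extractor.

    ``input_size=148`` is the native preprocessing scale (each ROI is
    resized up to 148x148); after four 2x2 pools this leaves a 9x9x512
    map which adaptive average pooling reduces to ``pool_grid`` (4x4) so
    the flattened feature length is 512*4*4 = 8192.  ``input_size=64``
    reaches a 4x4x512 map natively and is provided as a faster mode with
    the same feature length.
    """

    weights_source: str = "random"  # "random" or "pretrained"
    seed: int = 0
    input_size: int = 148
    pool_grid: int = 4
    weights_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.weights_source not in ("random", "pretrained"):
            raise ValueError(
                f"unknown weights_source {self.weights_source!r}; "
                "expected 'random' or 'pretrained'"
            )


def _he_init(rng: np.random.Generator, out_ch: int, in_ch: int) -> np.ndarray:
    std = np.sqrt(2.0 / (in_ch * 9))
    return rng.normal(0.0, std, size=(out_ch, in_ch, 3, 3)).astype(np.float32)


def _conv2d_relu(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 same-padding convolution + ReLU via im2col; x is (C, H, W)."""
    c, h, wd = x.shape
    o = w.shape[0]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (C, H, W, 3, 3)
    cols = win.transpose(1, 2, 0, 3, 4).reshape(h * wd, c * 9)
    out = cols @ w.reshape(o, -1).T + b
    np.maximum(out, 0.0, out=out)
    return np.ascontiguousarray(out.T.reshape(o, h, wd))


def _maxpool2(x: np.ndarray) -> np.ndarray:
    c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    v = x[:, : h2 * 2, : w2 * 2].reshape(c, h2, 2, w2, 2)
    return v.max(axis=(2, 4))


def _adaptive_avg_pool(x: np.ndarray, grid: int) -> np.ndarray:
    """Average-pool (C, H, W) to (C, grid, grid) with torch-style bins."""
    c, h, w = x.shape
    out = np.empty((c, grid, grid), dtype=x.dtype)
    for i in range(grid):
        r0, r1 = (i * h) // grid, max(((i + 1) * h + grid - 1) // grid, (i * h) // grid + 1)
        for j in range(grid):
            c0, c1 = (j * w) // grid, max(((j + 1) * w + grid - 1) // grid, (j * w) // grid + 1)
            out[:, i, j] = x[:, r0:r1, c0:c1].mean(axis=(1, 2))
    return out


class ConvFeatureExtractor:
    """VGG-16-style blocks 1-4 with adaptive pooling to a fixed grid."""

    def __init__(self, config: Optional[ExtractorConfig] = None) -> None:
        self.config = config or ExtractorConfig()
        self.weights: list[tuple[np.ndarray, np.ndarray]] = []
        if self.config.weights_source == "random":
            rng = np.random.default_rng(self.config.seed)
            in_ch = 3
            for block in VGG_BLOCKS:
                for out_ch in block:
                    self.weights.append(
                        (_he_init(rng, out_ch, in_ch), np.zeros(out_ch, np.float32))
                    )
                    in_ch = out_ch
        else:
            if not self.config.weights_path:
                raise ValueError(
                    "weights_source='pretrained' requires weights_path pointing "
                    "to an .npz checkpoint with conv{i}_w / conv{i}_b arrays "
                    "for the 10 conv layers of blocks 1-4"
                )
            data = np.load(self.config.weights_path)
            n_layers = sum(len(b) for b in VGG_BLOCKS)
            for i in range(n_layers):
                self.weights.append(
                    (data[f"conv{i}_w"].astype(np.float32),
                     data[f"conv{i}_b"].astype(np.float32))
                )

    @property
    def n_features(self) -> int:
        return VGG_BLOCKS[-1][-1] * self.config.pool_grid**2

    @property
    def fingerprint(self) -> dict:
        """Identity of the extractor: architecture, weights provenance,
        input scaling and channel mapping."""
        return {
            "architecture": "vgg16-blocks1-4",
            "blocks": [list(b) for b in VGG_BLOCKS],
            "weights_source": self.config.weights_source,
            "seed": self.config.seed if self.config.weights_source == "random" else None,
            "weights_path": self.config.weights_path,
            "input_size": self.config.input_size,
            "pool_grid": self.config.pool_grid,
            "n_features": self.n_features,
            "channel_mapping": "(nucleus, reporter, target) -> extractor RGB-order input",
        }

    def _prepare(self, roi: ROI | np.ndarray) -> np.ndarray:
        from skimage.transform import resize

        pixels = roi.pixels if isinstance(roi, ROI) else np.asarray(roi, np.float32)
        if pixels.ndim == 2:
            pixels = np.stack([pixels] * 3)
        if pixels.shape[0] != 3:
            raise ValueError(f"extractor expects 3-channel ROIs, got {pixels.shape}")
        size = self.config.input_size
        if pixels.shape[1:] != (size, size):
            pixels = resize(
                pixels, (3, size, size), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True,
            ).astype(np.float32)
        return pixels

    def forward(self, roi: ROI | np.ndarray, stop_after: Optional[int] = None) -> np.ndarray:
        """Run the conv stack; ``stop_after`` (1-based conv-layer index)
        returns that layer's feature maps instead of the final vector."""
        x = self._prepare(roi)
        layer = 0
        for block in VGG_BLOCKS:
            for _ in block:
                w, b = self.weights[layer]
                x = _conv2d_relu(x, w, b)
                layer += 1
                if stop_after is not None and layer == stop_after:
                    return x
            x = _maxpool2(x)
        pooled = _adaptive_avg_pool(x, self.config.pool_grid)
        return pooled.reshape(-1)

    def __call__(self, roi: ROI | np.ndarray) -> np.ndarray:
        return self.forward(roi)


class RadialProfileExtractor:
    """Weight-free classical extractor: radial intensity profile of the
    target channel (and nucleus channel) relative to the patch center,
    in ``n_bins`` equal-width normalized-radius bins."""

    def __init__(self, n_bins: int = 32) -> None:
        self.n_bins = n_bins

    @property
    def n_features(self) -> int:
        return 2 * self.n_bins

    @property
    def fingerprint(self) -> dict:
        return {
            "architecture": "radial-intensity-profile",
            "n_bins": self.n_bins,
            "n_features": self.n_features,
            "channel_mapping": "target + nucleus channels, radial bins from patch center",
        }

    def __call__(self, roi: ROI | np.ndarray) -> np.ndarray:
        pixels = roi.pixels if isinstance(roi, ROI) else np.asarray(roi, np.float32)
        if pixels.ndim == 2:
            pixels = np.stack([pixels] * 3)
        _, h, w = pixels.shape
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot((yy - (h - 1) / 2) / (h / 2), (xx - (w - 1) / 2) / (w / 2))
        bins = np.clip((r / np.sqrt(2) * self.n_bins).astype(int), 0, self.n_bins - 1)
        feats = []
        for ch in (2, 0):  # target, nucleus
            plane = pixels[ch]
            prof = np.bincount(bins.ravel(), weights=plane.ravel(), minlength=self.n_bins)
            counts = np.bincount(bins.ravel(), minlength=self.n_bins)
            feats.append(prof / np.maximum(counts, 1))
        return np.concatenate(feats).astype(np.float32)


def build_extractor(config: Optional[ExtractorConfig] = None, kind: str = "vgg"):
    """Build a feature extractor.

    ``kind="vgg"`` returns the convolutional extractor (8,192 features by
    default); ``kind="radial"`` the classical radial-profile extractor.
    """
    if kind == "vgg":
        return ConvFeatureExtractor(config)
    if kind == "radial":
        return RadialProfileExtractor()
    raise ValueError(f"unknown extractor kind {kind!r}; expected 'vgg' or 'radial'")


def extract_features(rois: Sequence[ROI | np.ndarray], extractor) -> np.ndarray:
    """Extract an (n, F) float32 feature matrix, preserving input order."""
    if len(rois) == 0:
        return np.zeros((0, extractor.n_features), dtype=np.float32)
    rows = [np.asarray(extractor(r), dtype=np.float32) for r in rois]
    matrix = np.stack(rows)
    if matrix.shape[1] != extractor.n_features:
        raise RuntimeError(
            f"feature length {matrix.shape[1]} does not match extractor "
            f"fingerprint ({extractor.n_features})"
        )
    if not np.isfinite(matrix).all():
        raise RuntimeError("non-finite feature values")
    return matrix


def save_features(path: str | Path, matrix: np.ndarray, fingerprint: dict,
                  roi_ids: Optional[Sequence[str]] = None) -> None:
    """Write a feature matrix as TSV with a sidecar JSON fingerprint."""
    path = Path(path)
    ids = list(roi_ids) if roi_ids is not None else [str(i) for i in range(len(matrix))]
    with open(path, "w") as fh:
        for rid, row in zip(ids, matrix):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(fingerprint, fh, indent=2)


def load_features(path: str | Path) -> tuple[np.ndarray, dict, list[str]]:
    path = Path(path)
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        fingerprint = json.load(fh)
    return np.asarray(rows, dtype=np.float32), fingerprint, ids


def visualize_filters(
    extractor: ConvFeatureExtractor,
    block: int,
    layer: int,
    out_dir: str | Path,
    roi: Optional[ROI | np.ndarray] = None,
    count: int = 16,
) -> dict:
    """Write a montage of convolutional filters from one layer, plus the
    intermediate feature maps that layer produces for one ROI.

    ``block``/``layer`` are 1-based; count defaults to 16 filters.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not (1 <= block <= len(VGG_BLOCKS)) or not (1 <= layer <= len(VGG_BLOCKS[block - 1])):
        raise IndexError(f"no layer {layer} in block {block}")
    flat_index = sum(len(b) for b in VGG_BLOCKS[: block - 1]) + layer  # 1-based
    w, _ = extractor.weights[flat_index - 1]
    if count > w.shape[0]:
        raise ValueError(f"requested {count} filters but layer has {w.shape[0]}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ncols = int(np.ceil(np.sqrt(count)))
    nrows = int(np.ceil(count / ncols))

    fig, axes = plt.subplots(nrows, ncols, figsize=(2 * ncols, 2 * nrows))
    for i, ax in enumerate(np.atleast_1d(axes).ravel()):
        ax.axis("off")
        if i < count:
            ax.imshow(w[i].mean(axis=0), cmap="gray")
    filter_path = out / f"filters_block{block}_layer{layer}.png"
    fig.savefig(filter_path, dpi=100)
    plt.close(fig)

    result = {"filters": str(filter_path), "feature_maps": None}
    if roi is not None:
        maps = extractor.forward(roi, stop_after=flat_index)
        fig, axes = plt.subplots(nrows, ncols, figsize=(2 * ncols, 2 * nrows))
        for i, ax in enumerate(np.atleast_1d(axes).ravel()):
            ax.axis("off")
            if i < count:
                ax.imshow(maps[i], cmap="viridis")
        fmap_path = out / f"feature_maps_block{block}_layer{layer}.png"
        fig.savefig(fmap_path, dpi=100)
        plt.close(fig)
        result["feature_maps"] = str(fmap_path)
    return result
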