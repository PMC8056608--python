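"""Synthetic fluorescence-microscopy field generator with full ground truth.

Emulates sub-confluent fields of transfected epithelial cells imaged in
three channels (nucleus stain, transfection reporter, target protein).
Each transfected cell carries one of three target-protein localization
phenotypes — ``nuclear``, ``nuclear_excluded`` or ``diffuse`` — rendered
as smooth elliptical sprites.  Degradations (Gaussian defocus blur,
additive Gaussian noise at a controlled level, and bubble / fiber /
overexposure artifacts) are applied after the ground truth is frozen, so
downstream quality-control and detection stages can be benchmarked
against an uncorrupted reference.

The generator is fully deterministic given a spec and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .types import (
    CHANNEL_ORDER,
    PHENOTYPE_CLASSES,
    Annotation,
    BBox,
    FieldImage,
    GroundTruth,
    stable_seed,
    validate_phenotype,
)

ARTIFACT_KINDS = ("bubble", "fiber", "overexposed")


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic acquisition.

    Parameters
    ----------
    image_size
        Side length of the square field in pixels (>= 64).
    cells_per_field
        Inclusive (low, high) range for the number of cells per field.
    phenotype_mix
        Proportions over (nuclear, nuclear_excluded, diffuse); must sum
        to 1.  The default is wildtype-like: ~10% nuclear cells.
    transfected_fraction
        Fraction of cells expressing reporter + target signal.  The
        remainder are nucleus-only distractors.
    blur_sigma
        Gaussian defocus sigma in pixels applied to every channel
        (0 = in focus).
    base_noise_sigma
        Additive Gaussian noise sigma at multiplier 1, in intensity
        units of the [0, 1] scale.
    noise_multiplier
        Unitless >= 0 factor on ``base_noise_sigma``.
    artifact_rates
        Per-field probabilities for each artifact kind.
    seed
        Master seed; every stochastic choice derives from it.
    """

    image_size: int = 512
    cells_per_field: tuple[int, int] = (8, 15)
    phenotype_mix: tuple[float, float, float] = (0.10, 0.70, 0.20)
    transfected_fraction: float = 0.7
    blur_sigma: float = 0.0
    base_noise_sigma: float = 0.06
    noise_multiplier: float = 1.0
    artifact_rates: dict = field(
        default_factory=lambda: {"bubble": 0.0, "fiber": 0.0, "overexposed": 0.0}
    )
    seed: int = 0
    # Morphology/levels (sub-confluent epithelial defaults at ~20x scale)
    cell_radius: tuple[float, float] = (16.0, 24.0)
    nucleus_ratio: tuple[float, float] = (0.38, 0.48)
    background: tuple[float, float, float] = (0.10, 0.28, 0.22)

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError(f"image_size must be >= 64, got {self.image_size}")
        if abs(sum(self.phenotype_mix) - 1.0) > 1e-9:
            raise ValueError(
                f"phenotype_mix must sum to 1, got {self.phenotype_mix}"
            )
        rates = {"bubble": 0.0, "fiber": 0.0, "overexposed": 0.0}
        rates.update(self.artifact_rates)
        self.artifact_rates = rates
        for name, rate in [
            ("transfected_fraction", self.transfected_fraction),
            *self.artifact_rates.items(),
        ]:
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if any(p < 0 for p in self.phenotype_mix):
            raise ValueError("phenotype_mix entries must be non-negative")
        if self.noise_multiplier < 0:
            raise ValueError("noise_multiplier must be >= 0")
        if self.cells_per_field[0] > self.cells_per_field[1] or self.cells_per_field[0] < 0:
            raise ValueError(f"invalid cells_per_field range {self.cells_per_field}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        for key in ("cells_per_field", "phenotype_mix", "cell_radius",
                    "nucleus_ratio", "background"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class CellGeometry:
    """Elliptical cell/nucleus geometry (semi-axes in pixels, shared angle)."""

    cell_a: float
    cell_b: float
    nucleus_a: float
    nucleus_b: float
    angle: float

    def __post_init__(self) -> None:
        if self.nucleus_a >= self.cell_a or self.nucleus_b >= self.cell_b:
            raise ValueError(
                f"nucleus radii {(self.nucleus_a, self.nucleus_b)} must be "
                f"smaller than cell radii {(self.cell_a, self.cell_b)}"
            )

    @property
    def extent(self) -> tuple[float, float]:
        """Half-extents (y, x) of the cell ellipse's axis-aligned bbox."""
        c, s = np.cos(self.angle), np.sin(self.angle)
        ex = float(np.hypot(self.cell_a * c, self.cell_b * s))
        ey = float(np.hypot(self.cell_a * s, self.cell_b * c))
        return ey, ex


def sample_geometry(spec: SyntheticSpec, rng: np.random.Generator) -> CellGeometry:
    cell_a = rng.uniform(*spec.cell_radius)
    cell_b = cell_a * rng.uniform(0.6, 0.95)
    ratio = rng.uniform(*spec.nucleus_ratio)
    return CellGeometry(
        cell_a=cell_a,
        cell_b=cell_b,
        nucleus_a=cell_a * ratio,
        nucleus_b=cell_b * ratio,
        angle=rng.uniform(0.0, np.pi),
    )


def _elliptical_distance(h: int, w: int, cy: float, cx: float,
                         a: float, b: float, angle: float) -> np.ndarray:
    """Normalized elliptical radius (1.0 on the ellipse boundary)."""
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = (dx * c + dy * s) / a
    v = (-dx * s + dy * c) / b
    return np.sqrt(u * u + v * v)


def _edge(d: np.ndarray, width: float) -> np.ndarray:
    """Soft unit-height plateau: ~1 inside d<1, logistic falloff of `width`."""
    return 1.0 / (1.0 + np.exp((d - 1.0) / width))


def render_cell(
    phenotype: str,
    geometry: CellGeometry,
    rng: np.random.Generator,
    transfected: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one cell sprite.

    Returns ``(sprite, nucleus_mask, cell_mask)`` where sprite is a
    3-channel ``(3, h, w)`` float patch in channel order
    (nucleus, reporter, target) and the masks are the boolean interiors
    of the nucleus and cell ellipses.

    The target channel realizes the localization phenotype: ``nuclear``
    concentrates >= 80% of target mass inside the nucleus mask,
    ``nuclear_excluded`` leaves <= 20% there, and ``diffuse`` spreads
    target uniformly over the cell so the inside fraction tracks the
    nucleus/cell area ratio.
    """
    validate_phenotype(phenotype)
    margin = 4
    ey, ex = geometry.extent
    h = int(np.ceil(2 * (ey + margin)))
    w = int(np.ceil(2 * (ex + margin)))
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    d_cell = _elliptical_distance(h, w, cy, cx, geometry.cell_a, geometry.cell_b,
                                  geometry.angle)
    d_nuc = _elliptical_distance(h, w, cy, cx, geometry.nucleus_a,
                                 geometry.nucleus_b, geometry.angle)
    cell_mask = d_cell < 1.0
    nucleus_mask = d_nuc < 1.0

    # Sharp-edged nucleus (DAPI-like), smooth cell body.
    amp_n = rng.uniform(0.55, 0.75)
    amp_r = rng.uniform(0.35, 0.55)
    amp_t = rng.uniform(0.40, 0.60)

    nucleus = amp_n * _edge(d_nuc, 0.03)
    cell_body = _edge(d_cell, 0.10)

    sprite = np.zeros((3, h, w), dtype=np.float32)
    sprite[0] = nucleus
    if transfected:
        sprite[1] = amp_r * cell_body
        if phenotype == "nuclear":
            sprite[2] = amp_t * _edge(d_nuc, 0.04) + 0.03 * amp_t * cell_body
        elif phenotype == "nuclear_excluded":
            # Suppression mask extends slightly past the nucleus boundary so
            # the nucleus interior is dark.
            suppression = _edge(d_nuc / 1.10, 0.05)
            sprite[2] = amp_t * cell_body * (1.0 - suppression)
        else:  # diffuse
            sprite[2] = amp_t * cell_body
    return sprite, nucleus_mask, cell_mask


def target_inside_fraction(sprite: np.ndarray, nucleus_mask: np.ndarray) -> float:
    """Fraction of target-channel mass falling inside the nucleus mask."""
    total = float(sprite[2].sum())
    if total == 0:
        return 0.0
    return float(sprite[2][nucleus_mask].sum()) / total


def _place_cells(
    spec: SyntheticSpec,
    geometries: Sequence[CellGeometry],
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Rejection-sample cell centers: whole cell inside the field, nuclei
    never overlapping, bodies mostly separated (sub-confluent culture)."""
    size = spec.image_size
    centers: list[tuple[float, float]] = []
    max_tries = 300 * max(len(geometries), 1)
    tries = 0
    for geom in geometries:
        ey, ex = geom.extent
        if 2 * ey + 4 >= size or 2 * ex + 4 >= size:
            raise ValueError(
                f"cell extent {(ey, ex)} cannot fit in a {size}px field"
            )
        while True:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    f"could not place {len(geometries)} cells in a "
                    f"{size}x{size} field: density too high"
                )
            cy = rng.uniform(ey + 2, size - ey - 2)
            cx = rng.uniform(ex + 2, size - ex - 2)
            ok = True
            for (oy, ox), ogeom in zip(centers, geometries):
                dist = np.hypot(cy - oy, cx - ox)
                nuc_sep = geom.nucleus_a + ogeom.nucleus_a + 4
                body_sep = 1.05 * (geom.cell_a + ogeom.cell_a)
                if dist < max(nuc_sep, body_sep):
                    ok = False
                    break
            if ok:
                centers.append((cy, cx))
                break
    return centers


def inject_artifact(
    image: np.ndarray, kind: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Add one acquisition artifact to a field image.

    ``bubble`` draws a bright high-gradient annulus, ``fiber`` an
    elongated bright streak, ``overexposed`` a saturated blob.  Works on
    ``(C, H, W)`` stacks or single 2-D planes; returns the modified image
    and a 2-D boolean mask covering the artifact.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}; expected {ARTIFACT_KINDS}")
    img = np.array(image, dtype=np.float32, copy=True)
    planes = img[None] if img.ndim == 2 else img
    h, w = planes.shape[1:]
    yy, xx = np.mgrid[0:h, 0:w]

    if kind == "bubble":
        r = rng.uniform(0.08, 0.2) * min(h, w)
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        d = np.hypot(yy - cy, xx - cx)
        ring = np.exp(-((d - r) ** 2) / (2 * 0.7**2))
        planes += 0.5 * ring[None]
        mask = np.abs(d - r) < 4.0
    elif kind == "fiber":
        # Random chord across the field.
        theta = rng.uniform(0, np.pi)
        c, s = np.cos(theta), np.sin(theta)
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.2 * w, 0.8 * w)
        dist = np.abs((xx - cx) * s - (yy - cy) * c)
        along = np.abs((xx - cx) * c + (yy - cy) * s)
        half_len = rng.uniform(0.3, 0.6) * min(h, w)
        streak = np.exp(-(dist**2) / (2 * 1.0**2)) * (along < half_len)
        planes += 0.45 * streak[None]
        mask = (dist < 4.0) & (along < half_len + 4)
    else:  # overexposed
        r = rng.uniform(0.03, 0.06) * min(h, w)
        cy = rng.uniform(r + 2, h - r - 2)
        cx = rng.uniform(r + 2, w - r - 2)
        d = np.hypot(yy - cy, xx - cx)
        mask = d < r
        planes[:, mask] = 1.0

    np.clip(planes, 0.0, 1.0, out=planes)
    out = planes[0] if image.ndim == 2 else planes
    if not mask.any():
        raise RuntimeError("artifact mask is empty")  # pragma: no cover
    return out, mask


def generate_field(
    spec: SyntheticSpec,
    rng: Optional[np.random.Generator] = None,
    field_id: str = "field_000",
) -> tuple[FieldImage, GroundTruth]:
    """Generate one field and its ground truth.

    Ground truth (boxes for transfected cells, phenotype labels, focus
    label, artifact masks) is recorded *before* blur and noise are
    applied.  Calling twice with the same spec seed is bit-identical.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    canvas = np.zeros((3, size, size), dtype=np.float32)
    for ch, bg in enumerate(spec.background):
        canvas[ch] = bg

    n_cells = int(rng.integers(spec.cells_per_field[0], spec.cells_per_field[1] + 1))
    geometries = [sample_geometry(spec, rng) for _ in range(n_cells)]
    centers = _place_cells(spec, geometries, rng)

    n_transfected = int(round(n_cells * spec.transfected_fraction))
    order = rng.permutation(n_cells)
    transfected = np.zeros(n_cells, dtype=bool)
    transfected[order[:n_transfected]] = True

    bg = np.array(spec.background, dtype=np.float32)[:, None, None]
    boxes: list[Annotation] = []
    labels: list[str] = []
    for i in range(n_cells):
        phenotype = PHENOTYPE_CLASSES[
            int(rng.choice(len(PHENOTYPE_CLASSES), p=spec.phenotype_mix))
        ]
        sprite, _, _ = render_cell(
            phenotype, geometries[i], rng, transfected=bool(transfected[i])
        )
        cy, cx = centers[i]
        h, w = sprite.shape[1:]
        r0 = int(round(cy - (h - 1) / 2))
        c0 = int(round(cx - (w - 1) / 2))
        r0c, c0c = max(r0, 0), max(c0, 0)
        r1c, c1c = min(r0 + h, size), min(c0 + w, size)
        region = canvas[:, r0c:r1c, c0c:c1c]
        patch = sprite[:, r0c - r0 : r1c - r0, c0c - c0 : c1c - c0]
        # Saturating combine: overlapping cell bodies take the max rather
        # than summing, so intensities stay physical.
        np.maximum(region, bg + patch, out=region)
        if transfected[i]:
            ey, ex = geometries[i].extent
            left = max((cx - ex) / size, 0.0)
            top = max((cy - ey) / size, 0.0)
            bbox = BBox(
                left=left,
                top=top,
                width=min((cx + ex) / size, 1.0) - left,
                height=min((cy + ey) / size, 1.0) - top,
            )
            boxes.append(Annotation(image=field_id, tag="cell", bbox=bbox))
            labels.append(phenotype)

    # Ground truth is frozen before any degradation below.
    artifact_masks: dict[str, np.ndarray] = {}
    for kind in ARTIFACT_KINDS:
        if rng.random() < spec.artifact_rates[kind]:
            canvas, mask = inject_artifact(canvas, kind, rng)
            artifact_masks[kind] = mask

    if spec.blur_sigma > 0:
        for ch in range(canvas.shape[0]):
            canvas[ch] = ndimage.gaussian_filter(canvas[ch], spec.blur_sigma)

    noise_sigma = spec.base_noise_sigma * spec.noise_multiplier
    if noise_sigma > 0:
        canvas += rng.normal(0.0, noise_sigma, size=canvas.shape).astype(np.float32)
    np.clip(canvas, 0.0, 1.0, out=canvas)

    truth = GroundTruth(
        boxes=boxes,
        phenotype_labels=labels,
        focus_label=spec.blur_sigma <= 0.5,
        artifact_masks=artifact_masks,
    )
    return FieldImage(canvas, CHANNEL_ORDER, field_id), truth


def generate_dataset(
    spec: SyntheticSpec,
    n_fields: int,
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict:
    """Write a dataset: one 16-bit multi-page TIFF per field, an
    annotation CSV, a phenotype label CSV and a JSON manifest.

    Per-field seeds are derived from the spec seed, so the dataset is
    reproducible as a whole.  Returns the manifest dict.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} exists and is not empty; pass overwrite=True to replace"
        )
    out.mkdir(parents=True, exist_ok=True)

    ann_rows = []
    label_rows = []
    files = []
    focus_labels = {}
    for i in range(n_fields):
        field_id = f"field_{i:04d}"
        fspec = dataclasses.replace(spec, seed=stable_seed(spec.seed, "field", i))
        field, truth = generate_field(fspec, field_id=field_id)
        fname = f"{field_id}.tif"
        write_field_tiff(out / fname, field)
        files.append(fname)
        focus_labels[field_id] = bool(truth.focus_label)
        for j, (ann, label) in enumerate(zip(truth.boxes, truth.phenotype_labels)):
            ann_rows.append(
                dict(image=fname, tag=ann.tag, left=ann.bbox.left, top=ann.bbox.top,
                     width=ann.bbox.width, height=ann.bbox.height)
            )
            label_rows.append(dict(image=fname, box=j, label=label))

    ann_path = out / "annotations.csv"
    pd.DataFrame(
        ann_rows, columns=["image", "tag", "left", "top", "width", "height"]
    ).to_csv(ann_path, index=False, float_format="%.17g")
    labels_path = out / "labels.csv"
    pd.DataFrame(label_rows, columns=["image", "box", "label"]).to_csv(
        labels_path, index=False
    )

    manifest = {
        "spec": spec.to_dict(),
        "seed": spec.seed,
        "n_fields": n_fields,
        "files": files,
        "focus_labels": focus_labels,
        "annotations": ann_path.name,
        "labels": labels_path.name,
        "channel_order": list(CHANNEL_ORDER),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def write_field_tiff(path: str | Path, field: FieldImage) -> None:
    """Write a field as a multi-page 16-bit TIFF (one page per channel)."""
    data = np.clip(field.image, 0.0, 1.0)
    tifffile.imwrite(
        str(path), (data * 65535.0).round().astype(np.uint16),
        photometric="minisblack",
    )


def read_field_tiff(path: str | Path, field_id: Optional[str] = None) -> FieldImage:
    """Read a multi-page TIFF (or 8-bit PNG single channel) back to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() == ".png":
        from PIL import Image

        arr = np.asarray(Image.open(path), dtype=np.float32) / 255.0
        if arr.ndim == 2:
            arr = arr[None]
        else:
            arr = arr.transpose(2, 0, 1)
    else:
        raw = tifffile.imread(str(path))
        if raw.ndim == 2:
            raw = raw[None]
        arr = raw.astype(np.float32)
        if raw.dtype == np.uint16:
            arr /= 65535.0
        elif raw.dtype == np.uint8:
            arr /= 255.0
    channels = CHANNEL_ORDER[: arr.shape[0]] if arr.shape[0] <= 3 else tuple(
        f"ch{i}" for i in range(arr.shape[0])
    )
    return FieldImage(arr, channels, field_id or path.stem)


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read an annotation CSV (image,tag,left,top,width,height; normalized)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"image", "tag", "left", "top", "width", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    return [
        Annotation(
            image=row.image,
            tag=row.tag,
            bbox=BBox(row.left, row.top, row.width, row.height),
        )
        for row in df.itertuples()
    ]


def read_dataset(directory: str | Path) -> tuple[list[FieldImage], dict, pd.DataFrame, pd.DataFrame]:
    """Load a generated dataset: fields, manifest, annotations, labels."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    fields = [
        read_field_tiff(directory / fname, field_id=Path(fname).stem)
        for fname in manifest["files"]
    ]
    annotations = pd.read_csv(directory / manifest["annotations"],
                              float_precision="round_trip")
    labels = pd.read_csv(directory / manifest["labels"])
    return fields, manifest, annotations, labels
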