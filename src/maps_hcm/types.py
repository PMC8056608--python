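"""Core value types shared across the pipeline.

Images are carried in memory as ``float32`` arrays of shape ``(C, H, W)``
with intensities in ``[0, 1]``; the saturation value is 1.0.  On disk a
field is a multi-page 16-bit TIFF, one page per channel, in the fixed
channel order ``(nucleus, reporter, target)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Canonical phenotype label set, in the order used by mixture parameters.
PHENOTYPE_CLASSES: tuple[str, ...] = ("nuclear", "nuclear_excluded", "diffuse")

#: Fixed channel order of a field image.
CHANNEL_ORDER: tuple[str, ...] = ("nucleus", "reporter", "target")

#: In-memory saturation value (float images in [0, 1]).
SATURATION_VALUE: float = 1.0


@dataclass(frozen=True)
class BBox:
    """Axis-aligned bounding box in normalized image coordinates.

    ``left``/``top`` are the minimum x/y corner and ``width``/``height``
    the extents, all as fractions of the image width/height in ``[0, 1]``.
    """

    left: float
    top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"box extents must be positive, got {self}")
        if self.left < -1e-9 or self.top < -1e-9:
            raise ValueError(f"box origin must be non-negative, got {self}")
        if self.left + self.width > 1 + 1e-9 or self.top + self.height > 1 + 1e-9:
            raise ValueError(f"box exceeds unit square: {self}")

    @property
    def right(self) -> float:
        return self.left + self.width

    @property
    def bottom(self) -> float:
        return self.top + self.height

    @property
    def area(self) -> float:
        return self.width * self.height

    def to_pixels(self, height: int, width: int) -> tuple[int, int, int, int]:
        """Return integer ``(row0, row1, col0, col1)`` pixel bounds."""
        col0 = int(np.floor(self.left * width))
        col1 = int(np.ceil(self.right * width))
        row0 = int(np.floor(self.top * height))
        row1 = int(np.ceil(self.bottom * height))
        return max(row0, 0), min(row1, height), max(col0, 0), min(col1, width)


@dataclass(frozen=True)
class Annotation:
    """A ground-truth or exported bounding box with its image id and tag."""

    image: str
    tag: str
    bbox: BBox


@dataclass(frozen=True)
class Detection:
    """A predicted bounding box with a confidence score in [0, 1]."""

    bbox: BBox
    score: float
    image: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must lie in [0, 1], got {self.score}")


@dataclass
class FieldImage:
    """One multi-channel micrograph with channel roles and provenance."""

    image: np.ndarray  # (C, H, W) float32 in [0, 1]
    channels: tuple[str, ...] = CHANNEL_ORDER
    field_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 3:
            raise ValueError("field image must be (C, H, W)")
        if self.image.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.image.shape[0]} planes but {len(self.channels)} channel roles"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[1], self.image.shape[2]

    def channel(self, name: str) -> np.ndarray:
        """Return the 2-D plane for a channel role; error names the channel."""
        try:
            idx = self.channels.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not present; available: {self.channels}"
            ) from None
        return self.image[idx]


@dataclass
class GroundTruth:
    """Per-field ground truth, frozen before blur/noise degradation."""

    boxes: list[Annotation] = field(default_factory=list)
    phenotype_labels: list[str] = field(default_factory=list)
    focus_label: bool = True  # True = in focus
    artifact_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.boxes) != len(self.phenotype_labels):
            raise ValueError("boxes and phenotype labels must be equal length")


@dataclass
class ROI:
    """A cropped single-cell patch carrying its source box and optional label."""

    pixels: np.ndarray  # (C, h, w) float32
    source_image: str
    bbox: BBox
    roi_id: str = ""
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 3 or self.pixels.size == 0:
            raise ValueError("ROI patch must be a non-empty (C, h, w) array")


def validate_phenotype(label: str) -> str:
    if label not in PHENOTYPE_CLASSES:
        raise ValueError(
            f"unknown phenotype label {label!r}; expected one of {PHENOTYPE_CLASSES}"
        )
    return label


def stable_seed(*parts: object) -> int:
    """Derive a reproducible 31-bit seed from arbitrary tags.

    Used to fan a single global seed out to pipeline stages and per-field
    noise draws without correlated streams.
    """
    import hashlib

    key = ":".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)
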