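"""Shared fixtures: synthetic fields and phenotype ROI sets.

Everything is generated programmatically at test time from fixed seeds;
session-scoped fixtures cache the larger sets so the suite stays fast.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from maps_hcm.synthetic import (
    SyntheticSpec,
    generate_field,
    render_cell,
    sample_geometry,
)
from maps_hcm.types import ROI, stable_seed


@pytest.fixture(scope="session")
def default_spec() -> SyntheticSpec:
    return SyntheticSpec(seed=0)


@pytest.fixture(scope="session")
def clean_field():
    """One noise-free in-focus field with ground truth."""
    spec = SyntheticSpec(seed=3, noise_multiplier=0.0)
    return generate_field(spec)


@pytest.fixture(scope="session")
def noisy_field():
    """One field at the default noise level."""
    spec = SyntheticSpec(seed=3)
    return generate_field(spec)


@pytest.fixture(scope="session")
def clean_field_set():
    """20 noise-free fields with ground truth (detection benchmark)."""
    out = []
    for i in range(20):
        spec = SyntheticSpec(seed=stable_seed(42, "t5", i), noise_multiplier=0.0)
        out.append(generate_field(spec, field_id=f"f{i:02d}"))
    return out


def make_phenotype_rois(phenotype: str, n: int, seed: int,
                        size: int = 64) -> list[ROI]:
    """Render n single-cell ROIs of one phenotype, resized to `size`."""
    from skimage.transform import resize

    from maps_hcm.types import BBox

    rng = np.random.default_rng(seed)
    spec = SyntheticSpec()
    rois = []
    for i in range(n):
        geom = sample_geometry(spec, rng)
        sprite, _, _ = render_cell(phenotype, geom, rng)
        patch = resize(sprite, (3, size, size), order=1, mode="edge",
                       anti_aliasing=False, preserve_range=True).astype(np.float32)
        rois.append(
            ROI(pixels=patch, source_image=f"synth_{phenotype}",
                bbox=BBox(0.1, 0.1, 0.5, 0.5),
                roi_id=f"{phenotype}:{i}", label=phenotype)
        )
    return rois


def make_garbage_rois(n: int, seed: int, size: int = 64) -> list[ROI]:
    """Structureless random-noise patches (debris/empty crops)."""
    from maps_hcm.types import BBox

    rng = np.random.default_rng(seed)
    return [
        ROI(pixels=rng.uniform(0, 1, (3, size, size)).astype(np.float32),
            source_image="synth_garbage", bbox=BBox(0.1, 0.1, 0.5, 0.5),
            roi_id=f"garbage:{i}", label=None)
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def labeled_phenotype_rois():
    """60 ROIs: 20 per phenotype class, for separation/cluster tests."""
    rois = []
    for i, ph in enumerate(("nuclear", "nuclear_excluded", "diffuse")):
        rois.extend(make_phenotype_rois(ph, 20, seed=100 + i))
    return rois


def blurred_variant(spec: SyntheticSpec, sigma: float, seed: int) -> SyntheticSpec:
    return dataclasses.replace(spec, blur_sigma=sigma, seed=seed)
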