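"""Fruit/background segmentation and ROI mean-spectrum extraction.

The fruit is separated from the dark background by thresholding reflectance at
a single band (fruit tissue is bright in the NIR, the stage is near-black),
keeping the largest 4-connected component, and averaging all fruit pixels into
one spectrum per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .hypercube import HyperCube

__all__ = ["PixelMask", "SegmentationError", "segment_threshold", "mean_spectrum"]


class SegmentationError(ValueError):
    """Raised when thresholding yields no usable fruit region."""


@dataclass
class PixelMask:
    """Boolean fruit mask over the cube's spatial axes (lines x pixels)."""

    values: np.ndarray
    source_band_nm: float
    threshold: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D (lines, pixels)")

    @property
    def n_pixels(self) -> int:
        return int(self.values.sum())


def segment_threshold(
    cube: HyperCube,
    band_nm: float = 800.0,
    threshold: float = 0.2,
    min_pixels: int = 50,
) -> PixelMask:
    """Threshold reflectance at the band nearest ``band_nm``; keep the largest
    4-connected component.

    Defaults (800 nm, reflectance 0.2) suit citrus on a dark stage: fruit
    reflectance is high across 750-950 nm while background stays near zero.
    """
    if cube.kind != "reflectance":
        raise ValueError("segmentation expects a calibrated reflectance cube")
    band = cube.grid.index_of(band_nm)
    plane = cube.values[:, :, band]
    raw_mask = plane >= threshold
    if not raw_mask.any():
        raise SegmentationError(
            f"empty mask: no pixel >= {threshold} at {cube.grid.centers[band]:g} nm "
            f"(max observed reflectance {plane.max():.4f})"
        )
    # 4-connectivity: von Neumann neighborhood
    structure = ndimage.generate_binary_structure(2, 1)
    labels, n_comp = ndimage.label(raw_mask, structure=structure)
    sizes = ndimage.sum_labels(raw_mask, labels, index=np.arange(1, n_comp + 1))
    best = int(np.argmax(sizes)) + 1
    mask = labels == best
    if sizes[best - 1] < min_pixels:
        raise SegmentationError(
            f"largest component has {int(sizes[best - 1])} pixels "
            f"(< min_pixels={min_pixels}) at threshold {threshold}, "
            f"band {cube.grid.centers[band]:g} nm"
        )
    return PixelMask(mask, float(cube.grid.centers[band]), float(threshold))


def mean_spectrum(cube: HyperCube, mask: PixelMask) -> np.ndarray:
    """Per-band arithmetic mean of reflectance over the masked pixels."""
    if mask.values.shape != cube.values.shape[:2]:
        raise ValueError(
            f"mask shape {mask.values.shape} does not match cube spatial "
            f"shape {cube.values.shape[:2]}"
        )
    if mask.n_pixels == 0:
        raise SegmentationError("mask is empty")
    return cube.values[mask.values].mean(axis=0)
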