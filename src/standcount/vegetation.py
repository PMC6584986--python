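"""Vegetation classification: green-ratio segmentation of seedlings.

The classifier is deliberately simple chromaticity thresholding: a pixel is
vegetation when the green band carries more than a fixed share of the total
R+G+B intensity (green ratio G/(R+G+B) > 0.36 by default).  Surviving pixels
are merged into connected components and components smaller than a minimum
pixel area (default 30 px, strict) are discarded as soil speckle.  The
result feeds template matching as a single-channel "plant layer" whose
background is zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_geo import GeoImage

__all__ = [
    "RatioMap",
    "PlantMask",
    "PlantLayer",
    "green_ratio",
    "classify_plants",
    "filter_components",
    "make_plant_layer",
    "segment",
]

DEFAULT_GREEN_RATIO_THRESHOLD = 0.36
DEFAULT_MIN_COMPONENT_PX = 30


@dataclass
class RatioMap:
    """Per-pixel green ratio in [0, 1]; 0 where R+G+B is 0."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("RatioMap must be 2-D")
        self.values = v


@dataclass
class PlantMask:
    """Boolean vegetation mask plus its connected-component labelling."""

    mask: np.ndarray
    labels: np.ndarray
    n_components: int
    component_sizes: np.ndarray  # index 0 unused; sizes[i] = px of label i
    connectivity: int = 8
    min_size: int = DEFAULT_MIN_COMPONENT_PX


@dataclass
class PlantLayer:
    """Single channel of the image with non-plant pixels zeroed."""

    values: np.ndarray
    channel: str
    mask: PlantMask | None = None


def green_ratio(image: GeoImage | np.ndarray) -> RatioMap:
    """Green chromaticity G/(R+G+B), computed in float64.

    Pixels whose bands sum to zero (pure black) get ratio 0: they can never
    be vegetation and a 0 keeps the map total and well-defined.
    """
    px = image.pixels if isinstance(image, GeoImage) else np.asarray(image)
    if px.ndim != 3 or px.shape[2] < 3:
        raise ValueError("green_ratio needs an H x W x 3 image")
    px = px[:, :, :3].astype(np.float64)
    total = px.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, px[:, :, 1] / np.where(total > 0, total, 1.0), 0.0)
    return RatioMap(ratio)


def classify_plants(
    ratio: RatioMap | np.ndarray,
    threshold: float = DEFAULT_GREEN_RATIO_THRESHOLD,
) -> np.ndarray:
    """Boolean mask of pixels with green ratio strictly above ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    values = ratio.values if isinstance(ratio, RatioMap) else np.asarray(ratio)
    return values > threshold


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def filter_components(
    mask: np.ndarray,
    min_size: int = DEFAULT_MIN_COMPONENT_PX,
    connectivity: int = 8,
) -> PlantMask:
    """Merge mask pixels into components; drop those below ``min_size`` px.

    The size cut is strict (< min_size removed), so a component of exactly
    ``min_size`` pixels survives.  Surviving components are relabelled
    1..n in scan order.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n:
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        keep = sizes >= min_size
        keep[0] = False
        relabel = np.zeros(n + 1, dtype=labels.dtype)
        relabel[keep] = np.arange(1, int(keep.sum()) + 1)
        labels = relabel[labels]
        n = int(keep.sum())
        sizes = np.concatenate([[0], sizes[keep]])
    else:
        sizes = np.zeros(1, dtype=np.int64)
    return PlantMask(
        mask=labels > 0,
        labels=labels,
        n_components=n,
        component_sizes=sizes,
        connectivity=connectivity,
        min_size=min_size,
    )


def make_plant_layer(
    image: GeoImage,
    plants: PlantMask,
    channel: str = "green",
) -> PlantLayer:
    """Copy one band where the mask is true, zero elsewhere.

    This is the classified single-channel layer that template matching
    operates on; zeroed background is part of the matching contract.
    """
    if channel not in ("red", "green", "blue"):
        raise ValueError(f"channel must be red/green/blue, got {channel!r}")
    band = image.band(channel).astype(np.float64)
    return PlantLayer(values=np.where(plants.mask, band, 0.0), channel=channel, mask=plants)


def segment(
    image: GeoImage,
    threshold: float = DEFAULT_GREEN_RATIO_THRESHOLD,
    min_size: int = DEFAULT_MIN_COMPONENT_PX,
    connectivity: int = 8,
    channel: str = "green",
) -> PlantLayer:
    """Full Part-I pipeline: ratio -> threshold -> size filter -> layer."""
    mask = classify_plants(green_ratio(image), threshold)
    plants = filter_components(mask, min_size=min_size, connectivity=connectivity)
    return make_plant_layer(image, plants, channel=channel)
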