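"""Crumb-slice texture analysis: masking, segmentation, region statistics.

The workflow mirrors a typical crumb "texture analyzer": load a slice
photograph whose background has been removed (alpha channel or near-white
fill), threshold the within-slice intensities to separate dark pores from
the crumb matrix, label connected components, then summarize counts per
size class and density parameters.  A colourmap rendering maps each
region's area through a per-image normalization for visual inspection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

__all__ = [
    "CrumbImage",
    "PoreRegion",
    "SizeClassConfig",
    "PoreStatistics",
    "NoContrastWarning",
    "load_slice",
    "segment_pores",
    "extract_regions",
    "classify_sizes",
    "render_colourmap",
]

_LUMA = (0.299, 0.587, 0.114)  # ITU-R BT.601, matching PIL's "L" conversion


class NoContrastWarning(UserWarning):
    """The slice has a single intensity value; no threshold exists."""


@dataclass
class CrumbImage:
    """A greyscale slice photo plus the mask separating bread from background."""

    pixels: np.ndarray
    slice_mask: np.ndarray
    scale_px_per_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.slice_mask = np.asarray(self.slice_mask, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if self.pixels.shape != self.slice_mask.shape:
            raise ValueError("pixels and slice_mask must share dimensions")

    @property
    def slice_area(self) -> int:
        return int(self.slice_mask.sum())


@dataclass(frozen=True)
class PoreRegion:
    region_id: int
    area: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]  # min_row, min_col, max_row, max_col (exclusive)
    touches_border: bool
    area_mm2: Optional[float] = None


@dataclass(frozen=True)
class SizeClassConfig:
    """Area bands (px²) and labelling conventions.

    ``small``: [min_area, small_max); ``medium``: [small_max, medium_max);
    ``large``: [medium_max, inf).  Components below ``min_area`` are
    treated as noise and discarded.  The band boundaries are reporting
    conventions, not physical constants — they are echoed in every output.
    """

    small_max: float = 100.0
    medium_max: float = 1000.0
    min_area: float = 2.0
    connectivity: int = 8
    method: str = "otsu"  # or "kmeans"

    def __post_init__(self) -> None:
        if not (0 < self.min_area <= self.small_max < self.medium_max):
            raise ValueError("need 0 < min_area <= small_max < medium_max")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.method not in ("otsu", "kmeans"):
            raise ValueError("method must be 'otsu' or 'kmeans'")


@dataclass(frozen=True)
class PoreStatistics:
    """Air-space counts by size class plus density-description parameters."""

    n_small: int
    n_medium: int
    n_large: int
    n_total: int
    porosity: float
    mean_pore_area: float
    pore_density: float  # pores per 10^4 slice pixels
    config: SizeClassConfig

    def __post_init__(self) -> None:
        if self.n_small + self.n_medium + self.n_large != self.n_total:
            raise ValueError("size-class counts must partition the total")
        if not (0.0 <= self.porosity < 1.0):
            raise ValueError("porosity must lie in [0, 1)")


def load_slice(
    path: str | Path,
    background_mode: str = "white_threshold",
    white_cutoff: float = 250.0,
    scale_px_per_mm: Optional[float] = None,
) -> CrumbImage:
    """Read a slice photograph and derive the slice mask.

    ``background_mode``:

    - ``"alpha"``: mask = pixels with alpha > 0 (requires an alpha channel)
    - ``"white_threshold"`` (default): mask = intensity < ``white_cutoff``
    - ``"none"``: the whole frame is slice

    RGB input is converted to grey by BT.601 luminance weights.  An empty
    resulting mask is an error ("empty slice").
    """
    img = Image.open(path)
    return slice_from_pil(img, background_mode, white_cutoff, scale_px_per_mm)


def slice_from_pil(
    img: Image.Image,
    background_mode: str = "white_threshold",
    white_cutoff: float = 250.0,
    scale_px_per_mm: Optional[float] = None,
) -> CrumbImage:
    if background_mode not in ("alpha", "white_threshold", "none"):
        raise ValueError(f"unknown background_mode {background_mode!r}")
    alpha = None
    if img.mode in ("RGBA", "LA"):
        alpha = np.asarray(img.getchannel("A"))
    arr = np.asarray(img.convert("RGB"), dtype=float)
    grey = arr @ np.asarray(_LUMA)

    if background_mode == "alpha":
        if alpha is None:
            raise ValueError("alpha background mode requires an image with an alpha channel")
        mask = alpha > 0
    elif background_mode == "white_threshold":
        mask = grey < white_cutoff
    else:
        mask = np.ones_like(grey, dtype=bool)
    if not mask.any():
        raise ValueError("empty slice: the background mask removed every pixel")
    return CrumbImage(pixels=grey, slice_mask=mask, scale_px_per_mm=scale_px_per_mm)


def _threshold(values: np.ndarray, method: str) -> float:
    if method == "otsu":
        return float(threshold_otsu(values))
    # 2-means on intensities; deterministic (Lloyd iterations from extremes)
    c = np.array([values.min(), values.max()], dtype=float)
    for _ in range(100):
        assign = np.abs(values[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([
            values[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)
        ])
        if np.allclose(new, c):
            break
        c = new
    return float(c.mean())


def segment_pores(image: CrumbImage, config: SizeClassConfig | None = None) -> np.ndarray:
    """Label the pore pixels of a slice.

    A global threshold is computed from the within-mask histogram by
    between-class variance maximization (Otsu; or 2-means when
    ``config.method == "kmeans"``).  Pixels inside the mask darker than
    the threshold are pore; connected components are labelled at the
    configured connectivity, components smaller than ``min_area`` are
    discarded and labels re-compacted from 1.

    A mask with a single intensity value has no threshold: a
    :class:`NoContrastWarning` is emitted and zero regions are returned.
    """
    config = config or SizeClassConfig()
    if image.slice_area == 0:
        raise ValueError("empty slice mask")
    values = image.pixels[image.slice_mask]
    labels = np.zeros(image.pixels.shape, dtype=np.int32)
    if np.ptp(values) == 0:
        warnings.warn("no contrast within the slice mask", NoContrastWarning, stacklevel=2)
        return labels
    thr = _threshold(values, config.method)
    pore = image.slice_mask & (image.pixels < thr)
    if not pore.any():
        return labels
    raw = sk_label(pore, connectivity=2 if config.connectivity == 8 else 1)
    # drop sub-min_area specks, re-compact ids
    ids, counts = np.unique(raw, return_counts=True)
    keep = ids[(ids > 0) & (counts >= config.min_area)]
    remap = np.zeros(int(raw.max()) + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return remap[raw]


def extract_regions(labels: np.ndarray, image: CrumbImage | None = None) -> list[PoreRegion]:
    """One :class:`PoreRegion` per label: area, centroid, bbox, border flag."""
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label map must be 2-D")
    h, w = labels.shape
    scale = image.scale_px_per_mm if image is not None else None
    regions = []
    for prop in regionprops(labels):
        minr, minc, maxr, maxc = prop.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        area_mm2 = float(prop.area) / scale**2 if scale else None
        regions.append(
            PoreRegion(
                region_id=int(prop.label),
                area=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                bbox=(minr, minc, maxr, maxc),
                touches_border=bool(touches),
                area_mm2=area_mm2,
            )
        )
    return regions


def classify_sizes(
    regions: Sequence[PoreRegion],
    slice_area: float,
    config: SizeClassConfig | None = None,
) -> PoreStatistics:
    """Counts per size band plus porosity, mean pore area and pore density.

    Border-touching pores are counted like any other (they carry a flag
    but no exclusion rule is applied).  With zero regions the mean pore
    area is 0 by convention.
    """
    config = config or SizeClassConfig()
    if slice_area <= 0:
        raise ValueError("slice_area must be positive")
    areas = np.array([r.area for r in regions], dtype=float)
    n_small = int(np.sum((areas >= config.min_area) & (areas < config.small_max)))
    n_medium = int(np.sum((areas >= config.small_max) & (areas < config.medium_max)))
    n_large = int(np.sum(areas >= config.medium_max))
    total_area = float(areas.sum())
    return PoreStatistics(
        n_small=n_small,
        n_medium=n_medium,
        n_large=n_large,
        n_total=n_small + n_medium + n_large,
        porosity=total_area / float(slice_area),
        mean_pore_area=float(areas.mean()) if areas.size else 0.0,
        pore_density=1e4 * len(regions) / float(slice_area),
        config=config,
    )


def render_colourmap(
    labels: np.ndarray,
    regions: Sequence[PoreRegion],
    cmap: str = "viridis",
    background_grey: int = 220,
) -> np.ndarray:
    """RGB rendering with each region coloured by its area.

    Region areas are normalized per image (smallest area -> first colormap
    entry, largest -> last), so a region of a given area may receive
    different colours on different images.  With all areas equal (or a
    single region) the midpoint colour is used.  Matrix and background are
    a neutral grey.  Deterministic for a fixed input.
    """
    import matplotlib

    labels = np.asarray(labels)
    out = np.full(labels.shape + (3,), background_grey, dtype=np.uint8)
    if not regions:
        return out
    colormap = matplotlib.colormaps[cmap]
    areas = np.array([r.area for r in regions], dtype=float)
    lo, hi = areas.min(), areas.max()
    for region, area in zip(regions, areas):
        frac = 0.5 if hi == lo else (area - lo) / (hi - lo)
        rgb = (np.asarray(colormap(frac)[:3]) * 255).round().astype(np.uint8)
        out[labels == region.region_id] = rgb
    return out
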