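"""SEM micrograph quantification of adhered bacteria.

Pipeline stages (each an independent function, chained by
:func:`quantify_image`):

1. ``preprocess``      — contrast-limited adaptive histogram equalization,
                         Gaussian denoising, background subtraction
                         (large-window morphological opening), rescale to
                         [0, 1].
2. ``binarize``        — local-mean adaptive threshold with an additive
                         offset margin, then area-based artifact removal.
3. ``split_touching``  — Euclidean distance transform + marker-controlled
                         watershed to delineate overlapping cells.
4. ``measure``         — connected-component morphometrics: area,
                         perimeter, circularity 4*pi*A/P^2, solidity
                         (area / convex-hull area), centroid.  Masks are
                         smoothed by a small morphological closing before
                         measurement.
5. ``classify``        — single cell vs aggregate from area, circularity
                         and solidity thresholds.
6. ``summarize``       — class counts, surface coverage, and the
                         coverage-scaled bacterial count using the mean
                         area occupied per bacterium (default 0.0077% of
                         the surface).

Object counting operates on connected components; the watershed split is
exposed for resolving constituent cells inside aggregates rather than
applied in the default counting path, so that an aggregate is counted and
classified as one (multi-cell) object.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import exposure, filters, measure as skmeasure, morphology, segmentation
from skimage.feature import peak_local_max

from .errors import ParameterError

__all__ = [
    "ImageRecord",
    "ParticleRecord",
    "AdhesionSummary",
    "PER_BACTERIUM_FRACTION",
    "DEFAULT_CELL_DIAMETER_UM",
    "preprocess",
    "binarize",
    "split_touching",
    "measure",
    "classify",
    "summarize",
    "quantify_image",
]

#: Mean fraction of the surface occupied by one bacterium (0.0077%).
PER_BACTERIUM_FRACTION = 7.7e-5

#: Nominal coccus diameter, um.
DEFAULT_CELL_DIAMETER_UM = 0.8


@dataclass(frozen=True)
class ImageRecord:
    """A grayscale micrograph with its physical pixel scale (um/pixel)."""

    pixels: np.ndarray
    pixel_size: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if not np.all(np.isfinite(self.pixels)):
            raise ParameterError("image contains non-finite intensities")


@dataclass(frozen=True)
class ParticleRecord:
    """One segmented object and its shape descriptors."""

    label: int
    area_px: int
    area_um2: float
    perimeter_px: float
    circularity: float
    solidity: float
    centroid: tuple[float, float]
    morphology_class: str | None = None  # "single" | "aggregate"


@dataclass(frozen=True)
class AdhesionSummary:
    """Image-level counts, coverage, and the coverage-scaled estimate."""

    n_total: int
    n_single: int
    n_aggregate: int
    coverage_fraction: float
    scaled_count: float


def preprocess(
    img: ImageRecord,
    clahe_clip: float = 0.01,
    gaussian_sigma: float = 1.0,
    bg_radius: int = 40,
) -> ImageRecord:
    """Contrast enhancement, denoising and illumination flattening.

    CLAHE (clip limit ``clahe_clip``) improves local contrast without
    over-enhancement, Gaussian smoothing (``gaussian_sigma``) suppresses
    high-frequency sensor noise, and a grayscale opening with a
    ``(2*bg_radius+1)``-pixel square window estimates the smooth
    background, which is subtracted to correct illumination
    non-uniformity.  Output intensities lie in [0, 1]; a constant input
    maps to a constant output.
    """
    a = np.asarray(img.pixels, dtype=float)
    if 2 * bg_radius + 1 > min(a.shape):
        raise ParameterError("background window larger than image")
    ptp = np.ptp(a)
    if ptp == 0:
        return replace(img, pixels=np.zeros_like(a))
    a = (a - a.min()) / ptp
    a = exposure.equalize_adapthist(a, clip_limit=clahe_clip)
    a = filters.gaussian(a, sigma=gaussian_sigma)
    background = ndi.grey_opening(a, size=(2 * bg_radius + 1, 2 * bg_radius + 1))
    # opening never exceeds the image, so the difference stays in [0, 1];
    # no max-rescale here or a blank field would amplify its own noise
    a = np.clip(a - background, 0.0, 1.0)
    return replace(img, pixels=a)


def binarize(
    img: ImageRecord,
    block_size: int = 51,
    offset: float = 0.15,
    min_area: int = 30,
    dark_objects: bool = False,
) -> np.ndarray:
    """Adaptive local-mean threshold plus area-based artifact filtering.

    A pixel is foreground when it exceeds the mean of its
    ``block_size``-pixel neighbourhood by more than ``offset`` (or falls
    below it, for ``dark_objects``).  Connected regions smaller than
    ``min_area`` pixels are removed.
    """
    if block_size < 3 or block_size % 2 == 0:
        raise ParameterError("block_size must be odd and >= 3")
    a = np.asarray(img.pixels, dtype=float)
    local_mean = filters.threshold_local(a, block_size=block_size, method="mean")
    mask = (local_mean - a > offset) if dark_objects else (a - local_mean > offset)
    return morphology.remove_small_objects(mask, max_size=min_area - 1)


def split_touching(mask: np.ndarray, min_distance: int = 7) -> np.ndarray:
    """Separate touching cells by distance-transform watershed.

    Peaks of the Euclidean distance transform (minimum separation
    ``min_distance``, at least one peak per connected component) seed a
    marker-controlled watershed on the inverted distance map.  Every
    foreground pixel receives exactly one positive label.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    components, _ = ndi.label(mask)
    coords = peak_local_max(
        distance, min_distance=min_distance, labels=components, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    # a component whose every peak was suppressed still needs a marker
    marked = set(np.unique(components[markers > 0]))
    for lab in np.unique(components[components > 0]):
        if lab not in marked:
            idx = np.unravel_index(
                np.argmax(np.where(components == lab, distance, -1)), mask.shape
            )
            markers[idx] = markers.max() + 1
    return segmentation.watershed(-distance, markers, mask=mask)


def _smooth_region(region_mask: np.ndarray, closing_radius: int) -> np.ndarray:
    pad = closing_radius + 1
    padded = np.pad(region_mask, pad)
    closed = morphology.closing(padded, morphology.disk(closing_radius))
    return closed


def measure(
    labels: np.ndarray, pixel_size: float, closing_radius: int = 1
) -> list[ParticleRecord]:
    """Per-object morphometrics from a labeled mask.

    Each object's binary mask is smoothed by a morphological closing
    (``closing_radius``) before measurement, then area, perimeter,
    circularity (4*pi*A/P^2), solidity and centroid are extracted.
    Returns an empty list for an empty mask.
    """
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be positive")
    records: list[ParticleRecord] = []
    for region in skmeasure.regionprops(np.asarray(labels)):
        closed = _smooth_region(region.image, closing_radius)
        props = skmeasure.regionprops(closed.astype(np.uint8))[0]
        area = int(props.area)
        perim = float(props.perimeter)
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else np.nan
        pad = closing_radius + 1
        r0, c0 = region.bbox[0] - pad, region.bbox[1] - pad
        cy, cx = props.centroid
        records.append(
            ParticleRecord(
                label=int(region.label),
                area_px=area,
                area_um2=area * pixel_size**2,
                perimeter_px=perim,
                circularity=float(circ),
                solidity=float(props.solidity),
                centroid=(r0 + cy, c0 + cx),
            )
        )
    return records


def classify(
    particles: list[ParticleRecord],
    area_single_max_um2: float | None = None,
    circ_min: float = 0.7,
    solid_min: float = 0.9,
    cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM,
) -> list[ParticleRecord]:
    """Label each particle ``single`` or ``aggregate`` from shape metrics.

    A particle is a single cell iff its area is at most
    ``area_single_max_um2`` (default 1.5x the nominal cell cross-section)
    AND circularity >= ``circ_min`` AND solidity >= ``solid_min``;
    boundary values count as single (inclusive thresholds).  All
    thresholds are in physical units so the rule is pixel-scale
    invariant.
    """
    if area_single_max_um2 is None:
        area_single_max_um2 = 1.5 * np.pi * (cell_diameter_um / 2.0) ** 2
    out = []
    for p in particles:
        is_single = (
            p.area_um2 <= area_single_max_um2
            and p.circularity >= circ_min
            and p.solidity >= solid_min
        )
        out.append(replace(p, morphology_class="single" if is_single else "aggregate"))
    return out


def summarize(
    particles: list[ParticleRecord],
    mask: np.ndarray,
    per_bacterium_fraction: float = PER_BACTERIUM_FRACTION,
) -> AdhesionSummary:
    """Counts by class, surface coverage, and the coverage-scaled count.

    ``scaled_count = coverage_fraction / per_bacterium_fraction`` converts
    fractional surface coverage into an estimated number of bacteria via
    the mean surface fraction occupied by one cell.
    """
    if per_bacterium_fraction <= 0:
        raise ParameterError("per_bacterium_fraction must be positive")
    mask = np.asarray(mask, dtype=bool)
    n_single = sum(p.morphology_class == "single" for p in particles)
    n_aggregate = sum(p.morphology_class == "aggregate" for p in particles)
    coverage = float(mask.sum()) / mask.size
    return AdhesionSummary(
        n_total=n_single + n_aggregate,
        n_single=n_single,
        n_aggregate=n_aggregate,
        coverage_fraction=coverage,
        scaled_count=coverage / per_bacterium_fraction,
    )


def quantify_image(
    img: ImageRecord,
    clahe_clip: float = 0.01,
    gaussian_sigma: float = 1.0,
    bg_radius: int = 40,
    block_size: int = 51,
    offset: float = 0.15,
    min_area: int = 30,
    area_single_max_um2: float | None = None,
    circ_min: float = 0.7,
    solid_min: float = 0.9,
) -> tuple[list[ParticleRecord], AdhesionSummary]:
    """Full pipeline: preprocess, binarize, measure, classify, summarize."""
    pre = preprocess(img, clahe_clip, gaussian_sigma, bg_radius)
    mask = binarize(pre, block_size, offset, min_area)
    labels, _ = ndi.label(mask)
    particles = measure(labels, img.pixel_size)
    particles = classify(
        particles,
        area_single_max_um2=area_single_max_um2,
        circ_min=circ_min,
        solid_min=solid_min,
    )
    return particles, summarize(particles, mask)
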