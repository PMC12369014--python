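"""Ground-truthed synthetic inputs for every pipeline stage.

``generate_image`` renders SEM-like micrographs of cocci: bright
anti-aliased discs (~0.8 um diameter) on a darker background, either
isolated single cells, deliberately touching single-cell pairs, or
multi-cell cluster aggregates, degraded by a smooth illumination gradient
and Gaussian sensor noise.  Every image ships its exact ground truth
(per-object class, centroid, constituent-cell count, coverage), so the
quantification pipeline can be validated without any real micrograph.

``generate_count_table`` emulates the factorial count data behind the
adhesion statistics (treatment x morphology, balanced), for exercising
the t-test and two-way ANOVA.

Both generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .sem_quant import DEFAULT_CELL_DIAMETER_UM, ImageRecord

__all__ = [
    "SyntheticImageSpec",
    "TruthParticle",
    "GroundTruth",
    "generate_image",
    "generate_count_table",
]


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of one synthetic micrograph.

    Defaults mirror the study conditions: a 1024 x 1024 field at
    0.05 um/pixel with 0.8 um cocci, 5% of singles placed as touching
    pairs, Gaussian noise of SD 0.05 and a 0.1-amplitude illumination
    ramp on [0, 1] intensities.
    """

    image_size: int = 1024
    pixel_size: float = 0.05          # um / pixel
    n_singles: int = 50
    n_clusters: int = 10
    cluster_size_range: tuple[int, int] = (3, 6)
    cell_diameter_um: float = DEFAULT_CELL_DIAMETER_UM
    overlap_fraction: float = 0.05    # proportion of singles placed as touching pairs
    noise_sd: float = 0.05
    gradient_amplitude: float = 0.1
    bg_level: float = 0.2
    fg_level: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_singles < 0 or self.n_clusters < 0:
            raise ParameterError("counts must be >= 0")
        if self.cell_diameter_um <= 0:
            raise ParameterError("cell_diameter_um must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ParameterError("overlap_fraction must be in [0, 1]")
        lo, hi = self.cluster_size_range
        if lo < 2 or hi < lo:
            raise ParameterError("cluster_size_range must satisfy 2 <= lo <= hi")


@dataclass(frozen=True)
class TruthParticle:
    """Ground truth for one rendered object (a component of the image)."""

    kind: str                      # "single" | "aggregate"
    centroid: tuple[float, float]  # (row, col), pixels
    n_cells: int


@dataclass
class GroundTruth:
    """Exact generative record of a synthetic micrograph."""

    particles: list[TruthParticle]
    mask: np.ndarray               # noiseless foreground mask
    coverage_fraction: float

    @property
    def n_objects(self) -> int:
        return len(self.particles)

    @property
    def n_singles(self) -> int:
        return sum(p.kind == "single" for p in self.particles)

    @property
    def n_clusters(self) -> int:
        return sum(p.kind == "aggregate" for p in self.particles)

    @property
    def total_cells(self) -> int:
        return sum(p.n_cells for p in self.particles)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": [p.kind for p in self.particles],
                "row": [p.centroid[0] for p in self.particles],
                "col": [p.centroid[1] for p in self.particles],
                "n_cells": [p.n_cells for p in self.particles],
            }
        )


def _draw_cell(canvas: np.ndarray, mask: np.ndarray, cy: float, cx: float,
               r: float, bg: float, fg: float) -> None:
    """Stamp one anti-aliased bright disc; update the hard foreground mask."""
    n = canvas.shape[0]
    r_int = int(np.ceil(r)) + 1
    y0, y1 = max(0, int(cy) - r_int), min(n, int(cy) + r_int + 1)
    x0, x1 = max(0, int(cx) - r_int), min(n, int(cx) + r_int + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.hypot(yy - cy, xx - cx)
    alpha = np.clip(r + 0.5 - dist, 0.0, 1.0)
    canvas[y0:y1, x0:x1] = np.maximum(canvas[y0:y1, x0:x1], bg + alpha * (fg - bg))
    mask[y0:y1, x0:x1] |= dist <= r


def _sample_center(rng, n, margin, placed, own_radius, clearance):
    """Rejection-sample an object center clear of previously placed objects."""
    for _ in range(5000):
        cy = rng.uniform(margin, n - margin)
        cx = rng.uniform(margin, n - margin)
        if all(
            np.hypot(cy - py, cx - px) >= own_radius + pr + clearance
            for py, px, pr in placed
        ):
            return cy, cx
    raise ParameterError("particle demand exceeds packable area")


def generate_image(spec: SyntheticImageSpec) -> tuple[ImageRecord, GroundTruth]:
    """Render one synthetic micrograph and its exact ground truth.

    Touching single-cell pairs (a fraction ``overlap_fraction`` of the
    singles, paired up) are rendered with centre separation 1.6 cell
    radii, so the pair merges into one blob; both members remain
    ``single`` in the ground truth.  Cluster cells are packed at
    1.0-1.3 radii from an existing member, forming one connected
    aggregate.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    r = spec.cell_diameter_um / (2.0 * spec.pixel_size)  # cell radius, px
    canvas = np.full((n, n), spec.bg_level, dtype=float)
    mask = np.zeros((n, n), dtype=bool)
    placed: list[tuple[float, float, float]] = []  # (row, col, footprint radius)
    particles: list[TruthParticle] = []
    clearance = 3.0 * r
    margin = 6.0 * r

    n_pairs = int(np.floor(spec.overlap_fraction * spec.n_singles / 2.0))
    n_isolated = spec.n_singles - 2 * n_pairs

    for _ in range(n_isolated):
        cy, cx = _sample_center(rng, n, margin, placed, r, clearance)
        _draw_cell(canvas, mask, cy, cx, r, spec.bg_level, spec.fg_level)
        placed.append((cy, cx, r))
        particles.append(TruthParticle("single", (cy, cx), 1))

    for _ in range(n_pairs):
        cy, cx = _sample_center(rng, n, margin, placed, 2.0 * r, clearance)
        theta = rng.uniform(0, 2 * np.pi)
        d = 1.6 * r
        for s in (-0.5, 0.5):
            py = cy + s * d * np.sin(theta)
            px = cx + s * d * np.cos(theta)
            _draw_cell(canvas, mask, py, px, r, spec.bg_level, spec.fg_level)
            particles.append(TruthParticle("single", (py, px), 1))
        placed.append((cy, cx, 2.0 * r))

    lo, hi = spec.cluster_size_range
    for _ in range(spec.n_clusters):
        k = int(rng.integers(lo, hi + 1))
        footprint = r * (1.5 + 0.7 * k)
        cy, cx = _sample_center(rng, n, margin, placed, footprint, clearance)
        cells = [(cy, cx)]
        while len(cells) < k:
            ay, ax = cells[int(rng.integers(len(cells)))]
            theta = rng.uniform(0, 2 * np.pi)
            d = r * rng.uniform(1.0, 1.3)
            py, px = ay + d * np.sin(theta), ax + d * np.cos(theta)
            if np.hypot(py - cy, px - cx) <= footprint:
                cells.append((py, px))
        for py, px in cells:
            _draw_cell(canvas, mask, py, px, r, spec.bg_level, spec.fg_level)
        centroid = (float(np.mean([c[0] for c in cells])),
                    float(np.mean([c[1] for c in cells])))
        placed.append((cy, cx, footprint))
        particles.append(TruthParticle("aggregate", centroid, k))

    if spec.gradient_amplitude > 0:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:n, 0:n] / (n - 1.0)
        ramp = np.cos(theta) * xx + np.sin(theta) * yy
        ramp = (ramp - ramp.mean()) / max(np.ptp(ramp), 1e-12)
        canvas = canvas + spec.gradient_amplitude * ramp
    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 1.0)

    truth = GroundTruth(
        particles=particles,
        mask=mask,
        coverage_fraction=float(mask.sum()) / mask.size,
    )
    return ImageRecord(pixels=canvas, pixel_size=spec.pixel_size,
                       source_id=f"synthetic-seed{spec.seed}"), truth


def generate_count_table(
    mean_a: float,
    mean_b: float,
    sd: float,
    n_per_group: int,
    seed: int = 0,
    treatments: tuple[str, str] = ("hydro-softened", "unsoftened"),
    morphologies: tuple[str, str] = ("single", "aggregate"),
) -> pd.DataFrame:
    """Balanced factorial count table emulating the adhesion-count design.

    Each (treatment, morphology) cell receives ``n_per_group`` Gaussian
    counts around the treatment mean (``mean_a`` for the first treatment,
    ``mean_b`` for the second), rounded to integers and clipped at zero.
    """
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    if sd < 0:
        raise ParameterError("sd must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for treat, mean in zip(treatments, (mean_a, mean_b)):
        for morph in morphologies:
            vals = np.clip(np.round(rng.normal(mean, sd, n_per_group)), 0, None)
            rows.extend(
                {"treatment": treat, "morphology": morph, "count": int(v)}
                for v in vals
            )
    return pd.DataFrame(rows)
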