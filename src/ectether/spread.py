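"""Prometaphase-spread metrics.

An ecDNA connected component is scored by the fraction of its boundary
pixels that touch chromosome-class pixels: below 25% it is untethered,
from 25% up to (but excluding) 100% it is tethered, and at exactly 100%
it is surrounded and dropped from the untethering denominator. Boundary
pixels are component pixels with at least one 8-neighbour outside the
component; pixels on the image border count as boundary with the
out-of-image side treated as non-chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import FluorImage
from .segmentation import (
    CHROMOSOME,
    ECDNA,
    BinaryMask,
    ComponentRecord,
    LabelMask,
)

__all__ = [
    "TetherParams",
    "SpreadMetrics",
    "adjacency_fraction",
    "classify_tether",
    "summarize_spread",
    "convex_hull_area",
    "class_intensity_ratio",
]

_NEIGHBOR_OFFSETS = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


@dataclass
class TetherParams:
    """Perimeter-adjacency cutoffs for tether classes."""

    untethered_max_frac: float = 0.25
    surrounded_frac: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.untethered_max_frac < self.surrounded_frac <= 1):
            raise ValueError("require 0 < untethered_max_frac < surrounded_frac <= 1")


@dataclass
class SpreadMetrics:
    """Per-cell spread summary."""

    n_chromosome_cc: int = 0
    n_untethered: int = 0
    n_tethered: int = 0
    n_surrounded: int = 0
    untethering_pct: float | None = None
    hull_area_px: int | None = None
    h3ac_ratio_chromosome: float | None = None
    h3ac_ratio_ecdna: float | None = None

    @property
    def n_ecdna_cc(self) -> int:
        return self.n_untethered + self.n_tethered + self.n_surrounded


def adjacency_fraction(component: ComponentRecord, labels: LabelMask) -> float:
    """Fraction of a component's boundary pixels adjacent to chromosome.

    Fills ``boundary_px`` and ``boundary_adj_chrom_px`` on the record.
    """
    if component.area_px == 0 or not component.pixel_list:
        raise ValueError("component has no pixels")
    grid = labels.pixels
    n_rows, n_cols = grid.shape
    pixels = component.pixel_list
    boundary = 0
    adj_chrom = 0
    for (r, c) in pixels:
        is_boundary = False
        touches_chrom = False
        for dr, dc in _NEIGHBOR_OFFSETS:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < n_rows and 0 <= nc < n_cols):
                is_boundary = True  # out-of-image side is outside, non-chromosome
                continue
            if (nr, nc) not in pixels:
                is_boundary = True
                if grid[nr, nc] == CHROMOSOME:
                    touches_chrom = True
        if is_boundary:
            boundary += 1
            if touches_chrom:
                adj_chrom += 1
    component.boundary_px = boundary
    component.boundary_adj_chrom_px = adj_chrom
    return adj_chrom / boundary if boundary else 0.0


def classify_tether(frac: float, params: TetherParams | None = None) -> str:
    """Map an adjacency fraction to ``untethered``/``tethered``/``surrounded``."""
    params = params or TetherParams()
    if not (0 <= frac <= 1):
        raise ValueError(f"adjacency fraction {frac} outside [0, 1]")
    if frac < params.untethered_max_frac:
        return "untethered"
    if frac >= params.surrounded_frac:
        return "surrounded"
    return "tethered"


def summarize_spread(
    labels: LabelMask,
    components: list[ComponentRecord],
    params: TetherParams | None = None,
) -> SpreadMetrics:
    """Tether-class counts, untethering percentage and individualization.

    ``untethering_pct`` is untethered over (untethered + tethered);
    surrounded components are excluded from the denominator. With no
    eligible ecDNA components the percentage is missing (None).
    """
    params = params or TetherParams()
    metrics = SpreadMetrics()
    for comp in components:
        if comp.class_code == CHROMOSOME:
            metrics.n_chromosome_cc += 1
        elif comp.class_code == ECDNA:
            frac = adjacency_fraction(comp, labels)
            tether = classify_tether(frac, params)
            if tether == "untethered":
                metrics.n_untethered += 1
            elif tether == "tethered":
                metrics.n_tethered += 1
            else:
                metrics.n_surrounded += 1
    denom = metrics.n_untethered + metrics.n_tethered
    if denom > 0:
        metrics.untethering_pct = 100.0 * metrics.n_untethered / denom
    return metrics


def _cross(o, a, b) -> int:
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _hull_monotone_chain(points: np.ndarray) -> list[tuple[int, int]]:
    """Convex hull of integer points, counterclockwise, collinear dropped."""
    pts = sorted({(int(p[0]), int(p[1])) for p in points})
    if len(pts) <= 2:
        return pts
    lower: list[tuple[int, int]] = []
    for p in pts:
        while len(lower) >= 2 and _cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[tuple[int, int]] = []
    for p in reversed(pts):
        while len(upper) >= 2 and _cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = lower[:-1] + upper[:-1]
    if len(hull) >= 3:
        area2 = sum(
            _cross(hull[0], hull[i], hull[i + 1]) for i in range(1, len(hull) - 1)
        )
        if area2 < 0:  # normalize orientation so interior cross products are >= 0
            hull.reverse()
    return hull


def convex_hull_area(dapi_mask: BinaryMask, fish_mask: BinaryMask) -> int:
    """Pixels inside or on the convex hull of the DAPI|FISH union.

    Counts pixel centers; exact integer arithmetic, boundary inclusive.
    Empty union gives 0.
    """
    if dapi_mask.shape != fish_mask.shape:
        raise ValueError("masks must share shape")
    union = dapi_mask.pixels.astype(bool) | fish_mask.pixels.astype(bool)
    coords = np.argwhere(union)
    if coords.shape[0] == 0:
        return 0
    hull = _hull_monotone_chain(coords)
    r0, c0 = coords.min(axis=0)
    r1, c1 = coords.max(axis=0)
    rr, cc = np.meshgrid(
        np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
    )
    if len(hull) == 1:
        return 1
    if len(hull) == 2:
        # degenerate: all points collinear; count lattice centers on the segment
        (ar, ac), (br, bc) = hull
        cross = (br - ar) * (cc - ac) - (bc - ac) * (rr - ar)
        dot = (rr - ar) * (br - ar) + (cc - ac) * (bc - ac)
        seg_len2 = (br - ar) ** 2 + (bc - ac) ** 2
        on_seg = (cross == 0) & (dot >= 0) & (dot <= seg_len2)
        return int(on_seg.sum())
    inside = np.ones(rr.shape, dtype=bool)
    for i in range(len(hull)):
        ar, ac = hull[i]
        br, bc = hull[(i + 1) % len(hull)]
        # ccw polygon: interior has nonnegative cross product for every edge
        cross = (br - ar) * (cc - ac) - (bc - ac) * (rr - ar)
        inside &= cross >= 0
    return int(inside.sum())


def class_intensity_ratio(
    if_image: FluorImage,
    dapi_image: FluorImage,
    labels: LabelMask,
    class_code: int,
) -> float | None:
    """Mean IF over mean DAPI across one pixel class (DNA-content normalized)."""
    if if_image.shape != dapi_image.shape or if_image.shape != labels.shape:
        raise ValueError("images and labels must share shape")
    sel = labels.pixels == class_code
    if not sel.any():
        return None
    dapi_mean = float(dapi_image.pixels[sel].mean())
    if dapi_mean == 0:
        raise ZeroDivisionError("zero mean DAPI intensity over class pixels")
    return float(if_image.pixels[sel].mean()) / dapi_mean
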