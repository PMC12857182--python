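"""Coverslip-cell metrics.

Metaphase untethering counts FISH-positive pixels off the genomic mass
(the largest DAPI component); daughter-pair metrics partition nuclei by
size rank into primaries, micronuclei and debris; foci counting applies
the more-than-five-pixels rule after Otsu segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .imaging import FluorImage
from .segmentation import (
    BinaryMask,
    DegenerateHistogramError,
    SegParams,
    binarize_channel,
    label_components,
)

__all__ = [
    "MetaphaseMetrics",
    "DaughterPairMetrics",
    "FociParams",
    "NucleiPartitionParams",
    "NucleiPartition",
    "PARTITION_BACKGROUND",
    "PARTITION_PRIMARY",
    "PARTITION_MICRONUCLEUS",
    "PARTITION_DEBRIS",
    "metaphase_untethering",
    "partition_daughter_nuclei",
    "micronuclei_metrics",
    "count_foci",
    "integrated_density",
    "classify_expression_tier",
    "line_profile_fit",
    "LineProfileFit",
]

PARTITION_BACKGROUND = 0
PARTITION_PRIMARY = 1
PARTITION_MICRONUCLEUS = 2
PARTITION_DEBRIS = 3
_PARTITION_CODES = frozenset(
    {PARTITION_BACKGROUND, PARTITION_PRIMARY, PARTITION_MICRONUCLEUS, PARTITION_DEBRIS}
)


@dataclass
class MetaphaseMetrics:
    genomic_mass_area_px: int
    myc_px_total: int
    myc_px_untethered: int
    untethered_pct: float | None


@dataclass
class DaughterPairMetrics:
    has_micronuclei: bool
    n_micronuclei: int
    myc_in_mn_pct: float | None
    mn_composition_pct: float | None


@dataclass
class FociParams:
    """Size rule for focus counting: components of >= min_focus_px count
    (the default 6 encodes "more than five pixels")."""

    min_focus_px: int = 6

    def __post_init__(self) -> None:
        if self.min_focus_px < 1:
            raise ValueError("min_focus_px must be >= 1")


@dataclass
class NucleiPartitionParams:
    """Automated stand-in for manual primary/micronucleus labeling.

    The ``n_primary`` largest DAPI components are primaries; remaining
    components with area in [min_mn_area_px, max_mn_area_frac x smallest
    primary area] are micronuclei; smaller ones are debris.
    """

    n_primary: int = 2
    min_mn_area_px: int = 10
    max_mn_area_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")
        if self.min_mn_area_px < 1:
            raise ValueError("min_mn_area_px must be >= 1")
        if not (0 < self.max_mn_area_frac < 1):
            raise ValueError("max_mn_area_frac must be in (0, 1)")


@dataclass
class NucleiPartition:
    """Per-pixel nucleus partition: 0 bg, 1 primary, 2 micronucleus, 3 debris."""

    pixels: np.ndarray
    provenance: str = "surrogate"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("partition must be 2-D")
        present = set(np.unique(px).tolist())
        if not present <= _PARTITION_CODES:
            raise ValueError(f"unknown partition codes {sorted(present - _PARTITION_CODES)}")
        self.pixels = px.astype(np.int32)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_micronuclei(self) -> int:
        labeled = measure.label(self.pixels == PARTITION_MICRONUCLEUS, connectivity=2)
        return int(labeled.max())


def metaphase_untethering(
    dapi_mask: BinaryMask,
    fish_mask: BinaryMask,
    params: SegParams | None = None,
) -> MetaphaseMetrics:
    """Untethered FISH pixel percentage against the genomic mass.

    The genomic mass is the largest DAPI component (ties broken toward
    the lowest component id); FISH-positive pixels overlapping it are
    tethered, all others untethered.
    """
    params = params or SegParams()
    if dapi_mask.shape != fish_mask.shape:
        raise ValueError("masks must share shape")
    if not dapi_mask.pixels.any():
        raise ValueError("empty DAPI mask: no genomic mass")
    components = label_components(dapi_mask, params)
    mass = max(components, key=lambda c: (c.area_px, -c.component_id))
    mass_grid = np.zeros(dapi_mask.shape, dtype=bool)
    rows, cols = zip(*mass.pixel_list)
    mass_grid[list(rows), list(cols)] = True
    fish = fish_mask.pixels.astype(bool)
    total = int(fish.sum())
    untethered = int((fish & ~mass_grid).sum())
    pct = 100.0 * untethered / total if total > 0 else None
    return MetaphaseMetrics(
        genomic_mass_area_px=mass.area_px,
        myc_px_total=total,
        myc_px_untethered=untethered,
        untethered_pct=pct,
    )


def partition_daughter_nuclei(
    dapi_mask: BinaryMask,
    params: NucleiPartitionParams | None = None,
    annotation: NucleiPartition | None = None,
) -> NucleiPartition:
    """Split DAPI components into primary nuclei, micronuclei and debris.

    An imported annotation is validated and passed through unchanged.
    """
    params = params or NucleiPartitionParams()
    if annotation is not None:
        if annotation.shape != dapi_mask.shape:
            raise ValueError("annotation shape must match mask")
        return NucleiPartition(annotation.pixels, provenance="imported")
    if not dapi_mask.pixels.any():
        raise ValueError("empty DAPI mask")
    components = label_components(dapi_mask)
    if len(components) < params.n_primary:
        raise ValueError(
            f"found {len(components)} components, need >= {params.n_primary} primaries"
        )
    ranked = sorted(components, key=lambda c: (-c.area_px, c.component_id))
    primaries = ranked[: params.n_primary]
    rest = ranked[params.n_primary:]
    max_mn_area = params.max_mn_area_frac * primaries[-1].area_px
    out = np.zeros(dapi_mask.shape, dtype=np.int32)
    for comp in primaries:
        rows, cols = zip(*comp.pixel_list)
        out[list(rows), list(cols)] = PARTITION_PRIMARY
    for comp in rest:
        rows, cols = zip(*comp.pixel_list)
        if params.min_mn_area_px <= comp.area_px <= max_mn_area:
            out[list(rows), list(cols)] = PARTITION_MICRONUCLEUS
        else:
            out[list(rows), list(cols)] = PARTITION_DEBRIS
    return NucleiPartition(out, provenance="surrogate")


def micronuclei_metrics(
    partition: NucleiPartition, fish_mask: BinaryMask
) -> DaughterPairMetrics:
    """MYC share in micronuclei and micronucleus MYC/DAPI composition.

    ``myc_in_mn_pct`` divides micronuclear FISH pixels by FISH pixels in
    primaries plus micronuclei; ``mn_composition_pct`` divides them by
    micronuclear DAPI pixels.
    """
    if partition.shape != fish_mask.shape:
        raise ValueError("partition and FISH mask must share shape")
    fish = fish_mask.pixels.astype(bool)
    in_mn = partition.pixels == PARTITION_MICRONUCLEUS
    in_primary = partition.pixels == PARTITION_PRIMARY
    fish_mn = int((fish & in_mn).sum())
    fish_nuclear = int((fish & (in_mn | in_primary)).sum())
    mn_dapi = int(in_mn.sum())
    n_mn = partition.n_micronuclei
    myc_in_mn = 100.0 * fish_mn / fish_nuclear if fish_nuclear > 0 else None
    composition = 100.0 * fish_mn / mn_dapi if mn_dapi > 0 else None
    return DaughterPairMetrics(
        has_micronuclei=n_mn > 0,
        n_micronuclei=n_mn,
        myc_in_mn_pct=myc_in_mn,
        mn_composition_pct=composition,
    )


def count_foci(
    if_image: FluorImage,
    params: SegParams | None = None,
    foci: FociParams | None = None,
    cell_mask: BinaryMask | None = None,
) -> int:
    """Number of IF foci of at least ``min_focus_px`` pixels.

    Segments by the higher 3-class Otsu threshold; a degenerate histogram
    (e.g. a blank image) counts zero foci with a warning.
    """
    params = params or SegParams(threshold_rule="higher")
    foci = foci or FociParams()
    try:
        mask = binarize_channel(if_image, params)
    except DegenerateHistogramError:
        warnings.warn("degenerate histogram: counting 0 foci", stacklevel=2)
        return 0
    grid = mask.pixels
    if cell_mask is not None:
        if cell_mask.shape != mask.shape:
            raise ValueError("cell mask shape must match image")
        grid = grid * cell_mask.pixels
    components = label_components(BinaryMask(grid), params)
    return sum(1 for c in components if c.area_px >= foci.min_focus_px)


def integrated_density(if_image: FluorImage, region: BinaryMask) -> float:
    """Sum of intensities over the region (total IF signal)."""
    if if_image.shape != region.shape:
        raise ValueError("image and region must share shape")
    if not region.pixels.any():
        warnings.warn("empty region: integrated density is 0", stacklevel=2)
        return 0.0
    return float(if_image.pixels[region.pixels.astype(bool)].sum())


def classify_expression_tier(
    densities, background_cutoff: float, top_frac: float = 0.20
) -> list[str]:
    """Per-cell expression tiers: negative / positive / high.

    Cells below ``background_cutoff`` are negative. Among expressing
    cells, those at or above the (1 - top_frac) linear-interpolation
    quantile are high (ties inclusive); the rest are positive.
    """
    densities = np.asarray(list(densities), dtype=float)
    if densities.size == 0:
        raise ValueError("no densities given")
    if not (0 < top_frac < 1):
        raise ValueError("top_frac must be in (0, 1)")
    tiers = np.full(densities.shape, "negative", dtype=object)
    expressing = densities >= background_cutoff
    if expressing.any():
        cutoff = float(np.quantile(densities[expressing], 1 - top_frac))
        tiers[expressing] = "positive"
        tiers[expressing & (densities >= cutoff)] = "high"
    return tiers.tolist()


@dataclass
class LineProfileFit:
    distances: np.ndarray
    samples: dict[str, np.ndarray] = field(default_factory=dict)
    coefficients: dict[str, np.ndarray] = field(default_factory=dict)
    residual_norm: dict[str, float] = field(default_factory=dict)


def line_profile_fit(
    images: list[FluorImage],
    p0: tuple[float, float],
    p1: tuple[float, float],
    degree: int = 6,
) -> LineProfileFit:
    """Bilinear line profile with a least-squares polynomial fit per channel.

    Samples at unit steps from ``p0`` toward ``p1`` (endpoint included
    when it falls on a step).
    """
    if not images:
        raise ValueError("no images given")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValueError("degenerate segment: endpoints coincide")
    distances = np.arange(0.0, length + 1e-9, 1.0)
    if degree < 0 or degree >= distances.size:
        raise ValueError("degree must be >= 0 and < number of samples")
    direction = (p1 - p0) / length
    rows = p0[0] + distances * direction[0]
    cols = p0[1] + distances * direction[1]
    result = LineProfileFit(distances=distances)
    for idx, image in enumerate(images):
        n_rows, n_cols = image.shape
        if not (
            0 <= p0[0] <= n_rows - 1 and 0 <= p0[1] <= n_cols - 1
            and 0 <= p1[0] <= n_rows - 1 and 0 <= p1[1] <= n_cols - 1
        ):
            raise ValueError("endpoints must lie inside the image")
        name = image.channel or f"channel_{idx}"
        samples = ndimage.map_coordinates(
            image.pixels, np.vstack([rows, cols]), order=1, mode="nearest"
        )
        coeffs = np.polyfit(distances, samples, degree)
        residual = float(np.linalg.norm(samples - np.polyval(coeffs, distances)))
        result.samples[name] = samples
        result.coefficients[name] = coeffs
        result.residual_norm[name] = residual
    return result
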