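"""Semantic pixel classes and connected components.

Thresholding follows the multi-level Otsu criterion (maximal between-class
variance over a binned histogram); components use the 8-neighbourhood
(``connectivity=2`` in 2-D) everywhere. The chromosome/ecDNA pixel
classifier is a deliberately simple rule-based surrogate for a learned
segmenter: externally produced masks can always be imported in its place
and take precedence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from skimage import measure

from .imaging import FluorImage

__all__ = [
    "BACKGROUND",
    "CHROMOSOME",
    "ECDNA",
    "NUCLEUS",
    "SegParams",
    "BinaryMask",
    "LabelMask",
    "ComponentRecord",
    "DegenerateHistogramError",
    "multi_otsu_thresholds",
    "binarize_channel",
    "label_components",
    "classify_spread_pixels",
]

# pixel class codes
BACKGROUND = 0
CHROMOSOME = 1
ECDNA = 2
NUCLEUS = 1  # cell context reuses code 1 for the nucleus class

SPREAD_CODES = frozenset({BACKGROUND, CHROMOSOME, ECDNA})
CELL_CODES = frozenset({BACKGROUND, NUCLEUS})


class DegenerateHistogramError(ValueError):
    """Raised when an image has too few distinct values to threshold."""


@dataclass
class SegParams:
    """Segmentation knobs.

    ``threshold_rule`` selects which multi-Otsu threshold defines the
    foreground: ``"higher"`` for FISH and metaphase DAPI, ``"lower"`` for
    interphase DAPI. Surrogate area cutoffs are in pixels at the working
    image scale.
    """

    n_otsu_classes: int = 3
    n_hist_bins: int = 256
    threshold_rule: str = "higher"
    connectivity: int = 8
    surrogate_min_chrom_area_px: int = 500
    surrogate_max_ecdna_area_px: int = 200

    def __post_init__(self) -> None:
        if self.n_otsu_classes < 2:
            raise ValueError("n_otsu_classes must be >= 2")
        if self.threshold_rule not in ("higher", "lower"):
            raise ValueError("threshold_rule must be 'higher' or 'lower'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.surrogate_max_ecdna_area_px >= self.surrogate_min_chrom_area_px:
            raise ValueError("max ecDNA area must be below min chromosome area")

    @property
    def skimage_connectivity(self) -> int:
        # skimage counts neighbourhood hops: 1 -> 4-neighbour, 2 -> 8-neighbour
        return 2 if self.connectivity == 8 else 1


@dataclass
class BinaryMask:
    """0/1 foreground mask with the threshold that produced it."""

    pixels: np.ndarray
    source_channel: str = ""
    threshold_used: float = float("nan")

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """Per-pixel semantic class grid.

    Spread context: {0 background, 1 chromosome, 2 ecDNA}; cell context:
    {0 background, 1 nucleus}. ``provenance`` is one of ``surrogate``,
    ``imported`` or ``ground_truth``.
    """

    pixels: np.ndarray
    provenance: str = "surrogate"
    context: str = "spread"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("label mask must be 2-D")
        allowed = SPREAD_CODES if self.context == "spread" else CELL_CODES
        present = set(np.unique(px).tolist())
        if not present <= allowed:
            raise ValueError(
                f"label mask contains unknown class codes {sorted(present - allowed)}"
            )
        if self.provenance not in ("surrogate", "imported", "ground_truth"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        self.pixels = px.astype(np.int32)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def class_mask(self, class_code: int) -> np.ndarray:
        return (self.pixels == class_code).astype(np.uint8)


@dataclass
class ComponentRecord:
    """One connected component of one pixel class.

    Boundary counts start at zero; the spread metrics stage fills them
    when it measures perimeter adjacency.
    """

    component_id: int
    class_code: int
    area_px: int
    pixel_list: frozenset  # of (row, col)
    boundary_px: int = 0
    boundary_adj_chrom_px: int = 0

    @property
    def pixel_array(self) -> np.ndarray:
        return np.array(sorted(self.pixel_list), dtype=int).reshape(-1, 2)


def _best_three_class_cuts(hist: np.ndarray) -> tuple[int, int]:
    """Exhaustive between-class-variance maximizer for three classes.

    Classes are bin ranges [0, i), [i, j), [j, n). Vectorized over j with
    prefix sums; ties resolve to the lexicographically smallest (i, j).
    """
    n = hist.size
    w_cum = np.concatenate([[0.0], np.cumsum(hist)])
    m_cum = np.concatenate([[0.0], np.cumsum(hist * np.arange(n))])

    def seg_score(w, m):
        # weighted squared class mean; grand-mean term is partition-invariant
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(w > 0, m**2 / np.maximum(w, 1e-300), -np.inf)

    best_score, best_cuts = -np.inf, None
    for i in range(1, n - 1):
        j = np.arange(i + 1, n)
        s = (
            seg_score(w_cum[i], m_cum[i])
            + seg_score(w_cum[j] - w_cum[i], m_cum[j] - m_cum[i])
            + seg_score(w_cum[n] - w_cum[j], m_cum[n] - m_cum[j])
        )
        k = int(np.argmax(s))
        if s[k] > best_score:
            best_score, best_cuts = float(s[k]), (i, int(j[k]))
    return best_cuts


def multi_otsu_thresholds(image: FluorImage, params: SegParams | None = None) -> np.ndarray:
    """Multi-level Otsu thresholds over a uniformly binned histogram.

    Returns ``n_otsu_classes - 1`` strictly increasing thresholds that
    maximize between-class variance; each threshold is the lower edge of
    the first bin of its upper class, so classifying pixels with ``>=``
    reproduces the histogram-space partition exactly.
    """
    params = params or SegParams()
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    if lo == hi:
        raise DegenerateHistogramError("constant image cannot be thresholded")
    n_bins = params.n_hist_bins
    binned = np.clip(((px - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    if np.unique(binned).size < params.n_otsu_classes:
        raise DegenerateHistogramError(
            f"need >= {params.n_otsu_classes} distinct binned values"
        )
    hist = np.bincount(binned.ravel(), minlength=n_bins).astype(float)
    bin_width = (hi - lo) / n_bins
    if params.n_otsu_classes == 3:
        cuts = _best_three_class_cuts(hist)
    else:
        # general case: plain exhaustive search over cut tuples
        import itertools

        n = hist.size
        idx = np.arange(n, dtype=float)
        best_score, cuts = -np.inf, None
        for cand in itertools.combinations(range(1, n), params.n_otsu_classes - 1):
            edges = (0,) + cand + (n,)
            score, ok = 0.0, True
            for a, b in zip(edges[:-1], edges[1:]):
                w = hist[a:b].sum()
                if w == 0:
                    ok = False
                    break
                score += (hist[a:b] * idx[a:b]).sum() ** 2 / w
            if ok and score > best_score:
                best_score, cuts = score, cand
    return lo + np.asarray(cuts, dtype=float) * bin_width


def binarize_channel(image: FluorImage, params: SegParams | None = None) -> BinaryMask:
    """Foreground mask at the higher or lower multi-Otsu threshold.

    A pixel equal to the threshold counts as foreground (``>=`` rule).
    """
    params = params or SegParams()
    thresholds = multi_otsu_thresholds(image, params)
    threshold = thresholds[-1] if params.threshold_rule == "higher" else thresholds[0]
    mask = (image.pixels >= threshold).astype(np.uint8)
    return BinaryMask(mask, source_channel=image.channel, threshold_used=float(threshold))


def _relabel_row_major(labeled: np.ndarray) -> np.ndarray:
    """Remap component ids to 1..N in row-major order of first pixels."""
    order: dict[int, int] = {}
    flat = labeled.ravel()
    for lab in flat[flat > 0]:
        if lab not in order:
            order[int(lab)] = len(order) + 1
    out = np.zeros_like(labeled)
    for old, new in order.items():
        out[labeled == old] = new
    return out


def label_components(
    mask: BinaryMask | LabelMask | np.ndarray,
    params: SegParams | None = None,
    class_code: int = 1,
) -> list[ComponentRecord]:
    """8-connected components of a binary mask or one class of a label mask.

    Ids run 1..N in row-major order of each component's first-encountered
    pixel. Boundary fields are zeroed here.
    """
    params = params or SegParams()
    if isinstance(mask, LabelMask):
        binary = mask.class_mask(class_code)
    elif isinstance(mask, BinaryMask):
        binary = mask.pixels
    else:
        binary = np.asarray(mask).astype(bool).astype(np.uint8)
    labeled = measure.label(binary, connectivity=params.skimage_connectivity)
    labeled = _relabel_row_major(labeled)
    records: list[ComponentRecord] = []
    for cid in range(1, labeled.max() + 1):
        rows, cols = np.nonzero(labeled == cid)
        pixels = frozenset(zip(rows.tolist(), cols.tolist()))
        records.append(
            ComponentRecord(
                component_id=cid,
                class_code=class_code,
                area_px=len(pixels),
                pixel_list=pixels,
            )
        )
    return records


def classify_spread_pixels(
    dapi_mask: BinaryMask,
    fish_mask: BinaryMask,
    params: SegParams | None = None,
    imported: LabelMask | None = None,
) -> LabelMask:
    """Chromosome/ecDNA pixel classes for a prometaphase spread.

    If ``imported`` is given it is validated and passed through untouched
    (the fidelity path). Otherwise the surrogate applies per-component
    area rules to the DAPI mask, with FISH overlap marking ecDNA:

    - area <= ``surrogate_max_ecdna_area_px`` -> ecDNA
    - small component (below the chromosome cutoff) touching FISH -> ecDNA
    - area >= ``surrogate_min_chrom_area_px`` -> chromosome, but its
      FISH-positive pixels are re-assigned to ecDNA (a tethered ecDNA
      merges with its chromosome in the DAPI mask)
    - intermediate-area components without FISH -> chromosome
    - FISH-positive pixels outside the DAPI mask -> ecDNA
    """
    params = params or SegParams()
    if imported is not None:
        if imported.context != "spread":
            raise ValueError("imported mask must use spread class codes")
        return LabelMask(imported.pixels, provenance="imported", context="spread")
    if dapi_mask.shape != fish_mask.shape:
        raise ValueError("DAPI and FISH masks must share shape")

    dapi = dapi_mask.pixels.astype(bool)
    fish = fish_mask.pixels.astype(bool)
    out = np.zeros(dapi.shape, dtype=np.int32)

    labeled = measure.label(dapi, connectivity=params.skimage_connectivity)
    for region in measure.regionprops(labeled):
        coords = tuple(region.coords.T)
        area = region.area
        touches_fish = bool(fish[coords].any())
        if area >= params.surrogate_min_chrom_area_px:
            out[coords] = CHROMOSOME
        elif area <= params.surrogate_max_ecdna_area_px or touches_fish:
            out[coords] = ECDNA
        else:
            out[coords] = CHROMOSOME
    # FISH signal inside a chromosome-class component marks embedded ecDNA;
    # FISH outside the DAPI mask is ecDNA missed by DAPI segmentation
    out[fish & (out == CHROMOSOME)] = ECDNA
    out[fish & ~dapi] = ECDNA
    return LabelMask(out, provenance="surrogate", context="spread")
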