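"""Seeded synthetic fluorescence scenes with per-object ground truth.

Every scene kind the pipeline consumes can be rendered here so each
metric is testable by parameter recovery. Rendering keeps the intensity
structure the thresholds assume — three DAPI populations (background,
ecDNA-level, chromosome-level), a two-level FISH background below the
probe level — without claiming optical realism. One random generator
per scene, derived from the explicit seed, drives all placement and
noise, so identical spec + seed reproduce bit-identical output.

Object counts requested as fractions are rounded half-up and the
realized values recorded in the truth, which is what tests compare
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cells import (
    PARTITION_MICRONUCLEUS,
    PARTITION_PRIMARY,
    NucleiPartition,
)
from .imaging import FluorImage, ZStack
from .segmentation import CHROMOSOME, ECDNA, BinaryMask, LabelMask
from .spread import TetherParams, adjacency_fraction, classify_tether
from .segmentation import ComponentRecord

__all__ = [
    "SceneSpec",
    "SceneTruth",
    "SceneGenerationError",
    "generate_spread_scene",
    "generate_metaphase_scene",
    "generate_daughter_pair_scene",
    "generate_foci_scene",
    "generate_focus_stack",
    "generate_scene",
]

_MAX_TRIES = 400


class SceneGenerationError(RuntimeError):
    """Raised when object placement fails after bounded retries."""


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


_DEFAULT_INTENSITY = {
    "dapi_bg": 10.0,
    "dapi_ecdna": 100.0,
    "dapi_chromosome": 220.0,
    "dapi_nucleus": 120.0,
    "dapi_speckle": 200.0,
    "fish_bg_lo": 5.0,
    "fish_bg_hi": 20.0,
    "fish": 150.0,
    "if_bg": 8.0,
    "if_nucleus": 60.0,
    "if_focus": 220.0,
}


@dataclass
class SceneSpec:
    """Generative parameters for one synthetic scene."""

    scene_kind: str = "spread"
    image_shape: tuple[int, int] = (384, 384)
    seed: int = 0
    n_chromosomes: int = 6
    n_ecdna: int = 20
    frac_untethered: float = 0.3
    frac_surrounded: float = 0.1
    n_micronuclei: int = 2
    myc_in_mn_frac: float = 0.1
    total_fish_px: int = 200
    n_foci: int = 4
    n_speckles: int = 6
    n_planes: int = 5
    focus_plane: int = 2
    blur_sigma: float = 2.0
    noise_sigma: float = 0.0
    intensity_levels: dict = field(default_factory=dict)
    h3ac_ratio_per_class: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image_shape = tuple(self.image_shape)
        kinds = {"spread", "metaphase", "daughter_pair", "foci", "focus_stack"}
        if self.scene_kind not in kinds:
            raise ValueError(f"scene_kind must be one of {sorted(kinds)}")
        if self.frac_untethered + self.frac_surrounded > 1 + 1e-12:
            raise ValueError("frac_untethered + frac_surrounded must be <= 1")
        for name in ("n_chromosomes", "n_ecdna", "n_micronuclei", "n_foci",
                     "n_speckles", "n_planes", "total_fish_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.frac_untethered <= 1 and 0 <= self.frac_surrounded <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if not (0 <= self.myc_in_mn_frac <= 1):
            raise ValueError("myc_in_mn_frac must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.scene_kind == "focus_stack" and not (0 <= self.focus_plane < self.n_planes):
            raise ValueError("focus_plane must index an existing plane")

    @property
    def intensities(self) -> dict:
        levels = dict(_DEFAULT_INTENSITY)
        levels.update(self.intensity_levels)
        return levels


@dataclass
class SceneTruth:
    """Ground truth recorded at generation time."""

    scene_kind: str
    labels: LabelMask | None = None
    objects: list = field(default_factory=list)
    # spread
    n_chromosomes: int = 0
    n_untethered: int = 0
    n_tethered: int = 0
    n_surrounded: int = 0
    untethering_pct: float | None = None
    # metaphase
    fish_total_px: int = 0
    fish_untethered_px: int = 0
    untethered_pct: float | None = None
    # daughter pair
    partition: NucleiPartition | None = None
    n_micronuclei: int = 0
    fish_in_mn_px: int = 0
    mn_dapi_px: int = 0
    myc_in_mn_pct: float | None = None
    mn_composition_pct: float | None = None
    # foci
    n_foci: int = 0
    # focus stack
    focus_plane: int = 0
    # optional IF channel rendered at configured per-class IF/DAPI ratios
    if_image: object | None = None


def _disc(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _capsule(shape, p0, p1, half_width) -> np.ndarray:
    """Pixels within half_width of the segment p0-p1."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    p0 = np.asarray(p0, float)
    d = np.asarray(p1, float) - p0
    seg_len2 = float(d @ d)
    t = ((rr - p0[0]) * d[0] + (cc - p0[1]) * d[1]) / seg_len2
    t = np.clip(t, 0.0, 1.0)
    dr = rr - (p0[0] + t * d[0])
    dc = cc - (p0[1] + t * d[1])
    return dr * dr + dc * dc <= half_width**2


def _dilate(mask: np.ndarray, r: int) -> np.ndarray:
    if r <= 0:
        return mask
    return ndimage.binary_dilation(mask, iterations=r)


def _fish_background(shape, levels) -> np.ndarray:
    """Two-level FISH background (mimics uneven illumination) so 3-class
    Otsu reliably places its higher threshold below the probe level."""
    bg = np.full(shape, levels["fish_bg_lo"])
    bg[:, shape[1] // 2:] = levels["fish_bg_hi"]
    return bg


def _add_noise(pixels: np.ndarray, sigma: float, rng) -> np.ndarray:
    if sigma > 0:
        pixels = pixels + rng.normal(0.0, sigma, size=pixels.shape)
    return np.clip(pixels, 0.0, None)


def _component_from_pixels(pixels: np.ndarray, class_code: int, cid: int) -> ComponentRecord:
    coords = frozenset((int(r), int(c)) for r, c in np.argwhere(pixels))
    return ComponentRecord(
        component_id=cid, class_code=class_code, area_px=len(coords), pixel_list=coords
    )


def generate_spread_scene(spec: SceneSpec):
    """Prometaphase spread: chromosome capsules plus ecDNA discs placed to
    realize the requested untethered/tethered/surrounded mix.

    Returns ``(dapi, fish, truth)``. Realized adjacency fractions are
    asserted against the intended tether class at generation time.
    """
    if spec.scene_kind != "spread":
        raise ValueError("spec.scene_kind must be 'spread'")
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    levels = spec.intensities
    tether_params = TetherParams()

    n_unt = _round_half_up(spec.frac_untethered * spec.n_ecdna)
    n_sur = _round_half_up(spec.frac_surrounded * spec.n_ecdna)
    if n_unt + n_sur > spec.n_ecdna:
        n_sur = spec.n_ecdna - n_unt
    n_teth = spec.n_ecdna - n_unt - n_sur

    chrom = np.zeros(shape, dtype=bool)
    chrom_list: list[np.ndarray] = []
    half_width = 6
    margin = 14
    if spec.n_chromosomes and min(shape) < 2 * margin + 65:
        raise SceneGenerationError(
            f"image {shape} too small to place chromosomes (needs >= {2 * margin + 65})"
        )
    for _ in range(spec.n_chromosomes):
        for _try in range(_MAX_TRIES):
            length = rng.uniform(45, 65)
            angle = rng.uniform(0, math.pi)
            cr = rng.uniform(margin + length / 2, shape[0] - margin - length / 2)
            cc = rng.uniform(margin + length / 2, shape[1] - margin - length / 2)
            dr = length / 2 * math.sin(angle)
            dc = length / 2 * math.cos(angle)
            cap = _capsule(shape, (cr - dr, cc - dc), (cr + dr, cc + dc), half_width)
            if not (_dilate(cap, 3) & chrom).any():
                chrom |= cap
                chrom_list.append(cap)
                break
        else:
            raise SceneGenerationError("could not place chromosome")

    labels = np.zeros(shape, dtype=np.int32)
    labels[chrom] = CHROMOSOME

    occupied_ecdna = np.zeros(shape, dtype=bool)
    objects = []

    def _try_place(intent: str) -> dict:
        for _try in range(_MAX_TRIES):
            radius = int(rng.integers(3, 7))
            if intent == "surrounded":
                radius = 3
                cap = chrom_list[int(rng.integers(len(chrom_list)))]
                # centers where the disc plus a 1-px chromosome ring fits
                interior = ndimage.binary_erosion(cap, iterations=radius + 2)
                interior &= ~_dilate(occupied_ecdna, 2 * radius + 3)
                centers = np.argwhere(interior)
                if centers.shape[0] == 0:
                    continue
                center = centers[int(rng.integers(centers.shape[0]))]
            elif intent == "untethered":
                cr = rng.uniform(radius + 1, shape[0] - radius - 2)
                cc = rng.uniform(radius + 1, shape[1] - radius - 2)
                center = (cr, cc)
            else:  # tethered: start from a chromosome edge pixel, sit half-out
                cap = chrom_list[int(rng.integers(len(chrom_list)))]
                edge = cap & ~ndimage.binary_erosion(cap)
                edges = np.argwhere(edge)
                er, ec = edges[int(rng.integers(edges.shape[0]))]
                offset = rng.uniform(0.2 * radius, 0.8 * radius)
                theta = rng.uniform(0, 2 * math.pi)
                center = (er + offset * math.sin(theta), ec + offset * math.cos(theta))
                if not (radius + 1 <= center[0] < shape[0] - radius - 1
                        and radius + 1 <= center[1] < shape[1] - radius - 1):
                    continue
            disc = _disc(shape, center, radius)
            if intent == "untethered":
                if (_dilate(disc, 3) & (chrom | occupied_ecdna)).any():
                    continue
            elif intent == "tethered":
                if (_dilate(disc, 2) & occupied_ecdna).any():
                    continue
                # must touch exactly one chromosome
                touched = [i for i, cap in enumerate(chrom_list)
                           if (_dilate(disc, 1) & cap).any()]
                if len(touched) != 1:
                    continue
                # a tethered disc must not sever its chromosome
                remainder = chrom_list[touched[0]] & ~disc
                n_cc = ndimage.label(remainder, structure=np.ones((3, 3)))[1]
                if n_cc != 1 or not remainder.any():
                    continue
            # evaluate realized adjacency on a draft label map
            draft = labels.copy()
            draft[disc] = ECDNA
            comp = _component_from_pixels(disc, ECDNA, 0)
            frac = adjacency_fraction(comp, LabelMask(draft, provenance="ground_truth"))
            realized = classify_tether(frac, tether_params)
            if realized != intent:
                continue
            if intent == "tethered" and not (0.30 <= frac <= 0.95):
                continue  # keep margin from both cutoffs for noise robustness
            labels[disc] = ECDNA
            occupied_ecdna[disc] = True
            return {"intent": intent, "realized_fraction": frac,
                    "center": (float(center[0]), float(center[1])), "radius": radius,
                    "area_px": int(disc.sum())}
        raise SceneGenerationError(f"could not place {intent} ecDNA")

    for intent, count in (("surrounded", n_sur), ("tethered", n_teth), ("untethered", n_unt)):
        for _ in range(count):
            objects.append(_try_place(intent))

    ecdna = labels == ECDNA
    dapi_px = np.full(shape, levels["dapi_bg"])
    dapi_px[chrom & ~ecdna] = levels["dapi_chromosome"]
    dapi_px[ecdna] = levels["dapi_ecdna"]
    fish_px = _fish_background(shape, levels)
    fish_px[ecdna] = levels["fish"]
    if_image = None
    if spec.h3ac_ratio_per_class:
        # IF signal proportional to clean DAPI, scaled per class, so the
        # mean-IF / mean-DAPI ratio per class equals the configured value
        if_px = np.full(shape, levels["if_bg"])
        ratios = {CHROMOSOME: spec.h3ac_ratio_per_class.get("chromosome", 1.0),
                  ECDNA: spec.h3ac_ratio_per_class.get("ecdna", 1.0)}
        for code, ratio in ratios.items():
            sel = labels == code
            if_px[sel] = ratio * dapi_px[sel]
        if_image = FluorImage(
            _add_noise(if_px, spec.noise_sigma, rng), channel="IF"
        )
    dapi_px = _add_noise(dapi_px, spec.noise_sigma, rng)
    fish_px = _add_noise(fish_px, spec.noise_sigma, rng)

    denom = n_unt + n_teth
    truth = SceneTruth(
        scene_kind="spread",
        labels=LabelMask(labels, provenance="ground_truth"),
        objects=objects,
        n_chromosomes=spec.n_chromosomes,
        n_untethered=n_unt,
        n_tethered=n_teth,
        n_surrounded=n_sur,
        untethering_pct=100.0 * n_unt / denom if denom else None,
        if_image=if_image,
    )
    return (
        FluorImage(dapi_px, channel="DAPI"),
        FluorImage(fish_px, channel="FISH"),
        truth,
    )


def _paint_pixels(region: np.ndarray, count: int, rng) -> np.ndarray:
    """Pick exactly ``count`` pixels from a boolean region, clustered by
    growing from random seeds so the result looks focus-like."""
    coords = np.argwhere(region)
    if coords.shape[0] < count:
        raise SceneGenerationError("region too small for requested pixel count")
    chosen = np.zeros(region.shape, dtype=bool)
    remaining = count
    while remaining > 0:
        seed_idx = int(rng.integers(coords.shape[0]))
        sr, sc = coords[seed_idx]
        radius = 1
        while True:
            blob = _disc(region.shape, (sr, sc), radius) & region & ~chosen
            if int(blob.sum()) >= min(remaining, 20) or radius > 12:
                break
            radius += 1
        blob_coords = np.argwhere(blob)
        take = min(remaining, blob_coords.shape[0])
        if take == 0:
            continue
        order = np.argsort(
            (blob_coords[:, 0] - sr) ** 2 + (blob_coords[:, 1] - sc) ** 2,
            kind="stable",
        )
        sel = blob_coords[order[:take]]
        chosen[sel[:, 0], sel[:, 1]] = True
        remaining -= take
    return chosen


def generate_metaphase_scene(spec: SceneSpec):
    """Metaphase cell: one dominant DAPI plate plus FISH pixels split
    on/off the plate so the off-plate share hits the target after
    half-up rounding of pixel counts."""
    if spec.scene_kind != "metaphase":
        raise ValueError("spec.scene_kind must be 'metaphase'")
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    levels = spec.intensities

    total = spec.total_fish_px
    n_off = _round_half_up(spec.frac_untethered * total)
    n_on = total - n_off

    center = (shape[0] / 2, shape[1] / 2)
    plate = _capsule(
        shape,
        (center[0] - shape[0] * 0.22, center[1]),
        (center[0] + shape[0] * 0.22, center[1]),
        shape[1] * 0.10,
    )
    plate_interior = ndimage.binary_erosion(plate, iterations=2)
    off_zone = ~_dilate(plate, 6)
    off_zone[: 4, :] = off_zone[-4:, :] = False
    off_zone[:, : 4] = off_zone[:, -4:] = False

    fish_on = _paint_pixels(plate_interior, n_on, rng) if n_on else np.zeros(shape, bool)
    fish_off = _paint_pixels(off_zone, n_off, rng) if n_off else np.zeros(shape, bool)
    fish = fish_on | fish_off

    dapi_px = np.full(shape, levels["dapi_bg"])
    dapi_px[plate] = levels["dapi_chromosome"]
    # dim rim keeps the DAPI histogram three-class even with no off-plate
    # signal; it sits below the higher threshold so the genomic mass is
    # the plate interior either way
    rim = plate & ~ndimage.binary_erosion(plate)
    dapi_px[rim] = levels["dapi_ecdna"]
    dapi_px[fish_off] = levels["dapi_ecdna"]  # untethered ecDNA carry dim DAPI
    fish_px = _fish_background(shape, levels)
    fish_px[fish] = levels["fish"]
    dapi_px = _add_noise(dapi_px, spec.noise_sigma, rng)
    fish_px = _add_noise(fish_px, spec.noise_sigma, rng)

    truth = SceneTruth(
        scene_kind="metaphase",
        fish_total_px=total,
        fish_untethered_px=n_off,
        untethered_pct=100.0 * n_off / total if total else None,
    )
    return (
        FluorImage(dapi_px, channel="DAPI"),
        FluorImage(fish_px, channel="FISH"),
        truth,
    )


def generate_daughter_pair_scene(spec: SceneSpec):
    """Newly divided daughter pair: two primary nuclei with chromatin
    speckles, micronuclei outside them, FISH split so the micronuclear
    share hits ``myc_in_mn_frac`` after half-up rounding."""
    if spec.scene_kind != "daughter_pair":
        raise ValueError("spec.scene_kind must be 'daughter_pair'")
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    levels = spec.intensities

    r_primary = int(min(shape) * 0.11)
    c1 = (shape[0] * 0.5, shape[1] * 0.28)
    c2 = (shape[0] * 0.5, shape[1] * 0.72)
    primaries = _disc(shape, c1, r_primary) | _disc(shape, c2, r_primary)

    # bright chromatin core per nucleus: a third DAPI population large
    # enough that 3-class Otsu separates background from dim nucleus
    # rather than splitting the background noise
    speckles = np.zeros(shape, dtype=bool)
    for c in (c1, c2):
        speckles |= _disc(shape, c, int(r_primary * 0.55))

    mn_masks: list[np.ndarray] = []
    occupied = _dilate(primaries, 3)
    for _ in range(spec.n_micronuclei):
        for _try in range(_MAX_TRIES):
            # radius >= 4 keeps each eroded interior large enough to hold
            # a realistic share of the FISH pixel budget
            radius = int(rng.integers(4, 8))
            cr = rng.uniform(radius + 2, shape[0] - radius - 3)
            cc = rng.uniform(radius + 2, shape[1] - radius - 3)
            disc = _disc(shape, (cr, cc), radius)
            if not (_dilate(disc, 3) & occupied).any():
                mn_masks.append(disc)
                occupied |= _dilate(disc, 3)
                break
        else:
            raise SceneGenerationError("could not place micronucleus")
    micronuclei = np.zeros(shape, dtype=bool)
    for m in mn_masks:
        micronuclei |= m

    total = spec.total_fish_px
    n_in_mn = _round_half_up(spec.myc_in_mn_frac * total) if mn_masks else 0
    n_in_primary = total - n_in_mn

    mn_interior = np.zeros(shape, dtype=bool)
    for m in mn_masks:
        mn_interior |= ndimage.binary_erosion(m, iterations=1)
    primary_interior = ndimage.binary_erosion(primaries, iterations=2)
    fish = np.zeros(shape, dtype=bool)
    if n_in_mn:
        fish |= _paint_pixels(mn_interior, n_in_mn, rng)
    if n_in_primary:
        fish |= _paint_pixels(primary_interior, n_in_primary, rng)

    dapi_px = np.full(shape, levels["dapi_bg"])
    dapi_px[primaries | micronuclei] = levels["dapi_nucleus"]
    dapi_px[speckles] = levels["dapi_speckle"]
    fish_px = _fish_background(shape, levels)
    fish_px[fish] = levels["fish"]
    dapi_px = _add_noise(dapi_px, spec.noise_sigma, rng)
    fish_px = _add_noise(fish_px, spec.noise_sigma, rng)

    part = np.zeros(shape, dtype=np.int32)
    part[primaries] = PARTITION_PRIMARY
    part[micronuclei] = PARTITION_MICRONUCLEUS
    mn_dapi = int(micronuclei.sum())
    truth = SceneTruth(
        scene_kind="daughter_pair",
        partition=NucleiPartition(part, provenance="ground_truth"),
        n_micronuclei=len(mn_masks),
        fish_in_mn_px=n_in_mn,
        mn_dapi_px=mn_dapi,
        myc_in_mn_pct=100.0 * n_in_mn / total if total else None,
        mn_composition_pct=100.0 * n_in_mn / mn_dapi if mn_dapi else None,
    )
    return (
        FluorImage(dapi_px, channel="DAPI"),
        FluorImage(fish_px, channel="FISH"),
        truth,
    )


def generate_foci_scene(spec: SceneSpec):
    """Nucleus with bright IF foci (>= 6 px) and sub-cutoff speckles."""
    if spec.scene_kind != "foci":
        raise ValueError("spec.scene_kind must be 'foci'")
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    levels = spec.intensities

    nucleus = _disc(shape, (shape[0] / 2, shape[1] / 2), min(shape) * 0.38)
    interior = ndimage.binary_erosion(nucleus, iterations=4)

    occupied = np.zeros(shape, dtype=bool)
    signal = np.zeros(shape, dtype=bool)

    def _place(area_big: bool) -> None:
        for _try in range(_MAX_TRIES):
            if area_big:
                radius = int(rng.integers(2, 4))
                cr, cc = np.argwhere(interior)[
                    int(rng.integers(int(interior.sum())))
                ]
                blob = _disc(shape, (cr, cc), radius)
            else:
                n_px = int(rng.integers(1, 6))  # 1..5 px, below the cutoff
                cr, cc = np.argwhere(interior)[
                    int(rng.integers(int(interior.sum())))
                ]
                plus = np.zeros(shape, dtype=bool)
                offsets = [(0, 0), (0, 1), (0, -1), (1, 0), (-1, 0)][:n_px]
                for dr, dc in offsets:
                    plus[cr + dr, cc + dc] = True
                blob = plus
            if not (blob & ~interior).any() and not (_dilate(blob, 2) & occupied).any():
                signal[blob] = True
                occupied[blob] = True
                return
        raise SceneGenerationError("could not place focus/speckle")

    for _ in range(spec.n_foci):
        _place(area_big=True)
    for _ in range(spec.n_speckles):
        _place(area_big=False)

    if_px = np.full(shape, levels["if_bg"])
    if_px[nucleus] = levels["if_nucleus"]
    if_px[signal] = levels["if_focus"]
    if_px = _add_noise(if_px, spec.noise_sigma, rng)

    truth = SceneTruth(scene_kind="foci", n_foci=spec.n_foci)
    return (
        FluorImage(if_px, channel="IF"),
        BinaryMask(nucleus.astype(np.uint8), source_channel="DAPI"),
        truth,
    )


def generate_focus_stack(spec: SceneSpec):
    """Z-stack with one sharp textured plane; blur grows with distance."""
    if spec.scene_kind != "focus_stack":
        raise ValueError("spec.scene_kind must be 'focus_stack'")
    rng = np.random.default_rng(spec.seed)
    shape = spec.image_shape
    sharp = rng.uniform(0.0, 200.0, size=shape)
    planes = []
    for z in range(spec.n_planes):
        dist = abs(z - spec.focus_plane)
        if dist == 0:
            px = sharp.copy()
        else:
            px = ndimage.gaussian_filter(sharp, sigma=spec.blur_sigma * dist)
        px = _add_noise(px, spec.noise_sigma, rng)
        planes.append(FluorImage(px, channel="DAPI", z_index=z))
    truth = SceneTruth(scene_kind="focus_stack", focus_plane=spec.focus_plane)
    return ZStack(planes=planes), truth


_GENERATORS = {
    "spread": generate_spread_scene,
    "metaphase": generate_metaphase_scene,
    "daughter_pair": generate_daughter_pair_scene,
    "foci": generate_foci_scene,
    "focus_stack": generate_focus_stack,
}


def generate_scene(spec: SceneSpec):
    """Dispatch to the generator for ``spec.scene_kind``."""
    return _GENERATORS[spec.scene_kind](spec)
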