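import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ectether.scenes import SceneSpec, generate_spread_scene
from ectether.segmentation import (
    CHROMOSOME,
    ECDNA,
    ComponentRecord,
    label_components,
)
from ectether.spread import (
    SpreadMetrics,
    TetherParams,
    adjacency_fraction,
    class_intensity_ratio,
    classify_tether,
    convex_hull_area,
    summarize_spread,
)

from conftest import make_binary, make_image, make_labels


def ecdna_component(labels, pixels):
    return ComponentRecord(
        component_id=1, class_code=ECDNA, area_px=len(pixels),
        pixel_list=frozenset(pixels),
    )


def oracle_adjacency(pixel_set, label_grid):
    """Brute-force oracle: enumerate neighbours with explicit bounds checks
    on a padded copy of the label grid."""
    grid = np.pad(np.asarray(label_grid), 1, constant_values=-1)
    boundary = adj = 0
    for (r, c) in pixel_set:
        neighbours = [
            (r + dr, c + dc)
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
            if (dr, dc) != (0, 0)
        ]
        outside = [n for n in neighbours if n not in pixel_set]
        if outside:
            boundary += 1
            if any(grid[nr + 1, nc + 1] == CHROMOSOME for nr, nc in outside):
                adj += 1
    return boundary, adj


class TestAdjacencyFraction:
    def test_isolated_block_zero(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[3:5, 3:5] = ECDNA
        comp = ecdna_component(labels, [(3, 3), (3, 4), (4, 3), (4, 4)])
        assert adjacency_fraction(comp, make_labels(labels)) == 0.0
        assert comp.boundary_px == 4

    def test_block_beside_chromosome_column_half(self):
        labels = np.zeros((6, 6), dtype=int)
        labels[0:6, 1] = CHROMOSOME
        labels[2:4, 2:4] = ECDNA
        comp = ecdna_component(labels, [(2, 2), (2, 3), (3, 2), (3, 3)])
        assert adjacency_fraction(comp, make_labels(labels)) == pytest.approx(0.5)
        assert comp.boundary_px == 4
        assert comp.boundary_adj_chrom_px == 2

    def test_single_pixel_fully_surrounded(self):
        labels = np.full((3, 3), CHROMOSOME, dtype=int)
        labels[1, 1] = ECDNA
        comp = ecdna_component(labels, [(1, 1)])
        assert adjacency_fraction(comp, make_labels(labels)) == 1.0

    def test_empty_component_raises(self):
        comp = ComponentRecord(1, ECDNA, 0, frozenset())
        with pytest.raises(ValueError):
            adjacency_fraction(comp, make_labels(np.zeros((3, 3), dtype=int)))

    def test_image_border_counts_as_non_chromosome(self):
        labels = np.zeros((3, 3), dtype=int)
        labels[0, 0] = ECDNA
        labels[0, 1] = labels[1, 0] = labels[1, 1] = CHROMOSOME
        comp = ecdna_component(labels, [(0, 0)])
        # corner pixel: all in-image neighbours are chromosome, but the
        # pixel is still boundary; fraction is adj/boundary = 1/1
        assert adjacency_fraction(comp, make_labels(labels)) == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(
            [0, CHROMOSOME, ECDNA], size=(16, 16), p=[0.5, 0.3, 0.2]
        )
        lm = make_labels(labels)
        for comp in label_components(lm, class_code=ECDNA):
            frac = adjacency_fraction(comp, lm)
            boundary, adj = oracle_adjacency(comp.pixel_list, labels)
            assert comp.boundary_px == boundary
            assert comp.boundary_adj_chrom_px == adj
            assert frac == pytest.approx(adj / boundary if boundary else 0.0)


class TestClassifyTether:
    @pytest.mark.parametrize(
        "frac,expected",
        [
            (0.10, "untethered"),
            (0.2499, "untethered"),
            (0.25, "tethered"),
            (0.999, "tethered"),
            (1.0, "surrounded"),
            (0.0, "untethered"),
        ],
    )
    def test_cutoffs(self, frac, expected):
        assert classify_tether(frac) == expected

    @pytest.mark.parametrize("frac", [-0.1, 1.1])
    def test_out_of_range_raises(self, frac):
        with pytest.raises(ValueError):
            classify_tether(frac)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=100, deadline=None)
    def test_total_partition(self, frac):
        assert classify_tether(frac) in {"untethered", "tethered", "surrounded"}

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            TetherParams(untethered_max_frac=0.0)


class TestSummarizeSpread:
    def _scene(self, labels):
        lm = make_labels(labels)
        comps = label_components(lm, class_code=CHROMOSOME)
        comps += label_components(lm, class_code=ECDNA)
        return lm, comps

    def test_counts_and_percentage(self):
        # untethered=5, tethered=3, surrounded=2 -> 62.5
        m = SpreadMetrics(n_untethered=5, n_tethered=3, n_surrounded=2)
        assert m.n_ecdna_cc == 10
        # percentage formula exercised end to end below; arithmetic here
        assert 100.0 * 5 / (5 + 3) == 62.5

    def test_no_ecdna_gives_missing_pct(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[2:8, 2:5] = CHROMOSOME
        lm, comps = self._scene(labels)
        m = summarize_spread(lm, comps)
        assert m.untethering_pct is None
        assert m.n_chromosome_cc == 1

    def test_constructed_classes(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[1:19, 1:6] = CHROMOSOME  # one chromosome slab
        labels[9, 3] = ECDNA            # surrounded single pixel
        labels[5:7, 6:8] = ECDNA        # touching the slab edge -> tethered
        labels[15:17, 15:17] = ECDNA    # isolated -> untethered
        lm, comps = self._scene(labels)
        m = summarize_spread(lm, comps)
        assert (m.n_untethered, m.n_tethered, m.n_surrounded) == (1, 1, 1)
        assert m.untethering_pct == pytest.approx(50.0)

    def test_tether_counts_partition_components(self, rng):
        labels = rng.choice([0, CHROMOSOME, ECDNA], size=(24, 24), p=[0.6, 0.25, 0.15])
        lm, comps = self._scene(labels)
        m = summarize_spread(lm, comps)
        n_ecdna = len(label_components(lm, class_code=ECDNA))
        assert m.n_untethered + m.n_tethered + m.n_surrounded == n_ecdna

    def test_zero_noise_scene_truth_exact(self):
        spec = SceneSpec(
            scene_kind="spread", seed=5, n_ecdna=20,
            frac_untethered=0.45, frac_surrounded=0.1, noise_sigma=0.0,
        )
        _, _, truth = generate_spread_scene(spec)
        lm = truth.labels
        comps = label_components(lm, class_code=CHROMOSOME)
        comps += label_components(lm, class_code=ECDNA)
        m = summarize_spread(lm, comps)
        assert m.n_untethered == truth.n_untethered
        assert m.n_tethered == truth.n_tethered
        assert m.n_surrounded == truth.n_surrounded
        assert m.untethering_pct == pytest.approx(truth.untethering_pct)

    def test_translation_toward_chromosome_monotone(self):
        # moving an isolated block until contact never lowers adjacency
        base = np.zeros((12, 20), dtype=int)
        base[2:10, 1:4] = CHROMOSOME
        fracs = []
        for col in (14, 10, 6, 4):
            labels = base.copy()
            labels[5:7, col: col + 2] = ECDNA
            lm = make_labels(labels)
            comp = label_components(lm, class_code=ECDNA)[0]
            fracs.append(adjacency_fraction(comp, lm))
        assert fracs == sorted(fracs)
        assert fracs[-1] > 0


class TestConvexHullArea:
    def test_filled_square(self):
        mask = np.zeros((12, 12), dtype=int)
        mask[1:11, 1:11] = 1
        empty = make_binary(np.zeros((12, 12)))
        assert convex_hull_area(make_binary(mask), empty) == 100

    def test_two_pixel_segment(self):
        mask = np.zeros((3, 6), dtype=int)
        mask[0, 0] = mask[0, 4] = 1
        empty = make_binary(np.zeros((3, 6)))
        assert convex_hull_area(make_binary(mask), empty) == 5

    def test_l_shape(self):
        mask = np.zeros((5, 5), dtype=int)
        for r, c in [(0, 0), (0, 1), (0, 2), (1, 0), (2, 0)]:
            mask[r, c] = 1
        empty = make_binary(np.zeros((5, 5)))
        # (1,1) lies on the hypotenuse and is inclusive
        assert convex_hull_area(make_binary(mask), empty) == 6

    def test_empty_union(self):
        empty = make_binary(np.zeros((6, 6)))
        assert convex_hull_area(empty, empty) == 0

    def test_single_pixel(self):
        mask = np.zeros((4, 4), dtype=int)
        mask[2, 2] = 1
        empty = make_binary(np.zeros((4, 4)))
        assert convex_hull_area(make_binary(mask), empty) == 1

    def test_union_of_channels(self):
        dapi = np.zeros((6, 6), dtype=int)
        fish = np.zeros((6, 6), dtype=int)
        dapi[0, 0] = 1
        fish[0, 4] = 1
        assert convex_hull_area(make_binary(dapi), make_binary(fish)) == 5

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            convex_hull_area(
                make_binary(np.zeros((4, 4))), make_binary(np.zeros((5, 4)))
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_hull_area_at_least_union(self, seed):
        rng = np.random.default_rng(seed)
        mask = (rng.random((20, 20)) < 0.15).astype(np.uint8)
        empty = make_binary(np.zeros((20, 20)))
        area = convex_hull_area(make_binary(mask), empty)
        assert area >= mask.sum()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_triangle_inclusion_oracle(self, seed):
        # oracle: a point is in the hull iff it lies in a triangle of
        # foreground points (or on a segment for degenerate sets)
        rng = np.random.default_rng(seed)
        mask = np.zeros((9, 9), dtype=np.uint8)
        pts = rng.integers(0, 9, size=(5, 2))
        mask[pts[:, 0], pts[:, 1]] = 1
        fg = [tuple(p) for p in np.argwhere(mask)]
        def in_tri(p, a, b, c):
            area2 = (b[0]-a[0])*(c[1]-a[1]) - (c[0]-a[0])*(b[1]-a[1])
            if area2 == 0:
                return False  # degenerate triangle: handled by on_seg
            d1 = (p[0]-b[0])*(a[1]-b[1]) - (a[0]-b[0])*(p[1]-b[1])
            d2 = (p[0]-c[0])*(b[1]-c[1]) - (b[0]-c[0])*(p[1]-c[1])
            d3 = (p[0]-a[0])*(c[1]-a[1]) - (c[0]-a[0])*(p[1]-a[1])
            neg = d1 < 0 or d2 < 0 or d3 < 0
            pos = d1 > 0 or d2 > 0 or d3 > 0
            return not (neg and pos)
        def on_seg(p, a, b):
            cross = (b[0]-a[0])*(p[1]-a[1]) - (b[1]-a[1])*(p[0]-a[0])
            if cross != 0:
                return False
            dot = (p[0]-a[0])*(b[0]-a[0]) + (p[1]-a[1])*(b[1]-a[1])
            return 0 <= dot <= (b[0]-a[0])**2 + (b[1]-a[1])**2
        import itertools
        expected = 0
        for r in range(9):
            for c in range(9):
                p = (r, c)
                hit = any(
                    in_tri(p, a, b, cc)
                    for a, b, cc in itertools.combinations(fg, 3)
                ) if len(fg) >= 3 else False
                hit = hit or any(
                    on_seg(p, a, b) for a, b in itertools.combinations(fg, 2)
                ) or p in fg
                expected += hit
        empty = make_binary(np.zeros((9, 9)))
        assert convex_hull_area(make_binary(mask), empty) == expected

    def test_convex_filled_shape_equality(self):
        # filled disc: hull area equals its own pixel count
        rr, cc = np.ogrid[:15, :15]
        mask = ((rr - 7) ** 2 + (cc - 7) ** 2 <= 25).astype(np.uint8)
        empty = make_binary(np.zeros((15, 15)))
        assert convex_hull_area(make_binary(mask), empty) == mask.sum()


class TestClassIntensityRatio:
    def test_ratio_arithmetic(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[1:3, 1:3] = CHROMOSOME
        if_img = make_image(np.full((4, 4), 200.0), channel="IF")
        dapi = make_image(np.full((4, 4), 100.0))
        assert class_intensity_ratio(if_img, dapi, make_labels(labels), CHROMOSOME) == 2.0

    def test_identity_gives_one(self, rng):
        pixels = rng.uniform(1, 50, size=(8, 8))
        labels = rng.integers(0, 3, size=(8, 8))
        img = make_image(pixels)
        for code in (CHROMOSOME, ECDNA):
            if (labels == code).any():
                assert class_intensity_ratio(
                    img, img, make_labels(labels), code
                ) == pytest.approx(1.0)

    def test_empty_class_missing(self):
        labels = np.zeros((4, 4), dtype=int)
        img = make_image(np.ones((4, 4)))
        assert class_intensity_ratio(img, img, make_labels(labels), ECDNA) is None

    def test_zero_dapi_raises(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0] = CHROMOSOME
        if_img = make_image(np.ones((4, 4)))
        dapi = make_image(np.zeros((4, 4)))
        with pytest.raises(ZeroDivisionError):
            class_intensity_ratio(if_img, dapi, make_labels(labels), CHROMOSOME)

    @pytest.mark.parametrize("code,key", [(CHROMOSOME, "chromosome"), (ECDNA, "ecdna")])
    def test_synthetic_ratio_recovered_within_5pct(self, code, key):
        spec = SceneSpec(
            scene_kind="spread", seed=21, n_ecdna=15, frac_untethered=0.4,
            frac_surrounded=0.0, noise_sigma=4.0,
            h3ac_ratio_per_class={"chromosome": 1.8, "ecdna": 0.6},
        )
        dapi, _, truth = generate_spread_scene(spec)
        ratio = class_intensity_ratio(truth.if_image, dapi, truth.labels, code)
        expected = {"chromosome": 1.8, "ecdna": 0.6}[key]
        assert ratio == pytest.approx(expected, rel=0.05)
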