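"""Per-scene quantification routines and batch orchestration.

Binds the stages in acquisition order — focus/projection, segmentation,
metrics — and runs them over directories of TIFF scenes, emitting one
CSV row per cell/pair/scene. All randomness flows from the explicit
seed; identical config + seed give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .cells import (
    FociParams,
    NucleiPartition,
    NucleiPartitionParams,
    count_foci,
    metaphase_untethering,
    micronuclei_metrics,
    partition_daughter_nuclei,
)
from .imaging import FluorImage, read_tiff_stack, select_best_focus
from .segmentation import (
    CHROMOSOME,
    ECDNA,
    BinaryMask,
    LabelMask,
    SegParams,
    binarize_channel,
    classify_spread_pixels,
    label_components,
)
from .scenes import SceneSpec, generate_scene
from .spread import (
    SpreadMetrics,
    TetherParams,
    convex_hull_area,
    summarize_spread,
)
from . import stats as stats_mod

log = logging.getLogger("ectether")

__all__ = [
    "components_to_table",
    "quantify_spread_scene",
    "quantify_metaphase_scene",
    "quantify_daughter_pair_scene",
    "quantify_foci_scene",
    "write_fixtures",
    "run_quantification",
    "run_stats",
]


def components_to_table(components) -> pd.DataFrame:
    """One row per connected component (id, class, area, boundary counts)."""
    return pd.DataFrame(
        [
            {
                "component_id": c.component_id,
                "class_code": c.class_code,
                "area_px": c.area_px,
                "boundary_px": c.boundary_px,
                "boundary_adj_chrom_px": c.boundary_adj_chrom_px,
            }
            for c in components
        ]
    )


def _seg(params: SegParams | None, rule: str) -> SegParams:
    base = params or SegParams()
    return dataclasses.replace(base, threshold_rule=rule)


def quantify_spread_scene(
    dapi: FluorImage,
    fish: FluorImage,
    seg_params: SegParams | None = None,
    tether_params: TetherParams | None = None,
    labels: LabelMask | None = None,
    with_hull: bool = True,
) -> SpreadMetrics:
    """Spread metrics from a DAPI/FISH pair.

    Without imported/ground-truth ``labels`` the surrogate classifier is
    used: DAPI at the lower threshold (chromosomes and ecDNA are both
    DAPI-positive), FISH at the higher.
    """
    dapi_mask = fish_mask = None
    if labels is None:
        dapi_mask = binarize_channel(dapi, _seg(seg_params, "lower"))
        fish_mask = binarize_channel(fish, _seg(seg_params, "higher"))
        labels = classify_spread_pixels(dapi_mask, fish_mask, seg_params)
    components = label_components(labels, seg_params, class_code=CHROMOSOME)
    components += label_components(labels, seg_params, class_code=ECDNA)
    metrics = summarize_spread(labels, components, tether_params)
    if with_hull and dapi_mask is not None:
        metrics.hull_area_px = convex_hull_area(dapi_mask, fish_mask)
    return metrics


def quantify_metaphase_scene(
    dapi: FluorImage, fish: FluorImage, seg_params: SegParams | None = None
):
    """Metaphase untethering from a DAPI/FISH pair (higher threshold on
    both channels, per the metaphase-DAPI rule)."""
    dapi_mask = binarize_channel(dapi, _seg(seg_params, "higher"))
    fish_mask = binarize_channel(fish, _seg(seg_params, "higher"))
    return metaphase_untethering(dapi_mask, fish_mask, seg_params)


def quantify_daughter_pair_scene(
    dapi: FluorImage,
    fish: FluorImage,
    seg_params: SegParams | None = None,
    partition_params: NucleiPartitionParams | None = None,
    annotation: NucleiPartition | None = None,
):
    """Daughter-pair micronuclei metrics (interphase DAPI: lower threshold)."""
    dapi_mask = binarize_channel(dapi, _seg(seg_params, "lower"))
    fish_mask = binarize_channel(fish, _seg(seg_params, "higher"))
    partition = partition_daughter_nuclei(dapi_mask, partition_params, annotation)
    return micronuclei_metrics(partition, fish_mask)


def quantify_foci_scene(
    if_image: FluorImage,
    cell_mask: BinaryMask | None = None,
    seg_params: SegParams | None = None,
    foci_params: FociParams | None = None,
) -> int:
    return count_foci(if_image, _seg(seg_params, "higher"), foci_params, cell_mask)


# ---------------------------------------------------------------------------
# fixtures on disk


def _write_image(path: Path, image: FluorImage) -> None:
    tifffile.imwrite(path, image.pixels.astype(np.float32))


def write_fixtures(out_dir, scene_specs: list[SceneSpec]) -> list[str]:
    """Materialize scenes as TIFF channels plus a truth JSON sidecar.

    Returns the list of scene names written. Images are float32 TIFFs;
    truth label maps and partitions are int32 TIFFs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, spec in enumerate(scene_specs):
        name = f"{spec.scene_kind}_{i:04d}"
        result = generate_scene(spec)
        truth = result[-1]
        sidecar = {
            "scene_kind": spec.scene_kind,
            "seed": spec.seed,
            "noise_sigma": spec.noise_sigma,
        }
        if spec.scene_kind == "spread":
            dapi, fish, _ = result
            _write_image(out_dir / f"{name}_DAPI.tif", dapi)
            _write_image(out_dir / f"{name}_FISH.tif", fish)
            tifffile.imwrite(
                out_dir / f"{name}_labels.tif", truth.labels.pixels.astype(np.int32)
            )
            sidecar.update(
                n_chromosomes=truth.n_chromosomes,
                n_untethered=truth.n_untethered,
                n_tethered=truth.n_tethered,
                n_surrounded=truth.n_surrounded,
                untethering_pct=truth.untethering_pct,
            )
        elif spec.scene_kind == "metaphase":
            dapi, fish, _ = result
            _write_image(out_dir / f"{name}_DAPI.tif", dapi)
            _write_image(out_dir / f"{name}_FISH.tif", fish)
            sidecar.update(
                fish_total_px=truth.fish_total_px,
                fish_untethered_px=truth.fish_untethered_px,
                untethered_pct=truth.untethered_pct,
            )
        elif spec.scene_kind == "daughter_pair":
            dapi, fish, _ = result
            _write_image(out_dir / f"{name}_DAPI.tif", dapi)
            _write_image(out_dir / f"{name}_FISH.tif", fish)
            tifffile.imwrite(
                out_dir / f"{name}_partition.tif",
                truth.partition.pixels.astype(np.int32),
            )
            sidecar.update(
                n_micronuclei=truth.n_micronuclei,
                myc_in_mn_pct=truth.myc_in_mn_pct,
                mn_composition_pct=truth.mn_composition_pct,
            )
        elif spec.scene_kind == "foci":
            if_image, cell_mask, _ = result
            _write_image(out_dir / f"{name}_IF.tif", if_image)
            tifffile.imwrite(
                out_dir / f"{name}_cellmask.tif", cell_mask.pixels.astype(np.uint8)
            )
            sidecar.update(n_foci=truth.n_foci)
        else:  # focus_stack
            stack, _ = result
            arr = np.stack([p.pixels for p in stack.planes]).astype(np.float32)
            tifffile.imwrite(out_dir / f"{name}_stack.tif", arr)
            sidecar.update(focus_plane=truth.focus_plane)
        (out_dir / f"{name}_truth.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True) + "\n"
        )
        names.append(name)
    return names


def _read_image(path: Path, channel: str) -> FluorImage:
    return FluorImage(tifffile.imread(path).astype(float), channel=channel)


def run_quantification(
    mode: str,
    input_dir,
    out_csv,
    seg_params: SegParams | None = None,
    tether_params: TetherParams | None = None,
    foci_params: FociParams | None = None,
    partition_params: NucleiPartitionParams | None = None,
    condition: str = "default",
) -> pd.DataFrame:
    """Quantify every scene of ``mode`` found under ``input_dir``.

    Scenes are located by their ``*_DAPI.tif`` / ``*_IF.tif`` /
    ``*_stack.tif`` channel files. Failures on individual cells are
    logged and skipped; the CSV gets one row per successful cell.
    """
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise FileNotFoundError(f"input directory {input_dir} does not exist")
    rows = []
    if mode in ("spread", "screen", "metaphase", "daughter_pair"):
        paths = sorted(input_dir.glob("*_DAPI.tif"))
    elif mode == "foci":
        paths = sorted(input_dir.glob("*_IF.tif"))
    elif mode == "focus":
        paths = sorted(input_dir.glob("*_stack.tif"))
    else:
        raise ValueError(f"unknown quantification mode {mode!r}")
    for path in paths:
        cell_id = path.name.rsplit("_", 1)[0]
        try:
            row = {"cell_id": cell_id, "condition": condition}
            if mode in ("spread", "screen"):
                dapi = _read_image(path, "DAPI")
                fish = _read_image(path.with_name(f"{cell_id}_FISH.tif"), "FISH")
                m = quantify_spread_scene(dapi, fish, seg_params, tether_params)
                row.update(
                    n_chromosome_cc=m.n_chromosome_cc,
                    n_untethered=m.n_untethered,
                    n_tethered=m.n_tethered,
                    n_surrounded=m.n_surrounded,
                    untethering_pct=m.untethering_pct,
                    hull_area_px=m.hull_area_px,
                )
            elif mode == "metaphase":
                dapi = _read_image(path, "DAPI")
                fish = _read_image(path.with_name(f"{cell_id}_FISH.tif"), "FISH")
                m = quantify_metaphase_scene(dapi, fish, seg_params)
                row.update(
                    genomic_mass_area_px=m.genomic_mass_area_px,
                    myc_px_total=m.myc_px_total,
                    myc_px_untethered=m.myc_px_untethered,
                    untethered_pct=m.untethered_pct,
                )
            elif mode == "daughter_pair":
                dapi = _read_image(path, "DAPI")
                fish = _read_image(path.with_name(f"{cell_id}_FISH.tif"), "FISH")
                m = quantify_daughter_pair_scene(
                    dapi, fish, seg_params, partition_params
                )
                row.update(
                    has_micronuclei=m.has_micronuclei,
                    n_micronuclei=m.n_micronuclei,
                    myc_in_mn_pct=m.myc_in_mn_pct,
                    mn_composition_pct=m.mn_composition_pct,
                )
            elif mode == "foci":
                if_image = _read_image(path, "IF")
                mask_path = path.with_name(f"{cell_id}_cellmask.tif")
                cell_mask = (
                    BinaryMask(tifffile.imread(mask_path))
                    if mask_path.exists()
                    else None
                )
                row["n_foci"] = quantify_foci_scene(
                    if_image, cell_mask, seg_params, foci_params
                )
            elif mode == "focus":
                stack = read_tiff_stack(path, channel="DAPI")
                idx, _ = select_best_focus(stack)
                row["best_focus_plane"] = idx
            rows.append(row)
        except Exception as exc:  # per-cell failures skip, not abort
            log.warning("skipping %s: %s", cell_id, exc)
    df = pd.DataFrame(rows)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(out_csv, index=False)
    return df


_VALID_STATS = ("one_way_anova", "tukey_hsd", "two_way_anova", "chi_squared", "linear_fit")


def run_stats(metrics_csv, out_csv, tests: list[dict]) -> pd.DataFrame:
    """Dispatch the named tests over a metrics CSV; write a tidy results CSV.

    Each test dict names the test and its columns, e.g.
    ``{"name": "one_way_anova", "value": "untethering_pct", "group": "condition"}``.
    """
    df = pd.read_csv(metrics_csv)
    if df.empty:
        raise ValueError("empty metrics table")
    rows = []
    for test in tests:
        name = test.get("name")
        if name not in _VALID_STATS:
            raise ValueError(f"unknown test {name!r}; valid: {', '.join(_VALID_STATS)}")
        value = test.get("value", "value")
        group = test.get("group", "condition")
        if name == "one_way_anova":
            sub = df.dropna(subset=[value])
            table = {
                str(g): s[value].to_numpy() for g, s in sub.groupby(group, sort=True)
            }
            res = stats_mod.one_way_anova(table)
            rows.append(
                dict(test=name, term=group, statistic=res.F,
                     df=f"{res.df_between},{res.df_within}", p=res.p, p_adjusted=None)
            )
            if res.p < 0.05:  # HSD gated on the omnibus test
                for pw in stats_mod.tukey_hsd(table):
                    rows.append(
                        dict(test="tukey_hsd", term=f"{pw.group_a} vs {pw.group_b}",
                             statistic=pw.mean_diff, df=None, p=None,
                             p_adjusted=pw.p_adjusted)
                    )
        elif name == "tukey_hsd":
            sub = df.dropna(subset=[value])
            table = {
                str(g): s[value].to_numpy() for g, s in sub.groupby(group, sort=True)
            }
            for pw in stats_mod.tukey_hsd(table):
                rows.append(
                    dict(test=name, term=f"{pw.group_a} vs {pw.group_b}",
                         statistic=pw.mean_diff, df=None, p=None,
                         p_adjusted=pw.p_adjusted)
                )
        elif name == "two_way_anova":
            factor2 = test.get("factor2", "factor2")
            sub = df.dropna(subset=[value]).rename(columns={value: "value"})
            for term, (F, p) in stats_mod.two_way_anova(sub, (group, factor2)).items():
                rows.append(dict(test=name, term=term, statistic=F, df=None,
                                 p=p, p_adjusted=None))
        elif name == "chi_squared":
            outcome = test.get("outcome")
            counts = pd.crosstab(df[group], df[outcome])
            stat, dof, p = stats_mod.chi_squared_contingency(counts.to_numpy())
            rows.append(dict(test=name, term=f"{group} x {outcome}", statistic=stat,
                             df=dof, p=p, p_adjusted=None))
        elif name == "linear_fit":
            xcol, ycol = test["x"], test["y"]
            sub = df.dropna(subset=[xcol, ycol])
            slope, intercept, r, p = stats_mod.linear_fit(sub[xcol], sub[ycol])
            rows.append(dict(test=name, term=f"{ycol} ~ {xcol}", statistic=slope,
                             df=None, p=p, p_adjusted=None))
    out = pd.DataFrame(rows)
    if out_csv is not None:
        Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
        out.to_csv(out_csv, index=False)
    return out
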