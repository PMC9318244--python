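"""Manifest-driven batch pipeline: images in, measurement and stats tables out.

The manifest CSV lists one row per lesion photograph: ``lesion_id, group,
illumination, path`` plus an optional ``melanoma_stage`` column. For each
image the pipeline runs grayscale conversion (if RGB), divide-blend
segmentation, morphometry, shape FD on the blended image, in-lesion ROI
extraction and per-ROI surface FD; it then assembles the group-comparison
statistics. All outputs are CSV; the full configuration is echoed to JSON
next to them for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import fractal, morphometry, roi, segmentation, stats
from .image import load_image

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["lesion_id", "group", "illumination", "path"]


@dataclass(frozen=True)
class PipelineConfig:
    manifest: str
    output_dir: str
    mm_per_pixel: float | None = None
    roi_size: int = roi.DEFAULT_ROI_SIZE
    white_threshold: int = segmentation.DEFAULT_WHITE_THRESHOLD
    min_component_fraction: float = segmentation.DEFAULT_MIN_COMPONENT_FRACTION
    grid_offset_averaging: bool = False
    master_seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.roi_size < 8:
            raise ValueError("roi_size must be >= 8")
        if self.mm_per_pixel is not None and self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if not (0 < self.white_threshold <= 255):
            raise ValueError("white_threshold must be in (0, 255]")


def process_image(
    path: str | Path,
    config: PipelineConfig,
) -> tuple[dict, list[dict]]:
    """Run one photograph through segmentation, morphometry and FD.

    Returns the lesion-level measurement record and a list of ROI-level
    surface-FD records (empty when the lesion is too small for any ROI).
    """
    img = load_image(path, mm_per_pixel=config.mm_per_pixel)
    seg_cfg = segmentation.SegmentationConfig(
        white_threshold=config.white_threshold,
        min_component_fraction=config.min_component_fraction,
    )
    blended, mask = segmentation.segment(img, seg_cfg)
    morph = morphometry.measure(mask, config.mm_per_pixel)
    shape = fractal.shape_fd(blended, grid_offset_averaging=config.grid_offset_averaging)
    rois = roi.extract_rois(img, mask, roi_size=config.roi_size)
    roi_rows = []
    for idx, patch in enumerate(rois.patches):
        res = fractal.surface_fd(patch, grid_offset_averaging=config.grid_offset_averaging)
        roi_rows.append(
            {"roi_index": idx, "origin_row": rois.origins[idx][0],
             "origin_col": rois.origins[idx][1],
             "surface_fd": res.fd, "r_squared": res.r_squared}
        )
    record = {
        "area": morph.area,
        "perimeter": morph.perimeter,
        "pixel_area": morph.pixel_area,
        "pixel_perimeter": morph.pixel_perimeter,
        "shape_fd": shape.fd,
        "shape_fd_r_squared": shape.r_squared,
        "n_rois": len(rois),
        "too_small_for_surface": rois.too_small,
    }
    return record, roi_rows


def run_pipeline(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis over a manifest of lesion photographs.

    Writes ``measurements.csv`` (one row per lesion × illumination),
    ``surface_fd.csv`` (one row per ROI), the statistics tables and a
    ``config.json`` echo into ``config.output_dir``; returns the tables.
    Unreadable images are skipped with a logged reason; a malformed
    manifest aborts.
    """
    manifest = pd.read_csv(config.manifest)
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"malformed manifest: missing columns {missing}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    records, roi_records, skipped = [], [], []
    for row in manifest.itertuples(index=False):
        try:
            rec, roi_rows = process_image(row.path, config)
        except (OSError, ValueError) as exc:
            logger.warning("skipping %s (%s): %s", row.lesion_id, row.path, exc)
            skipped.append(
                {"lesion_id": row.lesion_id, "illumination": row.illumination,
                 "path": row.path, "reason": str(exc)}
            )
            continue
        meta = {
            "lesion_id": row.lesion_id,
            "group": row.group,
            "illumination": row.illumination,
            "melanoma_stage": getattr(row, "melanoma_stage", None),
        }
        records.append({**meta, **rec})
        roi_records.extend({**meta, **r} for r in roi_rows)

    measurements = pd.DataFrame(records)
    surface = pd.DataFrame(roi_records)
    tables: dict[str, pd.DataFrame] = {
        "measurements": measurements,
        "surface_fd": surface,
    }
    if skipped:
        tables["skipped"] = pd.DataFrame(skipped)
    if len(measurements):
        tables.update(assemble_stats(measurements, surface))

    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "config.json").write_text(json.dumps(dataclasses.asdict(config), indent=2))
    logger.info("wrote %d tables to %s (%d lesions, %d skipped)",
                len(tables), out, len(measurements), len(skipped))
    return tables


def _report_to_frames(name: str, rep: stats.StatsReport) -> dict[str, pd.DataFrame]:
    frames = {name: rep.table.assign(test=rep.test_name, **{
        k: v for k, v in rep.extra.items() if not isinstance(v, (list, dict))
    })}
    if rep.pairwise is not None:
        frames[f"{name}_pairwise"] = rep.pairwise.rename_axis("group").reset_index()
    return frames


def assemble_stats(
    measurements: pd.DataFrame, surface: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    """Build every comparison table the analysis design calls for.

    Paired PL/NPL tests for area, perimeter and shape FD; group
    comparisons of each variable per illumination; Spearman correlations
    of shape FD with area and perimeter; ROI-level surface-FD group
    comparisons; melanoma in-situ vs invasive subgroup tests when stage
    labels are present.
    """
    tables: dict[str, pd.DataFrame] = {}
    paired_rows = []
    for var in ("area", "perimeter", "shape_fd"):
        rep = stats.paired_illumination_test(measurements, var)
        paired_rows.append(rep.table.assign(test=rep.test_name))
    tables["paired_illumination"] = pd.concat(paired_rows, ignore_index=True)

    multi_group = measurements["group"].nunique() >= 2
    enough = multi_group and measurements.groupby(["group", "illumination"]).size().min() >= 3
    if enough:
        for var in ("area", "perimeter", "shape_fd"):
            for illum in ("PL", "NPL"):
                rep = stats.group_comparison(measurements, var, illumination=illum)
                tables.update(_report_to_frames(f"group_{var}_{illum}", rep))
        if len(surface):
            for illum in ("PL", "NPL"):
                sub = surface[surface.illumination == illum]
                if sub.groupby("group").size().min() >= 3 and sub["group"].nunique() >= 2:
                    rep = stats.group_comparison(sub, "surface_fd")
                    tables.update(_report_to_frames(f"group_surface_fd_{illum}", rep))
    tables["correlations"] = stats.correlation_matrix(measurements)

    if measurements["melanoma_stage"].notna().any():
        sub_rows = []
        for illum in ("PL", "NPL"):
            rep = stats.melanoma_subgroup_test(
                measurements[measurements.illumination == illum], "shape_fd"
            )
            if not rep.table.empty:
                sub_rows.append(rep.table.assign(
                    illumination=illum, variable="shape_fd",
                    test=rep.test_name, p=rep.extra.get("p")))
            if len(surface):
                rep = stats.melanoma_subgroup_test(
                    surface[surface.illumination == illum], "surface_fd"
                )
                if not rep.table.empty:
                    sub_rows.append(rep.table.assign(
                        illumination=illum, variable="surface_fd",
                        test=rep.test_name, p=rep.extra.get("p")))
        if sub_rows:
            tables["melanoma_subgroups"] = pd.concat(sub_rows, ignore_index=True)
    return tables
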