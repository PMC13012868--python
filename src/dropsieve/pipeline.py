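"""End-to-end orchestration of the screening workflow.

``analyze_field`` runs one field of view through the full measurement chain
(resize, rolling-ball background removal, granulometry + moments, droplet
segmentation, per-FOV summary).  ``run_screen`` applies it to every image of
a plate, aggregates FOVs to wells, references compound wells against the
DMSO controls and writes the classified screen to disk.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import RunConfig
from .granulometry import (
    Image,
    compute_size_distribution,
    normalize_distribution,
    remove_background,
    resize_image,
)
from .io import parse_fov_filename, read_fov_image
from .screen import (
    PHENOTYPE_CLASSES,
    WELL_FEATURES,
    PhenotypeCall,
    ScreenReport,
    WellResult,
    aggregate_well,
    classify_phenotype,
    compute_control_stats,
    summarize_screen,
)
from .segmentation import FieldSummary, pooled_threshold, segment_droplets, summarize_field

__all__ = ["analyze_field", "preprocess_field", "run_screen", "ScreenOutputs"]

logger = logging.getLogger(__name__)


def preprocess_field(image: Image | np.ndarray, config: RunConfig) -> Image:
    """Resize then remove the slowly varying background of one FOV."""
    img = resize_image(image, config.resize_factor)
    return remove_background(img, config.ball_radius)


def analyze_field(
    image: Image | np.ndarray,
    config: RunConfig,
    fixed_threshold: Optional[float] = None,
    preprocessed: bool = False,
) -> FieldSummary:
    """Measure one field of view: granulometry moments + droplet features.

    ``fixed_threshold`` (in preprocessed-image ADU) overrides the per-image
    Otsu threshold; the screen pipeline passes a plate-wide threshold pooled
    from control FOVs.  Set ``preprocessed=True`` when the image has already
    been resized/background-subtracted.
    """
    img = image if preprocessed else preprocess_field(image, config)
    dist = compute_size_distribution(img, config.schedule(), connectivity=config.connectivity)
    ndist = normalize_distribution(dist) if dist.mass > 0 else None
    if fixed_threshold is not None:
        records = segment_droplets(
            img, config.min_area_px2, "fixed", fixed_threshold, config.connectivity
        )
    else:
        records = segment_droplets(img, config.min_area_px2, "otsu", connectivity=config.connectivity)
    return summarize_field(records, img, ndist)


def analyze_titration_series(
    series,
    config: RunConfig,
    metric: str = "n_droplets",
    frac_of_max: Optional[float] = None,
):
    """Measure a titration series and estimate its saturation concentration.

    ``series`` is a sequence of ``(concentration, image)`` pairs (extra
    trailing tuple elements, e.g. ground-truth tables, are ignored).  One
    segmentation threshold is pooled over the whole series, so fields below
    the tipping point — which contain nothing but noise — are not
    thresholded against themselves.
    """
    from .screen import estimate_saturation_concentration

    pre = [(float(item[0]), preprocess_field(item[1], config)) for item in series]
    thr = pooled_threshold([im for _, im in pre])
    wells = [
        (c, aggregate_well([analyze_field(im, config, fixed_threshold=thr, preprocessed=True)], well=f"c={c:g}"))
        for c, im in pre
    ]
    result = estimate_saturation_concentration(
        wells, metric=metric, frac_of_max=config.frac_of_max if frac_of_max is None else frac_of_max
    )
    return result, wells


@dataclass
class ScreenOutputs:
    report: ScreenReport
    well_results: pd.DataFrame
    calls: pd.DataFrame
    paths: dict


def _load_platemap(path: str | Path) -> pd.DataFrame:
    pm = pd.read_csv(path, dtype=str).fillna("")
    required = {"well", "role"}
    missing = required - set(pm.columns)
    if missing:
        raise ValueError(f"platemap missing columns: {sorted(missing)}")
    if "compound_id" not in pm.columns:
        pm["compound_id"] = ""
    return pm


def run_screen(config: RunConfig) -> ScreenOutputs:
    """Run the full screening workflow from images on disk to a screen report.

    Steps: enumerate and validate images against the plate map; preprocess
    every FOV; derive one plate-wide segmentation threshold from the pooled
    control FOVs (unless configured otherwise); measure each FOV; aggregate
    to wells; z-score compound wells against DMSO controls; classify and
    summarize.  Every table written embeds the config hash.
    """
    t0 = time.monotonic()
    images_dir = Path(config.images_dir)
    pm = _load_platemap(config.platemap)
    files = sorted(images_dir.glob("*.tif")) + sorted(images_dir.glob("*.tiff"))
    by_well: dict[str, list[Path]] = {}
    for f in files:
        _, well, _ = parse_fov_filename(f.name)
        by_well.setdefault(well, []).append(f)
    mapped = set(pm["well"])
    imaged = set(by_well)
    problems = []
    if mapped - imaged:
        problems.append(f"platemap wells without images: {sorted(mapped - imaged)}")
    if imaged - mapped:
        problems.append(f"imaged wells missing from platemap: {sorted(imaged - mapped)}")
    if problems:
        raise ValueError("; ".join(problems))

    logger.info("preprocessing %d FOVs in %d wells", len(files), len(by_well))
    pre: dict[str, list] = {}
    for well, paths in by_well.items():
        imgs = []
        for p in sorted(paths):
            img, _, _, _ = read_fov_image(p)
            imgs.append(preprocess_field(img, config))
        pre[well] = imgs

    roles = dict(zip(pm["well"], pm["role"]))
    compounds = dict(zip(pm["well"], pm["compound_id"]))
    control_wells = [w for w, r in roles.items() if r == "dmso_control"]

    fixed_thr: Optional[float] = None
    if config.threshold_method == "pooled_otsu":
        if not control_wells:
            raise ValueError("pooled_otsu thresholding requires dmso_control wells")
        fixed_thr = pooled_threshold([im for w in control_wells for im in pre[w]])
        logger.info("plate-wide threshold from %d control wells: %.2f ADU", len(control_wells), fixed_thr)
    elif config.threshold_method == "fixed":
        fixed_thr = config.fixed_threshold

    t1 = time.monotonic()
    well_results: dict[str, WellResult] = {}
    for well, imgs in pre.items():
        summaries = [
            analyze_field(im, config, fixed_threshold=fixed_thr, preprocessed=True) for im in imgs
        ]
        well_results[well] = aggregate_well(summaries, well=well)
    logger.info("measured %d wells in %.1f s", len(well_results), time.monotonic() - t1)

    controls = compute_control_stats([well_results[w] for w in control_wells])
    calls: list[PhenotypeCall] = []
    withheld: list[str] = []
    for well, result in well_results.items():
        if roles[well] != "compound":
            continue
        if not result.qc_pass:
            withheld.append(well)
            continue
        calls.append(classify_phenotype(result, controls, config.z_cut, compounds[well]))
    report = summarize_screen(calls, z_cut=config.z_cut)
    report.withheld_wells = withheld

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    wr_rows = []
    for well, r in sorted(well_results.items()):
        row = {"well": well, "role": roles[well], "compound_id": compounds[well], "n_fovs": r.n_fovs, "qc_pass": r.qc_pass}
        row.update({k: r.features[k] for k in WELL_FEATURES})
        row["config_hash"] = chash
        wr_rows.append(row)
    well_df = pd.DataFrame(wr_rows)
    well_df.to_csv(out_dir / "well_results.csv", index=False)

    call_rows = []
    for c in calls:
        row = {"well": c.well, "compound_id": c.compound_id, "call": c.call, "rationale": c.rationale}
        row.update({f"z_{k}": c.z_scores[k] for k in WELL_FEATURES})
        row["config_hash"] = chash
        call_rows.append(row)
    calls_df = pd.DataFrame(call_rows)
    calls_df.to_csv(out_dir / "phenotype_calls.csv", index=False)

    report_payload = {
        "counts": report.counts,
        "percentages": report.percentages,
        "total_screened": report.total_screened,
        "z_cut": config.z_cut,
        "withheld_wells": withheld,
        "config": config.to_dict(),
        "config_hash": chash,
    }
    with open(out_dir / "screen_report.json", "w") as fh:
        json.dump(report_payload, fh, indent=2, sort_keys=True)
    logger.info("screen complete in %.1f s: %s", time.monotonic() - t0, report.counts)
    return ScreenOutputs(
        report=report,
        well_results=well_df,
        calls=calls_df,
        paths={
            "well_results": str(out_dir / "well_results.csv"),
            "phenotype_calls": str(out_dir / "phenotype_calls.csv"),
            "screen_report": str(out_dir / "screen_report.json"),
        },
    )
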