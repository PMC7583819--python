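"""End-to-end orchestration: preprocess → segment → metrics → profile →
fit → volumes (→ match when a reference table is given).

A single validated configuration drives all stages; every stage writes
its artifact (CSV / ASCII grid / JSON) into the run directory so any
stage can be rerun or inspected in isolation.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import crown_metrics, profile_models, profile_points, volumes
from .cloud import CLASS_GROUND, PointCloud
from .preprocess import preprocess as preprocess_cloud
from .segmentation import rhcsa_segment, extract_crown_points
from .raster import write_ascii_grid
from .validation import MatchConfig, match_trees

logger = logging.getLogger(__name__)


class PreprocessParams(BaseModel):
    noise_radius: float = Field(default=5.0, gt=0)
    min_neighbors: int = Field(default=4, ge=1)
    ground_cell: float = Field(default=2.0, gt=0)
    ground_tol: float = Field(default=0.3, gt=0)
    resolution: float = Field(default=0.25, gt=0)


class SegmentParams(BaseModel):
    level_step: float = Field(default=0.1, gt=0)
    min_tree_height: float = Field(default=2.0, ge=0)
    circularity_threshold: float = Field(default=0.5, gt=0, le=1)
    min_region_cells: int = Field(default=5, ge=1)


class MetricsParams(BaseModel):
    bin_width: float = Field(default=0.5, gt=0)
    p: float = Field(default=1.0, gt=0)
    sigma_bins: float = Field(default=0.5, gt=0)


class ProfileParams(BaseModel):
    bin_width: float = Field(default=0.5, gt=0)
    percentiles: list[int] = Field(default=[90, 95, 99])
    fit_percentile: int = 95  # the percentile used for model fitting
    min_points: int = Field(default=3, ge=1)

    @field_validator("percentiles")
    @classmethod
    def _check_percentiles(cls, v):
        if not v or any(not 0 < p <= 100 for p in v):
            raise ValueError("percentiles must lie in (0, 100]")
        return v


class FitParams(BaseModel):
    families: list[str] = Field(
        default=["parabola", "mitscherlich", "power", "beta"]
    )
    scopes: list[str] = Field(default=["entire", "upper"])
    cv_mode: str = "by_tree"
    run_cv: bool = False

    @field_validator("families")
    @classmethod
    def _check_families(cls, v):
        unknown = set(v) - set(profile_models.FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")
        return v


class MatchParams(BaseModel):
    distance_fraction: float = Field(default=0.60, gt=0, lt=1)
    height_fraction: float = Field(default=0.15, gt=0, lt=1)


class PipelineConfig(BaseModel):
    """Validated stage parameters plus input/output paths."""

    cloud: str | None = None  # CSV(.gz) point cloud; None when given in-memory
    reference: str | None = None  # optional reference tree table CSV
    plot_area: float | None = Field(default=None, gt=0)
    out_dir: str = "crownlidar_run"
    seed: int = 0
    preprocess: PreprocessParams = PreprocessParams()
    segment: SegmentParams = SegmentParams()
    metrics: MetricsParams = MetricsParams()
    profile: ProfileParams = ProfileParams()
    fit: FitParams = FitParams()
    match: MatchParams = MatchParams()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.model_validate(raw)


def run_pipeline(config: PipelineConfig, cloud: PointCloud | None = None,
                 reference: pd.DataFrame | None = None) -> dict:
    """Execute all stages; returns a dict of in-memory results and writes
    artifacts under ``config.out_dir``.

    Failures carry the stage name; artifacts of completed stages remain
    on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_run_log(out)
    results: dict = {}
    if cloud is None:
        if config.cloud is None:
            raise ValueError("no input cloud: set config.cloud or pass one")
        cloud = PointCloud.from_csv(config.cloud)
    if reference is None and config.reference is not None:
        reference = pd.read_csv(config.reference)

    stage = "preprocess"
    try:
        pp = config.preprocess
        normalized, chm = preprocess_cloud(
            cloud, pp.noise_radius, pp.min_neighbors, pp.ground_cell,
            pp.ground_tol, pp.resolution,
        )
        normalized.to_csv(out / "normalized.csv.gz")
        chm.save(out / "chm.asc")
        results["normalized"], results["chm"] = normalized, chm

        stage = "segment"
        sp = config.segment
        segments = rhcsa_segment(chm, sp.level_step, sp.min_tree_height,
                                 sp.circularity_threshold, sp.min_region_cells)
        write_ascii_grid(out / "labels.asc", segments.labels.astype(float),
                         segments.resolution, segments.origin)
        segments.tree_table().to_csv(out / "trees.csv", index=False)
        nonground = normalized.select(normalized.classification != CLASS_GROUND)
        labeled = extract_crown_points(nonground, segments)
        labeled.to_csv(out / "labeled.csv.gz")
        results["segments"], results["labeled"] = segments, labeled

        stage = "metrics"
        mp = config.metrics
        metrics = crown_metrics.metrics_table(labeled, mp.bin_width, mp.p,
                                              mp.sigma_bins)
        apex = segments.tree_table().set_index("tree_id")
        metrics = metrics.join(apex[["apex_x", "apex_y"]], on="tree_id",
                               rsuffix="_chm")
        metrics.to_csv(out / "metrics.csv", index=False)
        results["metrics"] = metrics

        stage = "profile"
        fp = config.profile
        points = profile_points.build_profile_points(
            labeled, metrics, fp.bin_width, tuple(fp.percentiles), fp.min_points
        )
        points.to_csv(out / "profile_points.csv", index=False)
        results["profile_points"] = points

        stage = "fit"
        fits, cv_stats = _fit_stage(points, config)
        with open(out / "fits.json", "w") as fh:
            json.dump({"fits": [f.to_dict() for f in fits.values()],
                       "cv": {k: v.to_dict() for k, v in cv_stats.items()}},
                      fh, indent=2)
        results["fits"], results["cv"] = fits, cv_stats

        stage = "volume"
        volume_table, volume_report = _volume_stage(labeled, metrics, fits,
                                                    config)
        volume_table.to_csv(out / "volumes.csv", index=False)
        with open(out / "volume_report.json", "w") as fh:
            json.dump(volume_report, fh, indent=2)
        results["volumes"] = volume_table
        results["volume_report"] = volume_report

        if reference is not None:
            stage = "match"
            area = config.plot_area
            if area is None:
                area = float((cloud.x.max() - cloud.x.min())
                             * (cloud.y.max() - cloud.y.min()))
            detected = metrics.rename(columns={"apex_x": "x", "apex_y": "y"})
            match = match_trees(
                detected, reference, area,
                MatchConfig(config.match.distance_fraction,
                            config.match.height_fraction),
            )
            match.pairs.to_csv(out / "matches.csv", index=False)
            with open(out / "match_summary.json", "w") as fh:
                json.dump({"detection_accuracy": match.detection_accuracy,
                           "n_detected": match.n_detected,
                           "n_reference": match.n_reference,
                           "n_matched": int(len(match.pairs))}, fh, indent=2)
            results["match"] = match
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return results


def _fit_stage(points, config):
    fp, fc = config.profile, config.fit
    data = points[points["percentile"] == fp.fit_percentile]
    fits, cv_stats = {}, {}
    for family in fc.families:
        for scope in fc.scopes:
            key = f"{family}:{scope}"
            try:
                fits[key] = profile_models.fit_profile(data, family, scope)
            except (ValueError, RuntimeError) as exc:
                logger.warning("fit %s failed: %s", key, exc)
                continue
            if fc.run_cv:
                try:
                    cv_stats[key] = profile_models.cross_validate(
                        data, family, scope, fc.cv_mode)
                except (ValueError, RuntimeError) as exc:
                    logger.warning("CV %s failed: %s", key, exc)
    return fits, cv_stats


def _volume_stage(labeled, metrics, fits, config):
    rows = []
    entire = {k.split(":")[0]: f for k, f in fits.items()
              if k.endswith(":entire")}
    for row in metrics.itertuples(index=False):
        crown = labeled.select((labeled.tree_id == row.tree_id)
                               & (labeled.z >= row.CBH))
        rows.append({"tree_id": row.tree_id, "method": "cone",
                     "volume": volumes.cone_volume(row.LCR, row.CL)})
        try:
            rows.append({"tree_id": row.tree_id, "method": "hull3d",
                         "volume": volumes.hull3d_volume(crown)})
        except ValueError as exc:
            logger.info("hull3d failed for tree %d: %s", row.tree_id, exc)
        for family, fit in entire.items():
            profile = lambda x, f=fit, L=row.LCR: f.predict(x, L)  # noqa: E731
            rows.append({
                "tree_id": row.tree_id, "method": f"profile:{family}",
                "volume": volumes.volume_of_revolution(profile, row.CL),
            })
    table = pd.DataFrame(rows, columns=["tree_id", "method", "volume"])
    report = {}
    if "profile:beta" in set(table["method"]) and len(metrics) >= 2:
        try:
            _, report = volumes.compare_volumes(table, "profile:beta")
        except ValueError as exc:
            logger.info("volume comparison skipped: %s", exc)
    return table, report


def _setup_run_log(out_dir: Path) -> None:
    root = logging.getLogger("crownlidar")
    root.setLevel(logging.INFO)
    path = out_dir / "run.log"
    if not any(isinstance(h, logging.FileHandler)
               and getattr(h, "baseFilename", None) == str(path.resolve())
               for h in root.handlers):
        handler = logging.FileHandler(path, mode="w")
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        root.addHandler(handler)
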