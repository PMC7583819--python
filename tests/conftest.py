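"""Shared fixtures: synthetic stands run once through the pipeline."""

from __future__ import annotations

import numpy as np
import pytest

import crownlidar as cl


def run_stand(config: cl.StandConfig) -> dict:
    """Generate a stand and push it through preprocessing, segmentation,
    metrics and matching; return every intermediate product."""
    cloud, truth = cl.generate_stand(config)
    normalized, chm = cl.preprocess(cloud)
    segments = cl.rhcsa_segment(chm)
    nonground = normalized.select(normalized.classification != cl.CLASS_GROUND)
    labeled = cl.extract_crown_points(nonground, segments)
    metrics = cl.metrics_table(labeled)
    detected = segments.tree_table().rename(
        columns={"apex_x": "x", "apex_y": "y", "apex_height": "TH"})
    area = config.extent[0] * config.extent[1]
    match = cl.match_trees(detected, truth.trees, area)
    pairs = (
        match.pairs
        .merge(metrics, left_on="detected_id", right_on="tree_id")
        .merge(truth.trees, left_on="reference_id", right_on="tree_id",
               suffixes=("_est", "_true"))
    )
    return {
        "config": config, "cloud": cloud, "truth": truth,
        "normalized": normalized, "chm": chm, "segments": segments,
        "labeled": labeled, "metrics": metrics, "match": match,
        "pairs": pairs,
    }


@pytest.fixture(scope="session")
def separated_run() -> dict:
    """A 50-tree stand whose crowns cannot touch (5 m spacing)."""
    return run_stand(cl.well_separated_config(n_trees=50, seed=11))


@pytest.fixture(scope="session")
def plantation_run() -> dict:
    """Plantation-density stand: jittered 2 m grid (~2500 stems/ha)."""
    return run_stand(cl.StandConfig(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def gaussian_bump_chm(peaks, centers, sigma=1.5, resolution=0.25,
                      extent=(16.0, 16.0)) -> cl.CHMRaster:
    """CHM built from the pointwise maximum of Gaussian bumps."""
    nx = int(extent[0] / resolution)
    ny = int(extent[1] / resolution)
    x = (np.arange(nx) + 0.5) * resolution
    y = (np.arange(ny) + 0.5) * resolution
    xx, yy = np.meshgrid(x, y)
    values = np.zeros((ny, nx))
    for peak, (cx, cy) in zip(peaks, centers):
        bump = peak * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
        values = np.maximum(values, bump)
    return cl.CHMRaster(values, resolution, (0.0, 0.0))
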