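"""Synthetic forest-stand point clouds with full ground truth.

Emulates an even-aged conifer (larch-type) plantation scanned from
above by UAV-LiDAR: trees on a jittered planting grid (default 2 m
spacing ≈ 2500 stems/ha), tree heights ~9.7 ± 1.3 m, crown ratios
around 0.55, largest crown radii ~1.1–1.4 m from a height allometry,
and ~370 returns/m² of crown footprint.  Crown returns are sampled on
and inside a solid of revolution whose outer profile follows a chosen
model family (default: the modified beta equation with realistic
plantation coefficients); return density decays linearly from the tree
tip to the crown base (occlusion of the lower crown), and most returns
sit near the crown surface, as for a scanner looking down from above.
Sparse stem returns, gridded ground returns on a gently sloped terrain
and a handful of air/low noise points complete the cloud.

Everything is driven by a single seeded generator: a fixed seed gives
byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cloud import (CLASS_GROUND, CLASS_NOISE, CLASS_VEGETATION, PointCloud)
from .profile_models import evaluate_profile

logger = logging.getLogger(__name__)

# entire-crown beta coefficients of a larch plantation profile
DEFAULT_BETA_PARAMS = {"a": 1.0928, "b1": 1.4175, "b2": 0.1787,
                       "c1": 0.2125, "c2": 0.6590}


@dataclass(frozen=True)
class StandConfig:
    """Study-condition defaults for the simulated plantation."""

    extent: tuple = (20.0, 20.0)  # plot size (m × m)
    spacing: float = 2.0  # planting grid spacing (m); 2 m ≈ 2500 stems/ha
    jitter: float = 0.3  # uniform planting jitter (m)
    th_mean: float = 9.7  # tree height distribution (m)
    th_sd: float = 1.3
    th_range: tuple = (5.8, 13.0)  # truncation bounds (m)
    crown_ratio_mean: float = 0.55  # CL/TH
    crown_ratio_sd: float = 0.05
    crown_ratio_range: tuple = (0.40, 0.70)
    lcr_slope: float = 0.10  # LCR covariate allometry on TH (m per m)
    lcr_intercept: float = 0.25
    lcr_sd: float = 0.15
    lcr_min: float = 0.5
    profile_family: str = "beta"
    profile_params: dict = field(default_factory=lambda: dict(DEFAULT_BETA_PARAMS))
    point_density: float = 370.0  # returns per m² of crown footprint
    density_decay: float = 0.3  # surface density at crown base / at tip
    surface_fraction: float = 0.8  # share of returns near the crown surface
    position_noise: float = 0.03  # per-coordinate ranging noise (m)
    stem_points_per_meter: float = 2.0  # sparse stem returns below the crown
    ground_spacing: float = 0.3  # ground-return grid (m)
    terrain_slope_deg: float = 5.0
    terrain_aspect_deg: float = 90.0  # downslope direction (deg from east)
    terrain_base: float = 100.0  # elevation at the plot origin (m)
    n_air_points: int = 15
    n_low_points: int = 8
    seed: int = 0

    def validate(self) -> None:
        if self.spacing <= 0 or self.point_density < 0:
            raise ValueError("spacing and point_density must be positive")
        if not 0 < self.density_decay <= 1:
            raise ValueError("density_decay must lie in (0, 1]")
        if not 0 <= self.surface_fraction <= 1:
            raise ValueError("surface_fraction must lie in [0, 1]")
        if self.th_range[0] >= self.th_range[1]:
            raise ValueError("invalid TH truncation range")


@dataclass
class TruthTable:
    """Ground truth: per-tree metrics and per-point labels."""

    trees: pd.DataFrame  # tree_id, x, y, TH, CBH, CL, LCR, lcr_cov, DBH, volume
    point_tree_id: np.ndarray  # 0 for non-tree points
    point_class: np.ndarray  # true class codes (ground/vegetation/noise)


def terrain_elevation(config: StandConfig, x, y):
    """Planar terrain: base elevation plus a uniform slope."""
    slope = np.tan(np.radians(config.terrain_slope_deg))
    az = np.radians(config.terrain_aspect_deg)
    return config.terrain_base + slope * (
        np.asarray(x) * np.cos(az) + np.asarray(y) * np.sin(az)
    )


def _tree_positions(config: StandConfig, rng) -> np.ndarray:
    nx = int(np.floor(config.extent[0] / config.spacing))
    ny = int(np.floor(config.extent[1] / config.spacing))
    if nx < 1 or ny < 1:
        return np.empty((0, 2))
    gx = (np.arange(nx) + 0.5) * config.spacing
    gy = (np.arange(ny) + 0.5) * config.spacing
    xx, yy = np.meshgrid(gx, gy)
    pos = np.column_stack([xx.ravel(), yy.ravel()])
    pos += rng.uniform(-config.jitter, config.jitter, size=pos.shape)
    return pos


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():  # resample instead of clipping: no boundary atoms
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _sample_depths(rng, n, decay):
    """RDINC draws with linear surface-density decay from tip to base:
    weight w(x) = 1 − (1 − decay)·x, sampled by inverse CDF."""
    u = rng.uniform(size=n)
    if decay == 1.0:
        return u
    c = 1.0 - (1.0 - decay) / 2.0  # normalizing constant
    disc = 1.0 - 2.0 * (1.0 - decay) * c * u
    return (1.0 - np.sqrt(np.maximum(disc, 0.0))) / (1.0 - decay)


def _true_profile(config: StandConfig, lcr_cov: float):
    """Callable OR(x) of the true outer profile for one tree."""
    fam, params = config.profile_family, config.profile_params

    def profile(x):
        return evaluate_profile(fam, params, x, lcr_cov)

    return profile


def generate_stand(config: StandConfig = StandConfig()) -> tuple:
    """Simulate one plot; returns ``(cloud, truth)``.

    The emitted cloud carries raw (unnormalized) elevations and no class
    or tree labels — preprocessing and segmentation are supposed to
    recover them; the truth lives in the TruthTable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    positions = _tree_positions(config, rng)
    n_trees = len(positions)

    xs, ys, zs = [], [], []
    tree_ids, classes = [], []
    tree_rows = []
    grid = np.linspace(0.0, 1.0, 501)
    for k in range(n_trees):
        px, py = positions[k]
        th = float(_truncated_normal(rng, config.th_mean, config.th_sd,
                                     *config.th_range, size=1)[0])
        cr = float(_truncated_normal(rng, config.crown_ratio_mean,
                                     config.crown_ratio_sd,
                                     *config.crown_ratio_range, size=1)[0])
        cl = cr * th
        cbh = th - cl
        lcr_cov = max(config.lcr_min,
                      config.lcr_intercept + config.lcr_slope * th
                      + float(rng.normal(0.0, config.lcr_sd)))
        profile = _true_profile(config, lcr_cov)
        curve = np.asarray(profile(grid), dtype=float)
        lcr_true = float(curve.max())
        volume_true = float(np.pi * cl * np.trapezoid(curve**2, grid))

        n_crown = int(round(config.point_density * np.pi * lcr_true**2))
        depth = _sample_depths(rng, n_crown, config.density_decay)
        radius_at = np.interp(depth, grid, curve)
        u = rng.uniform(size=n_crown)
        on_surface = rng.uniform(size=n_crown) < config.surface_fraction
        radial = np.where(on_surface, 1.0 - 0.05 * u, np.sqrt(u))
        r = radius_at * radial
        az = rng.uniform(0.0, 2.0 * np.pi, size=n_crown)
        cx = px + r * np.cos(az)
        cy = py + r * np.sin(az)
        cz_height = th - depth * cl
        base = terrain_elevation(config, px, py)
        noise = rng.normal(0.0, config.position_noise, size=(n_crown, 3))
        xs.append(cx + noise[:, 0])
        ys.append(cy + noise[:, 1])
        zs.append(base + cz_height + noise[:, 2])
        tree_ids.append(np.full(n_crown, k + 1, dtype=np.int32))
        classes.append(np.full(n_crown, CLASS_VEGETATION, dtype=np.uint8))

        n_stem = int(round(config.stem_points_per_meter * cbh))
        if n_stem:
            sz = rng.uniform(0.05, cbh, size=n_stem)
            sr = rng.uniform(0.0, 0.05, size=n_stem)
            saz = rng.uniform(0.0, 2.0 * np.pi, size=n_stem)
            xs.append(px + sr * np.cos(saz))
            ys.append(py + sr * np.sin(saz))
            zs.append(base + sz)
            tree_ids.append(np.full(n_stem, k + 1, dtype=np.int32))
            classes.append(np.full(n_stem, CLASS_VEGETATION, dtype=np.uint8))

        dbh = max(5.1, 1.03 * th + float(rng.normal(0.0, 1.2)))
        tree_rows.append({
            "tree_id": k + 1, "x": px, "y": py, "TH": th, "CBH": cbh,
            "CL": cl, "LCR": lcr_true, "lcr_cov": lcr_cov, "DBH": dbh,
            "volume": volume_true,
        })

    # ground returns on a jittered grid across the full extent
    gx = np.arange(0.0, config.extent[0], config.ground_spacing)
    gy = np.arange(0.0, config.extent[1], config.ground_spacing)
    gxx, gyy = np.meshgrid(gx, gy)
    gxx = gxx.ravel() + rng.uniform(-0.05, 0.05, gxx.size)
    gyy = gyy.ravel() + rng.uniform(-0.05, 0.05, gyy.size)
    gzz = terrain_elevation(config, gxx, gyy) + rng.normal(0.0, 0.02, gxx.size)
    xs.append(gxx)
    ys.append(gyy)
    zs.append(gzz)
    tree_ids.append(np.zeros(gxx.size, dtype=np.int32))
    classes.append(np.full(gxx.size, CLASS_GROUND, dtype=np.uint8))

    # air and low noise points; air blunders (birds, multipath) float
    # well above the tallest possible crown
    air_base = config.th_range[1]
    for n_noise, dz_lo, dz_hi in (
            (config.n_air_points, air_base + 12.0, air_base + 35.0),
            (config.n_low_points, -6.0, -2.0)):
        if n_noise <= 0:
            continue
        nx = rng.uniform(0.0, config.extent[0], size=n_noise)
        ny = rng.uniform(0.0, config.extent[1], size=n_noise)
        nz = (terrain_elevation(config, nx, ny)
              + rng.uniform(dz_lo, dz_hi, size=n_noise))
        xs.append(nx)
        ys.append(ny)
        zs.append(nz)
        tree_ids.append(np.zeros(n_noise, dtype=np.int32))
        classes.append(np.full(n_noise, CLASS_NOISE, dtype=np.uint8))

    cloud = PointCloud(np.concatenate(xs), np.concatenate(ys), np.concatenate(zs))
    truth = TruthTable(
        trees=pd.DataFrame(tree_rows, columns=[
            "tree_id", "x", "y", "TH", "CBH", "CL", "LCR", "lcr_cov", "DBH",
            "volume",
        ]),
        point_tree_id=np.concatenate(tree_ids),
        point_class=np.concatenate(classes),
    )
    logger.info("generate_stand: %d trees, %d points", n_trees, len(cloud))
    return cloud, truth


def well_separated_config(n_trees: int = 50, spacing: float = 5.0,
                          seed: int = 0, **overrides) -> StandConfig:
    """A stand whose crowns cannot touch (spacing ≫ 2×LCR): convenient
    truth for end-to-end recovery checks."""
    nx = int(np.ceil(np.sqrt(n_trees)))
    ny = int(np.ceil(n_trees / nx))
    cfg = StandConfig(extent=(nx * spacing, ny * spacing), spacing=spacing,
                      jitter=0.4, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


def generate_profile_points(
    family,
    params,
    n_trees: int,
    bins_per_tree: int,
    lcr_range: tuple = (0.8, 2.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    percentile: int = 95,
) -> pd.DataFrame:
    """Direct profile-point samples from a known curve (for model tests).

    RDINC sits at bin midpoints; OR is the family curve plus Gaussian
    noise; each tree draws its LCR uniformly from ``lcr_range``.
    Returns the standard profile-point DataFrame (DINC is reported on a
    unit crown length, so DINC = RDINC).
    """
    rng = np.random.default_rng(seed)
    rdinc = (np.arange(bins_per_tree) + 0.5) / bins_per_tree
    frames = []
    for k in range(n_trees):
        lcr = float(rng.uniform(*lcr_range))
        truth = np.asarray(evaluate_profile(family, params, rdinc, lcr))
        noisy = truth + rng.normal(0.0, noise_sd, size=rdinc.size)
        frames.append(pd.DataFrame({
            "tree_id": k + 1, "percentile": percentile,
            "bin": np.arange(bins_per_tree), "DINC": rdinc, "RDINC": rdinc,
            "OR": noisy, "LCR": lcr,
        }))
    return pd.concat(frames, ignore_index=True)
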