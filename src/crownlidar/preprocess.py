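"""Point-cloud cleaning, height normalization and CHM rasterization.

UAV-LiDAR returns over a forest plot carry three kinds of noise: air
points (birds, multipath echoes high above the canopy), low points
(multipath below the terrain) and isolated points.  Isolated points are
removed by a neighbour-count rule (default search radius 5 m); air and
low points by robust height envelopes.  Ground is classified with a
grid-minimum seed + TIN surface (a deliberately simple terrain model:
the stands of interest are gentle slopes), heights are normalized by
subtracting the interpolated terrain, and the canopy height model (CHM)
is rasterized as the per-cell maximum normalized height with iterative
median filling of interior pits.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import cKDTree

from .cloud import CLASS_GROUND, CLASS_VEGETATION, PointCloud
from .raster import CHMRaster

logger = logging.getLogger(__name__)

DEFAULT_NOISE_RADIUS = 5.0  # m
DEFAULT_MIN_NEIGHBORS = 4
DEFAULT_GROUND_CELL = 2.0  # m
DEFAULT_GROUND_TOL = 0.3  # m, vertical tolerance of the TIN ground surface
DEFAULT_CHM_RESOLUTION = 0.25  # m


def remove_noise(
    cloud: PointCloud,
    radius: float = DEFAULT_NOISE_RADIUS,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
) -> PointCloud:
    """Drop isolated points with fewer than ``min_neighbors`` other points
    within ``radius`` (3-D Euclidean).  Order of survivors is preserved."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if min_neighbors < 1:
        raise ValueError("min_neighbors must be >= 1")
    if len(cloud) == 0:
        return cloud
    if len(cloud) <= min_neighbors:
        keep = np.zeros(len(cloud), dtype=bool)
    else:
        # a point has >= min_neighbors others within radius iff its
        # (min_neighbors+1)-th nearest neighbour (self included) is that close
        tree = cKDTree(cloud.xyz)
        dist, _ = tree.query(cloud.xyz, k=min_neighbors + 1)
        keep = dist[:, -1] <= radius
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("remove_noise: dropped %d isolated points", n_removed)
    return cloud.select(keep)


def remove_gross_outliers(
    cloud: PointCloud, air_margin: float = 10.0, low_margin: float = 1.0,
    cell_size: float = DEFAULT_GROUND_CELL,
) -> PointCloud:
    """Drop air and low points by a reproducible rule.

    Air points: z above the 99.9th height percentile plus ``air_margin``.
    Low points: z below the local (per ``cell_size`` grid cell) 1st
    height percentile minus ``low_margin`` — a proxy for "below ground"
    applied before any terrain model exists.  The 1st percentile tracks
    the lowest genuine returns (ground) even under a dense crown, where
    any higher quantile would sit inside the crown itself.
    """
    if len(cloud) == 0:
        return cloud
    air_cut = np.percentile(cloud.z, 99.9) + air_margin
    ix, iy, _, _ = _grid_index(cloud.x, cloud.y, cell_size)
    cell_key = ix.astype(np.int64) * (iy.max() + 1) + iy
    order = np.argsort(cell_key, kind="stable")
    low_ref = np.empty(len(cloud))
    for start, stop in _runs(cell_key[order]):
        sel = order[start:stop]
        low_ref[sel] = np.percentile(cloud.z[sel], 1.0)
    keep = (cloud.z <= air_cut) & (cloud.z >= low_ref - low_margin)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("remove_gross_outliers: dropped %d air/low points", n_removed)
    return cloud.select(keep)


def _runs(sorted_keys):
    """Yield (start, stop) index pairs of equal-value runs in a sorted array."""
    if sorted_keys.size == 0:
        return
    breaks = np.flatnonzero(np.diff(sorted_keys)) + 1
    edges = np.concatenate([[0], breaks, [sorted_keys.size]])
    for i in range(edges.size - 1):
        yield int(edges[i]), int(edges[i + 1])


def _grid_index(x, y, cell_size, origin=None):
    if origin is None:
        origin = (float(x.min()), float(y.min()))
    ix = np.floor((x - origin[0]) / cell_size).astype(int)
    iy = np.floor((y - origin[1]) / cell_size).astype(int)
    return ix, iy, origin[0], origin[1]


def classify_ground(
    cloud: PointCloud,
    cell_size: float = DEFAULT_GROUND_CELL,
    vertical_tol: float = DEFAULT_GROUND_TOL,
) -> PointCloud:
    """Label ground vs vegetation points.

    Per-cell minimum-z points seed a Delaunay TIN; every point within
    ``vertical_tol`` of the interpolated surface is classified ground,
    the rest vegetation.  Returns a new cloud with updated class labels.

    A cell that holds no ground return at all (e.g. fully occluded by a
    crown) would seed the TIN inside the canopy; such spike seeds are
    discarded when they sit more than 1 m above the median of their
    neighbouring seeds.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    n = len(cloud)
    if n < 3:
        raise ValueError("insufficient ground support")
    ix, iy, _, _ = _grid_index(cloud.x, cloud.y, cell_size)
    key = ix.astype(np.int64) * (iy.max() + 1) + iy
    order = np.lexsort((cloud.z, key))
    seed_idx = order[np.concatenate([[True], np.diff(key[order]) != 0])]
    seed_idx = _drop_spike_seeds(seed_idx, ix, iy, cloud.z)
    if seed_idx.size < 3:
        raise ValueError("insufficient ground support")
    surface = _tin_interpolator(
        cloud.x[seed_idx], cloud.y[seed_idx], cloud.z[seed_idx]
    )
    residual = cloud.z - surface(cloud.x, cloud.y)
    is_ground = np.abs(residual) <= vertical_tol
    classification = np.where(is_ground, CLASS_GROUND, CLASS_VEGETATION).astype(np.uint8)
    logger.info(
        "classify_ground: %d ground / %d vegetation points",
        int(is_ground.sum()), int((~is_ground).sum()),
    )
    return PointCloud(cloud.x, cloud.y, cloud.z, classification, cloud.tree_id)


def _drop_spike_seeds(seed_idx, ix, iy, z, spike_tol=1.0, max_iter=5):
    """Iteratively discard ground seeds far above their neighbours."""
    seeds = {(int(ix[i]), int(iy[i])): i for i in seed_idx}
    for _ in range(max_iter):
        bad = []
        for (cx, cy), i in seeds.items():
            neigh = [z[j] for (nx, ny), j in seeds.items()
                     if (nx, ny) != (cx, cy)
                     and abs(nx - cx) <= 1 and abs(ny - cy) <= 1]
            if len(neigh) >= 3 and z[i] > np.median(neigh) + spike_tol:
                bad.append((cx, cy))
        if not bad:
            break
        for cell in bad:
            del seeds[cell]
    return np.array(sorted(seeds.values()), dtype=int)


def _tin_interpolator(x, y, z):
    """Linear TIN interpolation with nearest-neighbour extrapolation
    outside the convex hull of the supports."""
    pts = np.column_stack([x, y])
    try:
        linear = LinearNDInterpolator(pts, z)
    except Exception as exc:  # degenerate (collinear) supports
        raise ValueError(f"insufficient ground support: {exc}") from exc
    nearest = NearestNDInterpolator(pts, z)

    def interp(qx, qy):
        qx = np.atleast_1d(np.asarray(qx, dtype=float))
        qy = np.atleast_1d(np.asarray(qy, dtype=float))
        vals = linear(qx, qy)
        outside = ~np.isfinite(vals)
        if outside.any():
            logger.debug("TIN: %d points outside hull, nearest-extrapolated",
                         int(outside.sum()))
            vals[outside] = nearest(qx[outside], qy[outside])
        return vals

    return interp


def normalize_heights(cloud: PointCloud, ground: PointCloud) -> PointCloud:
    """Replace z by height above the TIN through the ground points.

    Negative residuals are clipped to 0 (their count is logged); points
    outside the ground convex hull get nearest-triangle extrapolation.
    """
    if len(ground) == 0:
        raise ValueError("ground cloud is empty")
    surface = _tin_interpolator(ground.x, ground.y, ground.z)
    z_norm = cloud.z - surface(cloud.x, cloud.y)
    n_neg = int((z_norm < 0).sum())
    if n_neg:
        logger.info("normalize_heights: clipped %d negative heights to 0", n_neg)
    return cloud.with_z(np.maximum(z_norm, 0.0))


def rasterize_chm(
    cloud: PointCloud, resolution: float = DEFAULT_CHM_RESOLUTION
) -> CHMRaster:
    """Rasterize a pit-filled CHM: per-cell max z, with interior holes
    iteratively filled by the 3×3 median of non-empty neighbours."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if len(cloud) == 0:
        raise ValueError("cannot rasterize an empty cloud")
    origin = (float(cloud.x.min()), float(cloud.y.min()))
    col = np.floor((cloud.x - origin[0]) / resolution).astype(int)
    row = np.floor((cloud.y - origin[1]) / resolution).astype(int)
    nrows, ncols = row.max() + 1, col.max() + 1
    grid = np.full((nrows, ncols), -np.inf)
    np.maximum.at(grid, (row, col), cloud.z)
    occupied = np.isfinite(grid)
    grid[~occupied] = np.nan
    footprint = ndimage.binary_fill_holes(occupied)
    grid = _fill_pits(grid, footprint & ~occupied)
    grid[~footprint] = np.nan
    return CHMRaster(grid, resolution, origin)


def _fill_pits(grid, holes):
    """Fill hole cells by the median of their non-NaN 3×3 neighbours,
    iterating until no fillable interior hole remains."""
    grid = grid.copy()
    holes = holes.copy()
    while holes.any():
        filled_any = False
        rows, cols = np.nonzero(holes)
        new_vals = {}
        for r, c in zip(rows, cols):
            window = grid[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
            vals = window[np.isfinite(window)]
            if vals.size:
                new_vals[(r, c)] = float(np.median(vals))
        if not new_vals:
            break
        for (r, c), v in new_vals.items():
            grid[r, c] = v
            holes[r, c] = False
            filled_any = True
        if not filled_any:
            break
    return grid


def preprocess(
    cloud: PointCloud,
    noise_radius: float = DEFAULT_NOISE_RADIUS,
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS,
    ground_cell: float = DEFAULT_GROUND_CELL,
    ground_tol: float = DEFAULT_GROUND_TOL,
    resolution: float = DEFAULT_CHM_RESOLUTION,
):
    """Full preprocessing chain: outliers → noise → ground → normalize → CHM.

    Returns ``(normalized_cloud, chm)``; the normalized cloud keeps the
    ground/vegetation classification.
    """
    cloud = remove_gross_outliers(cloud, cell_size=ground_cell)
    cloud = remove_noise(cloud, noise_radius, min_neighbors)
    cloud = classify_ground(cloud, ground_cell, ground_tol)
    ground = cloud.select(cloud.classification == CLASS_GROUND)
    normalized = normalize_heights(cloud, ground)
    chm = rasterize_chm(normalized, resolution)
    return normalized, chm
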