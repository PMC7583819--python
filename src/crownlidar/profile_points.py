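"""Crown profile points: 2-D collapse, per-bin width percentiles, RDINC.

Each segmented crown is folded around the vertical axis through the tree
top: a point becomes (d, z) where d is its horizontal distance from the
axis.  The 2-D distribution is sliced into 0.5 m height bins from the
tree top down to the crown base; within each bin the 90th/95th/99th
percentile of d estimates the outer crown radius (OR) at that depth.
Depth into the crown (DINC, measured at the bin midpoint) is rescaled by
CL to the relative depth RDINC ∈ [0, 1], making profiles comparable
across trees.  The upper (light) crown is the portion above the depth of
the largest observed radius.

Profile points travel as a DataFrame with columns
``tree_id, percentile, bin, DINC, RDINC, OR, LCR`` — the interchange
format consumed by the model-fitting stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .cloud import PointCloud

logger = logging.getLogger(__name__)

DEFAULT_BIN = 0.5  # m
DEFAULT_PERCENTILES = (90, 95, 99)
MIN_POINTS_PER_BIN = 3

PROFILE_COLUMNS = ["tree_id", "percentile", "bin", "DINC", "RDINC", "OR", "LCR"]


def collapse_to_2d(crown_cloud: PointCloud, apex: tuple):
    """Map each crown point to (d, z): horizontal distance from the
    vertical axis through the apex, height unchanged."""
    if len(crown_cloud) == 0:
        raise ValueError("empty crown cloud")
    d = np.hypot(crown_cloud.x - apex[0], crown_cloud.y - apex[1])
    return d, crown_cloud.z.copy()


def bin_width_percentiles(
    d: np.ndarray,
    z: np.ndarray,
    TH: float,
    CBH: float,
    bin_width: float = DEFAULT_BIN,
    percentiles=DEFAULT_PERCENTILES,
    min_points: int = MIN_POINTS_PER_BIN,
) -> pd.DataFrame:
    """Per-bin width percentiles, bins running from the tree top down.

    Bin k covers [TH − (k+1)·bin, TH − k·bin); DINC is assigned at the
    bin midpoint.  Bins with fewer than ``min_points`` points emit no
    profile point.  Percentiles use linear interpolation between the
    closest ranks.
    """
    if TH <= CBH:
        raise ValueError("requires TH > CBH")
    d = np.asarray(d, dtype=float)
    z = np.asarray(z, dtype=float)
    n_bins = int(np.ceil((TH - CBH) / bin_width))
    rows = []
    for k in range(n_bins):
        lo, hi = TH - (k + 1) * bin_width, TH - k * bin_width
        dk = d[(z >= lo) & (z < hi)]
        if dk.size < min_points:
            continue
        dinc = TH - (lo + hi) / 2.0
        for p in percentiles:
            rows.append(
                {"percentile": int(p), "bin": k, "DINC": dinc,
                 "OR": float(np.percentile(dk, p))}
            )
    return pd.DataFrame(rows, columns=["percentile", "bin", "DINC", "OR"])


def rescale_rdinc(points: pd.DataFrame, CL: float) -> pd.DataFrame:
    """Add RDINC = DINC/CL, clipped to [0, 1]."""
    if CL <= 0:
        raise ValueError("CL must be positive")
    out = points.copy()
    out["RDINC"] = np.clip(out["DINC"] / CL, 0.0, 1.0)
    return out


def split_upper_crown(points: pd.DataFrame) -> pd.DataFrame:
    """Keep only points above (and including) the depth of the largest OR.

    Applied per tree and percentile; ties in the maximum OR resolve to
    the smallest RDINC.
    """
    if points.empty:
        return points.copy()
    group_cols = [c for c in ("tree_id", "percentile") if c in points.columns]

    def _upper(g: pd.DataFrame) -> pd.DataFrame:
        g = g.sort_values("RDINC", kind="stable")
        cut = g["RDINC"].iloc[int(np.argmax(g["OR"].to_numpy()))]
        return g[g["RDINC"] <= cut]

    if group_cols:
        parts = [_upper(g) for _, g in points.groupby(group_cols, sort=False)]
        return pd.concat(parts, ignore_index=True)
    return _upper(points).reset_index(drop=True)


def build_profile_points(
    labeled_cloud: PointCloud,
    metrics: pd.DataFrame,
    bin_width: float = DEFAULT_BIN,
    percentiles=DEFAULT_PERCENTILES,
    min_points: int = MIN_POINTS_PER_BIN,
) -> pd.DataFrame:
    """Profile points for every tree in the metrics table.

    Crown points (z ≥ CBH) are collapsed about the apex axis, binned and
    rescaled; each emitted point carries its tree's LCR for the
    reparameterized profile models.
    """
    frames = []
    for row in metrics.itertuples(index=False):
        tree = labeled_cloud.select(labeled_cloud.tree_id == row.tree_id)
        crown = tree.select(tree.z >= row.CBH)
        if len(crown) == 0:
            logger.info("tree %d has no crown points, skipped", row.tree_id)
            continue
        d, z = collapse_to_2d(crown, (row.apex_x, row.apex_y))
        pts = bin_width_percentiles(d, z, row.TH, row.CBH, bin_width,
                                    percentiles, min_points)
        if pts.empty:
            continue
        pts = rescale_rdinc(pts, row.CL)
        pts.insert(0, "tree_id", row.tree_id)
        pts["LCR"] = row.LCR
        frames.append(pts)
    if not frames:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[PROFILE_COLUMNS]
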