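"""Per-tree crown metrics from segmented, height-normalized point clouds.

TH is the height of the highest return; the crown base height (CBH) is
found from the vertical point-count profile: tree points are binned in
0.5 m layers from the ground up, the per-layer percentage of all tree
points (Np) is smoothed with a 3-tap Gaussian kernel, and the CBH is the
lower edge of the first layer (scanning upward) whose smoothed share
reaches p% (default 1%) — the height where the point count changes
abruptly from sparse stem returns to the dense crown.  CL = TH − CBH.
The largest crown radius (LCR) is the mean horizontal distance from the
vertices of the 2-D convex hull of the crown projection to the apex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .cloud import PointCloud

logger = logging.getLogger(__name__)

DEFAULT_BIN = 0.5  # m
DEFAULT_P = 1.0  # percent of tree points marking the crown base
# 3-tap Gaussian at sigma = 0.5 bins (the conventional 3x1 kernel); wider
# kernels leak enough of the crown-base bin into the empty bin below to
# trip the p% threshold one bin early, biasing CBH half a bin low
DEFAULT_SIGMA_BINS = 0.5
MIN_POINTS_FOR_CBH = 10


@dataclass
class TreeMetrics:
    """Crown variables of one tree (all heights above ground, in metres)."""

    tree_id: int
    TH: float
    CBH: float
    CL: float
    LCR: float
    apex_x: float
    apex_y: float

    def __post_init__(self) -> None:
        if not 0 <= self.CBH < self.TH:
            raise ValueError("requires 0 <= CBH < TH")
        if abs(self.CL - (self.TH - self.CBH)) > 1e-9:
            raise ValueError("CL must equal TH - CBH")


def height_histogram(z: np.ndarray, bin_width: float = DEFAULT_BIN,
                     sigma_bins: float = DEFAULT_SIGMA_BINS):
    """Vertical point-count profile: bin edges anchored at z = 0,
    percentage vector Np and its Gaussian-smoothed version.

    Returns ``(edges, counts, np_raw, np_smooth)``.
    """
    z = np.asarray(z, dtype=float)
    n_bins = int(np.floor(z.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(z, bins=edges)
    np_raw = 100.0 * counts / z.size
    # 3-tap Gaussian, renormalized at the edges so border bins are not damped
    kernel = np.exp(-0.5 * (np.array([-1.0, 0.0, 1.0]) / sigma_bins) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(np_raw, kernel, mode="same")
    norm = np.convolve(np.ones_like(np_raw), kernel, mode="same")
    return edges, counts, np_raw, smooth / norm


def compute_cbh(
    tree_cloud: PointCloud,
    bin_width: float = DEFAULT_BIN,
    p: float = DEFAULT_P,
    sigma_bins: float = DEFAULT_SIGMA_BINS,
) -> float:
    """Crown base height: lower edge of the first bin (from the ground up)
    whose smoothed point share reaches ``p`` percent."""
    if len(tree_cloud) < MIN_POINTS_FOR_CBH:
        raise ValueError("insufficient points for CBH")
    edges, counts, _, smooth = height_histogram(tree_cloud.z, bin_width,
                                                sigma_bins)
    th_bin = int(np.floor(tree_cloud.z.max() / bin_width))
    for i in range(th_bin + 1):
        # an empty bin cannot hold the crown base even when smoothing
        # leaks its neighbours' mass across the boundary
        if counts[i] > 0 and smooth[i] >= p:
            return float(edges[i])
    logger.warning("compute_cbh: no bin reaches %.2f%%; falling back to the "
                   "global-maximum bin", p)
    return float(edges[int(np.argmax(smooth))])


def compute_tree_metrics(tree_cloud: PointCloud, cbh: float,
                         tree_id: int = 0) -> TreeMetrics:
    """TH, CL and LCR of one tree given its crown base height."""
    if len(tree_cloud) == 0:
        raise ValueError("empty tree cloud")
    top = int(np.argmax(tree_cloud.z))
    th = float(tree_cloud.z[top])
    if not 0 <= cbh < th:
        raise ValueError("requires 0 <= cbh < max z")
    apex = (float(tree_cloud.x[top]), float(tree_cloud.y[top]))
    crown = tree_cloud.select(tree_cloud.z >= cbh)
    lcr = largest_crown_radius(crown.x, crown.y, apex)
    return TreeMetrics(
        tree_id=tree_id, TH=th, CBH=float(cbh), CL=th - float(cbh),
        LCR=lcr, apex_x=apex[0], apex_y=apex[1],
    )


def largest_crown_radius(x: np.ndarray, y: np.ndarray, apex: tuple) -> float:
    """Mean horizontal distance from 2-D convex-hull vertices to the apex."""
    pts = np.column_stack([x, y])
    try:
        hull = ConvexHull(pts)
    except (QhullError, ValueError) as exc:
        raise ValueError(f"degenerate hull: {exc}") from exc
    vertices = pts[hull.vertices]
    d = np.hypot(vertices[:, 0] - apex[0], vertices[:, 1] - apex[1])
    return float(d.mean())


def metrics_table(labeled_cloud: PointCloud, bin_width: float = DEFAULT_BIN,
                  p: float = DEFAULT_P, sigma_bins: float = DEFAULT_SIGMA_BINS):
    """Compute TreeMetrics for every labelled tree in a cloud.

    Trees whose clouds are too sparse or degenerate are skipped with a
    log message.  Returns a DataFrame with one row per tree.
    """
    import pandas as pd

    rows = []
    for tid in np.unique(labeled_cloud.tree_id):
        if tid == 0:
            continue
        tree = labeled_cloud.select(labeled_cloud.tree_id == tid)
        try:
            cbh = compute_cbh(tree, bin_width, p, sigma_bins)
            m = compute_tree_metrics(tree, cbh, tree_id=int(tid))
        except ValueError as exc:
            logger.info("tree %d skipped: %s", tid, exc)
            continue
        rows.append(vars(m))
    return pd.DataFrame(
        rows, columns=["tree_id", "TH", "CBH", "CL", "LCR", "apex_x", "apex_y"]
    )
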