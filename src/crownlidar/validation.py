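"""Detected-vs-reference tree matching and agreement statistics.

A detected tree matches a reference tree 1:1 when it lies within 60% of
the average tree distance of the plot and within 15% of the tallest
reference height; conflicts resolve to the closest candidate, each tree
used at most once.  Detection accuracy (DA) is the share of reference
trees with a 1:1 match.  Paired value lists are compared by Pearson
correlation, RMSE, Bias and their relative forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchConfig:
    distance_fraction: float = 0.60  # of the average tree distance
    height_fraction: float = 0.15  # of the tallest reference tree
    spacing_rule: str = "sqrt_area"  # or "mean_nn": mean nearest-neighbour

    def __post_init__(self) -> None:
        if not (0 < self.distance_fraction < 1 and 0 < self.height_fraction < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.spacing_rule not in ("sqrt_area", "mean_nn"):
            raise ValueError("spacing_rule must be 'sqrt_area' or 'mean_nn'")


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # columns: detected_id, reference_id, distance
    detection_accuracy: float  # percent
    n_detected: int
    n_reference: int


def average_tree_distance(reference: pd.DataFrame, plot_area: float,
                          rule: str = "sqrt_area") -> float:
    """Plot-level average spacing: √(area/n) by default, or the mean
    nearest-neighbour distance between reference trees."""
    if rule == "sqrt_area":
        return float(np.sqrt(plot_area / len(reference)))
    xy = reference[["x", "y"]].to_numpy(dtype=float)
    from scipy.spatial import cKDTree

    d, _ = cKDTree(xy).query(xy, k=2)
    return float(d[:, 1].mean())


def match_trees(
    detected: pd.DataFrame,
    reference: pd.DataFrame,
    plot_area: float,
    config: MatchConfig = MatchConfig(),
) -> MatchResult:
    """Greedy closest-first 1:1 matching under distance and height gates.

    ``detected`` needs columns x, y, TH (``tree_id`` optional);
    ``reference`` the same.  Candidate pairs require horizontal distance
    below ``distance_fraction ×`` the average tree distance and height
    difference below ``height_fraction × max reference TH``.
    """
    if len(detected) == 0 or len(reference) == 0:
        raise ValueError("detected and reference tables must be nonempty")
    if plot_area <= 0:
        raise ValueError("plot_area must be positive")
    spacing = average_tree_distance(reference, plot_area, config.spacing_rule)
    max_dist = config.distance_fraction * spacing
    max_dh = config.height_fraction * float(reference["TH"].max())

    det_xy = detected[["x", "y"]].to_numpy(dtype=float)
    ref_xy = reference[["x", "y"]].to_numpy(dtype=float)
    det_th = detected["TH"].to_numpy(dtype=float)
    ref_th = reference["TH"].to_numpy(dtype=float)
    det_ids = (detected["tree_id"] if "tree_id" in detected
               else pd.Series(range(len(detected)))).to_numpy()
    ref_ids = (reference["tree_id"] if "tree_id" in reference
               else pd.Series(range(len(reference)))).to_numpy()

    dist = np.hypot(det_xy[:, None, 0] - ref_xy[None, :, 0],
                    det_xy[:, None, 1] - ref_xy[None, :, 1])
    dh = np.abs(det_th[:, None] - ref_th[None, :])
    candidate = (dist < max_dist) & (dh < max_dh)
    di, ri = np.nonzero(candidate)
    order = np.argsort(dist[di, ri], kind="stable")
    used_det, used_ref, rows = set(), set(), []
    for k in order:
        d_i, r_i = int(di[k]), int(ri[k])
        if d_i in used_det or r_i in used_ref:
            continue
        used_det.add(d_i)
        used_ref.add(r_i)
        rows.append({"detected_id": det_ids[d_i], "reference_id": ref_ids[r_i],
                     "distance": float(dist[d_i, r_i])})
    pairs = pd.DataFrame(rows, columns=["detected_id", "reference_id", "distance"])
    da = 100.0 * len(pairs) / len(reference)
    logger.info("match_trees: %d/%d reference trees matched (DA %.1f%%)",
                len(pairs), len(reference), da)
    return MatchResult(pairs, da, len(detected), len(reference))


@dataclass
class ComparisonStats:
    """Agreement between estimated (y_L) and reference (y_G) values."""

    rho: float | None  # Pearson correlation; None when either list is constant
    rmse: float
    rmse_pct: float
    bias: float
    bias_pct: float
    n: int

    def to_dict(self) -> dict:
        return {"rho": self.rho, "RMSE": self.rmse, "RMSE%": self.rmse_pct,
                "Bias": self.bias, "Bias%": self.bias_pct, "n": self.n}


def comparison_stats(y_l, y_g) -> ComparisonStats:
    """RMSE = √(Σ(y_L−y_G)²/n), Bias = Σ(y_L−y_G)/n, relative forms in
    percent of mean(y_G), and the Pearson correlation."""
    y_l = np.asarray(y_l, dtype=float)
    y_g = np.asarray(y_g, dtype=float)
    if y_l.size != y_g.size or y_l.size < 2:
        raise ValueError("need two equal-length lists of at least 2 values")
    diff = y_l - y_g
    rmse = float(np.sqrt(np.mean(diff**2)))
    bias = float(np.mean(diff))
    mean_ref = float(np.mean(y_g))
    if mean_ref == 0:
        raise ValueError("mean of reference values is zero; relative "
                         "measures undefined")
    if np.std(y_l) == 0 or np.std(y_g) == 0:
        logger.warning("comparison_stats: zero variance, correlation undefined")
        rho = None
    else:
        rho = float(stats.pearsonr(y_l, y_g)[0])
    return ComparisonStats(
        rho=rho, rmse=rmse, rmse_pct=100.0 * rmse / mean_ref,
        bias=bias, bias_pct=100.0 * bias / mean_ref, n=int(y_l.size),
    )
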