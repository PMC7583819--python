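"""Individual-tree crown delineation by region-based hierarchical
cross-section analysis (RHCSA) on the CHM.

The CHM is treated as a mountain-like surface and sliced by equidistant
horizontal planes from the canopy top down.  Each cut yields connected
cross-section regions, which are tracked level to level:

* a region containing no previous-level region spawns a new *marker*
  (a candidate tree top at the region's maximum cell);
* a region that absorbs two or more tracked regions is a merge event.
  If the merged cross-section is near-circular it is taken to be a
  single crown whose extra markers are branch artifacts — only the
  marker with the greatest apex height survives.  Otherwise the region
  is split by marker-controlled watershed on the inverted CHM.

The circularity test fires only at the merge event itself.  At a 0.1 m
level step, two distinct crowns meet while their cross-sections barely
touch (compactness of two equal tangent disks is exactly 1/2, hence the
0.5 default threshold), whereas a branch bump joins its parent section
as a pimple on a disk and scores well above 1/2.  Re-testing the same
union as it grows would misclassify overlapping neighbours as one crown,
so once watershed has separated a group of markers they stay separated.

After the final cut, each label region is refined by a binary opening
(disk radius 1 cell) and tiny regions are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, segmentation as sk_seg

from .cloud import PointCloud
from .raster import CHMRaster

logger = logging.getLogger(__name__)

DEFAULT_LEVEL_STEP = 0.1  # m
DEFAULT_MIN_TREE_HEIGHT = 2.0  # m
DEFAULT_CIRCULARITY = 0.5
DEFAULT_MIN_REGION_CELLS = 5


@dataclass
class Marker:
    """A candidate tree top: the cell where a cross-section first emerged."""

    level: int  # index of the cut at which the marker appeared
    cell: tuple  # (row, col) of the region's maximum CHM cell
    height: float  # CHM value at that cell (apex height, m)


@dataclass
class SegmentMap:
    """Crown label raster (0 = background) plus one marker per label."""

    labels: np.ndarray  # int32, same grid as the CHM
    markers: dict  # label -> Marker
    resolution: float
    origin: tuple

    @property
    def n_trees(self) -> int:
        return len(self.markers)

    def tree_table(self):
        """Per-tree table: tree_id, apex x/y (cell centre) and apex height."""
        import pandas as pd

        rows = []
        for label, m in sorted(self.markers.items()):
            x = self.origin[0] + (m.cell[1] + 0.5) * self.resolution
            y = self.origin[1] + (m.cell[0] + 0.5) * self.resolution
            rows.append(
                {"tree_id": label, "apex_x": x, "apex_y": y, "apex_height": m.height}
            )
        return pd.DataFrame(rows, columns=["tree_id", "apex_x", "apex_y", "apex_height"])


def region_circularity(region_mask: np.ndarray) -> float:
    """Compactness 4πA/P² of a connected raster region.

    The perimeter is the length of the marching-squares boundary after
    two corner-cutting (Chaikin) passes, which removes the staircase
    bias of the raster boundary: a rasterized disk scores close to the
    analytic limit 1, a square ≈ π/4, and thin elongated regions score
    far lower.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    area = int(region_mask.sum())
    if area == 0:
        raise ValueError("empty region")
    padded = np.pad(region_mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("region has no boundary")
    perimeter = 0.0
    for contour in contours:
        poly = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
        if len(poly) < 3:
            continue
        poly = _chaikin(poly, iterations=2)
        closed = np.vstack([poly, poly[:1]])
        seg = np.diff(closed, axis=0)
        perimeter += float(np.hypot(seg[:, 0], seg[:, 1]).sum())
    if perimeter == 0.0:
        return 1.0  # single isolated cell
    return 4.0 * np.pi * area / perimeter**2


def _chaikin(poly: np.ndarray, iterations: int = 2) -> np.ndarray:
    """Chaikin corner cutting on a closed polygon (vertex array, no repeat)."""
    for _ in range(iterations):
        nxt = np.roll(poly, -1, axis=0)
        out = np.empty((2 * len(poly), 2))
        out[0::2] = 0.75 * poly + 0.25 * nxt
        out[1::2] = 0.25 * poly + 0.75 * nxt
        poly = out
    return poly


def rhcsa_segment(
    chm: CHMRaster,
    level_step: float = DEFAULT_LEVEL_STEP,
    min_tree_height: float = DEFAULT_MIN_TREE_HEIGHT,
    circularity_threshold: float = DEFAULT_CIRCULARITY,
    min_region_cells: int = DEFAULT_MIN_REGION_CELLS,
) -> SegmentMap:
    """Delineate crowns on the CHM; see the module docstring for the rules."""
    if level_step <= 0:
        raise ValueError("level_step must be positive")
    if min_tree_height < 0:
        raise ValueError("min_tree_height must be non-negative")
    values = chm.values
    if not np.isfinite(values).any():
        raise ValueError("CHM has no valid cells")
    top = chm.max()
    empty = SegmentMap(
        np.zeros(values.shape, dtype=np.int32), {}, chm.resolution, chm.origin
    )
    if top < min_tree_height:
        return empty

    heights = np.nan_to_num(values, nan=-np.inf)
    cuts = np.arange(top, min_tree_height, -level_step)
    if cuts.size == 0 or cuts[-1] > min_tree_height:
        cuts = np.append(cuts, min_tree_height)

    labels = np.zeros(values.shape, dtype=np.int32)
    markers: dict = {}
    prev_group: dict = {}  # label -> id of the connected region it sat in
    next_label = 1
    eight = np.ones((3, 3), dtype=int)

    for level_idx, cut in enumerate(cuts):
        mask = heights >= cut
        comp, n_comp = ndimage.label(mask, structure=eight)
        if n_comp == 0:
            continue
        slices = ndimage.find_objects(comp)
        new_labels = np.zeros_like(labels)
        group_of: dict = {}
        for region_id in range(1, n_comp + 1):
            sl = slices[region_id - 1]
            region = comp[sl] == region_id
            inside = np.unique(labels[sl][region])
            inside = inside[inside > 0]
            if inside.size == 0:
                local = np.where(region, heights[sl], -np.inf)
                r, c = np.unravel_index(np.argmax(local), local.shape)
                cell = (r + sl[0].start, c + sl[1].start)
                markers[next_label] = Marker(level_idx, cell, float(heights[cell]))
                new_labels[sl][region] = next_label
                group_of[next_label] = region_id
                next_label += 1
                continue
            if inside.size == 1:
                new_labels[sl][region] = inside[0]
                group_of[int(inside[0])] = region_id
                continue
            # Several tracked crowns share this cross-section.  Only a
            # *merge event* — labels that sat in distinct regions at the
            # previous cut — triggers the circularity test; a region that
            # merely grew keeps its watershed partition.
            n_prev_groups = len({prev_group.get(int(lab)) for lab in inside})
            is_merge = n_prev_groups >= 2
            if is_merge and region_circularity(region) >= circularity_threshold:
                # circular cross-section: extra markers are branch artifacts
                survivor = _best_marker(markers, inside)
                for lab in inside:
                    if lab != survivor:
                        del markers[int(lab)]
                new_labels[sl][region] = survivor
                group_of[survivor] = region_id
            else:
                seeds = np.zeros(region.shape, dtype=np.int32)
                for lab in inside:
                    cell = markers[int(lab)].cell
                    seeds[cell[0] - sl[0].start, cell[1] - sl[1].start] = lab
                ws = sk_seg.watershed(
                    -heights[sl], markers=seeds, mask=region, connectivity=2
                )
                new_labels[sl][region] = ws[region]
                for lab in inside:
                    group_of[int(lab)] = region_id
        labels = new_labels
        prev_group = group_of

    return _refine(labels, markers, chm, min_region_cells)


def _best_marker(markers: dict, candidates: np.ndarray) -> int:
    """Surviving marker among merged ones: greatest apex height, ties broken
    by earlier level then row-major cell order."""
    def key(lab):
        m = markers[lab]
        return (-m.height, m.level, m.cell[0], m.cell[1])

    return int(min(candidates, key=key))


def _refine(labels, markers, chm, min_region_cells) -> SegmentMap:
    """Binary opening per label, keep the component holding the marker
    (else the largest), drop regions below the minimum cell count."""
    selem = morphology.disk(1)
    out = np.zeros_like(labels)
    kept: dict = {}
    for label, marker in sorted(markers.items()):
        mask = labels == label
        if not mask.any():
            continue
        opened = ndimage.binary_opening(mask, structure=selem)
        if not opened.any():
            opened = mask  # opening annihilated a tiny crown; keep the raw region
        comp, n_comp = ndimage.label(opened, structure=np.ones((3, 3), dtype=int))
        if n_comp > 1:
            marker_comp = comp[marker.cell]
            if marker_comp == 0:
                sizes = np.bincount(comp.ravel())[1:]
                marker_comp = int(np.argmax(sizes)) + 1
            opened = comp == marker_comp
        if int(opened.sum()) < min_region_cells:
            logger.debug("dropping label %d: region below %d cells", label,
                         min_region_cells)
            continue
        out[opened] = label
        kept[label] = marker
    out, kept = _relabel(out, kept)
    logger.info("rhcsa_segment: %d crowns delineated", len(kept))
    return SegmentMap(out, kept, chm.resolution, chm.origin)


def _relabel(labels, markers):
    mapping = {old: new for new, old in enumerate(sorted(markers), start=1)}
    out = np.zeros_like(labels)
    for old, new in mapping.items():
        out[labels == old] = new
    return out, {mapping[old]: m for old, m in markers.items()}


def extract_crown_points(cloud: PointCloud, segments: SegmentMap) -> PointCloud:
    """Assign each point the label of the CHM cell below it (all heights).

    Points over background or outside the raster keep tree_id = 0.
    """
    col = np.floor((cloud.x - segments.origin[0]) / segments.resolution).astype(int)
    row = np.floor((cloud.y - segments.origin[1]) / segments.resolution).astype(int)
    nrows, ncols = segments.labels.shape
    inside = (row >= 0) & (row < nrows) & (col >= 0) & (col < ncols)
    tree_id = np.zeros(len(cloud), dtype=np.int32)
    tree_id[inside] = segments.labels[row[inside], col[inside]]
    return PointCloud(cloud.x, cloud.y, cloud.z, cloud.classification, tree_id)
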