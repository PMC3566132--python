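"""Nucleus detection and per-cell territory estimation.

The nuclear channel drives everything: nuclei are found by robust
thresholding (median + k·sigma_MAD, where sigma_MAD = 1.4826·MAD is the
MAD-based sigma estimate), hole-filled, size-filtered and optionally split
by a distance-transform watershed; each remaining pixel of the field is
then assigned to the nearest nucleus (Euclidean by default, geodesic within
a cytoplasm mask when one is supplied), clipped at a maximum radius from
the nucleus boundary.  Ties in the nearest-nucleus assignment go to the
lower label, which makes the partition deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as sklabel
from skimage.segmentation import relabel_sequential, watershed

from .config import AcquisitionConfig

logger = logging.getLogger(__name__)


def filter_small_regions(labels: np.ndarray, min_px: int) -> np.ndarray:
    """Zero out labeled regions with fewer than ``min_px`` pixels."""
    if min_px <= 1 or labels.max(initial=0) == 0:
        return labels
    counts = np.bincount(labels.ravel())
    small = counts < min_px
    small[0] = False
    out = labels.copy()
    out[small[labels]] = 0
    return out


def robust_threshold(grid: np.ndarray, k_sigma: float) -> float:
    """median + k_sigma * 1.4826 * MAD of the whole grid."""
    if k_sigma <= 0:
        raise ValueError(f"k_sigma must be > 0, got {k_sigma}")
    med = float(np.median(grid))
    mad = float(np.median(np.abs(grid.astype(np.float64) - med)))
    return med + k_sigma * 1.4826 * mad


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of nucleus detection and territory assignment."""

    k_sigma: float = 4.0
    min_nucleus_area_um2: float = 30.0
    split_touching: bool = True
    #: minimum distance (µm) between watershed seed peaks when splitting
    split_min_distance_um: float = 5.0
    max_radius_um: float | None = 40.0

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be > 0")
        if self.min_nucleus_area_um2 < 0:
            raise ValueError("min_nucleus_area_um2 must be >= 0")
        if self.max_radius_um is not None and self.max_radius_um <= 0:
            raise ValueError("max_radius_um must be > 0 or None")


@dataclass
class CellLabelMap:
    """Nucleus and cell-territory label grids with matched labels.

    Label i in ``cell_labels`` is the territory of nucleus i in
    ``nuclei_labels``; 0 is background/unassigned; labels are consecutive
    from 1.
    """

    nuclei_labels: np.ndarray
    cell_labels: np.ndarray

    @property
    def n_cells(self) -> int:
        return int(self.nuclei_labels.max(initial=0))

    def edge_labels(self) -> set[int]:
        """Labels whose nucleus touches the field border (partial cells)."""
        border = np.concatenate([
            self.nuclei_labels[0, :], self.nuclei_labels[-1, :],
            self.nuclei_labels[:, 0], self.nuclei_labels[:, -1],
        ])
        return set(np.unique(border[border > 0]).tolist())


def segment_nuclei(nuclear_grid: np.ndarray, acq: AcquisitionConfig,
                   params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Label nuclei in the nuclear (DAPI) channel.

    An all-constant image yields zero nuclei (an empty label grid, not an
    error).  Deterministic.
    """
    grid = np.asarray(nuclear_grid, dtype=np.float64)
    if grid.size == 0:
        raise ValueError("empty nuclear grid")
    thr = robust_threshold(grid, params.k_sigma)
    fg = grid > thr
    if not fg.any():
        return np.zeros(grid.shape, dtype=np.int32)
    fg = ndi.binary_fill_holes(fg)
    min_px = int(round(params.min_nucleus_area_um2 / acq.pixel_area_um2))
    labels = filter_small_regions(sklabel(fg, connectivity=2), min_px)
    fg = labels > 0
    if params.split_touching and labels.max() > 0:
        dist = ndi.distance_transform_edt(fg)
        min_dist_px = max(int(round(params.split_min_distance_um / acq.pixel_pitch_um)), 1)
        peaks = peak_local_max(dist, min_distance=min_dist_px, labels=labels,
                               exclude_border=False)
        if len(peaks):
            markers = np.zeros(grid.shape, dtype=np.int32)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            labels = filter_small_regions(watershed(-dist, markers=markers, mask=fg),
                                          min_px)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def _nearest_nucleus_euclidean(nuclei_labels: np.ndarray,
                               max_radius_px: float | None) -> np.ndarray:
    """Per-pixel nearest-nucleus assignment, lower label winning exact ties.

    Computed as an argmin over per-label distance transforms; with a radius
    clip each label's transform only needs its padded bounding box.
    """
    shape = nuclei_labels.shape
    n = int(nuclei_labels.max(initial=0))
    out = np.zeros(shape, dtype=np.int32)
    if n == 0:
        return out
    init = np.inf if max_radius_px is None else float(max_radius_px)
    best = np.full(shape, init, dtype=np.float64)
    objects = ndi.find_objects(nuclei_labels)
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        if sl is None:
            continue
        if max_radius_px is None:
            sub = (slice(0, shape[0]), slice(0, shape[1]))
        else:
            pad = int(np.ceil(max_radius_px)) + 1
            sub = (slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, shape[0])),
                   slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, shape[1])))
        dist = ndi.distance_transform_edt(nuclei_labels[sub] != lab)
        better = dist < best[sub]  # strict: earlier (lower) label keeps ties
        best[sub][better] = dist[better]
        out[sub][better] = lab
    return out


def _nearest_nucleus_geodesic(nuclei_labels: np.ndarray, cytoplasm_mask: np.ndarray,
                              max_radius_px: float | None) -> np.ndarray:
    """Geodesic nearest-nucleus assignment within a cytoplasm mask."""
    from skimage.graph import MCP_Geometric

    shape = nuclei_labels.shape
    n = int(nuclei_labels.max(initial=0))
    out = np.zeros(shape, dtype=np.int32)
    if n == 0:
        return out
    costs = np.where(cytoplasm_mask | (nuclei_labels > 0), 1.0, np.inf)
    init = np.inf if max_radius_px is None else float(max_radius_px)
    best = np.full(shape, init, dtype=np.float64)
    for lab in range(1, n + 1):
        starts = np.argwhere(nuclei_labels == lab)
        if len(starts) == 0:
            continue
        mcp = MCP_Geometric(costs)
        cum, _ = mcp.find_costs(starts.tolist())
        better = cum < best
        best[better] = cum[better]
        out[better] = lab
    return out


def estimate_cell_boundaries(nuclei_labels: np.ndarray, acq: AcquisitionConfig,
                             cytoplasm_grid: np.ndarray | None = None,
                             params: SegmentationParams = SegmentationParams(),
                             use_cytoplasm_mask: bool = False) -> CellLabelMap:
    """Partition the field into per-cell territories seeded at nuclei.

    Every pixel within ``max_radius_um`` of a nucleus boundary is assigned
    to its nearest nucleus (geodesic within the thresholded cytoplasm grid
    when ``use_cytoplasm_mask``); the regions are pairwise disjoint, contain
    their nucleus, and ties go to the lower label.
    """
    nuclei_labels = np.asarray(nuclei_labels)
    if nuclei_labels.max(initial=0) == 0:
        logger.warning("no nuclei: returning an all-zero cell label map")
        return CellLabelMap(nuclei_labels=nuclei_labels.astype(np.int32),
                            cell_labels=np.zeros_like(nuclei_labels, dtype=np.int32))
    max_radius_px = (None if params.max_radius_um is None
                     else params.max_radius_um / acq.pixel_pitch_um)
    if use_cytoplasm_mask:
        if cytoplasm_grid is None:
            raise ValueError("use_cytoplasm_mask=True requires a cytoplasm grid")
        cyto = np.asarray(cytoplasm_grid, dtype=np.float64)
        mask = cyto > robust_threshold(cyto, params.k_sigma)
        cells = _nearest_nucleus_geodesic(nuclei_labels, mask, max_radius_px)
    else:
        cells = _nearest_nucleus_euclidean(nuclei_labels, max_radius_px)
    return CellLabelMap(nuclei_labels=nuclei_labels.astype(np.int32), cell_labels=cells)


def match_cells_to_truth(cell_map: CellLabelMap, truth_centers: np.ndarray,
                         max_dist_px: float = 10.0) -> dict[int, int]:
    """1:1 match detected nuclei to simulated cells by centroid proximity.

    Returns {detected label -> truth row index}; greedy nearest-pair
    matching, used by recovery tests and ground-truth comparisons.
    """
    coms = ndi.center_of_mass(cell_map.nuclei_labels > 0, cell_map.nuclei_labels,
                              index=range(1, cell_map.n_cells + 1))
    if cell_map.n_cells == 0 or len(truth_centers) == 0:
        return {}
    coms = np.array(coms, dtype=np.float64)
    d = np.linalg.norm(coms[:, None, :] - truth_centers[None, :, :], axis=2)
    pairs = []
    for i in range(d.shape[0]):
        for j in range(d.shape[1]):
            if d[i, j] <= max_dist_px:
                pairs.append((d[i, j], i + 1, j))
    pairs.sort()
    matched: dict[int, int] = {}
    used_truth: set[int] = set()
    for _dist, lab, j in pairs:
        if lab in matched or j in used_truth:
            continue
        matched[lab] = j
        used_truth.add(j)
    return matched
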