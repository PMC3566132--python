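"""Protein and lipid binary masks.

A pixel is "positive" when it exceeds the per-field robust background
threshold (field median + k_sigma · sigma_MAD); objects smaller than
``min_object_px`` are discarded as shot noise, and the mask is restricted
to pixels assigned to some cell territory.  The threshold adapts to the
background, not to the signal amplitude, so rescaling the label intensity
leaves the mask (and hence Area Pm) essentially unchanged.  Thresholding is
global per field, then intersected with the cell territories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as sklabel

from .segmentation import CellLabelMap, filter_small_regions, robust_threshold


@dataclass(frozen=True)
class MaskParams:
    k_sigma: float = 4.0
    min_object_px: int = 4
    #: divide by a smoothed illumination profile before thresholding
    flatfield_correct: bool = False

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValueError(f"k_sigma must be > 0, got {self.k_sigma}")
        if self.min_object_px < 0:
            raise ValueError("min_object_px must be >= 0")


def _positive_mask(grid: np.ndarray, cell_labels: np.ndarray,
                   params: MaskParams) -> np.ndarray:
    grid = np.asarray(grid, dtype=np.float64)
    if grid.shape != cell_labels.shape:
        raise ValueError("intensity grid and cell labels must share shape")
    if params.flatfield_correct:
        from scipy import ndimage as ndi

        profile = ndi.gaussian_filter(grid, sigma=min(grid.shape) / 8)
        grid = grid / np.maximum(profile / profile.mean(), 1e-9)
    mask = grid > robust_threshold(grid, params.k_sigma)
    if params.min_object_px > 1:
        mask = filter_small_regions(sklabel(mask, connectivity=2),
                                    params.min_object_px) > 0
    return mask & (cell_labels > 0)


def make_protein_mask(protein_grid: np.ndarray, cell_map: CellLabelMap,
                      params: MaskParams = MaskParams()) -> np.ndarray:
    """Boolean mask of protein-positive pixels within assigned cell territories."""
    return _positive_mask(protein_grid, cell_map.cell_labels, params)


def make_lipid_mask(lipid_grid: np.ndarray, cell_map: CellLabelMap,
                    params: MaskParams = MaskParams()) -> np.ndarray:
    """Boolean mask of lipid-droplet pixels within assigned cell territories."""
    return _positive_mask(lipid_grid, cell_map.cell_labels, params)
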