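"""Per-cell readouts: Area Pm, Tii Pi Pm and the per-cell Pearson coefficient.

Area Pm is the area (µm²/cell) of the pixels classified positive for the
labelled protein within one cell's territory; Tii Pi Pm is the total
integrated intensity — the sum of the raw stored protein-image intensities
over those pixels (no background subtraction by default); Pr is the sample
Pearson correlation of paired pixel intensities of two channels over a
chosen per-cell pixel scope, ranging from −1 (perfect exclusion) to +1
(perfect coincidence) and undefined (NaN) when either channel is constant
over the scope.  A 4-channel field with two protein labels is analyzed
twice — once per protein channel — on the same segmentation, so cell
identities and the segmentation-derived quantities agree across the two
passes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .config import AcquisitionConfig
from .plateio import FieldImageSet
from .segmentation import CellLabelMap

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "well_id", "field_id", "cell_id", "protein_channel", "area_pm_um2",
    "tii_pi_pm", "pearson_pr", "lipid_area_um2", "cell_area_um2", "edge_flag",
]


@dataclass
class CellMeasurements:
    """One analyzed cell in one protein pass."""

    well_id: str
    field_id: int
    cell_id: int
    protein_channel: str
    area_pm_um2: float
    tii_pi_pm: float
    pearson_pr: float  # NaN marks an undefined (zero-variance) coefficient
    lipid_area_um2: float
    cell_area_um2: float
    edge_flag: bool


def area_pm(cell_protein_mask: np.ndarray, acq: AcquisitionConfig) -> float:
    """Protein-mask area in µm²: positive pixel count × pixel area."""
    return float(np.count_nonzero(cell_protein_mask)) * acq.pixel_area_um2


def tii_pi_pm(protein_grid: np.ndarray, cell_protein_mask: np.ndarray) -> float:
    """Total integrated intensity of the protein image within the protein mask."""
    if protein_grid.shape != cell_protein_mask.shape:
        raise ValueError("grid and mask must share shape")
    return float(protein_grid[cell_protein_mask].sum(dtype=np.float64))


def pearson_per_cell(grid_a: np.ndarray, grid_b: np.ndarray,
                     region: np.ndarray) -> float:
    """Sample Pearson correlation of two channels over a per-cell pixel scope.

    Returns NaN (with a warning) for an empty scope or when either channel
    has zero variance in scope.
    """
    if grid_a.shape != grid_b.shape or grid_a.shape != region.shape:
        raise ValueError("grids and region must share shape")
    a = grid_a[region].astype(np.float64)
    b = grid_b[region].astype(np.float64)
    if a.size == 0:
        logger.warning("empty pixel scope: Pearson coefficient undefined")
        return float("nan")
    a -= a.mean()
    b -= b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def quantify_field(fis: FieldImageSet, cell_map: CellLabelMap,
                   protein_mask: np.ndarray, lipid_mask: np.ndarray,
                   protein_channel: str,
                   pearson_scope: str = "whole_cell",
                   pearson_other_channel: str | None = None,
                   pearson_other_mask: np.ndarray | None = None) -> list[CellMeasurements]:
    """Per-cell measurements for one protein pass over a segmented field.

    ``pearson_scope`` is ``whole_cell`` (all pixels of the cell territory;
    default) or ``mask_union`` (union of this pass's protein mask with
    ``pearson_other_mask`` within the cell).  The Pearson coefficient pairs
    ``protein_channel`` with ``pearson_other_channel`` (default: the other
    protein channel of the acquisition).
    """
    acq = fis.acq
    if protein_channel not in (acq.channel_names[2], acq.channel_names[3]):
        raise ValueError(f"protein_channel must be one of "
                         f"{acq.channel_names[2:]!r}, got {protein_channel!r}")
    if pearson_scope not in ("whole_cell", "mask_union"):
        raise ValueError(f"unknown pearson scope {pearson_scope!r}")
    grid = fis.channels[protein_channel]
    if grid.shape != cell_map.cell_labels.shape:
        raise ValueError("field and cell label map shapes disagree")
    if pearson_other_channel is None:
        pearson_other_channel = (acq.channel_names[3]
                                 if protein_channel == acq.channel_names[2]
                                 else acq.channel_names[2])
    other = fis.channels[pearson_other_channel]

    labels = cell_map.cell_labels
    n = cell_map.n_cells
    if n == 0:
        return []
    edge = cell_map.edge_labels()
    objects = ndi.find_objects(labels)
    # vectorized per-label pixel counts / sums
    cell_px = np.bincount(labels.ravel(), minlength=n + 1)
    pm_px = np.bincount(labels[protein_mask].ravel(), minlength=n + 1)
    lm_px = np.bincount(labels[lipid_mask].ravel(), minlength=n + 1)
    tii = np.bincount(labels[protein_mask].ravel(),
                      weights=grid[protein_mask].astype(np.float64), minlength=n + 1)

    out: list[CellMeasurements] = []
    pixel_area = acq.pixel_area_um2
    for lab in range(1, n + 1):
        sl = objects[lab - 1] if lab - 1 < len(objects) else None
        if sl is None or cell_px[lab] == 0:
            continue
        in_cell = labels[sl] == lab
        if pearson_scope == "whole_cell":
            scope = in_cell
        else:
            union = protein_mask[sl].copy()
            if pearson_other_mask is not None:
                union |= pearson_other_mask[sl]
            scope = in_cell & union
        pr = pearson_per_cell(grid[sl], other[sl], scope)
        out.append(CellMeasurements(
            well_id=fis.well_id,
            field_id=fis.field_id,
            cell_id=lab,
            protein_channel=protein_channel,
            area_pm_um2=float(pm_px[lab]) * pixel_area,
            tii_pi_pm=float(tii[lab]),
            pearson_pr=pr,
            lipid_area_um2=float(lm_px[lab]) * pixel_area,
            cell_area_um2=float(cell_px[lab]) * pixel_area,
            edge_flag=lab in edge,
        ))
    return out
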