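"""Synthetic adipocyte plate images with per-cell ground truth.

The generator emulates the structure of fixed, 4-channel-labelled adipocyte
fields: DAPI nuclei as bright ellipses, lipid droplets as filled disks
clustered around each nucleus, and phospho-protein label as annular rims on
a condition-dependent subset of droplets, over a diffuse background with
Poisson shot noise plus Gaussian read noise.  Every simulated cell emits a
ground-truth record (true rim-positive area, true clean label intensity,
true droplet area) against which segmentation, masking and the per-cell
readouts are validated.

The per-cell rim-positive area is the controlled quantity: a per-cell
target is drawn from a gamma distribution with the condition's mean and CV,
and droplet rims (completing the last rim only partially, pixel by pixel in
angular order) are marked positive until the rasterized union reaches the
target.  The emitted truth is the exact pixel count of that union times the
pixel area, so recovery tests are free of rasterization slack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import draw as skdraw

from .config import AcquisitionConfig
from .plateio import FieldImageSet, PlateLayout, validate_well_id, write_field, write_measurements

WELL_IDS_96 = [f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)]


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition on a plate.

    ``rim_positive_area_mean_um2`` is the expected per-cell area of
    phospho-positive droplet rim (the quantity Area Pm estimates); the
    optional ``*_p2`` fields control the second protein channel
    independently (defaulting to the first channel's values), supporting
    dual-label designs where the same cells are analyzed twice.
    """

    condition_id: str
    rim_positive_area_mean_um2: float
    rim_positive_area_cv: float = 0.35
    protein_intensity_scale: float = 1.0
    time_min: float = 0.0
    n_wells: int = 3
    cells_per_field_mean: float = 80.0
    rim_positive_area_mean_um2_p2: float | None = None
    protein_intensity_scale_p2: float | None = None

    def __post_init__(self) -> None:
        if self.rim_positive_area_mean_um2 < 0:
            raise ValueError("rim_positive_area_mean_um2 must be >= 0")
        if self.rim_positive_area_cv < 0:
            raise ValueError("rim_positive_area_cv must be >= 0")
        if self.protein_intensity_scale < 0:
            raise ValueError("protein_intensity_scale must be >= 0")
        if self.n_wells < 1:
            raise ValueError("n_wells must be >= 1")
        if self.cells_per_field_mean < 0:
            raise ValueError("cells_per_field_mean must be >= 0")

    @property
    def p2_area_mean(self) -> float:
        v = self.rim_positive_area_mean_um2_p2
        return self.rim_positive_area_mean_um2 if v is None else v

    @property
    def p2_intensity_scale(self) -> float:
        v = self.protein_intensity_scale_p2
        return self.protein_intensity_scale if v is None else v


@dataclass(frozen=True)
class FieldModel:
    """Morphology, photometry and noise of the simulated fields.

    Lengths are µm; intensities are camera counts before noise.  Defaults
    describe differentiated adipocytes at 20×: nuclei ~6 µm in radius,
    8–30 droplets per cell with log-normal radii (median 2.5 µm) clustered
    within ~22 µm of the nucleus, rim thickness ~1.4 µm.
    """

    nucleus_radius_um: float = 6.0
    nucleus_radius_cv: float = 0.15
    nucleus_aspect_min: float = 0.7
    min_nucleus_separation_um: float = 16.0
    droplet_count_min: int = 12
    droplet_count_max: int = 40
    droplet_radius_median_um: float = 2.8
    droplet_radius_sigma: float = 0.35
    cluster_radius_um: float = 22.0
    rim_thickness_um: float = 1.4
    background: tuple[float, float, float, float] = (100.0, 150.0, 200.0, 200.0)
    nucleus_amplitude: float = 3000.0
    droplet_amplitude: float = 1500.0
    rim_amplitude: float = 2500.0
    read_noise_sigma: float = 10.0
    placement_attempts_per_cell: int = 300


@dataclass
class CellGroundTruth:
    """Simulator truth for one cell; areas in µm², intensity in clean counts."""

    cell_id: int
    well_id: str
    field_id: int
    nucleus_center_px: tuple[int, int]
    true_rim_positive_area_um2: float
    true_total_protein_intensity: float
    true_droplet_area_um2: float
    true_rim_positive_area_um2_p2: float = 0.0
    true_total_protein_intensity_p2: float = 0.0


def _place_nuclei(n: int, shape: tuple[int, int], min_sep_px: float,
                  rng: np.random.Generator, attempts_per_cell: int) -> np.ndarray:
    """Sequential random placement with a hard minimum separation."""
    if n == 0:
        return np.empty((0, 2))
    centers: list[tuple[float, float]] = []
    budget = attempts_per_cell * n
    while len(centers) < n and budget > 0:
        budget -= 1
        r = rng.uniform(0, shape[0])
        c = rng.uniform(0, shape[1])
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep_px ** 2 for r0, c0 in centers):
            centers.append((r, c))
    if len(centers) < n:
        raise ValueError(
            "cells_per_field_mean too large: could not place "
            f"{n} nuclei at {min_sep_px:.1f} px minimum separation in a "
            f"{shape[0]}x{shape[1]} field")
    return np.array(centers)


def _annulus_coords(center: tuple[float, float], r_outer: float, r_inner: float,
                    shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = skdraw.disk(center, max(r_outer, 1.0), shape=shape)
    if r_inner > 0:
        keep = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 >= r_inner ** 2
        rr, cc = rr[keep], cc[keep]
    return rr, cc


def _quantize(clean: np.ndarray, rng: np.random.Generator, model: FieldModel,
              acq: AcquisitionConfig) -> np.ndarray:
    noisy = rng.poisson(clean).astype(np.float64)
    noisy += rng.normal(0.0, model.read_noise_sigma, size=clean.shape)
    noisy = np.clip(np.rint(noisy), 0, acq.max_intensity)
    return noisy.astype(np.uint8 if acq.bit_depth == 8 else np.uint16)


def generate_field(condition: ConditionSpec, acq: AcquisitionConfig, rng_seed: int,
                   model: FieldModel = FieldModel(), well_id: str = "A1",
                   field_id: int = 0, return_masks: bool = False):
    """Simulate one field of view.

    Returns ``(FieldImageSet, list[CellGroundTruth])``, plus a dict of the
    generator's internal boolean masks (per-cell positive-rim and droplet
    masks) when ``return_masks`` is true.  Deterministic given
    ``(condition, acq, model, rng_seed)``.
    """
    rng = np.random.default_rng(rng_seed)
    shape = acq.shape
    px = acq.pixel_pitch_um
    pixel_area = acq.pixel_area_um2

    n_cells = int(rng.poisson(condition.cells_per_field_mean))
    centers = _place_nuclei(n_cells, shape, model.min_nucleus_separation_um / px,
                            rng, model.placement_attempts_per_cell)

    nuclei = np.zeros(shape, dtype=np.float64)
    lipid = np.zeros(shape, dtype=np.float64)
    pos1 = np.zeros(shape, dtype=bool)
    pos2 = np.zeros(shape, dtype=bool)

    truths: list[CellGroundTruth] = []
    masks: dict[str, dict[int, np.ndarray]] = {"rim_positive": {}, "rim_positive_p2": {},
                                               "droplets": {}}

    gamma_shape = (1.0 / condition.rim_positive_area_cv ** 2
                   if condition.rim_positive_area_cv > 0 else None)

    for idx in range(n_cells):
        cell_id = idx + 1
        center = centers[idx]
        # nucleus: rotated ellipse
        r_nuc = model.nucleus_radius_um / px * max(
            rng.normal(1.0, model.nucleus_radius_cv), 0.4)
        aspect = rng.uniform(model.nucleus_aspect_min, 1.0)
        theta = rng.uniform(0, math.pi)
        rr, cc = skdraw.ellipse(center[0], center[1], r_nuc, r_nuc * aspect,
                                shape=shape, rotation=theta)
        np.maximum.at(nuclei, (rr, cc), model.nucleus_amplitude * rng.uniform(0.85, 1.0))

        # droplets clustered in an annulus around the nucleus
        n_drop = int(rng.integers(model.droplet_count_min, model.droplet_count_max + 1))
        angles = rng.uniform(0, 2 * math.pi, n_drop)
        cluster_r = model.cluster_radius_um / px
        radial = r_nuc + 1.0 + np.sqrt(rng.uniform(0, 1, n_drop)) * max(cluster_r - r_nuc, 1.0)
        drop_centers = np.column_stack([center[0] + radial * np.sin(angles),
                                        center[1] + radial * np.cos(angles)])
        drop_radii = np.maximum(
            rng.lognormal(math.log(model.droplet_radius_median_um / px),
                          model.droplet_radius_sigma, n_drop), 1.2)

        droplet_mask = np.zeros(shape, dtype=bool)
        rim_coords: list[tuple[np.ndarray, np.ndarray]] = []
        rim_half = 0.5 * model.rim_thickness_um / px
        for (dr, dc), radius in zip(drop_centers, drop_radii):
            rr, cc = skdraw.disk((dr, dc), radius, shape=shape)
            droplet_mask[rr, cc] = True
            lipid_amp = model.droplet_amplitude * rng.uniform(0.7, 1.0)
            np.maximum.at(lipid, (rr, cc), lipid_amp)
            rim_coords.append(_annulus_coords((dr, dc), radius + rim_half,
                                              max(radius - rim_half, 0.5), shape))

        cell_truth = {"droplet_px": int(droplet_mask.sum())}
        for tag, canvas, mean_um2 in (
            ("p1", pos1, condition.rim_positive_area_mean_um2),
            ("p2", pos2, condition.p2_area_mean),
        ):
            cell_pos = np.zeros(shape, dtype=bool)
            target_um2 = 0.0
            if mean_um2 > 0:
                if gamma_shape is None:
                    target_um2 = mean_um2
                else:
                    target_um2 = rng.gamma(gamma_shape, mean_um2 / gamma_shape)
            target_px = target_um2 / pixel_area
            if target_px >= 0.5:
                order = rng.permutation(n_drop)
                placed = 0
                for j in order:
                    if placed >= target_px - 0.5:
                        break
                    rr, cc = rim_coords[j]
                    if rr.size == 0:
                        continue
                    novel = ~cell_pos[rr, cc]
                    n_novel = int(novel.sum())
                    remaining = target_px - placed
                    if n_novel <= remaining + 0.5:
                        cell_pos[rr, cc] = True
                        placed += n_novel
                    else:
                        # partial rim: take pixels in angular order until the
                        # target is met, so per-cell truth tracks the target
                        # to within one pixel
                        dj, cj = drop_centers[j]
                        ang = np.arctan2(rr - dj, cc - cj)
                        sel = np.argsort(ang, kind="stable")
                        novel_sorted = novel[sel]
                        cum = np.cumsum(novel_sorted)
                        k = int(np.searchsorted(cum, round(remaining)))
                        take = sel[: k + 1]
                        cell_pos[rr[take], cc[take]] = True
                        placed += int(novel_sorted[: k + 1].sum())
                        break
            canvas |= cell_pos
            cell_truth[f"{tag}_px"] = int(cell_pos.sum())
            if return_masks:
                key = "rim_positive" if tag == "p1" else "rim_positive_p2"
                masks[key][cell_id] = cell_pos

        if return_masks:
            masks["droplets"][cell_id] = droplet_mask

        truths.append(CellGroundTruth(
            cell_id=cell_id,
            well_id=well_id,
            field_id=field_id,
            nucleus_center_px=(int(round(center[0])), int(round(center[1]))),
            true_rim_positive_area_um2=cell_truth["p1_px"] * pixel_area,
            true_total_protein_intensity=(cell_truth["p1_px"] * model.rim_amplitude
                                          * condition.protein_intensity_scale),
            true_droplet_area_um2=cell_truth["droplet_px"] * pixel_area,
            true_rim_positive_area_um2_p2=cell_truth["p2_px"] * pixel_area,
            true_total_protein_intensity_p2=(cell_truth["p2_px"] * model.rim_amplitude
                                             * condition.p2_intensity_scale),
        ))

    bg = model.background
    clean = {
        acq.channel_names[0]: bg[0] + nuclei,
        acq.channel_names[1]: bg[1] + lipid,
        acq.channel_names[2]: bg[2] + (model.rim_amplitude * condition.protein_intensity_scale) * pos1,
        acq.channel_names[3]: bg[3] + (model.rim_amplitude * condition.p2_intensity_scale) * pos2,
    }
    channels = {name: _quantize(grid, rng, model, acq) for name, grid in clean.items()}
    fis = FieldImageSet(channels=channels, well_id=well_id, field_id=field_id, acq=acq)
    if return_masks:
        return fis, truths, masks
    return fis, truths


def field_seed(master_seed: int, well_index: int, field_index: int) -> int:
    """Deterministic per-field sub-seed (splittable counter scheme)."""
    ss = np.random.SeedSequence([int(master_seed), int(well_index), int(field_index)])
    return int(ss.generate_state(1)[0])


def assign_wells(conditions: list[ConditionSpec],
                 well_assignments: dict[str, list[str]] | None = None,
                 plate_id: str = "plate1") -> PlateLayout:
    """Lay conditions out on a 96-well plate (row-major fill by default)."""
    if not conditions:
        raise ValueError("condition list must be non-empty")
    rows: dict[str, tuple[str, float, int]] = {}
    cursor = 0
    for cond in conditions:
        if well_assignments and cond.condition_id in well_assignments:
            wells = [validate_well_id(w) for w in well_assignments[cond.condition_id]]
            if len(wells) != cond.n_wells:
                raise ValueError(f"{cond.condition_id}: {len(wells)} wells assigned, "
                                 f"n_wells={cond.n_wells}")
        else:
            wells = WELL_IDS_96[cursor:cursor + cond.n_wells]
            cursor += cond.n_wells
            if len(wells) < cond.n_wells:
                raise ValueError("plate overflow: more than 96 wells requested")
        for rep, well in enumerate(wells):
            if well in rows:
                raise ValueError(f"duplicate well assignment: {well} "
                                 f"({rows[well][0]} and {cond.condition_id})")
            rows[well] = (cond.condition_id, cond.time_min, rep)
    return PlateLayout(rows=rows, plate_id=plate_id)


def iter_plate_fields(conditions: list[ConditionSpec], acq: AcquisitionConfig,
                      fields_per_well: int, master_seed: int,
                      model: FieldModel = FieldModel(),
                      layout: PlateLayout | None = None):
    """Yield (condition, FieldImageSet, truths) for every (well, field) in order."""
    layout = layout if layout is not None else assign_wells(conditions)
    by_id = {c.condition_id: c for c in conditions}
    for well_index, (well_id, (cond_id, _t, _r)) in enumerate(layout.rows.items()):
        cond = by_id[cond_id]
        for f in range(fields_per_well):
            seed = field_seed(master_seed, well_index, f)
            fis, truths = generate_field(cond, acq, seed, model=model,
                                         well_id=well_id, field_id=f)
            yield cond, fis, truths


def truth_table(truths: list[CellGroundTruth]):
    import pandas as pd

    rows = []
    for t in truths:
        d = dict(t.__dict__)
        d["nucleus_row_px"], d["nucleus_col_px"] = d.pop("nucleus_center_px")
        rows.append(d)
    return pd.DataFrame(rows)


def generate_plate(conditions: list[ConditionSpec], acq: AcquisitionConfig,
                   fields_per_well: int = 4, master_seed: int = 0,
                   out_dir: str | Path | None = None,
                   model: FieldModel = FieldModel(), plate_id: str = "plate1",
                   image_format: str = "tiff",
                   well_assignments: dict[str, list[str]] | None = None):
    """Simulate a plate; optionally write images, layout and ground truth to disk.

    Returns ``(layout, ground_truth_frame)``; with ``out_dir`` set, one image
    file per (well, field, channel) is written using the image_io naming
    convention plus ``layout.csv`` and ``ground_truth.csv``.
    """
    layout = assign_wells(conditions, well_assignments, plate_id=plate_id)
    all_truths: list[CellGroundTruth] = []
    for _cond, fis, truths in iter_plate_fields(conditions, acq, fields_per_well,
                                                master_seed, model=model, layout=layout):
        all_truths.extend(truths)
        if out_dir is not None:
            write_field(fis, out_dir, plate_id=plate_id, image_format=image_format)
    truth = truth_table(all_truths)
    if out_dir is not None:
        out_dir = Path(out_dir)
        layout.write_csv(out_dir / "layout.csv")
        write_measurements(truth, out_dir / "ground_truth.csv")
    return layout, truth
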