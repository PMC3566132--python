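"""End-to-end orchestration: simulate → segment → mask → quantify → aggregate → compare.

The pipeline is deterministic given the seed.  ``run_simulated_plate`` is
the in-memory core used by the analysis drivers and the acceptance checks;
``run_experiment`` is the file-writing front end behind the CLI, which also
persists intermediate artifacts (label maps, masks) so single stages can be
re-run and audited.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AcquisitionConfig
from .masking import MaskParams, make_lipid_mask, make_protein_mask
from .plateio import FieldImageSet, PlateLayout, write_field, write_measurements
from .quantify import MEASUREMENT_COLUMNS, CellMeasurements, quantify_field
from .segmentation import SegmentationParams, estimate_cell_boundaries, segment_nuclei
from .stats import (WellSummary, aggregate_wells, compare_groups,
                    normalize_to_control, summaries_frame)
from .synthetic import ConditionSpec, FieldModel, assign_wells, iter_plate_fields, truth_table
from .presets import PRESETS, CONTROL_ID

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    conditions: list[ConditionSpec]
    acq: AcquisitionConfig = dc_field(default_factory=AcquisitionConfig)
    model: FieldModel = dc_field(default_factory=FieldModel)
    seg_params: SegmentationParams = dc_field(default_factory=SegmentationParams)
    mask_params: MaskParams = dc_field(default_factory=MaskParams)
    fields_per_well: int = 4
    seed: int = 0
    protein_channels: tuple[str, ...] = ("protein1", "protein2")
    pearson_scope: str = "whole_cell"
    stats_method: str = "anova_tukey"
    control_condition: str | None = CONTROL_ID
    exclude_edge: bool = True
    out_dir: Path | None = None
    write_images: bool = False

    @classmethod
    def from_preset(cls, preset: str, seed: int = 0, **overrides) -> "RunConfig":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
        preset_kwargs = overrides.pop("preset_kwargs", {})
        return cls(conditions=PRESETS[preset](**preset_kwargs), seed=seed, **overrides)


def process_field(fis: FieldImageSet, seg_params: SegmentationParams,
                  mask_params: MaskParams,
                  protein_channels: tuple[str, ...] = ("protein1", "protein2"),
                  pearson_scope: str = "whole_cell"):
    """Segment one field and quantify each requested protein channel.

    Returns ``(records, cell_map, masks)`` where ``masks`` maps channel
    name → boolean mask (including ``"lipid"``).  The same segmentation and
    lipid mask serve every protein pass, so segmentation-derived quantities
    are identical across passes.
    """
    acq = fis.acq
    nuclei = segment_nuclei(fis.channels[acq.channel_names[0]], acq, seg_params)
    cell_map = estimate_cell_boundaries(nuclei, acq, params=seg_params)
    lipid_mask = make_lipid_mask(fis.channels[acq.channel_names[1]], cell_map, mask_params)
    masks: dict[str, np.ndarray] = {"lipid": lipid_mask}
    for channel in protein_channels:
        masks[channel] = make_protein_mask(fis.channels[channel], cell_map, mask_params)
    records: list[CellMeasurements] = []
    for channel in protein_channels:
        other = [c for c in ("protein1", "protein2") if c != channel]
        other_mask = masks.get(other[0]) if other else None
        records.extend(quantify_field(
            fis, cell_map, masks[channel], lipid_mask, channel,
            pearson_scope=pearson_scope, pearson_other_mask=other_mask))
    return records, cell_map, masks


@dataclass
class PlateResult:
    layout: PlateLayout
    cells: pd.DataFrame
    summaries: list[WellSummary]
    truth: pd.DataFrame
    comparisons: dict[str, pd.DataFrame] = dc_field(default_factory=dict)

    def summaries_for(self, protein_channel: str) -> list[WellSummary]:
        return [s for s in self.summaries if s.protein_channel == protein_channel]

    def group_well_means(self, protein_channel: str,
                         value: str = "mean_area_pm_um2") -> dict[str, np.ndarray]:
        groups: dict[str, list[float]] = {}
        for s in self.summaries_for(protein_channel):
            groups.setdefault(s.condition_id, []).append(getattr(s, value))
        return {k: np.asarray(v) for k, v in groups.items()}


def run_simulated_plate(config: RunConfig) -> PlateResult:
    """Simulate and quantify a plate entirely in memory."""
    layout = assign_wells(config.conditions)
    all_records: list[CellMeasurements] = []
    all_truths = []
    for _cond, fis, truths in iter_plate_fields(
            config.conditions, config.acq, config.fields_per_well, config.seed,
            model=config.model, layout=layout):
        records, _cell_map, _masks = process_field(
            fis, config.seg_params, config.mask_params,
            config.protein_channels, config.pearson_scope)
        all_records.extend(records)
        all_truths.extend(truths)
        if config.write_images and config.out_dir is not None:
            write_field(fis, Path(config.out_dir) / "images", plate_id=layout.plate_id)
    cells = (pd.DataFrame([r.__dict__ for r in all_records])
             if all_records else pd.DataFrame(columns=MEASUREMENT_COLUMNS))
    summaries = aggregate_wells(cells, layout, exclude_edge=config.exclude_edge)
    if config.control_condition is not None and any(
            s.condition_id == config.control_condition for s in summaries):
        # normalize per protein channel so each pass has its own control scale
        for channel in {s.protein_channel for s in summaries}:
            chan = [s for s in summaries if s.protein_channel == channel
                    and s.n_cells > 0]
            if any(s.condition_id == config.control_condition for s in chan):
                normalize_to_control(chan, config.control_condition)
    return PlateResult(layout=layout, cells=cells, summaries=summaries,
                       truth=truth_table(all_truths))


def run_experiment(config: RunConfig) -> PlateResult:
    """Full run with persisted outputs: per-cell CSV per protein channel,
    well summaries, comparison tables and a run log."""
    out_dir = Path(config.out_dir) if config.out_dir is not None else None
    result = run_simulated_plate(config)
    comparisons: dict[str, pd.DataFrame] = {}
    for channel in config.protein_channels:
        groups = result.group_well_means(channel)
        groups = {k: v for k, v in groups.items() if len(v) >= 2 and np.isfinite(v).all()}
        if len(groups) >= 2:
            try:
                comparisons[channel] = compare_groups(
                    groups, method=config.stats_method,
                    control=config.control_condition)
            except ValueError as exc:
                logger.warning("comparison skipped for %s: %s", channel, exc)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        result.layout.write_csv(out_dir / "layout.csv")
        write_measurements(result.truth, out_dir / "ground_truth.csv")
        for channel in config.protein_channels:
            sub = result.cells[result.cells["protein_channel"] == channel] \
                if len(result.cells) else result.cells
            write_measurements(sub, out_dir / f"cells_{channel}.csv")
        write_measurements(summaries_frame(result.summaries),
                           out_dir / "well_summaries.csv")
        for channel, table in comparisons.items():
            table.to_csv(out_dir / f"comparisons_{channel}.csv", index=False)
        log = {
            "seed": config.seed,
            "fields_per_well": config.fields_per_well,
            "pearson_scope": config.pearson_scope,
            "stats_method": config.stats_method,
            "control_condition": config.control_condition,
            "exclude_edge": config.exclude_edge,
            "acq": config.acq.__dict__ | {"channel_names": list(config.acq.channel_names)},
            "segmentation": config.seg_params.__dict__,
            "masking": config.mask_params.__dict__,
            "conditions": [c.__dict__ for c in config.conditions],
            "cells_per_well": {
                s.well_id: s.n_cells for s in result.summaries
                if s.protein_channel == config.protein_channels[0]},
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    result.comparisons = comparisons
    return result
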