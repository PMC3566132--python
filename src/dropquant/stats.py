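"""Well-level aggregation, normalization, fold changes and group comparisons.

The experimental unit throughout is the WELL: per-cell measurements are
pooled over a well's fields into a well mean, and all hypothesis tests run
on well means (n = wells), never on cells — per-cell pseudo-replication
would grossly inflate significance.  SDs are sample SDs (n−1).  Group
comparisons follow the one-way-ANOVA-then-post-hoc convention: Dunnett's
test against a designated control, Tukey's HSD for all pairs, or Student's
t-test for a single two-group contrast, with significance flagged at the
0.05 / 0.01 / 0.001 (* / ** / ***) levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .plateio import PlateLayout

WELL_SUMMARY_COLUMNS = [
    "well_id", "condition_id", "time_min", "protein_channel", "n_cells",
    "mean_area_pm_um2", "sd_area_pm_um2", "mean_tii_pi_pm", "sd_tii_pi_pm",
    "mean_pr", "mean_lipid_area_um2", "normalized_mean", "fold_change", "qc_flag",
]


@dataclass
class WellSummary:
    """Per-well mean/SD/n of the per-cell measurements for one protein pass."""

    well_id: str
    condition_id: str
    time_min: float
    protein_channel: str
    n_cells: int
    mean_area_pm_um2: float
    sd_area_pm_um2: float
    mean_tii_pi_pm: float
    sd_tii_pi_pm: float
    mean_pr: float
    mean_lipid_area_um2: float
    normalized_mean: float = math.nan
    fold_change: float = math.nan
    qc_flag: str = ""


def _records_frame(cell_records) -> pd.DataFrame:
    if isinstance(cell_records, pd.DataFrame):
        return cell_records
    return pd.DataFrame([r.__dict__ for r in cell_records])


def aggregate_wells(cell_records, layout: PlateLayout,
                    exclude_edge: bool = True) -> list[WellSummary]:
    """Pool cells across a well's fields into one summary per (well, protein).

    Cells flagged as edge cells (nucleus on the field border) are excluded
    by default; undefined Pearson values are omitted from ``mean_pr``.
    Records whose well is absent from the layout raise.
    """
    df = _records_frame(cell_records)
    if df.empty:
        df = pd.DataFrame(columns=["well_id", "field_id", "cell_id", "protein_channel",
                                   "area_pm_um2", "tii_pi_pm", "pearson_pr",
                                   "lipid_area_um2", "edge_flag"])
    unknown = set(df["well_id"]) - set(layout.rows)
    if unknown:
        raise ValueError(f"cell records reference wells not in the layout: {sorted(unknown)}")
    if exclude_edge and len(df):
        df = df[~df["edge_flag"].astype(bool)]

    channels = sorted(df["protein_channel"].unique()) if len(df) else [""]
    out: list[WellSummary] = []
    for well_id, (condition_id, time_min, _rep) in layout.rows.items():
        for channel in channels:
            sub = df[(df["well_id"] == well_id) & (df["protein_channel"] == channel)] \
                if len(df) else df
            n = len(sub)
            if n == 0:
                out.append(WellSummary(
                    well_id=well_id, condition_id=condition_id, time_min=time_min,
                    protein_channel=channel, n_cells=0,
                    mean_area_pm_um2=math.nan, sd_area_pm_um2=math.nan,
                    mean_tii_pi_pm=math.nan, sd_tii_pi_pm=math.nan,
                    mean_pr=math.nan, mean_lipid_area_um2=math.nan,
                    qc_flag="no_cells"))
                continue
            pr = sub["pearson_pr"].dropna()
            out.append(WellSummary(
                well_id=well_id, condition_id=condition_id, time_min=time_min,
                protein_channel=channel, n_cells=n,
                mean_area_pm_um2=float(sub["area_pm_um2"].mean()),
                sd_area_pm_um2=float(sub["area_pm_um2"].std(ddof=1)) if n > 1 else 0.0,
                mean_tii_pi_pm=float(sub["tii_pi_pm"].mean()),
                sd_tii_pi_pm=float(sub["tii_pi_pm"].std(ddof=1)) if n > 1 else 0.0,
                mean_pr=float(pr.mean()) if len(pr) else math.nan,
                mean_lipid_area_um2=float(sub["lipid_area_um2"].mean()),
            ))
    return out


def summaries_frame(summaries: list[WellSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def fold_change(treated: list[WellSummary], control: list[WellSummary],
                value: str = "mean_area_pm_um2") -> float:
    """(mean over treated wells of the well mean) / (same over control wells)."""
    t = np.array([getattr(s, value) for s in treated], dtype=np.float64)
    c = np.array([getattr(s, value) for s in control], dtype=np.float64)
    if t.size == 0 or c.size == 0:
        raise ValueError("fold_change requires non-empty treated and control groups")
    c_mean = float(np.nanmean(c))
    if c_mean == 0:
        raise ValueError("control mean is zero; fold change undefined")
    return float(np.nanmean(t)) / c_mean


def normalize_to_control(summaries: list[WellSummary], control_condition_id: str,
                         value: str = "mean_area_pm_um2") -> list[WellSummary]:
    """Set each well's ``normalized_mean`` to its well mean over the control mean.

    The control group's normalized means average to 1 by construction.
    Returns the same summary objects, mutated.
    """
    control = [s for s in summaries if s.condition_id == control_condition_id]
    if not control:
        raise ValueError(f"no wells for control condition {control_condition_id!r}")
    c_mean = float(np.nanmean([getattr(s, value) for s in control]))
    if not c_mean > 0:
        raise ValueError("control mean must be positive to normalize")
    for s in summaries:
        s.normalized_mean = getattr(s, value) / c_mean
        s.fold_change = s.normalized_mean
    return summaries


_STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _stars(p: float) -> str:
    for level, mark in _STAR_LEVELS:
        if p < level:
            return mark
    return ""


def compare_groups(groups: dict[str, np.ndarray], method: str = "anova_tukey",
                   control: str | None = None) -> pd.DataFrame:
    """Pairwise comparisons of well-level values.

    ``groups`` maps group label to the vector of well means.  Methods:
    ``anova_tukey`` (all pairs, Tukey's HSD), ``anova_dunnett`` (each group
    vs the designated control) and ``t_test`` (exactly two groups, Student's
    two-sample t, equal variances).  The returned frame has one row per
    comparison with the adjusted p-value and */**/*** flags; the one-way
    ANOVA p-value is stored in ``result.attrs["anova_p"]`` for the ANOVA
    methods.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=np.float64) for k in names]
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 wells")
    rows = []
    attrs: dict[str, float] = {}

    if method == "t_test":
        if len(names) != 2:
            raise ValueError("t_test requires exactly 2 groups")
        t, p = sps.ttest_ind(arrays[0], arrays[1], equal_var=True)
        rows.append((names[0], names[1], float(t), float(p)))
    elif method == "anova_tukey":
        if len(names) < 2:
            raise ValueError("ANOVA requires at least 2 groups")
        attrs["anova_p"] = float(sps.f_oneway(*arrays).pvalue)
        res = sps.tukey_hsd(*arrays)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                rows.append((names[i], names[j], float(res.statistic[i, j]),
                             float(res.pvalue[i, j])))
    elif method == "anova_dunnett":
        if control is None:
            raise ValueError("anova_dunnett requires a control group label")
        if control not in groups:
            raise ValueError(f"control group {control!r} not among groups")
        attrs["anova_p"] = float(sps.f_oneway(*arrays).pvalue)
        others = [n for n in names if n != control]
        res = sps.dunnett(*[np.asarray(groups[n], dtype=np.float64) for n in others],
                          control=np.asarray(groups[control], dtype=np.float64))
        for name, stat, p in zip(others, np.atleast_1d(res.statistic),
                                 np.atleast_1d(res.pvalue)):
            rows.append((name, control, float(stat), float(p)))
    else:
        raise ValueError(f"unknown method {method!r}")

    table = pd.DataFrame(rows, columns=["group1", "group2", "statistic", "p_value"])
    table["significant_05"] = table["p_value"] < 0.05
    table["significant_01"] = table["p_value"] < 0.01
    table["significant_001"] = table["p_value"] < 0.001
    table["stars"] = table["p_value"].map(_stars)
    table["method"] = method
    table.attrs.update(attrs)
    return table
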