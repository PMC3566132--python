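"""Named condition presets encoding the published experiment designs.

Each preset returns the list of :class:`ConditionSpec` for one experiment,
with ground-truth per-cell rim-positive areas (µm²/cell) set to the
reported control means and fold changes:

* ``agonist_site5`` — pPeri-site 5, 5-min agonists: control 27 µm²/cell,
  FSK 7-fold, L-γ-MSH 8-fold; n = 3 wells (an average of ~532 cells/well).
* ``agonist_site6`` — pPeri-site 6: control 7 µm²/cell, FSK 11-fold,
  L-γ-MSH 27-fold; n = 8 wells (~272 cells/well).
* ``sirna_knockdown`` — perilipin siRNA titration, FSK-stimulated, readout
  normalized to the 0-siRNA control; up to a 90% reduction at the highest
  concentration; n = 6 wells.
* ``timecourse_site5`` — time course (1/5/20 min): pPeri-site 5 control
  ~20 µm²/cell with an immediate, sustained ~4-fold response to both FSK
  and L-γ-MSH; second channel pHSL-serine 563 rising more slowly and more
  strongly with L-γ-MSH; n = 7 wells (~930 cells/well).
* ``agonist_panel_site5`` — agonist panel (20 min): pPeri-site 5 control
  ~70 µm²/cell; isoproterenol +30%/+50%, FSK and L-γ-MSH ~2.5-fold;
  second channel pHSL-serine 660; n = 8 wells (~360 cells/well).

``cells_per_field_mean`` defaults to the published per-well cell counts
divided by 4 fields/well; runners may pass a smaller value to trade
per-well n for runtime (fold changes are ratios of well means and remain
unbiased under that rescaling).
"""

from __future__ import annotations

from .synthetic import ConditionSpec

CONTROL_ID = "control"


def agonist_site5(cells_per_field_mean: float = 133.0) -> list[ConditionSpec]:
    base = 27.0
    mk = lambda cid, fold: ConditionSpec(
        condition_id=cid, rim_positive_area_mean_um2=base * fold,
        time_min=5.0, n_wells=3, cells_per_field_mean=cells_per_field_mean)
    return [mk(CONTROL_ID, 1.0), mk("FSK", 7.0), mk("MSH", 8.0)]


def agonist_site6(cells_per_field_mean: float = 68.0) -> list[ConditionSpec]:
    base = 7.0
    mk = lambda cid, fold: ConditionSpec(
        condition_id=cid, rim_positive_area_mean_um2=base * fold,
        time_min=5.0, n_wells=8, cells_per_field_mean=cells_per_field_mean)
    return [mk(CONTROL_ID, 1.0), mk("FSK", 11.0), mk("MSH", 27.0)]


#: ground-truth fraction of the control signal remaining per siRNA level;
#: the highest level is the published "up to 90%" reduction, the
#: intermediate levels are plausible interpolations (the source quantifies
#: only the maximum).
KNOCKDOWN_REMAINING = {"siRNA_10nM": 0.30, "siRNA_20nM": 0.20, "siRNA_50nM": 0.10}


def sirna_knockdown(cells_per_field_mean: float = 80.0,
                   base_area_um2: float = 60.0) -> list[ConditionSpec]:
    conds = [ConditionSpec(condition_id=CONTROL_ID,
                           rim_positive_area_mean_um2=base_area_um2,
                           n_wells=6, cells_per_field_mean=cells_per_field_mean)]
    for cid, remaining in KNOCKDOWN_REMAINING.items():
        conds.append(ConditionSpec(
            condition_id=cid, rim_positive_area_mean_um2=base_area_um2 * remaining,
            n_wells=6, cells_per_field_mean=cells_per_field_mean))
    return conds


TIMEPOINTS_MIN = (1.0, 5.0, 20.0)

#: (site-5 area, HSL-563 area) µm²/cell per (agonist, time)
_TIMECOURSE_SITE5 = {
    (CONTROL_ID, 1.0): (20.0, 1.0), ("FSK", 1.0): (80.0, 4.0), ("MSH", 1.0): (80.0, 20.0),
    (CONTROL_ID, 5.0): (20.0, 2.0), ("FSK", 5.0): (80.0, 19.0), ("MSH", 5.0): (80.0, 41.0),
    (CONTROL_ID, 20.0): (20.0, 2.0), ("FSK", 20.0): (80.0, 45.0), ("MSH", 20.0): (80.0, 55.0),
}


def timecourse_site5(cells_per_field_mean: float = 232.0, n_wells: int = 7,
               agonists: tuple[str, ...] = (CONTROL_ID, "FSK", "MSH")) -> list[ConditionSpec]:
    conds = []
    for (agonist, t), (a1, a2) in _TIMECOURSE_SITE5.items():
        if agonist not in agonists:
            continue
        conds.append(ConditionSpec(
            condition_id=f"{agonist}_{t:g}min", rim_positive_area_mean_um2=a1,
            rim_positive_area_mean_um2_p2=a2, time_min=t, n_wells=n_wells,
            cells_per_field_mean=cells_per_field_mean))
    return conds


#: (site-5 area, HSL-660 area) µm²/cell for the 20-min agonist panel
_PANEL_SITE5 = {
    CONTROL_ID: (70.0, 48.0),
    "ISO_0.01uM": (91.0, 81.6),
    "ISO_0.1uM": (105.0, 96.0),
    "FSK_1uM": (175.0, 182.4),
    "FSK_6uM": (175.0, 206.4),
    "MSH_0.2uM": (175.0, 201.6),
}


def agonist_panel_site5(cells_per_field_mean: float = 90.0) -> list[ConditionSpec]:
    return [ConditionSpec(condition_id=cid, rim_positive_area_mean_um2=a1,
                          rim_positive_area_mean_um2_p2=a2, time_min=20.0,
                          n_wells=8, cells_per_field_mean=cells_per_field_mean)
            for cid, (a1, a2) in _PANEL_SITE5.items()]


def null_plate(n_wells: int = 4, n_groups: int = 2,
               cells_per_field_mean: float = 40.0,
               area_um2: float = 30.0) -> list[ConditionSpec]:
    """All groups identically distributed — for type-I-error checks."""
    return [ConditionSpec(condition_id=f"group{i}" if i else CONTROL_ID,
                          rim_positive_area_mean_um2=area_um2, n_wells=n_wells,
                          cells_per_field_mean=cells_per_field_mean)
            for i in range(n_groups)]


PRESETS = {
    "agonist_site5": agonist_site5,
    "agonist_site6": agonist_site6,
    "sirna_knockdown": sirna_knockdown,
    "timecourse_site5": timecourse_site5,
    "agonist_panel_site5": agonist_panel_site5,
    "null": null_plate,
}
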