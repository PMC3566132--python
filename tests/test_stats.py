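"""Well-level aggregation and group comparisons, checked against hand
arithmetic, a frozen R oracle (stats::TukeyHSD, multcomp Dunnett, t.test)
and a type-I-error simulation."""

import math

import numpy as np
import pytest

from dropquant.plateio import PlateLayout
from dropquant.quantify import CellMeasurements
from dropquant.stats import (WellSummary, aggregate_wells, compare_groups,
                             fold_change, normalize_to_control)


def _cell(well, cell_id, area, edge=False, channel="protein1", pr=0.5):
    return CellMeasurements(well_id=well, field_id=0, cell_id=cell_id,
                            protein_channel=channel, area_pm_um2=area,
                            tii_pi_pm=area * 100.0, pearson_pr=pr,
                            lipid_area_um2=50.0, cell_area_um2=900.0,
                            edge_flag=edge)


def _summary(well, cond, mean, time_min=0.0, n=100):
    return WellSummary(well_id=well, condition_id=cond, time_min=time_min,
                       protein_channel="protein1", n_cells=n,
                       mean_area_pm_um2=mean, sd_area_pm_um2=1.0,
                       mean_tii_pi_pm=mean * 100, sd_tii_pi_pm=10.0,
                       mean_pr=0.5, mean_lipid_area_um2=50.0)


LAYOUT = PlateLayout(rows={"A1": ("control", 0.0, 0), "A2": ("fsk", 0.0, 0)})


class TestAggregateWells:
    def test_mean_and_sample_sd(self):
        cells = [_cell("A1", i, a) for i, a in enumerate((10.0, 20.0, 30.0))]
        cells += [_cell("A2", 0, 5.0)]
        s = {x.well_id: x for x in aggregate_wells(cells, LAYOUT)}
        assert s["A1"].mean_area_pm_um2 == pytest.approx(20.0)
        assert s["A1"].sd_area_pm_um2 == pytest.approx(10.0)  # ddof=1
        assert s["A1"].n_cells == 3

    def test_order_invariance(self):
        cells = [_cell("A1", i, a) for i, a in enumerate((3.0, 7.0, 11.0, 2.0))]
        cells += [_cell("A2", 0, 5.0)]
        fwd = aggregate_wells(cells, LAYOUT)
        rev = aggregate_wells(list(reversed(cells)), LAYOUT)
        assert [s.__dict__ for s in fwd] == [s.__dict__ for s in rev]

    def test_edge_exclusion_filter(self):
        cells = [_cell("A1", 1, 10.0), _cell("A1", 2, 100.0, edge=True),
                 _cell("A2", 1, 5.0)]
        incl = {x.well_id: x for x in aggregate_wells(cells, LAYOUT, exclude_edge=False)}
        excl = {x.well_id: x for x in aggregate_wells(cells, LAYOUT, exclude_edge=True)}
        assert incl["A1"].n_cells == 2 and excl["A1"].n_cells == 1
        assert excl["A1"].mean_area_pm_um2 == pytest.approx(10.0)

    def test_empty_well_is_flagged(self):
        cells = [_cell("A1", 1, 10.0)]
        s = {x.well_id: x for x in aggregate_wells(cells, LAYOUT)}
        assert s["A2"].n_cells == 0 and s["A2"].qc_flag == "no_cells"
        assert math.isnan(s["A2"].mean_area_pm_um2)

    def test_unknown_well_raises(self):
        with pytest.raises(ValueError, match="not in the layout"):
            aggregate_wells([_cell("H12", 1, 1.0)], LAYOUT)

    def test_undefined_pearson_omitted_from_mean(self):
        cells = [_cell("A1", 1, 1.0, pr=0.4), _cell("A1", 2, 1.0, pr=float("nan")),
                 _cell("A2", 1, 1.0)]
        s = {x.well_id: x for x in aggregate_wells(cells, LAYOUT)}
        assert s["A1"].mean_pr == pytest.approx(0.4)


class TestFoldChange:
    def test_identity(self):
        wells = [_summary("A1", "c", 10.0), _summary("A2", "c", 12.0)]
        assert fold_change(wells, wells) == pytest.approx(1.0)

    def test_seven_fold(self):
        control = [_summary("A1", "c", 10.0), _summary("A2", "c", 10.0)]
        treated = [_summary("B1", "t", 70.0), _summary("B2", "t", 70.0)]
        assert fold_change(treated, control) == pytest.approx(7.0)

    def test_reciprocity(self):
        control = [_summary("A1", "c", 8.0), _summary("A2", "c", 12.0)]
        treated = [_summary("B1", "t", 33.0), _summary("B2", "t", 27.0)]
        assert fold_change(control, treated) == pytest.approx(
            1.0 / fold_change(treated, control))

    def test_zero_control_raises(self):
        control = [_summary("A1", "c", 0.0)]
        treated = [_summary("B1", "t", 1.0)]
        with pytest.raises(ValueError, match="control mean"):
            fold_change(treated, control)


class TestNormalizeToControl:
    def test_control_normalizes_to_unity(self):
        wells = [_summary("A1", "control", 9.0), _summary("A2", "control", 11.0)]
        normalize_to_control(wells, "control")
        assert np.mean([w.normalized_mean for w in wells]) == pytest.approx(1.0)

    def test_invariant_to_global_rescale(self):
        wells = [_summary("A1", "control", 10.0), _summary("A2", "kd", 3.0)]
        scaled = [_summary("A1", "control", 50.0), _summary("A2", "kd", 15.0)]
        normalize_to_control(wells, "control")
        normalize_to_control(scaled, "control")
        assert wells[1].normalized_mean == pytest.approx(scaled[1].normalized_mean)

    def test_missing_control_raises(self):
        with pytest.raises(ValueError, match="control"):
            normalize_to_control([_summary("A1", "kd", 3.0)], "control")


# Oracle dataset: 3 groups x 4 wells.  Expected values computed with R 4.3
# (aov + TukeyHSD, multcomp::glht Dunnett, t.test var.equal=TRUE) and frozen.
ORACLE_GROUPS = {
    "control": np.array([10.1, 12.3, 11.2, 9.8]),
    "fsk": np.array([14.2, 15.1, 13.3, 16.0]),
    "msh": np.array([10.9, 11.5, 12.8, 10.2]),
}
R_ANOVA_P = 0.00208398752139
R_TUKEY_P = {("control", "fsk"): 0.00274268117058,
             ("control", "msh"): 0.81145016927346,
             ("fsk", "msh"): 0.00666248906652}
R_DUNNETT_P = {"fsk": 0.00197886429265, "msh": 0.76456658265253}
R_TTEST_T, R_TTEST_P = -4.67158191428, 0.00342578858687


class TestCompareGroups:
    def test_tukey_matches_r_oracle(self):
        table = compare_groups(ORACLE_GROUPS, "anova_tukey")
        assert table.attrs["anova_p"] == pytest.approx(R_ANOVA_P, abs=1e-6)
        got = {(r.group1, r.group2): r.p_value for r in table.itertuples()}
        for pair, p in R_TUKEY_P.items():
            assert got[pair] == pytest.approx(p, abs=1e-6)

    def test_dunnett_matches_r_oracle(self):
        # both implementations integrate a multivariate t numerically;
        # agreement is asserted to the quadrature jitter, not 1e-6
        table = compare_groups(ORACLE_GROUPS, "anova_dunnett", control="control")
        got = {r.group1: r.p_value for r in table.itertuples()}
        for grp, p in R_DUNNETT_P.items():
            assert got[grp] == pytest.approx(p, abs=1e-3)

    def test_ttest_matches_r_oracle(self):
        table = compare_groups({k: ORACLE_GROUPS[k] for k in ("control", "fsk")},
                               "t_test")
        assert table.loc[0, "statistic"] == pytest.approx(R_TTEST_T, abs=1e-6)
        assert table.loc[0, "p_value"] == pytest.approx(R_TTEST_P, abs=1e-6)

    def test_identical_groups_p_is_one(self):
        table = compare_groups({"a": np.array([1.0, 2.0, 3.0]),
                                "b": np.array([1.0, 2.0, 3.0])}, "t_test")
        assert table.loc[0, "p_value"] == pytest.approx(1.0)
        assert table.loc[0, "stars"] == ""

    def test_overwhelming_separation_flags_three_stars(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(10.0, 1.0, 8)
        table = compare_groups({"a": a, "b": b}, "anova_tukey")
        assert table.loc[0, "p_value"] < 0.001
        assert table.loc[0, "stars"] == "***"

    def test_group_with_one_well_raises(self):
        with pytest.raises(ValueError, match="fewer than 2 wells"):
            compare_groups({"a": np.array([1.0]), "b": np.array([1.0, 2.0])},
                           "t_test")

    def test_dunnett_requires_valid_control(self):
        with pytest.raises(ValueError, match="control"):
            compare_groups(ORACLE_GROUPS, "anova_dunnett", control="nope")


def test_tukey_familywise_type_one_error_near_nominal():
    """Null simulation: 3 identical groups of 4 wells, 1000 replicates;
    the family-wise rejection rate at 0.05 stays within the binomial 99% CI."""
    rng = np.random.default_rng(2024)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        groups = {k: rng.normal(0.0, 1.0, 4) for k in ("a", "b", "c")}
        table = compare_groups(groups, "anova_tukey")
        if (table["p_value"] < 0.05).any():
            rejections += 1
    rate = rejections / reps
    half_width = 2.576 * math.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) <= half_width, f"family-wise rate {rate}"
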