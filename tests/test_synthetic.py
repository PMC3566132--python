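"""Properties of the synthetic plate generator: determinism, conservation of
rim-positive area against its own rasterized masks, linearity in the
intensity scale, convergence of the per-cell truth to the condition mean,
and monotonicity in the effect size."""

import numpy as np
import pytest

from dropquant.config import AcquisitionConfig
from dropquant.plateio import PlateLayout
from dropquant.synthetic import (ConditionSpec, FieldModel, assign_wells,
                                 generate_field, generate_plate)


def _cond(mean, cells=20.0, **kw):
    return ConditionSpec("c", rim_positive_area_mean_um2=mean,
                         cells_per_field_mean=cells, **kw)


def test_same_seed_gives_identical_field_and_truth(acq_small):
    a_fis, a_truth = generate_field(_cond(25.0), acq_small, rng_seed=3)
    b_fis, b_truth = generate_field(_cond(25.0), acq_small, rng_seed=3)
    for ch in acq_small.channel_names:
        np.testing.assert_array_equal(a_fis.channels[ch], b_fis.channels[ch])
    assert [t.__dict__ for t in a_truth] == [t.__dict__ for t in b_truth]
    c_fis, _ = generate_field(_cond(25.0), acq_small, rng_seed=4)
    assert any(not np.array_equal(a_fis.channels[ch], c_fis.channels[ch])
               for ch in acq_small.channel_names)


def test_zero_effect_condition_has_no_positive_rim(acq_small):
    cond = _cond(0.0)
    fis, truths = generate_field(cond, acq_small, rng_seed=5)
    assert truths, "expected some cells"
    assert all(t.true_rim_positive_area_um2 == 0.0 for t in truths)
    assert all(t.true_total_protein_intensity == 0.0 for t in truths)
    # protein channel is background + noise only: far below any rim signal
    model = FieldModel()
    assert fis.channels["protein1"].max() < model.background[2] + 15 * model.read_noise_sigma


def test_intensity_scale_doubles_truth_intensity_not_area(acq_small):
    base = _cond(30.0)
    doubled = ConditionSpec("c", 30.0, cells_per_field_mean=20.0,
                            protein_intensity_scale=2.0)
    _, t1 = generate_field(base, acq_small, rng_seed=11)
    _, t2 = generate_field(doubled, acq_small, rng_seed=11)
    for a, b in zip(t1, t2):
        assert b.true_rim_positive_area_um2 == a.true_rim_positive_area_um2
        assert b.true_total_protein_intensity == pytest.approx(
            2.0 * a.true_total_protein_intensity)


def test_rim_positive_area_matches_pixel_count_of_masks(sparse_field, acq):
    """Brute-force oracle: emitted truth equals the pixel count of the
    generator's own positive-rim mask times the pixel area."""
    _, truths, masks = sparse_field
    for t in truths:
        counted = masks["rim_positive"][t.cell_id].sum() * acq.pixel_area_um2
        assert abs(counted - t.true_rim_positive_area_um2) <= acq.pixel_area_um2
        counted2 = masks["rim_positive_p2"][t.cell_id].sum() * acq.pixel_area_um2
        assert abs(counted2 - t.true_rim_positive_area_um2_p2) <= acq.pixel_area_um2
        droplets = masks["droplets"][t.cell_id].sum() * acq.pixel_area_um2
        assert droplets == pytest.approx(t.true_droplet_area_um2)


def test_truth_mean_converges_to_condition_mean(acq):
    """Law of large numbers over >=2000 cells at a mid-range effect size."""
    cond = _cond(30.0, cells=150.0)
    areas = []
    seed = 0
    while len(areas) < 2000:
        _, truths = generate_field(cond, acq, rng_seed=1000 + seed)
        areas += [t.true_rim_positive_area_um2 for t in truths]
        seed += 1
    mean = float(np.mean(areas))
    assert mean == pytest.approx(30.0, rel=0.04)


def test_expected_truth_increases_with_effect_size(acq_small):
    means = []
    for target in (10.0, 40.0, 120.0):
        areas = []
        for s in range(4):
            _, truths = generate_field(_cond(target, cells=25.0), acq_small,
                                       rng_seed=50 + s)
            areas += [t.true_rim_positive_area_um2 for t in truths]
        means.append(np.mean(areas))
    assert means[0] < means[1] < means[2]


def test_impossible_density_raises_naming_parameter(acq_small):
    with pytest.raises(ValueError, match="cells_per_field_mean"):
        generate_field(_cond(10.0, cells=5000.0), acq_small, rng_seed=1)


def test_nucleus_centers_inside_field(sparse_field, acq):
    _, truths, _ = sparse_field
    for t in truths:
        r, c = t.nucleus_center_px
        assert 0 <= r < acq.image_height_px
        assert 0 <= c < acq.image_width_px


class TestGeneratePlate:
    tiny_acq = AcquisitionConfig(image_width_px=96, image_height_px=96)

    def _conditions(self):
        return [ConditionSpec("control", 10.0, n_wells=3, cells_per_field_mean=3.0),
                ConditionSpec("fsk", 40.0, n_wells=3, cells_per_field_mean=3.0)]

    def test_file_count_and_layout(self, tmp_path):
        layout, truth = generate_plate(self._conditions(), self.tiny_acq,
                                       fields_per_well=4, master_seed=9,
                                       out_dir=tmp_path)
        images = list(tmp_path.glob("*.tif"))
        assert len(images) == 2 * 3 * 4 * 4  # conditions x wells x fields x channels
        assert len(layout.rows) == 6
        assert (tmp_path / "layout.csv").exists()
        reread = PlateLayout.read_csv(tmp_path / "layout.csv")
        assert reread.rows.keys() == layout.rows.keys()

    def test_same_master_seed_is_byte_identical(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_plate(self._conditions(), self.tiny_acq, 2, 9, out_dir=d1)
        generate_plate(self._conditions(), self.tiny_acq, 2, 9, out_dir=d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_duplicate_well_assignment_raises(self):
        with pytest.raises(ValueError, match="duplicate well"):
            assign_wells(self._conditions(),
                         well_assignments={"control": ["A1", "A2", "A3"],
                                           "fsk": ["A3", "A4", "A5"]})
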