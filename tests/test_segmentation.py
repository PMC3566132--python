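"""Nucleus detection and nearest-nucleus territory assignment, checked
against constructed fixtures, a per-pixel brute-force oracle, and the
simulator's ground truth."""

import numpy as np
import pytest
from skimage.draw import disk

from dropquant.config import AcquisitionConfig
from dropquant.segmentation import (SegmentationParams, estimate_cell_boundaries,
                                    match_cells_to_truth, segment_nuclei)
from dropquant.synthetic import ConditionSpec, generate_field

ACQ64 = AcquisitionConfig(image_width_px=64, image_height_px=64)


def _nucleus_image(centers, radius=6, shape=(64, 64), amplitude=3000, bg=100):
    img = np.full(shape, float(bg))
    for c in centers:
        rr, cc = disk(c, radius, shape=shape)
        img[rr, cc] = amplitude
    rng = np.random.default_rng(0)
    return img + rng.normal(0, 5, shape)


def test_uniform_image_yields_zero_nuclei():
    labels = segment_nuclei(np.full((64, 64), 100.0), ACQ64)
    assert labels.max() == 0
    cell_map = estimate_cell_boundaries(labels, ACQ64)
    assert cell_map.cell_labels.max() == 0


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SegmentationParams(k_sigma=0)
    with pytest.raises(ValueError):
        SegmentationParams(min_nucleus_area_um2=-1)


def test_simulated_nuclei_centroids_recovered(acq):
    cond = ConditionSpec("c", 0.0, cells_per_field_mean=5.0)
    fis, truths = generate_field(cond, acq, rng_seed=21)
    labels = segment_nuclei(fis.channels["nuclei"], acq)
    assert labels.max() == len(truths)
    from scipy import ndimage as ndi

    from dropquant.segmentation import CellLabelMap

    edge = CellLabelMap(labels, labels).edge_labels()
    coms = np.array(ndi.center_of_mass(labels > 0, labels,
                                       range(1, labels.max() + 1)))
    centers = np.array([t.nucleus_center_px for t in truths], float)
    d = np.linalg.norm(coms[:, None] - centers[None], axis=2)
    # interior nuclei localize to <=2 px; border-clipped ellipses shift
    interior = [lab - 1 for lab in range(1, labels.max() + 1) if lab not in edge]
    assert len(interior) >= 3
    assert (d.min(axis=1)[interior] <= 2.0).all()


def test_touching_nuclei_split_by_watershed():
    # two disks with centers 1.5 radii apart: one blob unless split
    img = _nucleus_image([(32, 27), (32, 42)], radius=10)
    merged = segment_nuclei(img, ACQ64, SegmentationParams(split_touching=False))
    assert merged.max() == 1
    split = segment_nuclei(img, ACQ64, SegmentationParams(split_touching=True))
    assert split.max() == 2


def test_single_nucleus_unbounded_covers_field():
    img = _nucleus_image([(30, 30)])
    labels = segment_nuclei(img, ACQ64)
    cell_map = estimate_cell_boundaries(labels, ACQ64,
                                        params=SegmentationParams(max_radius_um=None))
    assert (cell_map.cell_labels == 1).all()


def test_two_seeds_split_at_perpendicular_bisector():
    nuclei = np.zeros((21, 40), np.int32)
    nuclei[10, 10] = 1
    nuclei[10, 30] = 2
    cell_map = estimate_cell_boundaries(nuclei, ACQ64,
                                        params=SegmentationParams(max_radius_um=None))
    # bisector at column 20; ties go to the lower label
    assert (cell_map.cell_labels[:, :21] == 1).all()
    assert (cell_map.cell_labels[:, 21:] == 2).all()


def _brute_force_nearest(nuclei, max_radius_px):
    """Per-pixel nearest-seed assignment with lower-label tie-break."""
    shape = nuclei.shape
    out = np.zeros(shape, np.int32)
    labels = sorted(set(nuclei.ravel()) - {0})
    coords = {lab: np.argwhere(nuclei == lab) for lab in labels}
    for r in range(shape[0]):
        for c in range(shape[1]):
            best, best_d = 0, np.inf if max_radius_px is None else float(max_radius_px)
            for lab in labels:
                pts = coords[lab]
                d = np.sqrt(((pts - (r, c)) ** 2).sum(axis=1).min())
                if d < best_d:
                    best, best_d = lab, d
            out[r, c] = best
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("max_radius_um", [None, 12.0])
def test_territories_equal_brute_force_oracle(seed, max_radius_um):
    rng = np.random.default_rng(seed)
    shape = (64, 64)
    nuclei = np.zeros(shape, np.int32)
    n = rng.integers(2, 6)
    pts = rng.integers(0, 64, size=(n, 2))
    for i, (r, c) in enumerate(pts):
        nuclei[r, c] = 0 if nuclei[r, c] else i + 1
    nuclei = _relabel(nuclei)
    acq = AcquisitionConfig(image_width_px=64, image_height_px=64, pixel_pitch_um=1.0)
    params = SegmentationParams(max_radius_um=max_radius_um)
    got = estimate_cell_boundaries(nuclei, acq, params=params).cell_labels
    want = _brute_force_nearest(nuclei, max_radius_um)
    np.testing.assert_array_equal(got, want)


def _relabel(nuclei):
    from skimage.segmentation import relabel_sequential

    return relabel_sequential(nuclei)[0].astype(np.int32)


def test_partition_contract(sparse_processed, acq):
    _, _, _, cell_map, _ = sparse_processed
    cells = cell_map.cell_labels
    nuclei = cell_map.nuclei_labels
    # each nucleus lies within its own territory
    for lab in range(1, cell_map.n_cells + 1):
        assert (cells[nuclei == lab] == lab).all()
    # labels are consecutive from 1
    assert set(np.unique(nuclei)) - {0} == set(range(1, cell_map.n_cells + 1))


def test_ground_truth_recovery_rate(acq):
    """At defaults and low noise, nearly all simulated cells are found 1:1."""
    cond = ConditionSpec("c", 30.0, cells_per_field_mean=80.0)
    fis, truths = generate_field(cond, acq, rng_seed=33)
    labels = segment_nuclei(fis.channels["nuclei"], acq)
    cell_map = estimate_cell_boundaries(labels, acq)
    centers = np.array([t.nucleus_center_px for t in truths], float)
    matched = match_cells_to_truth(cell_map, centers, max_dist_px=5.0)
    assert len(matched) >= 0.95 * len(truths)
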