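import pytest

from dropquant.config import AcquisitionConfig
from dropquant.masking import MaskParams
from dropquant.pipeline import process_field
from dropquant.segmentation import SegmentationParams
from dropquant.synthetic import ConditionSpec, generate_field


@pytest.fixture(scope="session")
def acq():
    """Default 20x acquisition, 512x512, 16-bit."""
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def acq_small():
    return AcquisitionConfig(image_width_px=256, image_height_px=256)


@pytest.fixture(scope="session")
def sparse_condition():
    """Low density so each cell's droplet cluster sits inside its own territory."""
    return ConditionSpec("sparse", rim_positive_area_mean_um2=30.0,
                         rim_positive_area_cv=0.3, cells_per_field_mean=12.0)


@pytest.fixture(scope="session")
def sparse_field(sparse_condition, acq):
    """One low-density field with the generator's internal masks exposed."""
    fis, truths, masks = generate_field(sparse_condition, acq, rng_seed=7,
                                        return_masks=True)
    return fis, truths, masks


@pytest.fixture(scope="session")
def sparse_processed(sparse_field):
    fis, truths, masks = sparse_field
    records, cell_map, pipe_masks = process_field(
        fis, SegmentationParams(), MaskParams(), ("protein1", "protein2"))
    return fis, truths, records, cell_map, pipe_masks
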