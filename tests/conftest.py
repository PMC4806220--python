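import numpy as np
import pytest

from lesionrate import phantom as ph
from lesionrate import registration as reg
from lesionrate import segmentation as seg


@pytest.fixture(scope="session")
def small_params():
    """Desk-scale phantom parameters shared by unit tests (40^3 grid)."""
    return ph.PhantomParams(grid_shape=(40, 40, 40), times_years=(0.0, 1.0, 2.0),
                            random_seed=7)


@pytest.fixture(scope="session")
def small_subject(small_params):
    """One noisy subject with atrophy and WMH growth, plus its truth."""
    return ph.generate_subject(small_params, 0, (-0.01, 0.6))


@pytest.fixture(scope="session")
def clean_subject(small_params):
    """Noise-free copy of the same subject geometry."""
    p = ph.PhantomParams(**{**small_params.__dict__, "noise_sd": (0.0, 0.0)})
    return ph.generate_subject(p, 0, (-0.01, 0.6))


@pytest.fixture(scope="session")
def fast_reg_config():
    return reg.RegConfig(iters=(20, 15, 8))


@pytest.fixture(scope="session")
def segmented_subject(small_subject):
    """Two-pass segmentation of the small subject (posteriors + WMH masks)."""
    from lesionrate.experiments import segment_subject

    series, truth = small_subject
    posteriors, masks, tpms = segment_subject(series, truth)
    return posteriors, masks, tpms


def truth_channels(label_map):
    """Repaired-style 3-class channels (CSF, GM, WM) from truth labels."""
    return [
        ((label_map == ph.CSF) | (label_map == ph.LACUNE)).astype(float),
        (label_map == ph.GM).astype(float),
        ((label_map == ph.WM) | (label_map == ph.WMH)).astype(float),
    ]


def dice(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.sum(a & b) / denom if denom else 1.0
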