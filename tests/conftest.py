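import logging

import numpy as np
import pytest

from mtquant.synth import CellImageParams, GrowthConeParams, make_cell_image, make_growthcone_image

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def cell_fixture():
    """One default noisy cell image (partition 0.3) with its ground truth."""
    return make_cell_image(CellImageParams(tyr_glu_partition=0.3), seed=42)


@pytest.fixture(scope="session")
def cone_fixture():
    """One default growth cone (15% invasion) with its ground truth."""
    return make_growthcone_image(GrowthConeParams(true_invasion_fraction=0.15), seed=42)
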