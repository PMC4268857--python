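import numpy as np
import pytest

import stromalens as sl


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic expression cohort (n=300, 2000 genes), seed 0."""
    expr, truth = sl.generate_cohort_expression(seed=0)
    return expr, truth


@pytest.fixture(scope="session")
def he_tile():
    """One synthetic H&E tile with a 0.40 stromal fraction."""
    rgb, tissue, stroma, achieved = sl.generate_he_image(0.40, seed=11)
    return rgb, tissue, stroma, achieved


@pytest.fixture
def rng():
    return np.random.default_rng(42)
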