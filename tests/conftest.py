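import numpy as np
import pytest

from mbester import design, rsm


@pytest.fixture(scope="session")
def bbd17() -> design.DesignTable:
    """The 17-run Box-Behnken design at the study's factor ranges."""
    return design.build_bbd(design.PAPER_FACTORS, n_center=5)


@pytest.fixture(scope="session")
def noiseless_table(bbd17) -> design.DesignTable:
    """BBD table with responses exactly from the published quadratic."""
    y = rsm.design_matrix(bbd17.coded) @ rsm.REFERENCE_MODEL.coefficients
    return bbd17.with_responses(y)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
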