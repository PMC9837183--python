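import numpy as np
import pytest

from bcseg.phantom import DEFAULT_TISSUES, PhantomTissues, TissueParams, synthesize_case


@pytest.fixture(scope="session")
def small_case():
    """One deterministic small phantom with realistic noise."""
    return synthesize_case(shape=(8, 64, 64), seed=42)


@pytest.fixture(scope="session")
def noiseless_tissues():
    """Tissue set with zero within-tissue variability (pure decay law)."""
    return PhantomTissues(
        background=TissueParams(30.0, 2.0),
        wall=TissueParams(200.0, 1.6),
        urine=TissueParams(1000.0, 3.0),
        tumor=TissueParams(450.0, 0.9),
    )


@pytest.fixture(scope="session")
def noiseless_case(noiseless_tissues):
    return synthesize_case(
        shape=(8, 64, 64), tissues=noiseless_tissues, noise_sigma=0.0, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
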