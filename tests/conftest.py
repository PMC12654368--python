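import numpy as np
import pytest

from odorkit import CompoundRecord, CurationConfig
from odorkit.synthetic import SynthSpec, gen_corpus


@pytest.fixture(scope="session")
def curation_config() -> CurationConfig:
    return CurationConfig.default()


@pytest.fixture(scope="session")
def small_corpus() -> list[CompoundRecord]:
    """120 synthetic compounds with structure-determined labels/thresholds."""
    return gen_corpus(SynthSpec(n_molecules=120, seed=42))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
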