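import numpy as np
import pytest

from aluhic.cifilter import stratify_and_filter
from aluhic.enrichment import TEIndex
from aluhic.simulate import default_config, simulate_bundle

#: single session-wide bundle under the default study conditions
BUNDLE_SEED = 7


@pytest.fixture(scope="session")
def bundle():
    return simulate_bundle(default_config({"seed": BUNDLE_SEED}))


@pytest.fixture(scope="session")
def stratified(bundle):
    return stratify_and_filter(bundle.binpairs, bundle.domains)


@pytest.fixture(scope="session")
def te_index(bundle):
    return TEIndex(bundle.repeats)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
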