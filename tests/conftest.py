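import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from mitoweaver import reconcile, synthio


@pytest.fixture(scope="session")
def small_truth():
    """One small reticulate genome with its graph and contigs (seeded)."""
    spec = synthio.random_spec(11)
    return synthio.simulate_structure(spec)


@pytest.fixture(scope="session")
def small_structure(small_truth):
    truth, graph, contigs = small_truth
    st = reconcile.resolve_structure("acc", contigs, graph, truth.gene_models)
    return truth, graph, contigs, st


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
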