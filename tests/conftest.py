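import numpy as np
import pytest

from regionrates import SyntheticConfig, generate_proteome
from regionrates.io_formats import PhyloTree

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


@pytest.fixture(scope="session")
def four_taxon_tree() -> PhyloTree:
    return PhyloTree.from_newick("((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.07);")


@pytest.fixture(scope="session")
def small_proteome():
    """A small generated proteome shared by annotation/statistics tests."""
    config = SyntheticConfig(n_proteins=60, seed=1234)
    return generate_proteome(config)
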