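import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mircna import synthetic


@pytest.fixture(scope="session")
def small_genome():
    """Two 10 Mb chromosomes, 4 bands each, 50 genes, 30 miRNAs."""
    return synthetic.generate_genome(2, 4, 50, 30, seed=7)


@pytest.fixture(scope="session")
def tiny_genome():
    """One chromosome, one band, no features."""
    return synthetic.generate_genome(1, 1, 0, 0, seed=1)
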