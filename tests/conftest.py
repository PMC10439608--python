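import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from magcurate import ColumnSpec, CommunitySpec, build_table, generate_community


@pytest.fixture
def toy_table():
    """Five contigs with length/coverage/taxonomy/features."""
    rows = {
        "c1": {"length": 100, "coverage": 10.0, "genus": "Escherichia", "ko": "K00001,K00001"},
        "c2": {"length": 300, "coverage": 20.0, "genus": "Escherichia", "ko": "K00002"},
        "c3": {"length": 2000, "coverage": 1.5, "genus": "Bacteroides", "ko": ""},
        "c4": {"length": 5000, "coverage": 0.5, "genus": None, "ko": "K00003,dsrA"},
        "c5": {"length": 800, "coverage": 3.0, "genus": "Clostridium", "ko": "K00001"},
    }
    specs = [
        ColumnSpec("length", "numeric"),
        ColumnSpec("coverage", "numeric"),
        ColumnSpec("genus", "categorical"),
        ColumnSpec("ko", "feature_set"),
    ]
    return build_table(rows, specs)


@pytest.fixture(scope="session")
def community():
    """Default synthetic community (5 well-separated genomes, seed 42)."""
    return generate_community(CommunitySpec(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(7)
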