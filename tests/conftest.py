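import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes tests/oracle.py importable

from seedimprint.simulate import SimConfig, simulate_allelic_counts


@pytest.fixture(scope="session")
def null_tables():
    """10,000 purely biallelic genes at the 2:1 triploid null, depths 20-200."""
    config = SimConfig(n_genes=10_000, frac_meg=0.0, frac_peg=0.0,
                       depth_range=(20, 200), seed=20160919)
    return simulate_allelic_counts(config)


@pytest.fixture(scope="session")
def planted_meg_tables():
    """Deep (>=100 reads) simulation with a planted 5% MEG / 2% PEG minority."""
    config = SimConfig(n_genes=2_000, frac_meg=0.05, frac_peg=0.02,
                       meg_maternal_fraction=0.95, peg_maternal_fraction=0.15,
                       depth_range=(100, 300), seed=20160919)
    return simulate_allelic_counts(config)
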