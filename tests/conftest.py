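import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from exmeth.meth_io import CpGCallTable
from exmeth.synthetic import SimConfig, simulate_all


def make_calls(records, sample_id="s1") -> CpGCallTable:
    """Build a call table from (chrom, pos, meth, total) tuples."""
    df = pd.DataFrame(records, columns=["chrom", "pos", "meth", "total"])
    df["rate"] = df["meth"] / df["total"]
    return CpGCallTable(sample_id=sample_id, df=df)


@pytest.fixture
def calls_factory():
    return make_calls


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale synthetic study shared across tests."""
    return simulate_all(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_sim():
    """A reduced synthetic study for fast integration checks."""
    cfg = SimConfig(
        seed=7,
        n_autosomes=2,
        include_x=True,
        chrom_length=400_000,
        n_cgis=60,
        n_genes=80,
        n_high_genes=8,
        n_low_genes=8,
        n_cells=400,
    )
    return cfg, simulate_all(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
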