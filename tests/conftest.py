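import pandas as pd
import pytest

from methylink import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort shared across test modules."""
    return simulate_cohort(SimulationConfig(seed=1234))


@pytest.fixture()
def toy_domains():
    """Hand-sized 100-kb unit table: 4 PMD units, 3 HMD units, 3 PMD units."""
    rows = []
    for i in range(4):
        rows.append(("chr1", i * 100_000, (i + 1) * 100_000, "PMD", 0.2, -1.0))
    for i in range(4, 7):
        rows.append(("chr1", i * 100_000, (i + 1) * 100_000, "HMD", 0.03, 1.0))
    for i in range(7, 10):
        rows.append(("chr1", i * 100_000, (i + 1) * 100_000, "PMD", 0.2, -1.0))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "dtype", "meth_variability", "rep_timing"])
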