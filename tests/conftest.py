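import numpy as np
import pandas as pd
import pytest

from beesym import simdata as sd
from beesym._distance import DistanceMatrix


@pytest.fixture
def host_tree():
    return sd.default_host_tree()


@pytest.fixture(scope="session")
def host_dm():
    host_tree = sd.default_host_tree()
    from beesym.cophylo import patristic_matrix

    return patristic_matrix(host_tree)


def make_dm(values, prefix="s") -> DistanceMatrix:
    values = np.asarray(values, dtype=float)
    labels = [f"{prefix}{i}" for i in range(values.shape[0])]
    return DistanceMatrix(labels, values)


@pytest.fixture
def allele_table_factory():
    """Build a one-sample allele table from (position, coverage, fA, fC, fG, fT) rows."""

    def build(rows, sample_id="s1", species_id="sp1"):
        df = pd.DataFrame(
            rows,
            columns=["position", "coverage", "freq_A", "freq_C", "freq_G", "freq_T"],
        )
        df.insert(0, "species_id", species_id)
        df.insert(1, "sample_id", sample_id)
        return df

    return build


@pytest.fixture
def two_host_metadata():
    rows = [
        {"sample_id": f"h{h}_s{j}", "host_species": f"host{h}", "location": "loc1"}
        for h in range(2)
        for j in range(10)
    ]
    return pd.DataFrame(rows).set_index("sample_id")
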