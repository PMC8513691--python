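import numpy as np
import pandas as pd
import pytest

from tephraseq import synthetic_community as sc
from tephraseq import decontamination as dc
from tephraseq.tables_io import FeatureTable

# Four-set Venn-region occupancies of the published overlap worked example:
# the six subaerial regions shared with drilling fluid or seawater
# (93+84+14+11+16+14), the submarine-and-drilling-fluid-only region (128)
# and the retained triple region (61).  The remaining regions are filled
# with synthetic counts; the classifier's labels do not depend on them.
REFERENCE_VENN_OCCUPANCIES = {
    "SUB_A+DF": 93,
    "SUB_A+SW": 84,
    "SUB_A+DF+SW": 14,
    "SUB_A+SUB_M+DF": 11,
    "SUB_A+SUB_M+SW": 16,
    "SUB_A+SUB_M+DF+SW": 14,
    "SUB_M+DF": 128,
    "SUB_M+DF+SW": 61,
    # synthetic filler for the endemic/unique regions
    "SUB_A": 180,
    "SUB_M": 1450,
    "DF": 210,
    "SW": 150,
    "SUB_A+SUB_M": 55,
    "SUB_M+SW": 45,
    "DF+SW": 95,
}


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic dataset (seed 42), shared across tests."""
    return sc.simulate_dataset(sc.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def cascade_run(default_sim):
    dataset, truth = default_sim
    calls, patterns = dc.run_cascade(dataset, blocklist_genera=sc.DEFAULT_BLOCKLIST)
    return dataset, truth, calls, patterns


@pytest.fixture()
def toy_table():
    return FeatureTable(
        pd.DataFrame(
            [[3, 0, 5], [1, 5, 0], [2, 2, 2]],
            index=["ASV1", "ASV2", "ASV3"],
            columns=["S1", "S2", "S3"],
        )
    )


def make_table(counts, features=None, samples=None) -> FeatureTable:
    counts = np.asarray(counts)
    features = features or [f"F{i}" for i in range(counts.shape[0])]
    samples = samples or [f"S{j}" for j in range(counts.shape[1])]
    return FeatureTable(pd.DataFrame(counts, index=features, columns=samples))
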