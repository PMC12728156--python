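import numpy as np
import pandas as pd
import pytest

from pdoimmune import simulate as sim
from pdoimmune.types import ExpressionMatrix, SampleMetadata


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort for fast unit tests (structure, not power)."""
    return sim.SimulationConfig(seed=11, n_genes=120, n_cells_per_type=100,
                                n_clones=100, n_validation_patients=30)


@pytest.fixture(scope="session")
def small_bulk(small_config):
    return sim.simulate_bulk(small_config)


@pytest.fixture(scope="session")
def small_cells(small_config):
    return sim.simulate_cells(small_config)


@pytest.fixture(scope="session")
def default_bulk():
    """One full-size cohort shared across tests that need planted power."""
    return sim.simulate_bulk(sim.SimulationConfig(seed=3))


@pytest.fixture
def toy_matrix():
    values = pd.DataFrame(
        {"s1": [1.0, 3.0], "s2": [2.0, 2.0], "s3": [3.0, 1.0]},
        index=pd.Index(["gA", "gB"], name="gene_id"),
    )
    return ExpressionMatrix(values, scale="log2")


@pytest.fixture
def paired_metadata():
    records = []
    for pat, resp in [("P1", "responder"), ("P2", "responder"),
                      ("P3", "non_responder"), ("P4", "non_responder")]:
        records.append(SampleMetadata(sample_id=f"{pat}_B", patient_id=pat,
                                      tissue="pdo", timepoint="baseline", response=resp))
        records.append(SampleMetadata(sample_id=f"{pat}_S", patient_id=pat,
                                      tissue="pdo", timepoint="stimulated", response=resp))
    return records
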