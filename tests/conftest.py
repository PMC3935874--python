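import numpy as np
import pandas as pd
import pytest

from miratlas import datasets
from miratlas.ingest import SampleMatrix


@pytest.fixture(scope="session")
def demo_atlas():
    return datasets.demo_cell_atlas()


@pytest.fixture(scope="session")
def demo_key():
    return datasets.demo_nomenclature_key()


@pytest.fixture(scope="session")
def demo_map():
    return datasets.demo_disease_map()


@pytest.fixture(scope="session")
def tb_reports():
    return datasets.tuberculosis_reports()


@pytest.fixture(scope="session")
def study_grid():
    return datasets.synthetic_study_grid()


def make_matrix(values: np.ndarray, *, batch=None, label=None, prefix="s") -> SampleMatrix:
    """Wrap a samples × features array into a SampleMatrix with stub metadata."""
    n, g = values.shape
    idx = [f"{prefix}{i:03d}" for i in range(n)]
    cols = [f"g{j:03d}" for j in range(g)]
    meta = pd.DataFrame(
        {
            "label": label if label is not None else ["cellA"] * n,
            "platform_version": "V1",
            "batch_id": batch if batch is not None else ["chip0"] * n,
        },
        index=idx,
    )
    return SampleMatrix(pd.DataFrame(values, index=idx, columns=cols), meta)
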