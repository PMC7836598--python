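import numpy as np
import pandas as pd
import pytest

from hyposig.datatypes import ClinicalTable, ExpressionMatrix


@pytest.fixture
def worked_matrix() -> ExpressionMatrix:
    """The hand-checkable 2-gene / 4-sample matrix: g1 ascending, g2 descending."""
    return ExpressionMatrix(pd.DataFrame(
        {"s1": [1.0, 4.0], "s2": [2.0, 3.0], "s3": [3.0, 2.0], "s4": [4.0, 1.0]},
        index=["g1", "g2"],
    ))


def make_clinical(n: int, rng: np.random.Generator, **overrides) -> ClinicalTable:
    """A structurally valid clinical table with random content."""
    data = {
        "sample_id": [f"P{i:03d}" for i in range(n)],
        "os_time": rng.exponential(20, n),
        "os_event": rng.integers(0, 2, n),
        "pfs_time": rng.exponential(12, n),
        "pfs_event": rng.integers(0, 2, n),
        "stage": rng.choice(["I", "II", "III/IV"], n).tolist(),
        "grade": rng.choice(["G1", "G2", "G3/G4"], n).tolist(),
        "residual": rng.integers(0, 2, n),
        "gender": rng.integers(0, 2, n),
    }
    data.update(overrides)
    return ClinicalTable(pd.DataFrame(data))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20210126)
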