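import numpy as np
import pandas as pd
import pytest

from mirsig.io_formats import ExpressionMatrix, SampleSheet


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 features x 2 samples, one not-detected cell, with a U6 row."""
    data = pd.DataFrame(
        {
            "s1": [500.0, 120.0, 1000.0],
            "s2": [450.0, np.nan, 1000.0],
        },
        index=["miR-1", "miR-2", "U6"],
    )
    return ExpressionMatrix(data, normalizer_id="U6")


@pytest.fixture
def rat_sheet_12() -> SampleSheet:
    """One-source rat design: 6 control vs 6 HFD case samples."""
    rows = []
    for i in range(1, 7):
        rows.append((f"c{i}", f"rat-ctl-{i}", "rat", "pancreas", "control", ""))
    for i in range(1, 7):
        rows.append((f"t{i}", f"rat-hfd-{i}", "rat", "pancreas", "case", "HFD"))
    return SampleSheet(
        pd.DataFrame(rows, columns=["sample_id", "subject_id", "species", "source", "group", "case_label"])
    )


def make_matrix(values: np.ndarray, features=None, samples=None, normalizer_id=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples), normalizer_id)
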