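import numpy as np
import pandas as pd
import pytest

from hces.core import CLASS, CONTINUOUS, DISCRETE, PREDICTOR, AttributeSpec, DataTable


def build_table(class_col, predictors: dict, continuous=()) -> DataTable:
    """Assemble a DataTable from raw columns.

    ``class_col`` values must be 0/1; discrete predictor states are the
    sorted distinct values observed.
    """
    specs = [AttributeSpec("Exacer", DISCRETE, CLASS, ("0", "1"))]
    data = {"Exacer": [str(int(v)) for v in class_col]}
    for name, vals in predictors.items():
        if name in continuous:
            specs.append(AttributeSpec(name, CONTINUOUS, PREDICTOR))
            data[name] = [float(v) for v in vals]
        else:
            svals = [str(v) for v in vals]
            states = tuple(sorted(set(svals)))
            specs.append(AttributeSpec(name, DISCRETE, PREDICTOR, states))
            data[name] = svals
    frame = pd.DataFrame(data, columns=list(data))
    return DataTable(frame, specs)


@pytest.fixture
def xor_table() -> DataTable:
    """8-row worked table: A = class copy, B = xor-ish, C = constant."""
    y = [0, 0, 0, 0, 1, 1, 1, 1]
    return build_table(
        y,
        {
            "A": [0, 0, 0, 0, 1, 1, 1, 1],
            "B": [0, 1, 0, 1, 1, 0, 1, 1],
            "C": [0, 0, 0, 0, 0, 0, 0, 0],
        },
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


def random_discrete_table(rng, n=60, p=4, k=2, informative=True) -> DataTable:
    """Random discrete table; when informative, the first predictor leans
    with the class."""
    y = rng.integers(0, 2, size=n)
    while len(set(y.tolist())) < 2:
        y = rng.integers(0, 2, size=n)
    preds = {}
    for j in range(p):
        if informative and j == 0:
            vals = np.where(rng.random(n) < 0.8, y % k, rng.integers(0, k, n))
        else:
            vals = rng.integers(0, k, size=n)
        preds[f"P{j}"] = vals
    return build_table(y, preds)
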