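"""Shared fixtures: small synthetic studies generated at test time."""

import numpy as np
import pandas as pd
import pytest

from toxclass.datatypes import CLASS_A, CLASS_B, CONTROL, ContrastMatrix, SampleMetadata
from toxclass.simulate import CompoundSpec, SyntheticConfig, generate_dataset
from toxclass import preprocess


@pytest.fixture(scope="session")
def mini_config():
    """Small two-class study: 8 compounds x 3 replicates, 400 probes."""
    compounds = tuple(
        CompoundSpec(f"a{i}", CLASS_A, 3, 25) for i in range(4)
    ) + tuple(CompoundSpec(f"b{i}", CLASS_B, 3, 25) for i in range(4))
    return SyntheticConfig(
        n_probesets=400,
        n_genes=300,
        compounds=compounds,
        n_controls=12,
        n_shared_per_class=40,
        seed=42,
    )


@pytest.fixture(scope="session")
def mini_dataset(mini_config):
    return generate_dataset(mini_config)


@pytest.fixture(scope="session")
def mini_contrasts(mini_dataset):
    expr, meta, annot, truth = mini_dataset
    return preprocess.subtract_controls(expr, meta), meta


@pytest.fixture()
def tiny_paired():
    """Hand-built 3-probe expression with 2 treated + 3 control samples."""
    expr_df = pd.DataFrame(
        {
            "t1": [6.0, 1.0, 0.0],
            "t2": [2.0, 2.0, 5.0],
            "c1": [3.0, 1.0, 0.0],
            "c2": [5.0, 3.0, 4.0],
            "c3": [2.0, 2.0, 5.0],
        },
        index=["P1", "P2", "P3"],
    )
    rows = [
        ("c1", CONTROL, CONTROL, "B1", 1, []),
        ("c2", CONTROL, CONTROL, "B1", 2, []),
        ("c3", CONTROL, CONTROL, "B2", 3, []),
        ("t1", "drugA", CLASS_A, "B1", 1, ["c1", "c2"]),
        ("t2", "drugB", CLASS_B, "B2", 1, ["c3"]),
    ]
    meta = SampleMetadata(pd.DataFrame(rows, columns=SampleMetadata.COLUMNS))
    from toxclass.datatypes import ExpressionMatrix

    return ExpressionMatrix(expr_df), meta


def make_contrasts(values: np.ndarray, compounds: dict[str, int]):
    """Build a ContrastMatrix + SampleMetadata from a dense array.

    ``compounds`` maps compound name -> number of replicate columns; class
    is CLASS_A for names starting with 'a', CLASS_B otherwise. Column
    order follows the dict order.
    """
    n_probes = values.shape[0]
    rows = [("ctrl1", CONTROL, CONTROL, "B1", 1, [])]
    cols = []
    for name, n_rep in compounds.items():
        cls = CLASS_A if name.startswith("a") else CLASS_B
        for r in range(n_rep):
            sid = f"{name}_r{r + 1}"
            cols.append(sid)
            rows.append((sid, name, cls, "B1", r + 1, ["ctrl1"]))
    assert values.shape[1] == len(cols)
    meta = SampleMetadata(pd.DataFrame(rows, columns=SampleMetadata.COLUMNS))
    con = ContrastMatrix(
        pd.DataFrame(values, index=[f"P{i:03d}" for i in range(n_probes)], columns=cols)
    )
    return con, meta
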