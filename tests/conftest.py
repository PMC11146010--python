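import numpy as np
import pandas as pd
import pytest

from subloc import synth
from subloc.annotation import ExpressionTable


@pytest.fixture(scope="session")
def synthetic_universe():
    """One seeded 2000-gene synthetic dataset shared across tests."""
    expr, truth = synth.simulate_expression(n_genes=2000, seed=42)
    return expr, truth


@pytest.fixture()
def tiny_expression():
    """Three genes x three compartments, two replicates, hand-checkable."""
    values = pd.DataFrame(
        {
            "TG_1": [2.0, 1.0, 0.0], "TG_2": [4.0, 1.0, 0.0],
            "ER_1": [3.0, 1.0, 0.0], "ER_2": [3.0, 1.0, 0.0],
            "CY_1": [5.0, 1.0, 0.0], "CY_2": [5.0, 1.0, 0.0],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    samples = pd.DataFrame(
        {
            "sample_id": values.columns,
            "compartment": [c.split("_")[0] for c in values.columns],
            "replicate": [int(c.split("_")[1]) for c in values.columns],
            "condition": "control",
        }
    )
    return ExpressionTable(values=values, samples=samples)


def make_expression(matrix: dict, genes, condition="control") -> ExpressionTable:
    """Helper: expression table from a {sample_id: values} dict."""
    values = pd.DataFrame(matrix, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame({
        "sample_id": list(matrix),
        "compartment": [s.split("_")[0] for s in matrix],
        "replicate": [int(s.split("_")[1]) for s in matrix],
        "condition": condition,
    })
    return ExpressionTable(values=values, samples=samples)
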