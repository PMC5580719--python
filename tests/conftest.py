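"""Shared fixtures: synthetic studies generated once per session."""

import numpy as np
import pandas as pd
import pytest

from lncbrain import core_io, synthetic_data as sd


@pytest.fixture(scope="session")
def planted_study():
    """Default planted study (modules, sex bias, CAGE), seed 1."""
    return sd.simulate_study(sd.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def null_study():
    """No planted effects: 2000 exchangeable genes, seed 3."""
    return sd.simulate_study(sd.null_config(n_genes=2000, seed=3))


@pytest.fixture()
def small_matrix():
    """A tiny hand-built expression matrix over a 2-region, 2-age design."""
    samples = pd.DataFrame(
        {
            "region": ["PFC", "PFC", "PFC", "PFC", "CB", "CB", "CB", "CB"],
            "age": [1, 1, 4, 4, 1, 1, 4, 4],
            "sex": ["F", "M", "F", "M", "F", "M", "F", "M"],
        },
        index=[f"s{i}" for i in range(8)],
    )
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(5, 200, size=(10, 8)),
        index=[f"g{i}" for i in range(10)],
        columns=samples.index,
    )
    gene_info = pd.DataFrame(
        {
            "length": rng.integers(300, 2000, size=10),
            "class_label": ["mRNA"] * 5 + ["lnc_intergenic"] * 5,
        },
        index=counts.index,
    )
    return core_io.ExpressionMatrix(counts, samples, gene_info)
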