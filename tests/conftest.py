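import numpy as np
import pandas as pd
import pytest

import trisomethyl as tm


@pytest.fixture(scope="session")
def sheet() -> tm.SampleSheet:
    return tm.default_sample_sheet()


@pytest.fixture(scope="session")
def small_chrom_map() -> dict:
    return {"chr2": 120, "chr7": 120, "chr8": 150}


@pytest.fixture(scope="session")
def sim_expression(small_chrom_map):
    """One default-parameter expression simulation shared across tests."""
    return tm.simulate_expression(n_genes_per_chrom=small_chrom_map, seed=11)


def make_matrix(values: np.ndarray, probe_ids=None, sample_ids=None,
                chrom="chr1") -> tm.ExpressionMatrix:
    """Tiny ExpressionMatrix with generic annotation, for unit tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    probe_ids = probe_ids or [f"p{i}" for i in range(n)]
    sample_ids = sample_ids or [f"s{j}" for j in range(m)]
    annot = pd.DataFrame(
        {
            "gene_symbol": [f"g{i}" for i in range(n)],
            "chrom": chrom,
            "position": np.arange(n) * 1000,
            "biotype": "coding",
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return tm.ExpressionMatrix(
        pd.DataFrame(values, index=annot.index, columns=sample_ids), annot
    )
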