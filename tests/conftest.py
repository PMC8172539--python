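import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from impulscreen.io_formats import ExpressionDataset


@pytest.fixture
def toy_dataset():
    """4 genes x 6 cells with hand-chosen CPM values.

    Cells c0-c2 form a natural target set, c3-c5 a contrast set.
    gene0: strongly target-selective; gene1: flat housekeeping;
    gene2: all-zero; gene3: contrast-selective.
    """
    mat = np.array(
        [
            [50.0, 40.0, 60.0, 1.0, 0.0, 2.0],
            [10.0, 10.0, 10.0, 10.0, 10.0, 10.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [0.5, 0.0, 1.0, 30.0, 25.0, 35.0],
        ]
    )
    return ExpressionDataset(
        sp.csr_matrix(mat),
        np.array(["gene0", "gene1", "gene2", "gene3"], dtype=object),
        np.array([f"c{i}" for i in range(6)], dtype=object),
    )


@pytest.fixture
def toy_annotation():
    """9-cell annotation: 4 reporter+ L5 cells, 3 GABAergic, 2 non-neuronal,
    plus optional L6/L2-3 glutamatergic cells added by individual tests."""
    rows = []
    for i in range(4):
        rows.append((f"t{i}", "glutamatergic", "L4/5 IT", True))
    for i in range(3):
        rows.append((f"g{i}", "GABAergic", "Pvalb", False))
    for i in range(2):
        rows.append((f"n{i}", "non-neuronal", "Astro", False))
    frame = pd.DataFrame(
        rows, columns=["cell_id", "cell_class", "cluster", "reporter_positive"]
    ).set_index("cell_id")
    frame["region"] = "ACA"
    return frame
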