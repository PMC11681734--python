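import numpy as np
import pandas as pd
import pytest

from xlps.data_io import ExpressionMatrix, SampleSheet


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    """Two species (one per group), two individuals each, paired design at 2 h."""
    rows = []
    for sp, grp in (("mouse", "resilient"), ("pig", "sensitive")):
        for i in (1, 2):
            for dose in (0.0, 10.0):
                rows.append({
                    "sample_id": f"{sp}_i{i}_d{dose:g}_t2", "species": sp, "group": grp,
                    "individual": f"{sp}_i{i}", "dose": dose, "time": 2.0,
                })
    sheet = SampleSheet(pd.DataFrame(rows))
    sheet.validate()
    return sheet


def make_matrix(values, sample_ids, gene_ids=None, missing=None, scale="log2") -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    missing = np.zeros(values.shape, dtype=bool) if missing is None else np.asarray(missing, bool)
    return ExpressionMatrix(list(gene_ids), list(sample_ids), values, missing, scale=scale)
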