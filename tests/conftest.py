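import numpy as np
import pytest

from haploscan import VariantTable


def table_from_matrix(matrix, chrom="I", start_pos=1, spacing=1):
    """Build a VariantTable from a sites x strains 0/1/-1 matrix."""
    matrix = np.asarray(matrix, dtype=np.int8)
    n_sites, n_strains = matrix.shape
    strains = [f"S{i}" for i in range(n_strains)]
    records = [
        (chrom, start_pos + i * spacing, "A", "T", matrix[i]) for i in range(n_sites)
    ]
    return VariantTable.from_records(strains, records)


@pytest.fixture
def small_table():
    """Four strains, three sites: two sites share one bipartition."""
    return table_from_matrix(
        [
            [0, 0, 1, 1],
            [0, 0, 1, 1],
            [0, 1, 0, 1],
        ]
    )
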