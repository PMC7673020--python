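import numpy as np
import pandas as pd
import pytest

from rilsweep.core import GenotypeMatrix, MarkerMap


def make_map(n_markers=30, chrom="chr01", spacing_cM=1.0, spacing_bp=100_000,
             prefix=None) -> MarkerMap:
    prefix = prefix or chrom
    rows = [
        (f"{prefix}_m{i:03d}", chrom, (i + 1) * spacing_bp, (i + 1) * spacing_cM)
        for i in range(n_markers)
    ]
    return MarkerMap(pd.DataFrame(rows, columns=list(MarkerMap.COLUMNS)))


def make_matrix(calls, line_prefix="L", marker_ids=None) -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    lines = [f"{line_prefix}{i:03d}" for i in range(calls.shape[0])]
    markers = marker_ids or [f"chr01_m{j:03d}" for j in range(calls.shape[1])]
    return GenotypeMatrix(lines, markers, calls)


@pytest.fixture
def small_map():
    return make_map(n_markers=30)
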