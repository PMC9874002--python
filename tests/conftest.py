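from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from circlinc.types import CountMatrix

# 20 x 4 toy count matrix; the expected TMM factors frozen in
# test_preprocess.py were computed from the reference trimmed-mean
# implementation on exactly this table.
TOY_COUNTS = {
    "columns": ["A", "B", "C", "D"],
    "index": [f"G{i:02d}" for i in range(20)],
    "data": [
        [2, 44, 5, 21], [33, 91, 9, 34], [8, 41, 18, 27], [8, 23, 8, 7],
        [20, 18, 3, 19], [7, 26, 3, 10], [12, 42, 5, 24], [46, 157, 56, 171],
        [6, 16, 8, 13], [4, 18, 3, 13], [25, 80, 15, 47], [57, 12, 14, 41],
        [21, 33, 8, 51], [6, 8, 0, 17], [21, 32, 8, 18], [55, 58, 20, 58],
        [9, 14, 3, 7], [22, 12, 4, 11], [6, 5, 3, 2], [3, 12, 2, 8],
    ],
}


def make_counts(data, genes=None, samples=None, group=None) -> CountMatrix:
    data = np.asarray(data)
    genes = genes or [f"G{i}" for i in range(data.shape[0])]
    samples = samples or [f"S{j}" for j in range(data.shape[1])]
    if group is None:
        half = data.shape[1] // 2
        group = ["term"] * half + ["sPTB"] * (data.shape[1] - half)
    return CountMatrix(
        counts=pd.DataFrame(data, index=genes, columns=samples),
        group=pd.Series(group, index=samples),
    )


@pytest.fixture
def toy_counts() -> CountMatrix:
    return make_counts(
        TOY_COUNTS["data"], TOY_COUNTS["index"], TOY_COUNTS["columns"],
        ["term", "term", "sPTB", "sPTB"],
    )


@pytest.fixture
def two_group_expr():
    """20-gene, 3+3-sample expression matrix for moderated-t checks."""
    rng = np.random.default_rng(11)
    vals = rng.normal(5.0, 1.0, (20, 6))
    vals[:5, 3:] += 1.5
    from circlinc.types import ExprMatrix

    samples = [f"S{j}" for j in range(6)]
    return ExprMatrix(
        values=pd.DataFrame(vals, index=[f"G{i}" for i in range(20)], columns=samples),
        group=pd.Series(["term"] * 3 + ["sPTB"] * 3, index=samples),
    )
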