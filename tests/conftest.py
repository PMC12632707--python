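import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_differential_table(features, log2fc, padj=None, p=None, significant=None):
    """Small helper for hand-built differential tables."""
    n = len(features)
    lfc = np.asarray(log2fc, dtype=float)
    tbl = pd.DataFrame(
        {
            "feature": [str(f) for f in features],
            "log2fc": lfc,
            "p": p if p is not None else np.full(n, 1e-6),
            "padj": padj if padj is not None else np.full(n, 1e-5),
        }
    )
    tbl["significant"] = significant if significant is not None else True
    tbl["direction"] = np.where(lfc > 0, "up", np.where(lfc < 0, "down", None))
    return tbl


@pytest.fixture
def diff_table_factory():
    return make_differential_table
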