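import numpy as np
import pandas as pd
import pytest

from deconcord import DiffTable, OrthologMap


def make_diff_table(ids, lfc, p_raw=None, p_adj=None, label="ds", layer="mrna"):
    n = len(ids)
    if p_raw is None:
        p_raw = [0.5] * n
    if p_adj is None:
        p_adj = [0.5] * n
    return DiffTable(
        dataset_label=label,
        layer=layer,
        records=pd.DataFrame(
            {
                "feature_id": list(ids),
                "log2fc": np.asarray(lfc, dtype=float),
                "p_raw": np.asarray(p_raw, dtype=float),
                "p_adj": np.asarray(p_adj, dtype=float),
            }
        ),
    )


def random_table(rng, n, prefix="g", label="ds", layer="mrna"):
    ids = [f"{prefix}{i:04d}" for i in range(n)]
    return make_diff_table(
        ids,
        rng.normal(size=n),
        p_raw=rng.uniform(size=n),
        p_adj=rng.uniform(size=n),
        label=label,
        layer=layer,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def table_factory():
    return make_diff_table


@pytest.fixture
def identity_map():
    def _make(ids):
        return OrthologMap(
            pairs=pd.DataFrame({"source_id": list(ids), "target_id": list(ids)})
        )

    return _make
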