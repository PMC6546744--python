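import numpy as np
import pandas as pd
import pytest

from betimed.io import CountTable


@pytest.fixture
def toy_counts() -> CountTable:
    counts = np.array([[1, 2], [3, 4], [5, 6]])
    return CountTable(["f1", "f2", "f3"], ["s1", "s2"], counts)


@pytest.fixture
def guide_counts() -> CountTable:
    """Two genes x two guides plus one control guide, ETP and FINAL samples."""
    meta = {
        "gA_sg1": ("gA", False),
        "gA_sg2": ("gA", False),
        "gB_sg1": ("gB", False),
        "gB_sg2": ("gB", False),
        "CTRL_1": ("NONTARGETING", True),
    }
    counts = np.array(
        [
            [100, 100],
            [200, 60],
            [150, 150],
            [120, 130],
            [90, 95],
        ]
    )
    return CountTable(list(meta), ["ETP_1", "FINAL_1"], counts, feature_meta=meta)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def write_tsv(path, text):
    path.write_text(text)
    return path


@pytest.fixture
def expr_matrix(rng) -> pd.DataFrame:
    genes = [f"g{i}" for i in range(50)]
    cols = [f"vehicle_{i}" for i in range(1, 4)] + [f"drug_{i}" for i in range(1, 4)]
    return pd.DataFrame(rng.normal(5, 1, size=(50, 6)), index=genes, columns=cols)
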