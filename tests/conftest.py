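from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flexiquantlf import IntensityTable


def make_table(rows: dict[str, list[float]], keys: list[tuple[str, str]], reference: list[str]) -> IntensityTable:
    """Build an IntensityTable from {sample: intensities} and (protein, peptide) keys."""
    data = pd.DataFrame.from_dict(rows, orient="index")
    data.columns = pd.MultiIndex.from_tuples(keys, names=["protein", "peptide"])
    return IntensityTable(data, reference)


@pytest.fixture
def six_peptide_table() -> IntensityTable:
    """Reference [10..60] and a sample where the last peptide lost half its signal."""
    keys = [("A", f"p{i}") for i in range(1, 7)]
    return make_table(
        {"ref": [10, 20, 30, 40, 50, 60], "t1": [10, 20, 30, 40, 50, 30]},
        keys,
        reference=["ref"],
    )


@pytest.fixture
def two_consensus_table() -> IntensityTable:
    """Two disjoint 3-peptide subsets each supporting a distinct slope (1 vs 2).

    Either pure subset yields a perfect 3-inlier consensus, so a single
    RANSAC run lands on whichever it happens to draw first; the slope-2 set
    has the smaller residuals on the full peptide set, so r^2-based
    selection across initiations prefers it.
    """
    keys = [("B", f"p{i}") for i in range(1, 7)]
    return make_table(
        {
            "ref": [10.0, 11.0, 12.0, 10.5, 11.5, 12.5],
            "s": [10.0, 11.0, 12.0, 21.0, 23.0, 25.0],
        },
        keys,
        reference=["ref"],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)
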