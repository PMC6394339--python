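import numpy as np
import pytest

from glvkit import AbundanceTable, GLVModel


@pytest.fixture
def two_taxon_model() -> GLVModel:
    return GLVModel(
        taxa=["A", "B"],
        growth_rates=[0.5, 0.3],
        interactions=[[-0.1, 0.02], [0.01, -0.2]],
    )


@pytest.fixture
def logistic_model() -> GLVModel:
    """Single species with r=1, alpha=-1 (carrying capacity 1)."""
    return GLVModel(taxa=["x"], growth_rates=[1.0], interactions=[[-1.0]])


@pytest.fixture
def small_table() -> AbundanceTable:
    return AbundanceTable(
        times=[0.0, 1.0, 2.0],
        taxa=["A", "B"],
        values=[[1.0, 2.0], [2.0, 1.5], [4.0, 1.0]],
    )


def write_tsv(path, header, rows):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    return path


@pytest.fixture
def tsv_writer():
    return write_tsv


def brute_force_dtw(a, b) -> float:
    """Independent DTW oracle: exhaustive warping-path enumeration.

    Enumerates every monotone path from (0, 0) to (m-1, n-1) with
    steps (1,0), (0,1), (1,1) and minimizes the summed absolute
    difference along the path.  Exponential; only for tiny series.
    """
    a = list(a)
    b = list(b)
    m, n = len(a), len(b)
    best = [np.inf]

    def walk(i: int, j: int, acc: float) -> None:
        acc += abs(a[i] - b[j])
        if acc >= best[0]:
            return
        if i == m - 1 and j == n - 1:
            best[0] = acc
            return
        if i + 1 < m and j + 1 < n:
            walk(i + 1, j + 1, acc)
        if i + 1 < m:
            walk(i + 1, j, acc)
        if j + 1 < n:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return float(best[0])


@pytest.fixture
def dtw_oracle():
    return brute_force_dtw
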