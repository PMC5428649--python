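import numpy as np
import pandas as pd
import pytest

from herbconnect import ExpressionMatrix, Signature


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 probes, two treated + two control replicates."""
    values = pd.DataFrame(
        {
            "trt_r1": [8.0, 1.0, 0.4, 5.0],
            "trt_r2": [8.0, 1.0, 0.4, 7.0],
            "ctl_r1": [2.0, 1.0, 1.0, 6.0],
            "ctl_r2": [2.0, 1.0, 1.0, 6.0],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    cmap = {
        "trt_r1": ("drug", 1), "trt_r2": ("drug", 2),
        "ctl_r1": ("DMSO", 1), "ctl_r2": ("DMSO", 2),
    }
    return ExpressionMatrix(values, cmap)


@pytest.fixture
def universe() -> list[str]:
    return [f"P{i:06d}" for i in range(100)]


@pytest.fixture
def query_signature(universe) -> Signature:
    return Signature(tuple(universe[:5]), tuple(universe[-5:]))


def brute_force_ks(tag_ranks: list[int], n: int) -> float:
    """Independent loop-based tag-set enrichment oracle (1-based ranks)."""
    V = sorted(tag_ranks)
    t = len(V)
    a = max(j / t - V[j - 1] / n for j in range(1, t + 1))
    b = max(V[j - 1] / n - (j - 1) / t for j in range(1, t + 1))
    return a if a > b else -b


@pytest.fixture
def ks_oracle():
    return brute_force_ks
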