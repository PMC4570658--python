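import itertools

import numpy as np
import pandas as pd
import pytest

from devdup.diffexpr import TernaryDEMatrix, pair_label
from devdup.formats import ExpressionTable
from devdup.synthio import FamilySimConfig, ScoreParams, simulate_dataset


def ternary_from_array(arr, n_samples=None):
    """Wrap a 2-D array of {-1,0,1} into a TernaryDEMatrix with synthetic
    sample-pair column labels."""
    arr = np.asarray(arr, dtype=np.int8)
    m = arr.shape[1]
    if n_samples is None:
        n_samples = 2
        while n_samples * (n_samples - 1) // 2 < m:
            n_samples += 1
    samples = [f"s{i}" for i in range(n_samples)]
    cols = [pair_label(i, j) for i, j in itertools.combinations(samples, 2)][:m]
    if len(cols) != m:
        raise ValueError("cannot label columns as sample pairs")
    df = pd.DataFrame(arr, index=[f"g{i:03d}" for i in range(arr.shape[0])], columns=cols)
    return TernaryDEMatrix(df, samples)


@pytest.fixture
def noise_free_world():
    """Small noise-free simulated dataset where truth is exactly recoverable."""
    cfg = FamilySimConfig(n_families=30, seed=3, noise_sigma=0.0)
    truth, hits, expr = simulate_dataset(cfg, ScoreParams(noise=0.0))
    return cfg, truth, hits, expr


@pytest.fixture
def expr_10_samples():
    """Deterministic 4-gene x 10-sample table with 3 stage groups."""
    rng = np.random.default_rng(42)
    samples = [f"s{i}" for i in range(10)]
    stages = {s: ("early" if i < 3 else "dauer" if i < 5 else "late")
              for i, s in enumerate(samples)}
    df = pd.DataFrame(
        rng.uniform(1, 100, size=(4, 10)),
        index=[f"g{i}" for i in range(4)], columns=samples,
    )
    return ExpressionTable(df, stage_groups=stages)
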