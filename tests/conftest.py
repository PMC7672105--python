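import numpy as np
import pandas as pd
import pytest

from sscatac import core, simulate


@pytest.fixture(scope="session")
def default_study():
    """One full synthetic study shared by read-only tests."""
    return simulate.simulate_accessibility(simulate.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def normalized_matrix(default_study):
    m = default_study.matrix
    core.intensity(core.quantile_normalize(m))
    return m


@pytest.fixture(scope="session")
def annotation(default_study):
    return core.annotate_nearest_gene(default_study.peaks, default_study.genes)


@pytest.fixture()
def tiny_matrix():
    """2 peaks x 2 samples with known counts."""
    df = pd.DataFrame(
        {"s1": [1, 3], "s2": [2, 4]},
        index=pd.Index(["p1", "p2"], name="peak_id"),
    )
    return core.AccessibilityMatrix(df)


def intensity_matrix(values: np.ndarray, samples=None) -> core.AccessibilityMatrix:
    """Build a matrix whose intensity layer equals ``values`` exactly."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    samples = samples or [f"s{j}" for j in range(m)]
    raw = pd.DataFrame(
        np.zeros((n, m), dtype=int),
        index=pd.Index([f"p{i}" for i in range(n)], name="peak_id"),
        columns=samples,
    )
    mat = core.AccessibilityMatrix(raw)
    mat.normalized = pd.DataFrame(2.0**values - 1.0, index=raw.index, columns=raw.columns)
    mat.intensity = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    return mat


def rank_mean_oracle(X: np.ndarray) -> np.ndarray:
    """Independent quantile-normalization oracle: per column, replace each
    value by the mean reference over its (possibly tied) rank block."""
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(len(col))
        i = 0
        while i < len(col):
            k = i
            while k < len(col) and col[order[k]] == col[order[i]]:
                k += 1
            assigned[order[i:k]] = ref[i:k].mean()
            i = k
        out[:, j] = assigned
    return out
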