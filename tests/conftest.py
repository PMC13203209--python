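import numpy as np
import pytest

from kdeknn import (
    FixtureSpec,
    GeneratorConfig,
    TabularDataset,
    fit_preprocessor,
    generate,
    make_clinical_fixture,
    split_train_test,
)


@pytest.fixture
def tiny_dataset() -> TabularDataset:
    """Three rows, two features, one missing cell."""
    values = np.array([[1.0, 2.0], [np.nan, 4.0], [3.0, 6.0]])
    return TabularDataset(values, np.array([0, 1, 0]), ["age", "lactate"])


@pytest.fixture(scope="session")
def clinical_fixture() -> TabularDataset:
    """Default clinical-shaped cohort: 979 controls / 296 cases, 27 features."""
    return make_clinical_fixture(FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def standardized_split(clinical_fixture):
    """(train_std, test_std, preprocessor) from an 85/15 stratified split."""
    train, test = split_train_test(clinical_fixture, 0.15, seed=1)
    pre = fit_preprocessor(train)
    return pre.apply(train), pre.apply(test), pre


@pytest.fixture(scope="session")
def generated_default(standardized_split):
    """One full generator run on the default fixture, shared across tests."""
    train_std, _, _ = standardized_split
    config = GeneratorConfig(seed=7)
    synthetic, report = generate(train_std, config)
    return train_std, config, synthetic, report


def brute_force_min_dist(a: np.ndarray, b: np.ndarray, exclude_self: bool) -> np.ndarray:
    """O(N*Q) double-loop nearest-record distances, the test oracle."""
    out = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        best = np.inf
        for j in range(b.shape[0]):
            if exclude_self and i == j:
                continue
            dist = float(np.sqrt(((a[i] - b[j]) ** 2).sum()))
            best = min(best, dist)
        out[i] = best
    return out
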