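import numpy as np
import pytest

import pdtkit as pk


@pytest.fixture(scope="session")
def cohort_frame():
    """One default 16/10 cohort run through the full extraction pipeline."""
    subjects = pk.simulate_cohort(16, 10, seed=3)
    return pk.cohort_features(subjects)


@pytest.fixture(scope="session")
def cohort_data(cohort_frame):
    return pk.frame_to_dataset(cohort_frame)


def make_gaussian_dataset(
    n_pos: int,
    n_neg: int,
    effects: list[float],
    seed: int,
    names: list[str] | None = None,
) -> pk.LabeledDataset:
    """Feature-level two-class dataset: column j separated by ``effects[j]`` SDs."""
    rng = np.random.default_rng(seed)
    m = len(effects)
    Xp = rng.normal(size=(n_pos, m)) + np.asarray(effects)
    Xn = rng.normal(size=(n_neg, m))
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(n_pos, int), -np.ones(n_neg, int)])
    return pk.LabeledDataset(
        X=X, y=y, feature_names=names or [f"f{j}" for j in range(m)]
    )


@pytest.fixture
def blobs():
    """Two well-separated Gaussian blobs (separation 10x SD), 2-D."""
    return make_gaussian_dataset(10, 10, [10.0, 10.0], seed=11)
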