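import numpy as np
import pytest

from mlphvg import LabeledFeatureSet, extract_features, gen_two_class_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_surrogate_dataset():
    """Two-class surrogate (12 + 12 signals, length 1024) with scale-2
    features: enough separation for protocol tests at low cost."""
    signals, labels = gen_two_class_dataset(n_per_class=12, length=1024, seed=11)
    pairs = [
        extract_features(s, [2], L=1, signal_id=f"s{i:03d}")[0].as_pair()
        for i, s in enumerate(signals)
    ]
    return LabeledFeatureSet(
        signal_ids=tuple(f"s{i:03d}" for i in range(len(signals))),
        features=np.array(pairs),
        labels=labels,
    )


@pytest.fixture(scope="session")
def separable_features():
    """Hand-built, perfectly margin-separated two-class feature set."""
    rng = np.random.default_rng(5)
    c0 = rng.normal([0.2, 0.5], 0.02, size=(20, 2))
    c1 = rng.normal([0.8, 3.0], 0.02, size=(20, 2))
    X = np.vstack([c0, c1])
    y = np.repeat([0, 1], 20)
    return LabeledFeatureSet(
        signal_ids=tuple(f"p{i}" for i in range(40)), features=X, labels=y
    )
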