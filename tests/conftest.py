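import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250921)


@pytest.fixture(scope="session")
def small_training_set():
    """Shared labelled-window fixture (4 individuals, 40 windows/class)."""
    from burrowacc.signal_features import extract_features_stack
    from burrowacc.simulate import make_training_set

    raw, labels, owners = make_training_set(
        n_individuals=4, windows_per_class=40, seed=7
    )
    X = extract_features_stack(raw)
    return X, labels, owners
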