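import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from sleepose.detector import tiny_train_config, train  # noqa: E402
from sleepose.pipeline import evaluate_model  # noqa: E402
from sleepose.synthetic import desk_spec, generate_dataset  # noqa: E402

_DESK_CACHE: dict[int, tuple] = {}


def _desk_run(seed: int):
    """Train the desk-scale detector on 400 synthetic scenes (held-out
    val/test splits of 50 each) and evaluate it; memoized per seed."""
    if seed not in _DESK_CACHE:
        spec = desk_spec(seed=100 + seed)
        splits = generate_dataset(spec, 500)
        model, history = train(splits.train, splits.val,
                               tiny_train_config(seed=seed))
        metrics = evaluate_model(model, splits.test)
        _DESK_CACHE[seed] = (model, splits, history, metrics)
    return _DESK_CACHE[seed]


@pytest.fixture(scope="session")
def desk_run_factory():
    return _desk_run


@pytest.fixture(scope="session")
def desk_run():
    """The seed-0 desk-scale training run: (model, splits, history,
    held-out metrics)."""
    return _desk_run(0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
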