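import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracle.py importable

from hamil import ModelConfig, init_params, fixture_micro_cohort
from hamil.data import Cohort, Sample


@pytest.fixture
def micro_cohort():
    return fixture_micro_cohort()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_sample(rng, n_cells, n_types, m, label=0, sample_id="S", ensure_absent=False):
    """Random bag; with ensure_absent=True at least one type index is unused."""
    pool = np.arange(n_types - 1) if (ensure_absent and n_types > 1) else np.arange(n_types)
    cell_types = rng.choice(pool, size=n_cells)
    X = rng.normal(size=(n_cells, m))
    return Sample(X=X, cell_types=cell_types, label=label, sample_id=sample_id)


def random_cohort(rng, n_samples=6, n_types=4, m=5, n_classes=2, max_cells=12):
    samples = []
    for s in range(n_samples):
        n = int(rng.integers(1, max_cells + 1))
        samples.append(random_sample(
            rng, n, n_types, m, label=s % n_classes, sample_id=f"R{s}",
            ensure_absent=bool(s % 2)))
    return Cohort(samples, n_types, n_classes)


def random_model(rng, m=5, n_classes=2, mode="ha", hidden_dim=4,
                 n_hidden_layers=1, force_softmax_head=False, att_scale=0.7):
    """Random config + params with non-trivial attention vectors."""
    config = ModelConfig(
        input_dim=m, n_classes=n_classes, mode=mode, hidden_dim=hidden_dim,
        n_hidden_layers=n_hidden_layers, force_softmax_head=force_softmax_head,
        seed=int(rng.integers(2**31)))
    params = init_params(config, rng)
    params.att_w = rng.normal(0, att_scale, size=hidden_dim)
    params.type_v = rng.normal(0, att_scale, size=hidden_dim)
    params.att_b = float(rng.normal())
    params.type_b = float(rng.normal())
    return config, params
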