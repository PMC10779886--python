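import numpy as np
import pytest

from confsol import SplitRule, SynthSpec, generate_dataset, sequential_split
from confsol.conformal import repeated_cv_predictions
from confsol.selection import GridSpec, grid_search_cv


@pytest.fixture(scope="session")
def small_split():
    """240 synthetic compounds (3 informative + 12 noise), 160/80 split."""
    spec = SynthSpec(
        n_samples=240,
        n_informative=3,
        n_noise=12,
        effect_sizes=(2.0, 1.5, 1.0),
        seed=7,
    )
    table = generate_dataset(spec)
    tr, te = sequential_split(table, SplitRule(period=3, start_offsets=(2,)))
    return table.subset(tr), table.subset(te)


@pytest.fixture(scope="session")
def small_tuned(small_split):
    """Grid-tuned learner spec (5-fold) on the small training set."""
    train, _ = small_split
    grid = GridSpec(
        max_depth_values=(3,), eta_values=(0.3,), max_rounds=40, n_folds=5
    )
    return grid_search_cv(train.X, train.y, grid, seed=11)


@pytest.fixture(scope="session")
def small_cvp(small_split, small_tuned):
    """Repeated-CV predictions (5 repeats) on the small training set."""
    train, _ = small_split
    return repeated_cv_predictions(train.X, train.y, small_tuned, n_repeats=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
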