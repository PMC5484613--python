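import numpy as np
import pytest

import hiertree as ht


@pytest.fixture(scope="session")
def spec2():
    """Default two-level task: sigma = 10 cd/m^2 on a 50 cd/m^2 background."""
    return ht.make_tree_task()


@pytest.fixture(scope="session")
def spec3():
    return ht.make_tree_task(n_levels=3, difficulty_levels=((2, 4, 8),) * 3)


@pytest.fixture(scope="session")
def noiseless_spec():
    return ht.make_tree_task(noise_sd=0.0)


@pytest.fixture(scope="session")
def small_batch(spec2):
    """200 trials with mixed difficulty and random target paths."""
    return ht.generate_trials(spec2, 200, seed=101)
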