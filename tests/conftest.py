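import numpy as np
import pytest

import omicsboost as ob


@pytest.fixture(scope="session")
def default_cohort():
    """Desk-scale labelled cohort with planted informative features."""
    return ob.generate_cohort(ob.default_config(seed=0))


@pytest.fixture(scope="session")
def default_selection(default_cohort):
    return ob.select_features(default_cohort)


@pytest.fixture(scope="session")
def default_design(default_cohort, default_selection):
    return ob.assemble_design(default_cohort, default_selection)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Narrow cohort for fast structural tests."""
    cfg = ob.CohortConfig(
        n_samples=60,
        class_balance=0.5,
        blocks=(
            ob.BlockSpec("clin", "discrete", 5, 2, effect_size=2.0),
            ob.BlockSpec("prot", "continuous", 40, 8, effect_size=1.5),
        ),
        seed=11,
    )
    return ob.generate_cohort(cfg)
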