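import warnings

import numpy as np
import pytest
from hypothesis import settings

# wall-clock deadlines are flaky on loaded CI machines
settings.register_profile("no_deadline", deadline=None)
settings.load_profile("no_deadline")

from sliderirt import (
    McmcConfig,
    ModelConfig,
    fit_model,
    make_design,
    paper_like_population,
    simulate_study,
)
from sliderirt.simulate import draw_true_params


@pytest.fixture(scope="session")
def pop():
    return paper_like_population()


@pytest.fixture(scope="session")
def tiny_study(pop):
    """12 persons x 2 traits x 4 items x 2 occasions = 192 records."""
    design = make_design(12, 4, 2, ("E", "C"), seed=101)
    truth = draw_true_params(design, pop, seed=102)
    table = simulate_study(design, truth, pop, seed=103)
    return design, truth, table


@pytest.fixture(scope="session")
def small_fit(pop):
    """A cheap but real joint fit used by several contract tests."""
    design = make_design(20, 4, 2, ("E", "C"), seed=201)
    truth = draw_true_params(design, pop, seed=202)
    table = simulate_study(design, truth, pop, seed=203)
    cfg = ModelConfig(
        mcmc=McmcConfig(chains=2, warmup=100, draws=120, seed=7, target_accept=0.85)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws = fit_model(table, cfg)
    return table, truth, draws


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
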