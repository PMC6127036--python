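import numpy as np
import pytest

from priorlearn.ddm import AccumulatorParams, counterfactual_posterior_map
from priorlearn.observer import DEFAULT_GENERATOR_PARAMS, simulate_observer
from priorlearn.task import generate_experiment

# coarse grid shared by most tests: fast to build, accurate enough for the
# qualitative and statistical checks (high-accuracy grids are used where a
# numerical tolerance demands them)
FIT_DT = 0.0075
FIT_NE = 181


@pytest.fixture(scope="session")
def gen_params():
    return DEFAULT_GENERATOR_PARAMS


@pytest.fixture(scope="session")
def fit_maps(gen_params):
    acc = AccumulatorParams(kappa=gen_params.kappa, bound=gen_params.bound,
                            dt=FIT_DT, n_evidence=FIT_NE, dt_sim=0.001)
    return counterfactual_posterior_map(acc)


@pytest.fixture(scope="session")
def small_design():
    return generate_experiment(20, rng_seed=11)


@pytest.fixture(scope="session")
def behavior_small(small_design, gen_params, fit_maps):
    return simulate_observer(small_design, gen_params, fit_maps,
                             np.random.default_rng(5))
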