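import warnings

import numpy as np
import pandas as pd
import pytest

from prtddm import hier_model, pipeline, preprocess as prep
from prtddm.hier_model import ModelSpec, PriorSpec
from prtddm.task_sim import TaskConfig


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """4 agents in 2 groups with default parameter distributions."""
    from prtddm import task_sim
    cfg = TaskConfig()
    trials, truth = task_sim.simulate_cohort(
        {"star": {}, "thumbs": {}}, n_per_group=2, config=cfg, seed=123)
    return trials, truth, cfg


@pytest.fixture(scope="session")
def recovery_result():
    """The headline recovery run: 12 agents x 288 trials, reduced MCMC
    (2 chains x 500 warmup / 500 draws), fixed seed."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = pipeline.run_recovery(n_agents=12, seed=1)
    return report


def _bias_cohort_interval(z_mapped: float, seed: int):
    import dataclasses
    from scipy.special import ndtri
    from prtddm.pipeline import default_truth_generator, simulate_recovery_cohort

    z_raw = float(ndtri(z_mapped))

    def gen(rng, region=None):
        return dataclasses.replace(default_truth_generator(rng), z_raw=z_raw)

    trials, truth = simulate_recovery_cohort(12, TaskConfig(), seed, truth_generator=gen)
    filtered, _, _ = prep.preprocess(trials)
    model = hier_model.build_model(filtered, PriorSpec(), ModelSpec.reduced())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        draws, diag = hier_model.fit(model, seed=seed)
    return hier_model.cohort_bias_interval(draws, "star")


@pytest.fixture(scope="session")
def biased_cohort_interval():
    """95% posterior interval of the cohort-mean mapped bias for a cohort
    generated with true mapped bias 0.53."""
    return _bias_cohort_interval(0.53, seed=11)


@pytest.fixture(scope="session")
def unbiased_cohort_interval():
    """Same for a cohort generated with true mapped bias 0.50."""
    return _bias_cohort_interval(0.50, seed=11)
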