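import numpy as np
import pandas as pd
import pytest

import socialrl as s


@pytest.fixture(scope="session")
def exp1_config():
    return s.TaskConfig.exp1()


@pytest.fixture(scope="session")
def exp2_config():
    return s.TaskConfig.exp2()


@pytest.fixture(scope="session")
def exp2_schedule(exp2_config):
    return s.make_schedule(exp2_config, 1, subject_id="s00")


@pytest.fixture(scope="session")
def vs2_dataset(exp2_schedule):
    """One subject simulated from VS2 at moderate parameters."""
    params = s.ParameterSet(alpha_p=0.4, alpha_i=0.3, beta=5.0, kappa=0.3)
    return s.simulate_agent(s.get_model("VS2"), params, exp2_schedule, 2)


def simulate_cohort(model, params, config, n_subjects, seed):
    """Simulate n subjects of one model on freshly generated schedules."""
    spec = s.get_model(model)
    frames = []
    for i, sseq in enumerate(np.random.SeedSequence(seed).spawn(n_subjects)):
        rng = np.random.default_rng(sseq)
        sched = s.make_schedule(config, int(rng.integers(2**31)), subject_id=f"c{i:03d}")
        frames.append(s.simulate_agent(spec, params, sched, int(rng.integers(2**31))))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def cohort_factory():
    return simulate_cohort
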