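import numpy as np
import pandas as pd
import pytest

from nkbandit import ModelParams, TaskConfig, build_schedule, simulate_agent


@pytest.fixture(scope="session")
def default_schedule():
    return build_schedule(TaskConfig(), seed=123)


@pytest.fixture(scope="session")
def hc_like_params():
    return ModelParams(model_id="nkRL", alpha=0.3, beta=0.3, k=0.43, nu=12.43)


@pytest.fixture(scope="session")
def pg_like_params():
    return ModelParams(model_id="nkRL", alpha=0.3, beta=0.3, k=1.38, nu=5.58)


@pytest.fixture(scope="session")
def simulated_log(default_schedule, hc_like_params):
    return simulate_agent(default_schedule, hc_like_params, seed=7, subject_id="hc0")
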