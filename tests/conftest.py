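import numpy as np
import pytest

from somtask import AgentParams, CohortSpec, RLParams, simulate_cohort, simulate_participant
from somtask.agent_sim import build_cohort_schedule
from somtask.schedule import (generate_feedback_schedule, generate_schedule,
                              generate_thresholds)


@pytest.fixture(scope="session")
def filled_schedule():
    """Default-size session schedule with feedback and thresholds filled."""
    sched = generate_schedule(1, n_main=88, n_starter=16)
    sched = generate_feedback_schedule(2, sched)
    return generate_thresholds(3, sched)


@pytest.fixture(scope="session")
def params():
    return RLParams(alpha=0.3, beta=0.8)


@pytest.fixture(scope="session")
def record(filled_schedule):
    """One session of a biased agent on the default schedule."""
    agent = AgentParams(alpha=0.3, beta=0.8, w_som_StoO=0.2, w_som_OtoS=0.1)
    return simulate_participant(filled_schedule, agent, seed=5)


@pytest.fixture(scope="session")
def pure_record(filled_schedule):
    """One session of an unbiased (pure tracking) agent."""
    agent = AgentParams(alpha=0.3, beta=0.8)
    return simulate_participant(filled_schedule, agent, seed=6)


@pytest.fixture(scope="session")
def small_cohort():
    """4 participants per group, two sessions each, with a cTBS shift."""
    spec = CohortSpec(n_per_group=4, seed=3, ctbs_som_delta=0.3)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def cohort_schedule():
    return build_cohort_schedule(CohortSpec(seed=1))
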