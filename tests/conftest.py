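import numpy as np
import pytest

import opercard as oc


@pytest.fixture(scope="session")
def schedule():
    return oc.load_payoff_schedule("bechara_standard")


@pytest.fixture(scope="session")
def ideal_log(schedule):
    policy = oc.igt_agent(oc.IGTAgentParams(archetype="ideal"))
    return oc.run_igt_session(policy, schedule, 200, seed=11, participant_id="ideal")


@pytest.fixture(scope="session")
def learner_logs(schedule):
    """A small heterogeneous synthetic cohort of 200-trial IGT sessions."""
    members, _ = oc.build_cohort(
        8,
        "igt",
        {"learning_rate": ("loguniform", 0.02, 0.4), "inverse_temperature": 3.0},
        seed=42,
    )
    return [
        oc.run_igt_session(
            oc.igt_agent(m.params), schedule, 200, m.seed, participant_id=m.agent_id
        )
        for m in members
    ]


@pytest.fixture(scope="session")
def matching_session():
    """Condition-1 session of a sensitivity-1 matching agent (fully delivered)."""
    agent = oc.act_agent(oc.ACTAgentParams(sensitivity=1.0))
    return oc.run_session(agent, 1, seed=7)


def sequence_log(decks):
    """Build a deck-label sequence usable by the analysis functions."""
    return list(decks)
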