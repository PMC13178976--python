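import numpy as np
import pandas as pd
import pytest

from teamdynam.covariates import ActorTable, build_dyad_design
from teamdynam.sensor_events import PresenceSchedule


def always_on(actor_ids, until=10_000.0):
    """Presence schedule with every badge on from t=0."""
    return PresenceSchedule({a: [(0.0, until)] for a in actor_ids})


@pytest.fixture
def four_actor_team():
    """Hand-built 4-actor team: two women (one senior), two men (one senior)."""
    table = pd.DataFrame(
        {
            "actor_id": ["a", "b", "c", "d"],
            "team_id": ["t1"] * 4,
            "context": ["lab"] * 4,
            "gender": ["woman", "woman", "man", "man"],
            "seniority": ["senior", "junior", "senior", "junior"],
            "tenure_months": [80.0, 6.0, 40.0, 6.0],
            "age_years": [50.0, 28.0, 40.0, 28.0],
        }
    )
    return ActorTable(table)


def empty_net(ids):
    n = len(ids)
    m = np.zeros((n, n))
    return pd.DataFrame(m, index=ids, columns=ids)


@pytest.fixture
def four_actor_design(four_actor_team):
    ids = ["a", "b", "c", "d"]
    advice = empty_net(ids)
    advice.loc["a", "c"] = 1.0  # a seeks advice from c
    friendship = empty_net(ids)
    friendship.loc["b", "d"] = 1.0
    friendship.loc["d", "b"] = 1.0
    colocation = empty_net(ids)
    colocation.loc["a", "b"] = colocation.loc["b", "a"] = 1.0
    designs = build_dyad_design(
        four_actor_team,
        {"t1": advice},
        {"t1": friendship},
        {"t1": colocation},
    )
    return designs["t1"]


@pytest.fixture
def four_actor_presence():
    return always_on(["a", "b", "c", "d"])


@pytest.fixture(scope="session")
def tiny_study():
    """Small simulated study shared by integration-level tests."""
    from teamdynam.simulate import SimConfig, simulate_study

    cfg = SimConfig(
        seed=42,
        teams_per_context={"uni": 1, "lab": 1, "bus": 1},
        team_size_range=(6, 6),
        events_per_team=120,
        missing_rate=0.2,
    )
    return simulate_study(cfg)
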