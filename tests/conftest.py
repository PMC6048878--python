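"""Shared fixtures: small deterministic trials plus session-cached
multi-seed simulation sweeps used by the acceptance suite."""

from __future__ import annotations

import numpy as np
import pytest

import mcart

N_SWEEP_SEEDS = 20


@pytest.fixture(scope="session")
def trial_1a():
    return mcart.simulate_trial(mcart.make_scenario("1A"), 7)


@pytest.fixture(scope="session")
def trial_2b():
    return mcart.simulate_trial(mcart.make_scenario("2B"), 1)


def _mcart_sweep(scenario_id: str):
    out = []
    spec = mcart.make_scenario(scenario_id)
    for seed in range(N_SWEEP_SEEDS):
        trial = mcart.simulate_trial(spec, seed)
        model = mcart.fit(trial, seed=seed)
        rep = mcart.report(model, trial)
        out.append((model, rep))
    return out


@pytest.fixture(scope="session")
def sweep_2b():
    return _mcart_sweep("2B")


@pytest.fixture(scope="session")
def sweep_2c():
    return _mcart_sweep("2C")


@pytest.fixture(scope="session")
def node_counts_1a():
    return [m.n_subgroups for m, _ in _mcart_sweep("1A")]


@pytest.fixture(scope="session")
def node_counts_2a():
    return [m.n_subgroups for m, _ in _mcart_sweep("2A")]


@pytest.fixture(scope="session")
def lr_2a_sweep():
    """(subgroup count, any node with max ASD > 0.2) per seeded 2A trial
    for the LR + effect-partitioning comparator."""
    spec = mcart.make_scenario("2A")
    out = []
    for seed in range(N_SWEEP_SEEDS):
        trial = mcart.simulate_trial(spec, seed)
        est = mcart.lr_backward_aic(trial)
        _, rep = mcart.partition_effects(est, trial)
        out.append((len(rep), bool((rep["max_asd"] > 0.2).any())))
    return out
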