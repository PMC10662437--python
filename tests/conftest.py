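"""Shared fixtures: analytic fixtures, a default synthetic cohort and one
full pipeline run reused by the slower integration tests."""

from __future__ import annotations

import numpy as np
import pytest

from entroflux.model_core import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction
from entroflux.pipeline import (
    default_config_for_bundle,
    run_pipeline,
    simulate_command,
)
from entroflux.synthetic_data import (
    SyntheticScenario,
    make_fixture_chain,
    make_fixture_cycle,
    make_toy_network,
)


@pytest.fixture()
def chain_u1():
    return make_fixture_chain(1, uptake=1.0)


@pytest.fixture()
def cycle():
    return make_fixture_cycle()


@pytest.fixture(scope="session")
def default_scenario():
    return SyntheticScenario(seed=0)


@pytest.fixture(scope="session")
def toy():
    """(model, ground truth) for the default scenario."""
    return make_toy_network(SyntheticScenario(seed=0))


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory, default_scenario):
    """One full simulate->build->solve->diff->crossmatch run (seed 0)."""
    base = tmp_path_factory.mktemp("pipeline")
    paths = simulate_command(base / "bundle", default_scenario)
    config = default_config_for_bundle(paths, base / "out", default_scenario)
    summary = run_pipeline(config)
    return {"paths": paths, "config": config, "summary": summary,
            "state": summary["state"]}


def diamond_network(rng: np.random.Generator, n_parallel: int = 2
                    ) -> MetabolicModel:
    """Random small network with n_parallel^2-ish flux degrees of freedom.

    EX_A (fixed uptake) -> {n_parallel parallel routes} -> B ->
    {n_parallel parallel routes} -> C -> EX_C: after fixing the uptake the
    null space has dimension 2*(n_parallel - 1), i.e. 2 for the default
    diamond, suitable for the brute-force oracle.
    """
    u = float(rng.uniform(0.5, 5.0))
    mets = [Metabolite(m) for m in ("A[c]", "B[c]", "C[c]")]
    rxns = [Reaction("EX_A", {"A[c]": -1.0}, -u, -u)]
    for i in range(n_parallel):
        lb = 0.0 if rng.random() < 0.5 else -DEFAULT_BOUND
        rxns.append(Reaction(f"p{i}", {"A[c]": -1.0, "B[c]": 1.0}, lb, DEFAULT_BOUND))
    for i in range(n_parallel):
        lb = 0.0 if rng.random() < 0.5 else -DEFAULT_BOUND
        rxns.append(Reaction(f"q{i}", {"B[c]": -1.0, "C[c]": 1.0}, lb, DEFAULT_BOUND))
    rxns.append(Reaction("EX_C", {"C[c]": -1.0}, -DEFAULT_BOUND, DEFAULT_BOUND))
    return MetabolicModel("diamond", mets, rxns)
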