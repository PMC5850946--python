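import numpy as np
import pytest

from pertnet import (
    SimulationConfig,
    consensus_stage,
    simulate_study,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_genes=40, n_perturbations=12, edge_density=0.08, seed=3
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture(scope="session")
def small_stage(small_study):
    return consensus_stage(small_study.profiles)


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory, small_study):
    out = tmp_path_factory.mktemp("study")
    small_study.write(out)
    return out


def random_digraph(rng: np.random.Generator, max_nodes: int = 6, signed: bool = False):
    """Random small digraph as (nodes, edges) with optional random signs."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [f"n{i}" for i in range(n)]
    p = rng.uniform(0.15, 0.6)
    edges = {}
    for a in nodes:
        for b in nodes:
            if a != b and rng.random() < p:
                edges[(a, b)] = int(rng.choice((-1, 1))) if signed else 1
    return nodes, edges


def random_signed_dag(rng: np.random.Generator, max_nodes: int = 6):
    """Random signed DAG via a random topological order."""
    n = int(rng.integers(2, max_nodes + 1))
    order = [f"n{i}" for i in range(n)]
    rng.shuffle(order)
    p = rng.uniform(0.2, 0.7)
    edges = {}
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges[(order[i], order[j])] = int(rng.choice((-1, 1)))
    return order, edges
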