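import numpy as np
import pytest

from symptomnet import SyntheticSpec, generate_dataset
from symptomnet.estimation import RegularizedNetwork


def chain_spec(
    weights: dict[tuple[int, int], float],
    n_nodes: int,
    n_subjects: int = 500,
    seed: int = 0,
) -> SyntheticSpec:
    """Small custom truth with benign continuous-ish marginals."""
    P = np.eye(n_nodes)
    for (i, j), w in weights.items():
        P[i, j] = P[j, i] = w
    return SyntheticSpec(
        node_names=[f"v{i:02d}" for i in range(n_nodes)],
        true_partial_corr=P,
        means=np.full(n_nodes, 50.0),
        sds=np.full(n_nodes, 10.0),
        score_bounds=np.tile([-1000.0, 1000.0], (n_nodes, 1)),
        n_subjects=n_subjects,
        group_label="sim",
        seed=seed,
    )


def network_from_weights(
    names: list[str], edges: dict[tuple[str, str], float]
) -> RegularizedNetwork:
    """Hand-built network object (bypasses estimation) for pathway tests."""
    p = len(names)
    idx = {n: i for i, n in enumerate(names)}
    W = np.zeros((p, p))
    for (a, b), w in edges.items():
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    return RegularizedNetwork(
        node_names=list(names), W=W, lambda_selected=0.1, gamma=0.5, n=100
    )


@pytest.fixture
def small_planted_dataset():
    """p=4 chain with one strong edge, n=500."""
    spec = chain_spec({(0, 1): 0.4, (1, 2): 0.3, (2, 3): 0.3}, 4, n_subjects=500, seed=11)
    return spec, generate_dataset(spec)
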