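"""Shared fixtures and independent brute-force oracles.

The oracles enumerate full joint state spaces directly from the CPT
arrays with itertools — no variable elimination, no factor algebra — so
they stay independent of the inference path they are used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from nanohazard.bn.network import DiscreteBayesNet, NodeSpec
from nanohazard.loe import tio2_fixture
from nanohazard.scoring import fit_aggregation_weights


@pytest.fixture(scope="session")
def tio2():
    return tio2_fixture()


@pytest.fixture(scope="session")
def fitted_weights(tio2):
    weights, _ = fit_aggregation_weights(tio2)
    return weights


# ---------------------------------------------------------------------------
# brute-force enumeration oracles

def joint_configs(net: DiscreteBayesNet):
    """Yield (config dict, probability) for every full joint configuration,
    with the probability read off the CPT entries directly."""
    names = list(net.nodes)
    for combo in itertools.product(*(range(net.nodes[n].card) for n in names)):
        assign = dict(zip(names, combo))
        p = 1.0
        for name in names:
            idx = tuple(assign[v] for v in net.parents[name]) + (assign[name],)
            p *= float(net.cpts[name][idx])
        yield assign, p


def brute_posterior(net: DiscreteBayesNet, evidence: dict, query: str) -> np.ndarray:
    """P(query | evidence) by full joint summation."""
    coded = {k: net.nodes[k].index(v) for k, v in (evidence or {}).items()}
    probs = np.zeros(net.nodes[query].card)
    for assign, p in joint_configs(net):
        if all(assign[k] == v for k, v in coded.items()):
            probs[assign[query]] += p
    total = probs.sum()
    if total <= 0:
        raise ZeroDivisionError("evidence has zero probability")
    return probs / total


def brute_mutual_information(
    net: DiscreteBayesNet, x: str, y: str, evidence: dict | None = None
) -> float:
    """I(x; y | evidence) from the enumerated joint (natural log)."""
    coded = {k: net.nodes[k].index(v) for k, v in (evidence or {}).items()}
    joint = np.zeros((net.nodes[x].card, net.nodes[y].card))
    for assign, p in joint_configs(net):
        if all(assign[k] == v for k, v in coded.items()):
            joint[assign[x], assign[y]] += p
    joint = joint / joint.sum()
    px, py = joint.sum(axis=1), joint.sum(axis=0)
    mi = 0.0
    for i, j in itertools.product(range(len(px)), range(len(py))):
        if joint[i, j] > 0:
            mi += joint[i, j] * math.log(joint[i, j] / (px[i] * py[j]))
    return mi


def random_network(
    rng: np.random.Generator, max_nodes: int = 6, max_states: int = 4
) -> DiscreteBayesNet:
    """A random DAG (edges only forward in node order) with Dirichlet CPTs."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = [
        NodeSpec(f"n{i}", tuple(f"s{j}" for j in range(rng.integers(2, max_states + 1))))
        for i in range(n)
    ]
    edges = [
        (nodes[i].name, nodes[j].name)
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < 0.5
    ]
    net = DiscreteBayesNet(nodes, edges)
    for name in net.nodes:
        shape = net.cpt_shape(name)
        flat = rng.dirichlet(np.ones(shape[-1]), size=int(np.prod(shape[:-1]) or 1))
        net.set_cpt(name, flat.reshape(shape))
    return net
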