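"""Network structure: nodes, edges, conditional probability tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

CATEGORIES = ("physchem", "experimental", "biological", "hazard")


class BNError(ValueError):
    """Invalid network structure, table, or evidence."""


@dataclass(frozen=True)
class NodeSpec:
    """A categorical variable: its name, ordered states, and thematic
    category (physchem, experimental, biological, or hazard)."""

    name: str
    states: tuple[str, ...]
    category: str = "physchem"

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise BNError(f"node {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise BNError(f"node {self.name!r} has duplicate states")
        if self.category not in CATEGORIES:
            raise BNError(
                f"node {self.name!r}: category {self.category!r} not in {CATEGORIES}"
            )

    @property
    def card(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise BNError(
                f"node {self.name!r}: unknown state {state!r} "
                f"(states: {list(self.states)})"
            ) from None


class DiscreteBayesNet:
    """DAG over categorical nodes with one CPT per node.

    A CPT is stored as an array with one axis per parent (in declared
    order) plus a final axis for the node itself; every slice along the
    final axis sums to one.
    """

    def __init__(
        self,
        nodes: Sequence[NodeSpec],
        edges: Sequence[tuple[str, str]],
        cpts: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.nodes: dict[str, NodeSpec] = {n.name: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise BNError("duplicate node names")
        for u, v in edges:
            for name in (u, v):
                if name not in self.nodes:
                    raise BNError(f"edge ({u}, {v}) references unknown node {name!r}")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise BNError(f"graph has a cycle: {cycle}")
        self.graph = g
        self.parents: dict[str, tuple[str, ...]] = {
            name: tuple(sorted(g.predecessors(name), key=list(self.nodes).index))
            for name in self.nodes
        }
        self.cpts: dict[str, np.ndarray] = {}
        for name in self.nodes:
            if cpts is not None and name in cpts:
                self.set_cpt(name, cpts[name])
            else:
                self.set_cpt(name, self._uniform_cpt(name))
        if cpts is not None:
            extra = set(cpts) - set(self.nodes)
            if extra:
                raise BNError(f"CPTs for unknown nodes: {sorted(extra)}")

    # -- structure ---------------------------------------------------------

    def cpt_shape(self, name: str) -> tuple[int, ...]:
        return tuple(self.nodes[p].card for p in self.parents[name]) + (
            self.nodes[name].card,
        )

    def _uniform_cpt(self, name: str) -> np.ndarray:
        shape = self.cpt_shape(name)
        return np.full(shape, 1.0 / shape[-1])

    def set_cpt(self, name: str, table: np.ndarray) -> None:
        arr = np.asarray(table, dtype=float)
        expected = self.cpt_shape(name)
        if arr.shape != expected:
            raise BNError(
                f"CPT for {name!r} has shape {arr.shape}, expected {expected} "
                f"(parents {self.parents[name]})"
            )
        if (arr < 0).any():
            raise BNError(f"CPT for {name!r} has negative entries")
        sums = arr.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise BNError(
                f"CPT for {name!r}: columns sum to "
                f"[{sums.min():.12f}, {sums.max():.12f}], expected 1"
            )
        self.cpts[name] = arr

    def topological_order(self) -> list[str]:
        declared = list(self.nodes)
        return list(
            nx.lexicographical_topological_sort(self.graph, key=declared.index)
        )

    def family(self, name: str) -> tuple[str, ...]:
        return self.parents[name] + (name,)

    def copy(self) -> "DiscreteBayesNet":
        return DiscreteBayesNet(
            list(self.nodes.values()),
            list(self.graph.edges),
            {k: v.copy() for k, v in self.cpts.items()},
        )

    # -- sampling ----------------------------------------------------------

    def sample(
        self,
        n: int,
        rng: np.random.Generator,
        clamp: Mapping[str, str] | None = None,
    ) -> "pd.DataFrame":
        """Ancestral sampling of ``n`` joint configurations (state names).

        ``clamp`` conditions on root-node states (exact conditioning, since
        roots have no parents); clamping a non-root or a zero-prior state
        raises.
        """
        import pandas as pd

        clamp = dict(clamp or {})
        for name, state in clamp.items():
            if self.parents[name]:
                raise BNError(f"can only clamp root nodes, {name!r} has parents")
            if self.cpts[name][self.nodes[name].index(state)] <= 0:
                raise BNError(f"clamped state {name}={state!r} has zero prior")
        codes: dict[str, np.ndarray] = {}
        for name in nx.topological_sort(self.graph):
            spec = self.nodes[name]
            if name in clamp:
                codes[name] = np.full(n, spec.index(clamp[name]), dtype=int)
                continue
            cpt = self.cpts[name]
            parents = self.parents[name]
            if not parents:
                codes[name] = rng.choice(spec.card, size=n, p=cpt)
            else:
                flat = cpt.reshape(-1, spec.card)
                strides = np.cumprod(
                    [1] + [self.nodes[p].card for p in reversed(parents[1:])]
                )[::-1]
                idx = sum(codes[p] * s for p, s in zip(parents, strides))
                u = rng.random(n)
                cum = np.cumsum(flat[idx], axis=1)
                codes[name] = (u[:, None] > cum).sum(axis=1)
        return pd.DataFrame(
            {name: [self.nodes[name].states[c] for c in codes[name]] for name in self.nodes}
        )

    # -- serialization -----------------------------------------------------

    def to_config(self) -> dict:
        return {
            "nodes": [
                {"name": n.name, "states": list(n.states), "category": n.category}
                for n in self.nodes.values()
            ],
            "edges": [[u, v] for u, v in self.graph.edges],
            "cpts": {name: self.cpts[name].tolist() for name in self.nodes},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_config(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "DiscreteBayesNet":
        return build_network(yaml.safe_load(Path(path).read_text()))


def build_network(spec: Mapping) -> DiscreteBayesNet:
    """Build a validated network from a declarative config mapping with
    ``nodes`` (name, states, category), ``edges``, and optional ``cpts``
    (nested lists, axes = parents in declared order then the node)."""
    nodes = [
        NodeSpec(
            name=str(n["name"]),
            states=tuple(str(s) for s in n["states"]),
            category=str(n.get("category", "physchem")),
        )
        for n in spec["nodes"]
    ]
    edges = [(str(u), str(v)) for u, v in spec.get("edges", [])]
    cpts = None
    if spec.get("cpts"):
        cpts = {str(k): np.asarray(v, dtype=float) for k, v in spec["cpts"].items()}
    return DiscreteBayesNet(nodes, edges, cpts)


def default_structure() -> DiscreteBayesNet:
    """The default hazard network over the literature-database node set.

    Nodes and state discretisations follow the published case-table header
    (shape, nanoparticle, dissolution, surface area, surface charge,
    surface coatings, surface reactivity, aggregation, particle size,
    administration route, study type) plus the four-state hazard node. The
    published model's final learned edge set was not released, so the
    default wiring is the tree-shaped classifier orientation —
    nanoparticle -> hazard -> each descriptor — whose per-node tables stay
    estimable from a few hundred records; richer layered structures can be
    supplied via config. CPTs initialise uniform and are meant to be
    learned.
    """
    ref = resources.files("nanohazard.data").joinpath("bn_structure.yaml")
    with resources.as_file(ref) as path:
        return build_network(yaml.safe_load(Path(path).read_text()))
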