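"""Exact inference by sum-product variable elimination.

Factors are dense arrays with one axis per variable. Evidence is applied
by slicing; elimination order is greedy (smallest intermediate factor
first). Small networks throughout, so dense exact inference is the right
tool — no approximate or sampling inference is provided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .network import BNError, DiscreteBayesNet


class InconsistentEvidenceError(BNError):
    """Evidence with probability zero under the model."""


@dataclass(frozen=True)
class Factor:
    vars: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        if self.table.ndim != len(self.vars):
            raise BNError("factor table rank does not match variable list")


def _align(f: Factor, vars_: Sequence[str], cards: Mapping[str, int]) -> np.ndarray:
    """Broadcast a factor's table to the axis layout of ``vars_``."""
    perm = [f.vars.index(v) for v in vars_ if v in f.vars]
    t = np.transpose(f.table, perm)
    shape = [cards[v] if v in f.vars else 1 for v in vars_]
    return t.reshape(shape)


def factor_product(factors: Sequence[Factor], cards: Mapping[str, int]) -> Factor:
    vars_: list[str] = []
    for f in factors:
        vars_.extend(v for v in f.vars if v not in vars_)
    table = np.ones([cards[v] for v in vars_])
    for f in factors:
        table = table * _align(f, vars_, cards)
    return Factor(tuple(vars_), table)


def _sum_out(f: Factor, var: str) -> Factor:
    axis = f.vars.index(var)
    return Factor(
        tuple(v for v in f.vars if v != var), f.table.sum(axis=axis)
    )


def _reduce_evidence(
    factors: list[Factor], evidence: Mapping[str, int], cards: Mapping[str, int]
) -> list[Factor]:
    reduced = []
    for f in factors:
        t, vars_ = f.table, list(f.vars)
        for var in f.vars:
            if var in evidence:
                axis = vars_.index(var)
                t = np.take(t, evidence[var], axis=axis)
                vars_.pop(axis)
        reduced.append(Factor(tuple(vars_), t))
    return reduced


def _eliminate_all(
    factors: list[Factor], keep: set[str], cards: Mapping[str, int]
) -> Factor:
    """Sum out every variable not in ``keep``; greedy smallest-product-first
    ordering."""
    factors = list(factors)
    to_go = {v for f in factors for v in f.vars} - keep
    while to_go:
        best_var, best_cost = None, None
        for var in to_go:
            involved = [f for f in factors if var in f.vars]
            scope = {v for f in involved for v in f.vars}
            cost = int(np.prod([cards[v] for v in scope]))
            if best_cost is None or cost < best_cost:
                best_var, best_cost = var, cost
        involved = [f for f in factors if best_var in f.vars]
        rest = [f for f in factors if best_var not in f.vars]
        factors = rest + [_sum_out(factor_product(involved, cards), best_var)]
        to_go.discard(best_var)
    return factor_product(factors, cards)


@dataclass(frozen=True)
class PosteriorDistribution:
    """Posterior probabilities over the states of one node."""

    node: str
    states: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if len(p) != len(self.states):
            raise BNError("probability vector length does not match states")
        if (p < -1e-12).any() or abs(p.sum() - 1.0) > 1e-9:
            raise BNError(f"invalid posterior for {self.node!r}: {p}")
        object.__setattr__(self, "probs", np.clip(p, 0.0, None))

    def __getitem__(self, state: str) -> float:
        return float(self.probs[self.states.index(state)])

    @property
    def argmax_state(self) -> str:
        # ties resolve to the earliest (lowest-severity) state
        return self.states[int(np.argmax(self.probs))]


def _code_evidence(net: DiscreteBayesNet, evidence: Mapping[str, str]) -> dict[str, int]:
    coded = {}
    for name, state in evidence.items():
        if name not in net.nodes:
            raise BNError(f"evidence on unknown node {name!r}")
        coded[name] = net.nodes[name].index(state)
    return coded


def _ve(
    net: DiscreteBayesNet,
    evidence: Mapping[str, str],
    query_vars: tuple[str, ...],
) -> tuple[np.ndarray, float]:
    """Joint posterior table over ``query_vars`` and the evidence
    probability P(evidence)."""
    coded = _code_evidence(net, evidence)
    for q in query_vars:
        if q in coded:
            raise BNError(f"query node {q!r} is already in the evidence")
    cards = {name: spec.card for name, spec in net.nodes.items()}
    factors = [
        Factor(net.family(name), net.cpts[name]) for name in net.nodes
    ]
    factors = _reduce_evidence(factors, coded, cards)
    result = _eliminate_all(factors, set(query_vars), cards)
    z = float(result.table.sum())
    if z <= 0.0:
        raise InconsistentEvidenceError(
            f"evidence {dict(evidence)} has probability zero under the model"
        )
    table = _align(result, query_vars, cards).reshape(
        [cards[v] for v in query_vars]
    )
    return table / z, z


def posterior_marginal(
    net: DiscreteBayesNet,
    evidence: Mapping[str, str],
    query_vars: Sequence[str],
) -> np.ndarray:
    """Joint posterior over several query variables given evidence, as an
    array with one axis per query variable (in the given order)."""
    table, _ = _ve(net, evidence or {}, tuple(query_vars))
    return table


def infer_posterior(
    net: DiscreteBayesNet,
    evidence: Mapping[str, str] | None,
    query: str,
) -> PosteriorDistribution:
    """Exact conditional distribution of one node given evidence."""
    table, _ = _ve(net, evidence or {}, (query,))
    return PosteriorDistribution(query, net.nodes[query].states, table)


def log_evidence(net: DiscreteBayesNet, evidence: Mapping[str, str]) -> float:
    """log P(evidence) under the network."""
    if not evidence:
        return 0.0
    first = next(iter(net.nodes))
    query = first if first not in evidence else next(
        n for n in net.nodes if n not in evidence
    ) if len(evidence) < len(net.nodes) else None
    if query is None:
        # fully observed: multiply the relevant CPT entries directly
        coded = _code_evidence(net, evidence)
        logp = 0.0
        for name in net.nodes:
            idx = tuple(coded[p] for p in net.family(name))
            p = float(net.cpts[name][idx])
            if p <= 0.0:
                raise InconsistentEvidenceError(
                    f"evidence {dict(evidence)} has probability zero under the model"
                )
            logp += np.log(p)
        return logp
    _, z = _ve(net, evidence, (query,))
    return float(np.log(z))
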