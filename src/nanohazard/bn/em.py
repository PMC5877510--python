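"""Expectation-maximization estimation of CPTs from incomplete records.

Records are categorical observations of a subset of the nodes; absent
values mean the node was unobserved in that study, never a distinct
state. The E-step computes, for every node family (parents + node) and
every distinct observation pattern, the exact family posterior given the
observed entries; the M-step renormalises expected counts with a Laplace
pseudo-count per CPT cell. The observed-data log-likelihood is
nondecreasing across iterations, and on complete data a single M-step
yields the (smoothed) empirical frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import _ve, log_evidence
from .network import BNError, DiscreteBayesNet

_MISSING_TOKENS = {"-", "", "na", "nan"}


def _encode(net: DiscreteBayesNet, dataset: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Integer-code a dataframe of state names; -1 marks missing."""
    cols = [c for c in dataset.columns if c in net.nodes]
    if not cols:
        raise BNError("dataset has no columns matching network nodes")
    coded = np.full((len(dataset), len(cols)), -1, dtype=int)
    for j, col in enumerate(cols):
        spec = net.nodes[col]
        lookup = {s: i for i, s in enumerate(spec.states)}
        for i, raw in enumerate(dataset[col].tolist()):
            if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                continue
            text = str(raw)
            if text.strip().lower() in _MISSING_TOKENS:
                continue
            if text not in lookup:
                raise BNError(
                    f"row {i}, column {col!r}: unknown state {text!r} "
                    f"(states: {list(spec.states)})"
                )
            coded[i, j] = lookup[text]
    return coded, cols


@dataclass
class EMResult:
    net: DiscreteBayesNet
    log_likelihoods: list[float]
    n_iter: int
    converged: bool


def learn_parameters_em(
    net: DiscreteBayesNet,
    dataset: pd.DataFrame,
    max_iter: int = 200,
    tol: float = 1e-6,
    smoothing: float = 1.0,
) -> EMResult:
    """Fit CPTs by EM on (possibly incomplete) categorical records.

    The structure is fixed; only the tables move. ``tol`` is the relative
    change in observed-data log-likelihood that stops the iteration;
    ``smoothing`` is the Laplace pseudo-count added to every CPT cell in
    each M-step (it also regularises families never observed together).
    """
    if len(dataset) == 0:
        raise BNError("empty training dataset")
    coded, cols = _encode(net, dataset)

    # collapse duplicate observation patterns; EM cost then scales with the
    # number of distinct patterns, not records
    patterns, counts = np.unique(coded, axis=0, return_counts=True)
    col_index = {c: j for j, c in enumerate(cols)}

    current = net.copy()
    lls: list[float] = []
    converged = False
    for _ in range(max_iter):
        expected = {
            name: np.zeros(current.cpt_shape(name)) for name in current.nodes
        }
        ll = 0.0
        for pattern, count in zip(patterns, counts):
            evidence = {
                c: current.nodes[c].states[pattern[col_index[c]]]
                for c in cols
                if pattern[col_index[c]] >= 0
            }
            ll += count * log_evidence(current, evidence)
            for name in current.nodes:
                fam = current.family(name)
                hidden = tuple(v for v in fam if v not in evidence)
                post = _ve(current, evidence, hidden)[0] if hidden else np.array(1.0)
                # scatter the posterior mass into the family cell(s);
                # hidden axes of `post` line up with the slice positions
                idx = tuple(
                    slice(None) if v in hidden
                    else current.nodes[v].index(evidence[v])
                    for v in fam
                )
                expected[name][idx] += count * post
        lls.append(ll)
        for name in current.nodes:
            cnt = expected[name] + smoothing
            current.set_cpt(name, cnt / cnt.sum(axis=-1, keepdims=True))
        if len(lls) >= 2:
            prev, cur = lls[-2], lls[-1]
            if abs(cur - prev) <= tol * max(1.0, abs(prev)):
                converged = True
                break
    return EMResult(
        net=current, log_likelihoods=lls, n_iter=len(lls), converged=converged
    )
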