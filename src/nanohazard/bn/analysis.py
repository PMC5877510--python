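"""Entropy, value of information, hazard scoring, and scenario tables.

The value-of-information analysis ranks input nodes by how much observing
them would reduce the entropy of the hazard node — the conditional mutual
information between each candidate and the hazard given current evidence.
The normalised hazard score collapses the four-state hazard posterior to
[0, 1] with the uniform utility scale (0, 1/3, 2/3, 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .inference import (
    InconsistentEvidenceError,
    PosteriorDistribution,
    infer_posterior,
)
from .network import BNError, DiscreteBayesNet


def entropy(dist: PosteriorDistribution | Sequence[float], base: float | None = None) -> float:
    """Shannon entropy ``-sum p log p`` with ``0 log 0 = 0``.

    Natural log by default; pass ``base`` (e.g. 2) to rescale. The base
    only rescales value-of-information rankings, never reorders them.
    """
    p = dist.probs if isinstance(dist, PosteriorDistribution) else np.asarray(dist, float)
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return max(h, 0.0)


@dataclass(frozen=True)
class HazardScale:
    """Utilities for the hazard states; nondecreasing from 0 to 1.

    The default uniform scale (0, 1/3, 2/3, 1) maps (None, Low, Medium,
    High) onto equal steps.
    """

    states: tuple[str, ...] = ("None", "Low", "Medium", "High")
    utilities: tuple[float, ...] = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)

    def __post_init__(self) -> None:
        if len(self.states) != len(self.utilities):
            raise BNError("one utility per hazard state required")
        u = np.asarray(self.utilities, float)
        if u[0] != 0.0 or u[-1] != 1.0 or (np.diff(u) < 0).any():
            raise BNError("utilities must be nondecreasing from 0 to 1")


def normalized_hazard_score(
    posterior: PosteriorDistribution, scale: HazardScale = HazardScale()
) -> float:
    """Weighted sum of hazard-state probabilities and the utility scale;
    a score in [0, 1] (display convention: percentage rounded to integer)."""
    if tuple(posterior.states) != tuple(scale.states):
        raise BNError(
            f"posterior states {posterior.states} do not match scale states "
            f"{scale.states}"
        )
    return float(np.dot(posterior.probs, scale.utilities))


def value_of_information(
    net: DiscreteBayesNet,
    target: str,
    candidates: Sequence[str],
    evidence: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Expected entropy reduction of ``target`` from observing each
    candidate node, given base evidence; returned ranked descending.

    For candidate X this is ``H(target | e) - E_x[H(target | e, X=x)]``,
    the conditional mutual information I(target; X | e): nonnegative, and
    zero exactly when X is conditionally independent of the target.
    """
    evidence = dict(evidence or {})
    if target in evidence:
        raise BNError("target node cannot be part of the evidence")
    h_base = entropy(infer_posterior(net, evidence, target))
    out: dict[str, float] = {}
    for cand in candidates:
        if cand == target:
            continue
        if cand in evidence:
            warnings.warn(f"candidate {cand!r} already observed; skipped")
            continue
        p_cand = infer_posterior(net, evidence, cand)
        h_cond = 0.0
        for state, p in zip(p_cand.states, p_cand.probs):
            if p <= 0:
                continue
            h_cond += p * entropy(
                infer_posterior(net, {**evidence, cand: state}, target)
            )
        out[cand] = max(h_base - h_cond, 0.0)  # clip -eps from float noise
    return dict(sorted(out.items(), key=lambda kv: (-kv[1], kv[0])))


def scenario_table(
    net: DiscreteBayesNet,
    nm: str,
    input_node: str,
    nm_node: str = "nanoparticle",
    hazard_node: str = "hazard",
    scale: HazardScale = HazardScale(),
) -> pd.DataFrame:
    """Normalised hazard score for each state of one input node.

    Each row conditions on the nanomaterial plus one state of
    ``input_node``; the final ``No Evidence`` row conditions on the
    nanomaterial alone. States inconsistent with the model leave a missing
    cell.
    """
    if net.nodes[input_node].card < 2:
        raise BNError(f"input node {input_node!r} has fewer than 2 states")
    rows = []
    for state in net.nodes[input_node].states:
        try:
            post = infer_posterior(
                net, {nm_node: nm, input_node: state}, hazard_node
            )
            score = normalized_hazard_score(post, scale)
        except InconsistentEvidenceError:
            score = np.nan
        rows.append((state, score))
    baseline = normalized_hazard_score(
        infer_posterior(net, {nm_node: nm}, hazard_node), scale
    )
    rows.append(("No Evidence", baseline))
    return pd.DataFrame(rows, columns=[input_node, nm]).set_index(input_node)
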