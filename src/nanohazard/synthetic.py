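"""Synthetic line-of-evidence generator.

Emulates the statistical shape of a literature hazard database: a few
hundred categorical records sampled from a known ground-truth network
over nanomaterial identity, discretised physico-chemical descriptors,
study type and an observed hazard state, with values missing completely
at random the way real study reports omit characterisation data. Each
case also receives a toxicity-class likelihood vector concentrated on the
class matching its true hazard state and study-quality criteria drawn per
study, so the weight-of-evidence scoring and the network learning consume
*correlated* signals — the property the two-framework comparison needs.

Because the generating network is known, exact oracle quantities (state
marginals, the Bayes-optimal prediction accuracy) are available for
validating the learning pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .bn.inference import Factor, factor_product, infer_posterior
from .bn.network import BNError, DiscreteBayesNet, NodeSpec
from .loe import (
    MISSING,
    EvidenceTable,
    LOERecord,
    StudyQuality,
    ToxClassAssignment,
)
from .scoring import CategoricalRule, ScoringRuleSet

#: hazard state -> toxicity class index (C1..C5 as 0..4); None maps to the
#: no-evidence class, High to the convincing-causal-evidence class
DEFAULT_CLASS_MAP = {"None": 0, "Low": 1, "Medium": 3, "High": 4}


def _child_cpt(n_hazard: int, k: int, orientation: int, spread: float = 1.1) -> np.ndarray:
    """CPT of a descriptor given hazard: a discretised bump whose location
    tracks hazard severity (orientation +1) or runs against it (-1),
    mixed with a uniform floor so no state is impossible."""
    cpt = np.empty((n_hazard, k))
    for h in range(n_hazard):
        sev = h / (n_hazard - 1)
        m = (sev if orientation > 0 else 1.0 - sev) * (k - 1)
        w = np.exp(-((np.arange(k) - m) ** 2) / (2 * spread**2))
        cpt[h] = 0.9 * w / w.sum() + 0.1 / k
    return cpt


def default_ground_truth() -> DiscreteBayesNet:
    """Three nanomaterials of low, mid and high intrinsic hazard, a
    four-state hazard node, and four descriptors carrying graded signal
    about the hazard state (small particle size, high surface reactivity
    and low aggregation lean hazardous; in vivo studies report hazard
    slightly more often)."""
    nodes = [
        NodeSpec("nanoparticle", ("NM_low", "NM_mid", "NM_high"), "physchem"),
        NodeSpec("hazard", ("None", "Low", "Medium", "High"), "hazard"),
        NodeSpec("particle_size", ("0-10", "10-50", "50-100", ">100"), "physchem"),
        NodeSpec("surface_reactivity", ("Low", "Medium", "High"), "physchem"),
        NodeSpec("aggregation", ("Low", "Medium", "High"), "physchem"),
        NodeSpec("study_type", ("in vitro", "in vivo"), "experimental"),
    ]
    edges = [("nanoparticle", "hazard")] + [
        ("hazard", c)
        for c in ("particle_size", "surface_reactivity", "aggregation", "study_type")
    ]
    cpts = {
        "nanoparticle": np.array([1 / 3, 1 / 3, 1 / 3]),
        "hazard": np.array(
            [
                [0.55, 0.25, 0.12, 0.08],  # NM_low
                [0.25, 0.30, 0.25, 0.20],  # NM_mid
                [0.05, 0.12, 0.30, 0.53],  # NM_high
            ]
        ),
        "particle_size": _child_cpt(4, 4, -1),
        "surface_reactivity": _child_cpt(4, 3, +1),
        "aggregation": _child_cpt(4, 3, -1),
        "study_type": _child_cpt(4, 2, +1, spread=1.6),
    }
    return DiscreteBayesNet(nodes, edges, cpts)


def synthetic_rules() -> ScoringRuleSet:
    """Physico-chemical scoring rules aligned with the ground-truth
    orientation of each descriptor (hazardous states score high)."""
    return ScoringRuleSet(
        {
            "particle_size": CategoricalRule(
                {"0-10": 100.0, "10-50": 75.0, "50-100": 50.0, ">100": 25.0}
            ),
            "surface_reactivity": CategoricalRule(
                {"Low": 25.0, "Medium": 50.0, "High": 100.0}
            ),
            "aggregation": CategoricalRule(
                {"Low": 100.0, "Medium": 50.0, "High": 25.0}
            ),
        }
    )


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic database.

    Defaults mirror the reference literature corpus: three nanomaterials
    at ~75 lines of evidence each, a held-out test set of ~14 cases per
    nanomaterial, 20% of descriptor values missing completely at random,
    toxicity likelihoods Dirichlet-concentrated (alpha 8 vs 1) on the
    class matching the true hazard state, and study-quality criteria drawn
    from Beta(5, 2) (mean 0.71, the typical published study weight).
    """

    ground_truth: DiscreteBayesNet = field(default_factory=default_ground_truth)
    nm_node: str = "nanoparticle"
    hazard_node: str = "hazard"
    cases_per_nm: int | Mapping[str, int] = 75
    test_per_nm: int = 14
    missingness: float = 0.2
    test_missingness: float = 0.2
    tox_concentration: float = 8.0
    class_map: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MAP)
    )
    quality_beta: tuple[float, float] = (5.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (self.nm_node, self.hazard_node):
            if name not in self.ground_truth.nodes:
                raise BNError(f"ground truth has no node {name!r}")
        counts = self.counts()
        if any(c < 1 for c in counts.values()) or self.test_per_nm < 1:
            raise BNError("case counts must be >= 1")
        for rate in (self.missingness, self.test_missingness):
            if not 0.0 <= rate < 1.0:
                raise BNError(f"missingness rate {rate} outside [0,1)")
        if self.tox_concentration <= 0:
            raise BNError("tox concentration must be positive")

    def counts(self) -> dict[str, int]:
        nms = self.ground_truth.nodes[self.nm_node].states
        if isinstance(self.cases_per_nm, Mapping):
            return {nm: int(self.cases_per_nm.get(nm, 0)) for nm in nms}
        return {nm: int(self.cases_per_nm) for nm in nms}

    @property
    def input_nodes(self) -> list[str]:
        return [
            n
            for n in self.ground_truth.nodes
            if n not in (self.nm_node, self.hazard_node)
        ]


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must recover."""

    net: DiscreteBayesNet
    config: GeneratorConfig
    hazard_marginals: dict[str, np.ndarray]  # per NM, exact P(hazard | NM)
    rules: ScoringRuleSet


@dataclass
class SyntheticBundle:
    woe_tables: dict[str, EvidenceTable]
    train: pd.DataFrame
    test: pd.DataFrame
    truth: GroundTruth


def _apply_missingness(
    df: pd.DataFrame, nodes: list[str], rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    out = df.copy()
    if rate > 0:
        for col in nodes:
            mask = rng.random(len(out)) < rate
            out.loc[mask, col] = MISSING
    return out


def generate(config: GeneratorConfig | None = None) -> SyntheticBundle:
    """Sample a full synthetic bundle: per-NM WoE evidence tables, a
    network training table with gaps, a disjoint held-out test table, and
    the ground-truth record."""
    config = config or GeneratorConfig()
    net = config.ground_truth
    rng = np.random.default_rng(config.seed)
    nm_states = net.nodes[config.nm_node].states
    hazard_states = net.nodes[config.hazard_node].states
    inputs = config.input_nodes

    train_parts, test_parts = [], []
    woe_tables: dict[str, EvidenceTable] = {}
    for nm in nm_states:
        n_train = config.counts()[nm]
        full = net.sample(n_train + config.test_per_nm, rng, clamp={config.nm_node: nm})
        train_full = full.iloc[:n_train].reset_index(drop=True)
        test_full = full.iloc[n_train:].reset_index(drop=True)
        train_masked = _apply_missingness(train_full, inputs, config.missingness, rng)
        test_masked = _apply_missingness(test_full, inputs, config.test_missingness, rng)
        train_parts.append(train_masked)
        test_parts.append(test_masked)
        woe_tables[nm] = _woe_table(nm, train_masked, config, rng)

    truth = GroundTruth(
        net=net,
        config=config,
        hazard_marginals={
            nm: infer_posterior(net, {config.nm_node: nm}, config.hazard_node).probs
            for nm in nm_states
        },
        rules=synthetic_rules() if _rules_cover(inputs) else ScoringRuleSet({}),
    )
    return SyntheticBundle(
        woe_tables=woe_tables,
        train=pd.concat(train_parts, ignore_index=True),
        test=pd.concat(test_parts, ignore_index=True),
        truth=truth,
    )


def _rules_cover(inputs: list[str]) -> bool:
    return bool(set(synthetic_rules().rules) & set(inputs))


def _woe_table(
    nm: str, cases: pd.DataFrame, config: GeneratorConfig, rng: np.random.Generator
) -> EvidenceTable:
    from .loe import STUDY_TYPES

    class_map = dict(config.class_map)
    a, b = config.quality_beta
    records = []
    for i, row in cases.iterrows():
        hazard = str(row[config.hazard_node])
        alpha = np.ones(5)
        alpha[class_map.get(hazard, 0)] = config.tox_concentration
        d = rng.dirichlet(alpha)
        d = d / d.sum()
        quality = StudyQuality(
            {
                "adequacy": float(rng.beta(a, b)),
                "reliability": float(rng.beta(a, b)),
                "statistical_power": float(rng.beta(a, b)),
                "toxicological_significance": float(rng.beta(a, b)),
            }
        )
        physchem = {
            node: row[node]
            for node in config.input_nodes
            if row[node] != MISSING and node in synthetic_rules().rules
        }
        study_type = (
            str(row["study_type"])
            if "study_type" in cases.columns and row.get("study_type") in STUDY_TYPES
            else MISSING
        )
        records.append(
            LOERecord(
                loe_id=f"{nm}-{i + 1}",
                nm=nm,
                reference="synthetic",
                physchem=physchem,
                tox=ToxClassAssignment(tuple(d)),
                quality=quality,
                study_type=study_type,
                hazard_label=hazard if hazard in ("None", "Low", "Medium", "High") else MISSING,
            )
        )
    return EvidenceTable(nm=nm, records=records)


# ---------------------------------------------------------------------------
# oracle

_MAX_ENUM_CELLS = 5_000_000


def full_joint(net: DiscreteBayesNet) -> tuple[list[str], np.ndarray]:
    """Dense joint distribution over all nodes (declared order)."""
    names = list(net.nodes)
    cards = {n: net.nodes[n].card for n in names}
    if np.prod([cards[n] for n in names]) > _MAX_ENUM_CELLS:
        raise BNError(
            "network too large for exact enumeration; use Monte Carlo estimation"
        )
    factors = [Factor(net.family(n), net.cpts[n]) for n in names]
    joint = factor_product(factors, cards)
    # realign axes to declared order
    perm = [joint.vars.index(n) for n in names]
    return names, np.transpose(joint.table, perm)


def oracle_bayes_accuracy(config: GeneratorConfig | None = None) -> float:
    """Expected accuracy of the argmax-posterior hazard predictor under the
    *true* generating network, by exact enumeration.

    Accounts for the test-set missingness: the prediction marginalises the
    masked descriptors while the actual label is drawn from the full
    configuration, exactly as in the sampled benchmark. The nanomaterial
    identity is always observed.
    """
    config = config or GeneratorConfig()
    net = config.ground_truth
    names, joint = full_joint(net)
    h_ax = names.index(config.hazard_node)
    input_axes = [names.index(n) for n in config.input_nodes]
    if len(input_axes) > 16:
        raise BNError("too many descriptors to enumerate missingness patterns")
    p_miss = config.test_missingness

    card_h = net.nodes[config.hazard_node].card
    total = 0.0
    for masked in itertools.chain.from_iterable(
        itertools.combinations(input_axes, k) for k in range(len(input_axes) + 1)
    ):
        p_mask = (p_miss ** len(masked)) * (
            (1 - p_miss) ** (len(input_axes) - len(masked))
        )
        if p_mask == 0.0:
            continue
        marg = joint.sum(axis=tuple(masked), keepdims=True) if masked else joint
        pred = np.argmax(marg, axis=h_ax)  # P(observed, hazard) maximiser
        shape = [1] * joint.ndim
        shape[h_ax] = card_h
        indicator = (
            np.expand_dims(pred, h_ax) == np.arange(card_h).reshape(shape)
        )
        total += p_mask * float((joint * indicator).sum())
    return total
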