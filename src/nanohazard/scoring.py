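"""Quantitative weight-of-evidence (WoE) scoring with multi-criteria
decision analysis.

Each line of evidence j gets a physico-chemical index ``S_pchem`` (the
arithmetic mean of per-criterion hazard scores in [0, 100]), a toxicity
index ``S_tox = sum_i C_i * D_ij`` (class scores dotted with the class
likelihoods), an aggregated index ``S_j`` (a weighted sum with
``w_pchem < w_tox``), and a study-quality weight ``W_j``. Normalising the
weights to ``w'_j = W_j / sum(W)`` and summing ``WI_j = S_j * w'_j`` gives
the hazard score ``V`` in [0, 100], comparable between nanomaterials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .loe import (
    EvidenceError,
    EvidenceTable,
    StudyQuality,
    ToxClassAssignment,
    parse_interval,
)

#: toxicity class scores C1..C5: the evenly spaced [0,100] grid with C5=100
#: (convincing causal evidence scores full marks)
DEFAULT_CLASS_SCORES = (0.0, 25.0, 50.0, 75.0, 100.0)


class ScoringError(ValueError):
    """A profile or rule set that cannot be scored."""


@dataclass(frozen=True)
class NumericRule:
    """Score a continuous criterion via ordered breakpoints.

    ``breakpoints`` of length k split the axis into k+1 half-open bins
    ``(-inf, b0), [b0, b1), ..., [b_{k-1}, inf)``; ``scores`` has length
    k+1, one score per bin.
    """

    breakpoints: tuple[float, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if list(self.breakpoints) != sorted(set(self.breakpoints)):
            raise ScoringError("breakpoints must be strictly increasing")
        if len(self.scores) != len(self.breakpoints) + 1:
            raise ScoringError("need one score per bin (len(breakpoints)+1)")
        if any(not 0 <= s <= 100 for s in self.scores):
            raise ScoringError("scores must lie in [0,100]")

    def score(self, value: float) -> float:
        return self.scores[int(np.searchsorted(self.breakpoints, value, side="right"))]


@dataclass(frozen=True)
class CategoricalRule:
    """Score a categorical criterion by exact state lookup."""

    state_scores: Mapping[str, float]

    def __post_init__(self) -> None:
        if any(not 0 <= s <= 100 for s in self.state_scores.values()):
            raise ScoringError("scores must lie in [0,100]")
        object.__setattr__(self, "state_scores", dict(self.state_scores))

    def score(self, state: str) -> float:
        try:
            return self.state_scores[str(state)]
        except KeyError:
            raise ScoringError(f"state {state!r} has no score") from None


@dataclass
class ScoringRuleSet:
    """Per-criterion scoring rules for the physico-chemical index."""

    rules: dict[str, NumericRule | CategoricalRule] = field(default_factory=dict)

    def score_criterion(self, name: str, value: object) -> float:
        rule = self.rules[name]
        if isinstance(rule, NumericRule):
            return rule.score(_as_number(name, value))
        return rule.score(value)

    @classmethod
    def from_config(cls, cfg: Mapping) -> "ScoringRuleSet":
        """Build from a declarative mapping::

            aspect_ratio: {breakpoints: [3], scores: [25, 100]}
            surface_coating: {states: {None: 25, PVP: 75}}
        """
        rules: dict[str, NumericRule | CategoricalRule] = {}
        for name, spec in cfg.items():
            if "breakpoints" in spec:
                rules[name] = NumericRule(
                    tuple(float(b) for b in spec["breakpoints"]),
                    tuple(float(s) for s in spec["scores"]),
                )
            elif "states" in spec:
                rules[name] = CategoricalRule(
                    {str(k): float(v) for k, v in spec["states"].items()}
                )
            else:
                raise ScoringError(
                    f"rule for {name!r} needs 'breakpoints'+'scores' or 'states'"
                )
        return cls(rules)


def default_rules() -> ScoringRuleSet:
    """The published aspect-ratio rule (>= 1:3 elongation scores 100, below
    scores 25). Rules for the remaining criteria are study-team inputs and
    are supplied through configuration."""
    return ScoringRuleSet({"aspect_ratio": NumericRule((3.0,), (25.0, 100.0))})


def _as_number(name: str, value: object) -> float:
    """Numeric value of a criterion: plain number, ``a:b`` ratio (as the
    elongation b/a), or an interval state scored at its lower edge."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    if ":" in text:
        a, _, b = text.partition(":")
        lo, hi = sorted((float(a), float(b)))
        if lo == 0:
            raise ScoringError(f"{name}: degenerate ratio {text!r}")
        return hi / lo
    try:
        return float(text)
    except ValueError:
        pass
    try:
        return parse_interval(text)[0]
    except EvidenceError:
        raise ScoringError(f"{name}: cannot interpret {text!r} numerically") from None


@dataclass(frozen=True)
class ToxClassScores:
    """Scores C1..C5 for the five toxicity classes; nondecreasing, C5=100."""

    c: tuple[float, float, float, float, float] = DEFAULT_CLASS_SCORES

    def __post_init__(self) -> None:
        arr = np.asarray(self.c, dtype=float)
        if len(arr) != 5 or (np.diff(arr) < 0).any():
            raise ScoringError("class scores must be 5 nondecreasing values")
        if arr[-1] != 100.0:
            raise ScoringError("C5 is fixed at 100")
        if (arr < 0).any():
            raise ScoringError("class scores must lie in [0,100]")


@dataclass(frozen=True)
class AggregationWeights:
    """Convex weights for combining the physico-chemical and toxicity
    indices; toxicity evidence weighs more by construction."""

    w_pchem: float = 0.3
    w_tox: float = 0.7

    def __post_init__(self) -> None:
        if self.w_pchem < 0 or self.w_tox < 0:
            raise ScoringError("aggregation weights must be nonnegative")
        if abs(self.w_pchem + self.w_tox - 1.0) > 1e-9:
            raise ScoringError("aggregation weights must sum to 1")
        if self.w_pchem > self.w_tox:
            raise ScoringError("w_pchem must not exceed w_tox")


@dataclass
class HazardScore:
    """Hazard score V for one nanomaterial, with the per-LOE breakdown."""

    nm: str
    v: float
    breakdown: pd.DataFrame  # columns: loe_id, s_pchem, s_tox, s_total,
    #                          quality_weight, weight_norm, weighted_index


# ---------------------------------------------------------------------------
# steps 1-5

def score_physchem(profile: Mapping[str, object], rules: ScoringRuleSet) -> float:
    """Physico-chemical index: arithmetic mean of the scores of all criteria
    present in the profile that have a rule. Criteria without data are left
    out of the mean rather than imputed."""
    scores = [
        rules.score_criterion(name, value)
        for name, value in profile.items()
        if name in rules.rules
    ]
    if not scores:
        raise ScoringError(
            "no scoreable physico-chemical criterion "
            f"(profile has {sorted(profile)}, rules cover {sorted(rules.rules)})"
        )
    return float(np.mean(scores))


def score_toxicity(
    assignment: ToxClassAssignment, c: ToxClassScores = ToxClassScores()
) -> float:
    """Toxicity index: class scores dotted with the class likelihoods."""
    return float(np.dot(c.c, assignment.as_array))


def aggregate_loe(
    s_pchem: float, s_tox: float, weights: AggregationWeights = AggregationWeights()
) -> float:
    """Aggregated LOE index S_j, a convex combination of the two indices."""
    for name, s in (("s_pchem", s_pchem), ("s_tox", s_tox)):
        if not 0 <= s <= 100:
            raise ScoringError(f"{name}={s} outside [0,100]")
    return weights.w_pchem * s_pchem + weights.w_tox * s_tox


def fit_aggregation_weights(table: EvidenceTable) -> tuple[AggregationWeights, dict]:
    """Recover the aggregation weights from a table carrying all three index
    columns, by least squares on ``S_j = a*S_pchem + (1-a)*S_tox``.

    Returns the weights and a residual report (per-row residuals, max
    absolute residual).
    """
    sp, st, s = (table.column(c) for c in ("s_pchem", "s_tox", "s_total"))
    if np.isnan(sp).any() or np.isnan(st).any() or np.isnan(s).any():
        raise ScoringError("fit requires s_pchem, s_tox and s_total on every row")
    x = sp - st
    if len(table) < 2 or np.allclose(x, x[0]):
        raise ScoringError(
            "degenerate system: need >=2 rows with distinct s_pchem - s_tox"
        )
    y = s - st
    a = float(np.dot(x, y) / np.dot(x, x))
    residuals = a * sp + (1 - a) * st - s
    report = {
        "residuals": residuals,
        "max_abs_residual": float(np.abs(residuals).max()),
        "n": len(table),
    }
    return AggregationWeights(a, 1.0 - a), report


def normalize_weights(w: Sequence[float]) -> np.ndarray:
    """Normalise study-quality weights to proportions summing to one."""
    arr = np.asarray(w, dtype=float)
    if (arr < 0).any():
        raise ScoringError("study weights must be nonnegative")
    total = arr.sum()
    if total <= 0:
        raise ScoringError("study weights sum to zero; nothing to normalise")
    return arr / total


def quality_weight(
    quality: StudyQuality, logic: Mapping[str, float] | None = None
) -> float:
    """Study weight W_j from the four regulatory quality criteria.

    A pre-established override passes through unchanged. Otherwise the
    criteria are combined by a weighted mean; ``logic`` maps criterion name
    to its relative weight (default: plain arithmetic mean). The published
    studies derive W_j from a richer rule table that was not released, so
    the mean is a declared stand-in and fully configurable.
    """
    if quality.weight_override is not None:
        return quality.weight_override
    from .loe import QUALITY_CRITERIA

    missing = [c for c in QUALITY_CRITERIA if c not in quality.criteria]
    if missing:
        raise ScoringError(f"quality criteria missing: {missing} (and no override)")
    if logic is None:
        logic = {c: 1.0 for c in QUALITY_CRITERIA}
    total = sum(logic.values())
    return sum(quality.criteria[c] * w for c, w in logic.items()) / total


def hazard_score(
    table: EvidenceTable,
    rules: ScoringRuleSet | None = None,
    class_scores: ToxClassScores = ToxClassScores(),
    weights: AggregationWeights = AggregationWeights(),
    quality_logic: Mapping[str, float] | None = None,
) -> HazardScore:
    """Hazard score V for one nanomaterial (WoE steps 1-5).

    Precomputed index columns take precedence over raw inputs, so published
    tables are re-aggregated exactly as printed; tables with raw profiles
    are scored from the rule set. Missing-evidence policy per LOE: absent
    toxicity evidence scores zero (the row stays in), while an LOE with no
    scoreable physico-chemical criterion at all falls back to its toxicity
    index alone (the weight renormalises onto the available component,
    shown as a gap in the breakdown).
    """
    if len(table) == 0:
        raise ScoringError("empty evidence table")
    rules = rules if rules is not None else default_rules()

    sp, st, w = [], [], []
    for r in table:
        if "s_pchem" in r.precomputed:
            sp.append(r.precomputed["s_pchem"])
        elif r.physchem and any(name in rules.rules for name in r.physchem):
            sp.append(score_physchem(r.physchem, rules))
        else:
            sp.append(math.nan)
        if "s_tox" in r.precomputed:
            st.append(r.precomputed["s_tox"])
        elif r.tox is not None:
            st.append(score_toxicity(r.tox, class_scores))
        else:
            # absent toxicity evidence contributes zero, not exclusion
            st.append(0.0)
        if "quality_weight" in r.precomputed:
            w.append(r.precomputed["quality_weight"])
        elif r.quality is not None:
            w.append(quality_weight(r.quality, quality_logic))
        else:
            raise ScoringError(f"LOE {r.loe_id}: no study quality information")

    sp, st = np.asarray(sp), np.asarray(st)
    s = np.where(
        np.isnan(sp), st, weights.w_pchem * np.nan_to_num(sp) + weights.w_tox * st
    )
    wn = normalize_weights(w)
    wi = s * wn
    breakdown = pd.DataFrame(
        {
            "loe_id": [r.loe_id for r in table],
            "s_pchem": sp,
            "s_tox": st,
            "s_total": s,
            "quality_weight": np.asarray(w, dtype=float),
            "weight_norm": wn,
            "weighted_index": wi,
        }
    )
    return HazardScore(nm=table.nm, v=float(wi.sum()), breakdown=breakdown)
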