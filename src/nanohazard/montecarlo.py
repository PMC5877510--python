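"""Monte Carlo sensitivity and uncertainty analysis of the WoE hazard score.

Four sampling scenarios stress the score: (i) redraw every per-LOE
physico-chemical index uniformly on [0, 100]; (ii) likewise the toxicity
index; (iii) redraw the study-quality weights uniformly on [0, 1] and
renormalise; (iv) redraw all three at once. Each scenario reruns the
scoring 10,000 times (by default) and summarises the simulated scores V'
by mean, standard deviation and average absolute deviation |V' - V| from
the observed score. Ranking the per-iteration scores of several
nanomaterials gives the distribution of hazard-order permutations — the
stability of the ranking under input uncertainty.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .loe import EvidenceTable, LOERecord
from .scoring import AggregationWeights, HazardScore, ScoringError, hazard_score


@dataclass(frozen=True)
class ScenarioSpec:
    """One sampling scenario: which inputs to redraw, how often, over what
    ranges."""

    vary_pchem: bool = False
    vary_tox: bool = False
    vary_weights: bool = False
    n_iter: int = 10_000
    seed: int | None = None
    index_range: tuple[float, float] = (0.0, 100.0)
    weight_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not (self.vary_pchem or self.vary_tox or self.vary_weights):
            raise ScoringError("scenario must vary at least one input")
        if self.n_iter < 1:
            raise ScoringError("n_iter must be >= 1")

    @property
    def label(self) -> str:
        names = {
            (True, False, False): "i",
            (False, True, False): "ii",
            (False, False, True): "iii",
            (True, True, True): "iv",
        }
        key = (self.vary_pchem, self.vary_tox, self.vary_weights)
        return names.get(key, "+".join(
            n for n, f in zip(("pchem", "tox", "weights"), key) if f
        ))


def standard_scenarios(n_iter: int = 10_000, seed: int | None = None) -> list[ScenarioSpec]:
    """The four canonical scenarios (i)-(iv)."""
    return [
        ScenarioSpec(vary_pchem=True, n_iter=n_iter, seed=seed),
        ScenarioSpec(vary_tox=True, n_iter=n_iter, seed=seed),
        ScenarioSpec(vary_weights=True, n_iter=n_iter, seed=seed),
        ScenarioSpec(vary_pchem=True, vary_tox=True, vary_weights=True,
                     n_iter=n_iter, seed=seed),
    ]


@dataclass
class MCResult:
    """Summary of one scenario on one nanomaterial."""

    nm: str
    scenario: str
    baseline_v: float
    samples: np.ndarray
    mean: float
    sd: float
    avg_abs_dev: float

    @property
    def stderr(self) -> float:
        return float(self.sd / np.sqrt(len(self.samples)))


def _baseline_vectors(
    table: EvidenceTable, weights: AggregationWeights
) -> tuple[np.ndarray, np.ndarray, np.ndarray, HazardScore]:
    base = hazard_score(table, weights=weights)
    b = base.breakdown
    return (
        b["s_pchem"].to_numpy(),
        b["s_tox"].to_numpy(),
        b["quality_weight"].to_numpy(),
        base,
    )


def _draw(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, ...],
    sp: np.ndarray,
    st: np.ndarray,
    w: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw perturbed inputs; fixed draw order (pchem, tox, weights) keeps a
    single-iteration run stream-identical to :func:`perturb_table`."""
    lo, hi = spec.index_range
    wlo, whi = spec.weight_range
    sp_d = rng.uniform(lo, hi, shape) if spec.vary_pchem else np.broadcast_to(sp, shape)
    st_d = rng.uniform(lo, hi, shape) if spec.vary_tox else np.broadcast_to(st, shape)
    w_d = rng.uniform(wlo, whi, shape) if spec.vary_weights else np.broadcast_to(w, shape)
    return sp_d, st_d, w_d


def perturb_table(
    table: EvidenceTable,
    spec: ScenarioSpec,
    rng: np.random.Generator,
    weights: AggregationWeights = AggregationWeights(),
) -> EvidenceTable:
    """One perturbation draw: flagged per-LOE quantities are replaced by
    independent uniform draws over their range; everything else is kept
    bit-identical. Derived columns (S_j, w', WI_j) are recomputed."""
    sp, st, w, _ = _baseline_vectors(table, weights)
    n = len(table)
    sp_d, st_d, w_d = _draw(spec, rng, n, (n,), sp, st, w)
    s_d = weights.w_pchem * sp_d + weights.w_tox * st_d
    wn = w_d / w_d.sum()
    records = []
    for i, r in enumerate(table):
        records.append(
            replace(
                r,
                precomputed={
                    "s_pchem": float(sp_d[i]),
                    "s_tox": float(st_d[i]),
                    "s_total": float(s_d[i]),
                    "quality_weight": float(w_d[i]),
                    "weight_norm": float(wn[i]),
                    "weighted_index": float(s_d[i] * wn[i]),
                },
            )
        )
    return EvidenceTable(nm=table.nm, records=records)


def _simulate_v(
    table: EvidenceTable,
    spec: ScenarioSpec,
    rng: np.random.Generator,
    weights: AggregationWeights,
) -> tuple[np.ndarray, float]:
    sp, st, w, base = _baseline_vectors(table, weights)
    n = len(table)
    shape = (spec.n_iter, n)
    sp_d, st_d, w_d = _draw(spec, rng, n, shape, sp, st, w)
    s_d = weights.w_pchem * sp_d + weights.w_tox * st_d
    wsum = w_d.sum(axis=1, keepdims=True)
    if (wsum == 0).any():
        raise ScoringError("all-zero weight draw; shrink the weight range")
    v = (s_d * (w_d / wsum)).sum(axis=1)
    return v, base.v


def run_scenario(
    table: EvidenceTable,
    spec: ScenarioSpec,
    weights: AggregationWeights = AggregationWeights(),
    rng: np.random.Generator | None = None,
) -> MCResult:
    """Run one sampling scenario and summarise the simulated scores."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    v, baseline = _simulate_v(table, spec, rng, weights)
    return MCResult(
        nm=table.nm,
        scenario=spec.label,
        baseline_v=baseline,
        samples=v,
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
        avg_abs_dev=float(np.abs(v - baseline).mean()),
    )


def scenario_summary(results: Sequence[MCResult]) -> pd.DataFrame:
    """Mean (SD) and average absolute deviation per scenario, one NM per
    block — the layout of the published sensitivity table."""
    return pd.DataFrame(
        {
            "nm": [r.nm for r in results],
            "scenario": [r.scenario for r in results],
            "baseline_v": [r.baseline_v for r in results],
            "mean": [r.mean for r in results],
            "sd": [r.sd for r in results],
            "avg_abs_dev": [r.avg_abs_dev for r in results],
        }
    )


@dataclass
class RankDistribution:
    """Percentages of each hazard-order permutation, per scenario plus a
    Total column (unweighted mean across scenarios). Orders list the
    nanomaterials from lowest to highest simulated score; rows are the
    permutations of the baseline (observed) order."""

    orders: list[tuple[str, ...]]
    table: pd.DataFrame  # index: " < ".join(order); columns: scenarios + Total

    @property
    def modal_order(self) -> tuple[str, ...]:
        return self.orders[int(np.argmax(self.table["Total"].to_numpy()))]


def rank_stability(
    tables: Mapping[str, EvidenceTable],
    specs: Sequence[ScenarioSpec],
    weights: AggregationWeights = AggregationWeights(),
    seed: int | None = None,
) -> RankDistribution:
    """Distribution of hazard-ranking orders under Monte Carlo perturbation.

    Each scenario draws independently per nanomaterial (one substream per
    NM, spawned from a common seed so iterations are aligned); per
    iteration the NMs are sorted by simulated score ascending and the
    resulting permutation counted. Ties — a probability-zero event under
    continuous draws — fall back to the baseline order of the tied NMs.
    """
    if len(tables) < 2:
        raise ScoringError("rank stability needs at least two nanomaterials")
    n_iters = {spec.n_iter for spec in specs}
    if len(n_iters) != 1:
        raise ScoringError("all scenarios must share n_iter for aligned ranking")

    nms = list(tables)
    baseline = {
        nm: hazard_score(tables[nm], weights=weights).v for nm in nms
    }
    base_order = sorted(nms, key=lambda nm: (baseline[nm], nm))
    orders = list(itertools.permutations(base_order))

    k = len(nms)
    perm_code = {
        order: sum(base_order.index(order[j]) * k**j for j in range(k))
        for order in orders
    }
    ss = np.random.SeedSequence(seed)
    columns: dict[str, np.ndarray] = {}
    for spec in specs:
        child = ss.spawn(1)[0]
        streams = child.spawn(k)
        draws = []
        for nm, stream in zip(base_order, streams):
            rng = np.random.Generator(np.random.PCG64(stream))
            v, _ = _simulate_v(tables[nm], spec, rng, weights)
            draws.append(v)
        # columns in baseline order + stable sort => ties keep observed order
        argorder = np.argsort(np.column_stack(draws), axis=1, kind="stable")
        codes = (argorder * (k ** np.arange(k))).sum(axis=1)
        counts = np.bincount(codes, minlength=k**k)
        columns[spec.label] = np.array(
            [100.0 * counts[perm_code[o]] / spec.n_iter for o in orders]
        )

    df = pd.DataFrame(columns, index=[" < ".join(o) for o in orders])
    df["Total"] = df.mean(axis=1)
    return RankDistribution(orders=orders, table=df)
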