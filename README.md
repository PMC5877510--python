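# nanohazard

Comparative hazard screening for engineered nanomaterials (TiO₂, Ag, ZnO
and synthetic stand-ins), for risk assessors and nanotoxicology
researchers who need to rank the intrinsic hazard of materials from a
heterogeneous literature evidence base. The package implements two
complementary frameworks over the same kind of evidence and the analysis
comparing them:

**Quantitative weight of evidence (WoE/MCDA).** Every line of evidence
*j* (one experimental result from a study) receives a physico-chemical
index *S*ⱼᵖᶜʰᵉᵐ ∈ [0,100] (arithmetic mean of per-criterion hazard
scores), a toxicity index *S*ⱼᵗᵒˣ = Σᵢ *C*ᵢ *D*ᵢⱼ (class scores *C*₁..*C*₅
dotted with the likelihood *D*ᵢⱼ that the study's conclusions fall in
class *i*), an aggregated index *S*ⱼ = *w*ᵖᶜʰᵉᵐ·*S*ⱼᵖᶜʰᵉᵐ +
*w*ᵗᵒˣ·*S*ⱼᵗᵒˣ with *w*ᵖᶜʰᵉᵐ < *w*ᵗᵒˣ, and a study-quality weight *W*ⱼ.
With *w*′ⱼ = *W*ⱼ/Σ*W*, the hazard score is

&nbsp;&nbsp;&nbsp;&nbsp;*V* = Σⱼ *S*ⱼ·*w*′ⱼ ∈ [0,100],

comparable across nanomaterials. A Monte Carlo layer stresses *V* by
redrawing the indices uniformly on [0,100] and/or the weights on [0,1]
(10,000 iterations per scenario), summarising the simulated *V*′ by mean,
SD and average absolute deviation |*V*′−*V*|, and tabulating the
distribution of ranking permutations across materials.

**Discrete Bayesian network (BN).** A DAG over categorical nodes —
discretised physico-chemical descriptors, administration route, study
type, and a four-state hazard node — with one CPT per node. The package
provides exact inference (variable elimination), EM parameter learning on
records with missing values, entropy-based value-of-information analysis
(*H*(X) = −Σ P(X) log P(X); the VOI of a node is its conditional mutual
information with the hazard node), the normalised hazard score (posterior
dotted with the uniform scale 0, ⅓, ⅔, 1), per-state scenario tables, and
argmax-posterior cross-validation.

A synthetic evidence generator with a known ground-truth network closes
the loop: it emits WoE tables and BN training/test data with correlated
hazard signal, plus exact oracles (enumerated marginals and Bayes-optimal
accuracy) for validating the learning pipeline end to end.

## Worked example

```python
from nanohazard import tio2_fixture, hazard_score, fit_aggregation_weights

table = tio2_fixture()                      # 22 published TiO2 lines of evidence
weights, report = fit_aggregation_weights(table)
print(weights)                              # AggregationWeights(w_pchem=0.2999..., w_tox=0.7000...)
result = hazard_score(table, weights=weights)
print(round(result.v, 2))                   # 44.23
```

The recovered weights say toxicity evidence carries 70% of the aggregated
index; the hazard score 44.23 reproduces the published TiO₂ value (44.24,
printed at 2 decimals) from the published per-study indices. The Monte
Carlo layer then quantifies its stability:

```python
import numpy as np
from nanohazard import run_scenario
from nanohazard.montecarlo import ScenarioSpec

r = run_scenario(table, ScenarioSpec(vary_weights=True, n_iter=10_000),
                 weights=weights, rng=np.random.default_rng(0))
print(round(r.mean, 1), round(r.avg_abs_dev, 1))   # 42.7 2.1
```

Randomising the study-quality weights moves the score by only ~2 points
on average — the score is robust to how studies are weighted, and far
more sensitive to the toxicity indices themselves.

The full analysis lives in `analysis/01_woe_scoring.py` …
`analysis/05_compare_frameworks.py`, numbered narrative drivers that
write their tables under `results/`. A `nanohazard` command-line
interface (`woe-score`, `mc`, `bn train|predict|voi|scenario|crossval`,
`simulate`, `compare`) wraps the same library functions for
config-driven runs.

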