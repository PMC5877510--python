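# Methods

## Scope and data model

The unit of analysis is the *line of evidence* (LOE): one experimental
result extracted from a study, described by the nanomaterial it concerns,
a physico-chemical characterisation, a likelihood assignment over five
toxicity classes, regulatory study-quality criteria, administration
route, study type, and (for network training data) the hazard state the
study observed. Evidence tables are delimited text with a canonical
snake_case header; arbitrary headers map onto it via a schema config.
Missing values are `-` on disk (also accepted: empty, `NA`) and a single
canonical marker in memory — missingness always means *unobserved*, never
a distinct category. Discretised numeric states such as `10-50` or `>100`
are half-open bins `[low, high)`.

The bundled TiO₂ table carries the published per-study indices at their
printed 2-decimal precision; derived checks against it therefore use a
0.02 tolerance (accumulated rounding) and the headline score a 0.05
tolerance. Raw physico-chemical measurements per LOE were never
published, so the fixture holds the aggregated indices, not raw profiles.

## WoE scoring

Five steps per nanomaterial: (1) the physico-chemical index is the
arithmetic mean of per-criterion scores in [0,100]; criteria without data
are excluded from the mean rather than imputed, because the published
per-row denominators visibly vary. Only the aspect-ratio rule was
published (elongation ≥ 3 scores 100, below scores 25); it ships as the
default, all other criterion rules are config-supplied. (2) The toxicity
index is the dot product of the class scores **C** with the per-study
class likelihoods **D** (Σ*D* = 1). The default **C** = (0, 25, 50, 75,
100) is the unique evenly spaced [0,100] grid with *C*₅ = 100 consistent
with the published toxicity indices, which are all multiples of 12.5.
(3) Aggregation is a convex combination with *w*ᵖᶜʰᵉᵐ ≤ *w*ᵗᵒˣ. The
published analysis states the inequality but not the values;
`fit_aggregation_weights` recovers them from any table that prints all
three index columns by one-parameter least squares, and the bundled
table identifies (0.30, 0.70) with max residual 0.004 — these are the
package defaults. (4) Study weights come from a pre-established override
when present; otherwise from a configurable weighted mean of the four
quality criteria. The richer originating logic-model rule table was
never released, so the mean is an explicit, flagged stand-in. (5) *V* =
Σ *S*ⱼ*w*′ⱼ with *w*′ normalised to sum 1.

Missing-evidence policy per LOE: absent toxicity evidence scores 0 and
the row stays in (the published table does exactly this); an LOE with no
scoreable physico-chemical criterion at all falls back to its toxicity
index alone, i.e. the aggregation weight renormalises onto the available
component, and the breakdown shows a gap. All intermediate values are
kept at full precision; printed-precision comparisons happen only in
tests.

## Monte Carlo uncertainty and rank stability

Four scenarios: redraw per-LOE *S*ᵖᶜʰᵉᵐ uniformly on [0,100] (i), *S*ᵗᵒˣ
likewise (ii), *W* uniformly on [0,1] with renormalisation (iii), or all
three (iv); 10,000 iterations each, every LOE drawn independently.
Independent per-LOE draws and post-draw renormalisation are not optional
details: with exchangeable uniform weights E[*V*′] collapses to the plain
mean of the *S*ⱼ column (42.7 on the bundled table), and scenario (i)'s
mean to *w*ᵖᶜʰᵉᵐ·50 + *w*ᵗᵒˣ·Σ*S*ⱼᵗᵒˣ*w*′ⱼ (46.6) — both matching the
published summary table, which a shared-draw design does not.

Rank stability sorts, per iteration, the simulated scores of all
materials ascending and counts the resulting permutation; percentages are
reported per scenario plus a Total column that is the unweighted mean
across scenarios (this convention reproduces the published pooled
figure). Draws are independent per material, one spawned RNG substream
per (scenario, material), so iterations are aligned and reruns with the
same seed are bit-identical. Ties — probability zero under continuous
draws — resolve to the baseline (observed) order via a stable sort.

## Bayesian network

Structure is an input, not learned: the default node set and state
discretisations follow the published case-table header (shape,
nanoparticle, dissolution, surface area, surface charge, surface
coatings, surface reactivity, aggregation, particle size, administration
route, study type, plus the four-state hazard node). The originally
learned edge set was never published, so the default wiring is the
tree-shaped classifier orientation nanoparticle → hazard → each
descriptor, whose per-node tables (≤ 4 columns each) remain estimable
from a few hundred records; a layered structure can be supplied via
config. An all-descriptors-as-parents-of-hazard wiring was rejected: its
hazard CPT would need ~10⁶ columns, unlearnable at any realistic corpus
size.

Inference is exact sum-product variable elimination over dense factors
(greedy smallest-intermediate-first ordering); the networks involved are
small, so approximate inference is deliberately out of scope. Evidence
with zero probability raises an explicit inconsistent-evidence error.

EM groups duplicate observation patterns (cost scales with distinct
patterns, not records), computes exact family posteriors per pattern in
the E-step, and renormalises expected counts with a Laplace pseudo-count
(default α = 1 per CPT cell) in the M-step; convergence when the relative
observed-data log-likelihood change drops below 1e-6, cap 200 iterations.
On complete data one M-step equals the smoothed empirical frequencies.

Value of information is the conditional mutual information between a
candidate node and the hazard node given the current evidence, computed
from exact posteriors; natural log by default (the base rescales, never
reorders, the ranking — configurable). The normalised hazard score is the
hazard posterior dotted with the uniform utility scale (0, ⅓, ⅔, 1) for
(None, Low, Medium, High); display convention is a percentage rounded to
integer. Prediction takes the argmax posterior state, ties resolving to
the lowest-severity state, deterministically. Cross-validation trains by
EM, predicts each held-out case from its observed inputs, and reports
accuracy overall and per material plus a per-case table in the published
Actual/Predicted layout.

## Synthetic generator

The generator emulates the statistical shape of the literature corpus the
analysis assumes: three nanomaterials of low/mid/high intrinsic hazard
(uniform identity prior; hazard-given-material CPTs with well-separated
marginals), four descriptors carrying graded signal (discretised bumps
whose location tracks hazard severity — small particle size, high surface
reactivity and low aggregation lean hazardous; in vivo studies report
hazard slightly more often), ~75 training cases per material, a held-out
test set of 14 per material (echoing the ~41-case out-of-sample design),
and 20% missingness, completely at random, on descriptors. Toxicity
likelihood vectors are Dirichlet draws with concentration 8 on the class
aligned to the true hazard state (None→C₁, Low→C₂, Medium→C₄, High→C₅,
spreading the class-score range) so WoE and BN consume correlated
signal; quality criteria are Beta(5, 2) draws (mean 0.71, the typical
published study weight). Everything is reproducible from one seed.

Oracles come from exact enumeration of the generating network: state
marginals, and the Bayes-optimal accuracy of the argmax predictor —
computed over all input configurations *and* all missingness masks, so
the oracle target matches the sampled benchmark's observation model. The
validation experiments scale the corpus up where variance, not bias, is
the question: parameter recovery uses 20,000 records, and the
closure check (EM-trained accuracy within 5 points of the oracle) uses
5,000 training and 2,100 test cases so the binomial noise of the accuracy
estimate (~1 point) stays well inside the band being checked.

What passing synthetic tests does not show: real literature evidence is
not missing at random (in vitro studies systematically omit
administration route), descriptors are correlated beyond what a single
hazard parent induces, and expert-assigned class likelihoods are not
Dirichlet. An optional study-type-dependent missingness mode covers the
first gap; the others bound how far synthetic validation generalises.

## Known limitations

- The published VOI values, per-state scenario-table cells and the
  67%/72% cross-validation accuracies depend on the original model's
  unpublished CPTs and cannot be recomputed from printed information;
  the package validates those code paths against enumeration oracles and
  synthetic ground truth instead.
- The silver and zinc-oxide evidence tables live in supplementary
  material that is not bundled; multi-material analyses here use
  synthetic companions, clearly labelled as such.
- The study-quality logic model is represented by a configurable
  weighted mean, not the original rule table.
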