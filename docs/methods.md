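# Methods

## The index

The unmet medical need of a disease is modelled as a weighted sum of eleven
ordinal criterion scores,

```
total = Σᵢ scoreᵢ · wᵢ ,   scoreᵢ ∈ {1,…,5},  wᵢ ≥ 0,
```

with criteria spanning patient suffering (commonality, duration, QALYs lost,
5-year mortality), the current standard of care (disease-modifying activity,
adverse events, administration route and frequency), and accessibility
(cost, supply robustness, regulatory barriers). Higher scores always mean
greater need. The default weights (0.25/0.5/0.75/1 · 1/0.75/0.5/0.25 ·
0.25/0.25/0.25, summing to 5.75) express a rare-disease-first prioritisation:
mortality and the absence of disease modification dominate; cost and
logistics matter but cannot outvote them. Weights are configuration — any
organisation can re-weight without touching code — and no normalisation is
applied, so with the defaults every total is a multiple of 0.25 in
[5.75, 28.75], a useful integrity check on any scored output.

Ranking uses competition ranking (ties share the smallest applicable rank);
the tie rule is a documented choice where alternatives exist, picked because
it keeps `top_percent = 100·rank/N` well defined. `top_percent` is rounded
to one decimal, the precision at which such rankings are usually reported.

Assumptions worth stating: criterion scores are treated as interval-scaled
when summed, averaged, correlated or factored — standard practice for
5-point scales, but an approximation; and the criteria are assumed close to
mutually exclusive, though duration and QALYs lost are naturally correlated
(longer illness, more total QALY loss).

## Raters

A *rater* is anything that maps (disease, criterion) to a 1–5 integer.

**Rubric rater.** Deterministic lookup of a structured attribute profile in
per-criterion threshold tables: numeric criteria use four strictly
increasing cut-points defining five half-open, lower-inclusive bands;
categorical criteria use explicit category → score maps. Need direction is a
per-criterion flag — commonality is need-inverted (rarer ⇒ higher score) to
match the rare-disease weighting intent. The shipped default anchors
(5-year mortality <1 / 1–10 / 10–30 / 30–60 / ≥60 %; prevalence per 100,000
≥500 / 50–500 / 5–50 / 0.5–5 / <0.5; dosing <4 / 4–12 / 12–52 / 52–365 /
≥365 per year; duration <3 months … ≥20 years or lifelong; QALY-loss
fraction <0.05 … ≥0.5 per year) are clinically plausible placements of the
band edges, and *all* of them are configuration (JSON), never constants: the
method fixes the shape of a rubric (five bands, measurable units), not the
numbers. A coverage checker reports gaps (missing bands) and overlaps
(non-monotone cut-points) before a rubric is used. Profiles use prevalence
by default; incidence can be substituted by re-pointing the commonality rule
at a different attribute column.

**LLM rater.** The prompt harness renders a fixed epidemiologist role
preamble (system) and a five-anchor classification instruction (user,
beginning "Output only a number from 1 to 5"), with disease synonyms
appended as "Name (also known as: s1; s2)" — synonym use improves
whole-name recognition for descriptive rare-disease names; the exact
injection format is our choice. Replies must be JSON objects with a
`response` key. The parser coerces integer-valued strings ("4") and
integer-valued decimals (3.0) but rejects true non-integers and values
outside 1–5, each as a typed failure. The audit loop re-queries a failing
cell at most `max_regenerations` times (default 1) with the original
parameters; cells still failing are left missing and flagged, never imputed.
Temperature defaults to 0 to minimise sampling variability (outputs may
still vary across model versions — the audit loop, not the adapter, owns
correctness). The live adapter is a two-method interface with no bundled
network client; tests use a scripted fixture rater exclusively.

**Mock rater.** Perturbs an existing matrix cell-wise: with probability
`rates[k]` a cell shifts ±k (sign uniform), clamped to [1, 5]. Clamping
rather than rejection keeps the marginal on-scale at the cost of slightly
deflating realized shift frequencies for extreme base scores — a deliberate
deviation from unbounded noise, visible when calibrating against configured
rates.

## Reconciliation and agreement

Two independent raters are compared by |Δ| band (0 / 1 / 2 / ≥3). One-point
differences are accepted as a reasonable margin of uncertainty; larger gaps
go to a mediator whose value becomes the consensus and is logged. Agreeing
and one-point cells are merged as the arithmetic mean, so consensus lives in
half-integer space; the mean is our convention — reference-rater summary
statistics are generally not integer-consistent with a single rater, so
*some* merged value is implied, but the merging rule itself is an open
choice. The mediator's value must land within one point of at least one
original rater; this is enforced, guaranteeing the post-mediation invariant
`min(|c−a|, |c−b|) ≤ 1` for every cell.

Rater performance gates: |mean difference| ≤ 1 point and |SD difference| ≤
0.5 points per criterion, boundaries inclusive ("within" is read
inclusively). Standard deviations use the n−1 denominator (sample-statistic
context). The difference sign convention is reference − candidate.

The pooled battery per criterion: Spearman ρ (average ranks, then Pearson),
a 95% percentile-bootstrap CI from 1,000 paired resamples (degenerate
resamples with a constant vector are redrawn; BCa was not used — at n ≈ 40
the percentile interval's ~95% coverage is adequate and simpler to
reproduce), MAE and RMSE, and a two-sided paired Wilcoxon signed-rank test.
Wilcoxon drops zero differences (Wilcoxon's convention, shared by the common
implementations), uses the exact null when the effective n ≤ 25 with no tied
|d|, and otherwise the normal approximation with tie and continuity
corrections. The inequality RMSE ≥ MAE ≥ |mean difference| holds for all
inputs and is property-tested.

## Factor suite

Run on an n × 11 score table (n > 11 required):

* **Bartlett sphericity**: χ² = −(n − 1 − (2p+5)/6)·ln det R on p(p−1)/2 df
  (55 for eleven criteria).
* **KMO**: per-item and overall MSA from anti-image partial correlations;
  the conventional adequacy floor is 0.6, and EFA is refused below an
  overall 0.5 (configurable).
* **Parallel analysis**: eigenvalues of the *reduced* correlation matrix
  (squared multiple correlations on the diagonal — principal-factor, not
  principal-component, retention) against the same quantity from simulated
  uncorrelated normal data of identical shape. The comparison curve is the
  mean of the simulated eigenvalues by default; note the mean curve has an
  appreciable false-positive rate on pure-noise data (the leading null
  eigenvalue exceeds the mean curve roughly half the time), so the 95th
  percentile curve (`criterion="p95"`) is provided and used when noise
  rejection matters. Defaults: 1,000 simulations, seed-reproducible.
* **EFA**: maximum-likelihood extraction via the uniqueness profile
  likelihood (L-BFGS-B over uniquenesses bounded to [0.005, 1]; a
  uniqueness pinned at the floor flags a Heywood case), followed by oblique
  quartimin (oblimin, γ = 0) rotation using the gradient-projection
  algorithm. ML + oblique is the convention of the common psychometrics
  stack whose factor labels ("ML1…") this field uses; rotation is
  configurable (`"none"` gives the canonical unrotated solution, which
  matches R's `factanal(rotation="none")` to column sign — asserted in a
  test). Factor signs are normalised so each column's dominant loading is
  positive.
* **Grouping**: each criterion is assigned to its highest-|loading| factor
  (negative loadings group by magnitude); ties break to the lowest factor
  index with a warning.

Confirmatory factor analysis is deliberately out of scope: at the sample
sizes this battery is designed for (tens of diseases) a CFA is underpowered
and its fit statistics uninformative.

## Synthetic data

The generators emulate the study design, not disease biology:

* `gen_profiles` inverse-constructs attribute profiles — sample the target
  score from a per-criterion spectrum plan (uniform by default, so a
  40-disease panel spans all five levels of every criterion), then draw an
  attribute uniformly within that score's rubric band. Open-ended top bands
  are truncated to the attribute domain; the open duration band draws
  "lifelong" half the time.
* `gen_rater_pair` pairs a plan-sampled reference matrix with a mock-rated
  second rater; disagreement shifts are sign-symmetric because only
  magnitudes are modelled.
* `gen_factor_scores` draws multivariate-normal latents under a planted
  loading model and discretises at fixed cut-points (−1.5, −0.5, 0.5, 1.5 on
  the standard scale, configurable), giving roughly centre-heavy 1–5
  marginals. Discretisation attenuates correlations relative to the implied
  latent matrix, which the recovery tests tolerate by asserting structure,
  not printed loadings. The shipped 4-factor model plants a
  burden / access-barriers / modifiability / treatment-complexity block
  structure with one cross-loading and factor correlations of 0.2.

What passing tests on these data do *not* show: that any particular LLM
scores real diseases accurately, that the default rubric anchors are
clinically optimal, or that real expert score matrices have the planted
factor structure. They show the machinery is correct: scores land where the
rubric says, statistics match independent oracles (exhaustive
rank-then-Pearson, full sign enumeration, R's `factanal`), calibrated noise
is recovered at its configured rates, bootstrap coverage is ~95% where
planted, and parallel analysis recovers planted k ∈ {1, 2, 4}.

## Numerical and scale choices

Skewness is the population Fisher–Pearson g₁ = m₃/m₂^{3/2}; at the scale the
index is used (≈20k diseases) the small-sample adjustment is negligible.
Zero-variance inputs are flagged, not errored, in the distribution summary;
histograms over a data range too narrow for the requested bins widen the
range symmetrically. Registry ingestion accepts any `prefix:digits` CURIE
and only warns on non-MONDO prefixes (the method is ontology-agnostic);
duplicate ids and malformed CURIEs are hard errors with locations. Missing
score cells are representable everywhere but refused by every downstream
statistic — imputation would be invented behaviour. Obsolete ontology terms
are not filtered; ingestion scores whatever list it is given.

Problem sizes in the test and acceptance runs — 40 × 11 grids for the
rater-pair pipeline, n = 500 rows for factor recovery (50 seeded runs, 200
simulations per parallel analysis), 500 replicates × 1,000 resamples for
bootstrap coverage, 10,000 cells for mock-rater calibration — are the
package's standard verification sizes; all complete in seconds on one CPU.

## Known limitations

* Rubric anchor values are defensible defaults, not validated clinical
  thresholds; real deployments should re-anchor per use case.
* The mock rater's clamping biases realized disagreement slightly downward
  for base scores at the scale ends.
* Pearson correlations on 5-point scores understate latent correlations
  (no polychoric option).
* The consensus-mean and mediator-verbatim reconciliation rules are
  conventions; alternatives (e.g. discussion-to-integer) are not modelled.
* The live LLM adapter is an interface only; provider clients, retries
  beyond the audit loop, and cost accounting are out of scope.
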