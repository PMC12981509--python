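# umni — an unmet medical need index across the disease landscape

`umni` quantifies the *unmet medical need* of diseases so that research and
drug-repurposing effort can be prioritised where current medicine serves
patients worst. Every disease — identified by an ontology CURIE such as
`MONDO:0007803` — is scored 1–5 on eleven criteria grouped into three
categories:

| Category | Criteria | Weights |
|---|---|---|
| Patient suffering | Commonality, Duration, QALYs lost, Mortality | 0.25, 0.5, 0.75, 1 |
| Standard of care | Disease modification, Adverse events, Route of administration, Frequency of administration | 1, 0.75, 0.5, 0.25 |
| Accessibility | Cost to patients, Robust supply, Regulatory barriers | 0.25, 0.25, 0.25 |

and the composite score is the plain weighted sum

```
total = Σᵢ scoreᵢ · wᵢ ,    scoreᵢ ∈ {1,…,5}
```

Under the default weights (Σ wᵢ = 5.75, chosen to up-weight rare,
high-mortality diseases lacking an effective standard of care) every total is
a multiple of 0.25 in [5.75, 28.75]. Diseases are then ranked (rank 1 =
greatest need, competition ranking for ties) and reported as a top-percent of
the scored universe.

Scores can come from any *rater*: a deterministic rubric over measurable
disease attributes (prevalence per 100,000, 5-year mortality bands, dosing
frequency, …), a seeded mock rater that perturbs an existing matrix with a
controlled disagreement profile, or an LLM behind a pluggable adapter whose
JSON replies (`{"response": <int>}`) are parsed, audited for non-integer or
out-of-range values, and re-queried at most once per cell. The package also
implements the evaluation battery used to decide whether a candidate rater is
trustworthy:

* **per-criterion gates** — mean difference within ±1 point and SD difference
  within ±0.5 points of the reference rater (boundaries inclusive);
* **pooled agreement** — Spearman rank correlation with a 95%
  percentile-bootstrap CI (1,000 paired resamples), MAE, RMSE, and a paired
  Wilcoxon signed-rank test of median difference zero;
* **reconciliation** — two-rater disagreement tabulation by |Δ| band, and
  third-rater mediation of >1-point differences;
* **factor suite** — Bartlett's sphericity test, KMO sampling adequacy,
  parallel analysis on the reduced correlation matrix, maximum-likelihood EFA
  with oblimin rotation, and grouping of criteria by highest |loading|.

A synthetic-data module generates every input the pipeline needs offline:
spectrum-spanning disease profiles, paired rater matrices with controlled
disagreement rates, and score matrices with planted latent-factor structure.

## Worked example

```python
from umni import (gen_rater_pair, diff_histogram, per_criterion_report,
                  composite_totals, rank_and_percent, default_weights)

# 40 synthetic diseases x 11 criteria; a second rater disagreeing on
# ~20.45% of cells by +-1 point and ~5.45% by +-2
expert, llm = gen_rater_pair(40, rates={1: 0.2045, 2: 0.0545}, seed=7)

table = diff_histogram(expert, llm)
print("disagreements:", table.counts,
      f"({table.within_one_point_pct():.1f}% within 1 point)")

report = per_criterion_report(expert, llm)
print(report[["criterion", "mean_diff", "sd_diff",
              "gate_mean", "gate_sd"]].head(4).round(2).to_string(index=False))

totals = composite_totals(expert, default_weights())
top = min(rank_and_percent(totals), key=lambda r: r.rank)
print(f"highest need: {top.disease_id}  total={top.total_score}"
      f"  rank={top.rank}  top {top.top_percent}%")
```

prints

```
disagreements: {'0': 346, '1': 80, '2': 14, '>=3': 0} (96.8% within 1 point)
  criterion  mean_diff  sd_diff gate_mean gate_sd
Commonality       0.05     0.10      pass    pass
   Duration      -0.10     0.01      pass    pass
 QALYs lost       0.17     0.06      pass    pass
  Mortality       0.05    -0.11      pass    pass
highest need: MONDO:9000001  total=23.25  rank=1  top 2.5%
```

The two raters agree or differ by one point on 96.8% of the 440 cells, every
criterion clears both performance gates, and the top-ranked disease's
composite (23.25) is, as it must be, a multiple of 0.25.

The same pipeline is available from the shell:

```sh
umni simulate --seed 11 --out data/
umni score    --profiles data/profiles.csv --out out/scored
umni agree    --expert data/expert.csv --llm data/llm.csv --seed 3 --out out/agree
umni factors  --scores data/factor_scores.csv --seed 5 --out out/factors
```

Every command writes a `manifest.json` (command, seed, parameter values,
SHA-256 of inputs, package version); reruns with identical manifests produce
byte-identical outputs.

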