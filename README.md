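# clpnet

Cross-lagged panel networks (CLPNs) for two-wave symptom cohorts, built
around the screening of psychotic-like experiences (PLEs) in young-adult
populations. The package covers the full longitudinal network workflow:

* **score** screening instruments — CAPE-P15 (weighted score, 1.57
  screening cut-off, three subtype factors PI / BEs / PAs), PHQ-9, GAD-7
  and the ASLEC adverse-life-events checklist (five factors) — and apply
  the cohort exclusion cascade (duplicates, sub-5-minute speeders,
  psychotic-disorder history, interview refusals);
* **split** the cohort into baseline screen-positive and screen-negative
  groups and estimate one directed network per group;
* **estimate** the CLPN by node-wise L1-regularized regression: each of
  the 24 wave-2 node scores (3 PLEs factors, 9 depression items, 7 anxiety
  items, 5 life-event factors) is regressed on all 24 wave-1 node scores
  plus socio-demographic covariates;
* **summarize** node roles with expected influence (in-EI / out-EI) and
  bridge expected influence, autoregressive effects removed;
* **quantify** edge accuracy and centrality stability by nonparametric and
  case-drop bootstrapping (correlation-stability coefficients);
* **compare** the two group networks (edge-matrix correlation, edge
  replication, centrality correlations);
* **simulate** seeded two-wave Likert cohorts with a known sparse
  cross-lagged ground truth and realistic administrative artifacts, since
  cohort data of this kind are typically access-restricted.

## Model

For standardized node scores $x^{(1)}, x^{(2)} \in \mathbb{R}^{24}$ at
waves 1 and 2, each outcome node $j$ is fit by LASSO:

$$\hat\beta_{\cdot j} = \arg\min_\beta \tfrac{1}{2n}\lVert x^{(2)}_j - X^{(1)}\beta - Z\gamma \rVert^2 + \lambda_j \lVert\beta\rVert_1,$$

with covariates $Z$ unpenalized (projected out by Frisch–Waugh–Lovell, so
adjustment is never shrunk away). The coefficient vectors form the weight
matrix $W$ with $W_{ij}$ the lagged effect of node $i$ on node $j$;
$W_{ii}$ are autoregressive effects. Centralities are absolute row/column
sums of $W$ with the diagonal removed; bridge variants restrict the sums
to edges crossing construct boundaries (PLEs, depression, anxiety, life
events). $\lambda_j$ is chosen per node by seeded K-fold cross-validation
(prediction-error minimum by default, 1-SE rule and fixed-$\lambda$ modes
available).

## Worked example

```python
import pandas as pd
from clpnet import (SimulationConfig, generate_cohort, apply_exclusions,
                    PipelineConfig, run_pipeline, write_panel_csv)

cfg = SimulationConfig(n_participants=3000, seed=1,
                       duplicate_rate=0.01, followup_loss_rate=0.05)
data, truth = generate_cohort(cfg)
print(f"realized screen-positive prevalence: {truth.realized_prevalence:.3f}")

write_panel_csv(data, "cohort.csv")
manifest = run_pipeline(PipelineConfig(out_dir="run/", dataset_path="cohort.csv",
                                       seed=1, min_group_n=100))
print(manifest["stages"]["split"])
print(manifest["stages"]["compare"]["matrix_correlation"])
```

prints

```
realized screen-positive prevalence: 0.123
{'cutoff': 1.57, 'n_positive': 353, 'n_negative': 2497}
{'r': 0.6707790713444106, 'p': 2.069199320835274e-73}
```

The realized prevalence sits near the 13.5% calibration target; the group
split at the 1.57 weighted-score cut-off yields a small screen-positive
and a large screen-negative group; and because both groups here are draws
from one generating truth, their estimated networks correlate far more
strongly than two networks from genuinely different populations would.
`run/` then holds the per-group edge matrices (`network_*.csv`,
`network_*.graphml`), centrality tables, the exclusion flow report, the
comparison report and a manifest from which the run can be reproduced.

The same stages are available as a CLI:

```bash
clpnet simulate --n 3000 --seed 1 --out sim/
clpnet run --data sim/dataset.csv --out run/ --seed 1 --min-group-n 100
```

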