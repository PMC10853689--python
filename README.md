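# tricotkit

Design, analysis and reporting toolkit for **tricot** (triadic comparison)
trials: decentralized experiments in which each participant receives a blind
package of three technology options (positions A/B/C) and reports the best
and worst per trait.

What it does:

- **Trial design** (`tricotkit.design`) — incomplete block designs with
  blocks of three: near-equal replication, sequential balance (consecutive
  packages stay balanced, so consecutive numbers can be handed out per
  village or per day), position balance (each option appears near-equally
  as A, B and C), and approximate A-optimality by local minimization of the
  Kirchhoff index of the option concurrence graph.
- **Rankings** (`tricotkit.rankings`) — converts best/worst responses into
  full or partial rankings over option labels, plus a win-graph
  estimability check.
- **Plackett-Luce estimation** (`tricotkit.plackett`) — exact likelihood
  (partial rankings via exact marginals), monotone MM/EM fitting,
  pseudo-comparison regularization for sparse or disconnected data,
  observed-information standard errors, pairwise outperformance
  probabilities, and a seeded response simulator.
- **Heterogeneity detection** (`tricotkit.pltree`) — Plackett-Luce trees:
  likelihood-ratio recursive partitioning on participant covariates with
  Bonferroni-adjusted chi-square tests, and greedy forward covariate
  selection by cross-validated held-out log-likelihood.
- **Agro-climatic covariates** (`tricotkit.agroclimate`) — growing degree
  days, maximum dry spell and heat days over planting-date windows from
  user-supplied daily weather.
- **Projects, I/O and reports** (`tricotkit.trial`, `tricotkit.io`,
  `tricotkit.report`) — project JSON, package QR payloads, plain-CSV
  persistence, end-to-end synthetic trial generation, and markdown reports
  (manager overview + personalized participant result sheets).

A published 20-package / 10-option bean-variety example design is bundled
at `tricotkit.example_design_path()` and exercised throughout the tests.

## Command line

```sh
tricotkit design   --options 10 --packages 20 --seed 1 --out design.csv --diagnostics diag.json
tricotkit validate --design design.csv
tricotkit simulate --design design.csv --log-worths worths.json --seed 2 --response-rate 0.9 --out obs.csv
tricotkit fit      --design design.csv --observations obs.csv --trait overall --out fit.json
tricotkit tree     --design design.csv --observations obs.csv --covariates cov.csv --trait overall --out tree.json
tricotkit climate  --weather weather.csv --planting-dates planting.csv --duration 90 --out cov.csv
tricotkit report   --project project.json --observations obs.csv --out report/
```

File formats (all UTF-8 CSV/JSON):

- design: `package_id,option_a,option_b,option_c`
- observations: `package_id,trait,best,worst` with best/worst in
  {A, B, C, empty} — observation files are blind, option names never
  appear in them
- covariates: `package_id` plus arbitrary numeric/categorical columns
- weather: `date,tmin,tmax,precip` with ISO-8601 dates

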