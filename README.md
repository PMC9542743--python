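# socialsampling

An agent-based simulator and analysis pipeline for *social sampling*:
a social-learning heuristic in which each member of a new generation
samples a random member of the previous generation and accepts or
rejects that companion's belief with probability proportional to the
likelihood of newly observed evidence under it. Populations following
this rule perform distributed Bayesian inference — the popularity of a
belief tracks the ideal posterior conditioned on all evidence the
population has seen — and the package provides both the simulator and
the metrics that quantify how close a population gets to that ideal.

## What's inside

- `socialsampling.environment` — hidden binary feature vectors,
  generation-shared Bernoulli evidence blocks, and censoring masks
  (evidence about a feature visible only if the observed companion
  chose it).
- `socialsampling.decision_models` — six decision rules: three asocial
  (problem matching, Bayesian problem matching, utility maximizing),
  naive copying, and two social-sampling rules (Bayesian and
  probability-matching acceptance), plus their analytic one-step-ahead
  popularity predictions and the accept-loop closed form
  `p·L1 / (p·L1 + (1−p)·L0)`. The exact asocial forms and the
  matching rule for belief 0 are reconstructions (the stated fractions
  applied symmetrically).
- `socialsampling.simulator` — multigenerational networks with two
  timing regimes (decide on your own generation's evidence, or on
  censored feedback from the previous generation's), built-in presets
  `exp1` and `exp2-c1`..`exp2-c5`, and a convergence report.
- `socialsampling.metrics` — ideal posterior (log-space), popularity,
  Pearson correlations, fixed-effects OLS of popularity on evidence
  fractions, and per-model predicted-vs-observed popularity MSE
  (one-step-ahead: each model predicts generation-t popularity from the
  *observed* generation-(t−1) popularity plus the evidence the
  generation-t deciders saw).
- `socialsampling.cli` — `simulate`, `evaluate`, `convergence-check`
  and `suite` subcommands with manifested, reproducible CSV outputs.

## CLI

```bash
# Experiment-1 layout (3 networks x 10 generations x 20 agents, 8
# features, J=4, theta1=0.6/theta0=0.3, 2 trials) under Bayesian social
# sampling with a 19% social proportion:
socialsampling simulate --preset exp1 --model social_sampling_bayes \
    --rho 0.19 --seed 7 --out runs/exp1

# Analysis: popularity/evidence analysis rows, correlations,
# fixed-effects regression, per-model MSE table:
socialsampling evaluate --decisions runs/exp1/decisions.csv \
    --evidence runs/exp1/evidence.csv --out runs/exp1-analysis

# Does popularity track the ideal posterior as N grows?
socialsampling convergence-check --n-list 20,200,2000 --replicates 50

# All presets at once (exp1 plus the five censored-feedback conditions):
socialsampling suite --model social_sampling_bayes --seed 3 --out runs/suite
```

Custom layouts can be passed as YAML via `simulate --config`
(fields: `n_networks, n_generations, n_agents, n_features, n_evidence,
theta1, theta0, censored, evidence_timing, gen0, n_trials, seed`).

Conventions: decision generations are 0-based, with generation 0 the
first (asocial or guessing) generation; evidence blocks are 1-based.
Every output directory contains a `manifest.json` with the config echo,
root seed, package version and per-file SHA-256 checksums; re-running
with the same seed reproduces identical files.

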