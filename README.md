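# panelmarkov

Three-state continuous-time Markov modelling of postpartum-depression
severity from panel data (visit-based observations). The package provides:

- **State classification** — EPDS total scores mapped to severity states
  (normal < 10, mild 10–12, severe ≥ 13; cutpoints configurable).
- **Descriptives** — consecutive-visit transition counts and the
  deterioration / improvement / no-change split.
- **Panel likelihood** — the exact likelihood of panel-observed
  continuous-time Markov chains, `Σ log [exp(Q(z)·Δt)]_{s,s'}`, with
  proportional-intensity covariate effects `q_ij(z) = q0_ij·exp(β_ij·(z−ref))`
  and complex-step gradients.
- **Fitting & inference** — quasi-Newton MLE, covariance from the observed
  information, hazard-ratio reports with 95% CIs, jump-probability/sojourn
  summaries, and interval transition probabilities over follow-up horizons
  with parametric-bootstrap CIs.
- **Synthetic cohorts** — latent-trajectory simulation (competing
  exponentials) read off at visit times, emulating the reference study
  design (304 subjects, visits at 6/13/26 weeks postpartum, five support /
  age covariates), plus a deterministic fixture cohort whose pair counts
  reproduce the published observed-transition table exactly.

All rates are per week; month horizons convert at 52/12 weeks per month.

## Command-line usage

```bash
# simulate a synthetic cohort (CSV + ground-truth JSON)
panelmarkov simulate --output-dir out/sim --n-subjects 304 --seed 1

# descriptive transition table and change summary from a panel CSV
panelmarkov describe --input out/sim/cohort.csv --output-dir out/desc

# fit the panel likelihood; optional covariates and bootstrap CIs
panelmarkov fit --input out/sim/cohort.csv --output-dir out/fit \
    --covariates emotional_support --bootstrap-reps 1000 --seed 1

# interval-probability table from the published-summary generator (no fit)
panelmarkov fit --reference-q --output-dir out/tables
```

Input CSVs are long format with a header: one row per subject-visit with
columns `subject`, `time` (weeks), and `state` (1/2/3) or `epds` (0–30);
extra numeric columns are treated as covariates. Column names can be
remapped via `read_panel(columns=...)`.

## Layout

```
src/panelmarkov/
  markov.py      # state space, generator algebra, expm, jump/sojourn/stationary
  panel.py       # panel data model, CSV IO, EPDS classification, descriptives
  likelihood.py  # panel CTMC likelihood + covariate effects + gradients
  fitting.py     # MLE, covariance, hazard ratios, fitted tables, bootstrap CIs
  simulate.py    # synthetic cohorts, latent paths, deterministic fixture
  reference.py   # published summary constants used as defaults/ground truth
  cli.py         # simulate / describe / fit / tables subcommands
```
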