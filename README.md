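# pkcross

Population and non-compartmental pharmacokinetic analysis of IV/IM crossover
studies, built around a closed-form two-compartment disposition model with
first-order (depot) absorption. The package covers the full workflow of a
small-animal crossover PK study:

- **`pkcross.model`** — bi-/tri-exponential closed forms (IV bolus and depot
  input), micro-constant reparameterization, dose superposition, analytic
  AUC and body-amount functions. Units are fixed package-wide (h, mg, L,
  µg/mL).
- **`pkcross.datagen`** — synthetic crossover study generator (log-normal
  between-subject variability shared across occasions, proportional residual
  error), plus calibration/repeatability and tissue-concentration table
  generators. Everything is seed-deterministic, so the test suite and the
  acceptance report need no external data.
- **`pkcross.nca`** — non-compartmental analysis: terminal-slope regression
  (best adjusted R² over contiguous terminal subsets), linear-log trapezoidal
  AUC/AUMC with analytic tails, clearance/volume terms, dose-normalized
  bioavailability, study-level summaries.
- **`pkcross.nlme`** — nonlinear mixed-effects estimation of the
  two-compartment model from both routes simultaneously. Two back-ends:
  SAEM (Metropolis-within-Gibbs E-step, closed-form M-steps) and a
  deterministic Laplace marginal-likelihood maximizer; `SAEM+LAPLACE` chains
  them. Includes importance-sampling objective function values, RSE% from a
  finite-difference information matrix, condition number, η/ε shrinkage,
  IWRES/CWRES diagnostics, allometric bodyweight covariate (fixed 0.75/1.0
  exponents or estimated), and nested/AIC model comparison (ΔMOFV 7.879 at
  p < 0.005 for 1 df).
- **`pkcross.diagnostics`** — visual predictive check (observed percentiles
  vs simulated percentile confidence bands) and nonparametric subject-level
  bootstrap.
- **`pkcross.regimen`** — multiple-dose superposition, steady-state
  detection, therapeutic-window occupancy scoring (15–20 µg/mL default) with
  an explicit composite ranking rule, and washout-time computation.
- **`pkcross.bioanalytics`** — calibration linearity (R² > 0.99), replicate
  repeatability (mean/SD/RSD), accuracy recovery (80–120% band), S/N-based
  LOD/LOQ, exact Mann–Whitney U test by full enumeration for small groups,
  tissue median (min, max) summaries.
- **`pkcross.io` / `pkcross.cli`** — event-table CSV dialect (ID, OCC, TIME,
  AMT, DV, EVID, ROUTE, BW), YAML pipeline configuration, and the `pkcross`
  command-line interface.

## CLI

```bash
pkcross simulate --subjects 4 --seed 1 --out events.csv
pkcross nca --input events.csv --route both --per-kg --out nca.csv
pkcross fit --input events.csv --method SAEM --seed 1 --out fit.json
pkcross vpc --input events.csv --fit fit.json --replicates 1000 --out vpc.csv
pkcross bootstrap --input events.csv --n-boot 200 --seed 1 --out boot.csv
pkcross regimen --dose 4 --route im --tau 24 --bw 31.5 --n 10 --out profile.csv
pkcross validate --calibration cal.csv --out report.json
pkcross tissue --input tissue.csv --out summary.csv
pkcross run --config config.yaml          # full pipeline
```

`pkcross run` chains simulate → NCA → population fit → VPC → regimen scoring
into a run directory with a seed-stamped `run_log.json`; two runs from the
same config produce byte-identical numeric outputs.

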