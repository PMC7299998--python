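# aggkinetics

Analysis toolkit for protein aggregation kinetics and chaperone activity:

* **Kinetic model** — the unseeded nucleation–elongation master equation for
  amyloid fibril formation, with combined rate parameters
  λ = √(2·k₊·kₙ·m₀^nc) and κ = √(2·k₊·k₂·m₀^(n2+1)), the closed-form fibril
  mass fraction, a moment-ODE reference integrator, and the empirical
  sigmoidal (logistic) signal model.
* **Trace processing** — plate-reader CSV ingestion (wide or long dialect),
  baseline correction, plateau normalization, replicate averaging, endpoint
  extraction.
* **Fitting** — per-trace sigmoidal fits (τ½, r_max), multi-concentration
  global fits of the shared combined constants √(kₙ·k₊) and √(k₊·k₂),
  single-rate-free inhibition mechanism selection ranked by χ², per-dose
  combined-constant fits, γ-exponent half-time scaling, and inhibitor
  dose-dependence summaries.
* **Chaperone assay** — turbidity dose–response: per-experiment-block
  normalized final intensities vs chaperone:substrate molar ratio, with
  chaperone comparison and concentration recalibration.
* **Synthetic data** — deterministic plate generators (ThT fibrillization
  with configurable inhibitor action; turbidity with suppressed plateaus)
  that emit the same CSV dialects the pipeline reads plus a JSON truth
  record, so the whole pipeline is exercisable without external data.

Internal units are molar and seconds; metadata concentrations are ingested
in µM.

## CLI

```bash
# simulate an 8-concentration unseeded ThT plate (known ground truth)
aggkinetics simulate --kind tht-concentrations --sqrt-knkp 6.4 \
    --sqrt-kpk2 2.74e5 --noise-sd 0.02 --seed 1 --out runs/sim

# global fit of the two shared combined rate constants
aggkinetics fit-global --plate runs/sim/tht_concentrations_plate.csv \
    --meta runs/sim/tht_concentrations_meta.csv --out runs/fit

# dose-series plate and mechanism selection (which rate does the inhibitor hit?)
aggkinetics simulate --kind tht-doses --seed 1 --out runs/dose
aggkinetics fit-mechanism --plate runs/dose/tht_doses_plate.csv \
    --meta runs/dose/tht_doses_meta.csv --out runs/mech

# tau-half extraction, gamma scaling, turbidity dose-response
aggkinetics fit-sigmoidal --plate ... --meta ... --out runs/sig
aggkinetics scaling --plate ... --meta ... --out runs/gamma
aggkinetics dose-response --plate ... --meta ... --out runs/dr
```

Options can also be supplied via `--config config.yaml`; explicit flags win.
Every output directory receives the resolved config (`config_resolved.yaml`)
and a `run.log` for provenance.

## Data formats

* **Plate CSV (wide)** — column `time_s`, then one signal column per well;
  **(long)** — columns `time_s`, `well`, `signal`.
* **Metadata CSV** — `well`, `assay` (ThT/turbidity), `substrate`,
  `substrate_conc_uM`, `inhibitor`, `inhibitor_conc_uM`, `molar_ratio`,
  `replicate_group`.
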