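# cellgrowth

Tools for developing and interrogating ODE models of substrate-modulated
cell-population growth in static well-plate culture.

The state of a culture well is `(n, cg, cl, co)`: cell population
(cells/well) plus glucose, lactate and dissolved-oxygen concentrations
(mol m⁻³). Growth is logistic with a multiplicative environmental factor
`F_env = f1(co)·f2(cg)·f3(cl)` whose per-substrate form (zero-order,
first-order, or Michaelis–Menten) is unknown a priori; enumerating the
permitted forms yields a 27-member candidate family that the package
calibrates, filters, ranks and analyses end to end:

| stage | module | what it does |
|---|---|---|
| model family | `cellgrowth.models` | candidate enumeration, the structural oxygen/glucose dependence filter (27 → 22), stiff-capable simulation |
| synthetic experiments | `cellgrowth.synthetic` | the study design (4 environments × 4 seedings × 9 replicates), periodic sampling schedules, multiplicative replicate noise, stratified 60/20/20 splits |
| calibration | `cellgrowth.calibration` | inverse-variance weighted NLS objective, maxi-min Latin-hypercube starts, Adam → L-BFGS-B (→ trust-region polish) multi-start search |
| selection & validation | `cellgrowth.selection` | AIC/BIC ranking on the selection split, nested-limit reasoning between candidates, mean relative error and replicate-noise metrics |
| identifiability | `cellgrowth.identifiability` | profile likelihood with nuisance re-optimisation, χ²-threshold confidence intervals, finite/unbounded classification |
| sensitivity | `cellgrowth.sensitivity` | Sobol first/total-order indices (Saltelli/Jansen estimators, bootstrap CIs) of terminal and time-resolved outputs w.r.t. culture controls |
| protocol design | `cellgrowth.protocol` | simulate → corrupt → re-infer sweeps over sampling periods and noise levels; sampling-period recommendation |
| applications | `cellgrowth.applications` | long-horizon culture with periodic media refreshment and yield reporting |
| plumbing | `cellgrowth.config` / `datasets` / `pipeline` / `cli` | YAML config (strictly validated), CSV dataset IO, seeded end-to-end pipeline with a run manifest |

Units: rate constants are per second; every public interface takes and
returns time in hours.

## CLI

All stages are exposed as subcommands of one entry point:

```sh
cellgrowth enumerate                      # candidate family + filter verdicts
cellgrowth --out-dir out generate         # synthetic dataset from the config
cellgrowth --config cfg.yaml fit out/dataset.csv --n-starts 100
cellgrowth --config cfg.yaml select out/dataset.csv
cellgrowth --config cfg.yaml profile out/dataset.csv out/fit_OxyGluLac.json
cellgrowth --config cfg.yaml validate out/dataset.csv out/fit_OxyGluLac.json
cellgrowth gsa --n-base 8000
cellgrowth --config cfg.yaml mbdep
cellgrowth refresh
cellgrowth --config cfg.yaml pipeline     # full workflow + manifest.json
```

The YAML config controls the model family restriction, parameter and
constant defaults, experimental design, noise, split fractions, fit
budgets and bounds, identifiability settings, GSA ranges and the
optional MBDEP/refreshment stages; unknown keys are rejected. See
`tests/test_io_config.py::MICRO_CONFIG` for a complete worked example.

## Notes

- The default calibration search space is the `[1e-7, 1e7]` hypercube on
  log10 scale. Desk-scale fixtures use `physical_search_space()`
  (bounds from division-rate and media-capacity limits) so the
  reduced-budget multi-start recovers the generating parameters in
  minutes instead of hours.
- `published_parameters()` carries the reported calibrated values
  verbatim; `default_synthetic_parameters()` is the package's synthetic
  fixture (half-saturation constants inside the experimental ranges,
  per-well consumption units) — a fixture choice, documented as such.
- Sobol estimation is implemented in-package (paired-matrix design,
  Saltelli-2010 first-order and Jansen total-order estimators,
  bootstrap CIs) and validated against closed-form oracles.
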