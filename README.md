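# kinepi

Cryptic (non-specific) epistasis in enzyme catalytic cycles.

Enzyme kinetic parameters (k_cat, K_M, K_D, k_cat/K_M) are non-linear maps
of the free energies of the catalytic cycle's ground and transition states.
Even when two mutations perturb those free energies *perfectly additively*,
the composite parameters of the double mutant can deviate from the
multiplicative null expectation — apparent epistasis with no physical
interaction behind it. `kinepi` provides:

- **`mechanism_core`** — Eyring/transition-state-theory rate constants from
  free-energy profiles, and kinetic parameters for a two-step
  (E+S ⇌ ES → E+P) and a three-step (E+S ⇌ ES ⇌ EP → E+P) mechanism.
- **`mutation_simulator`** — random additive free-energy perturbations
  ("mutations"), applied singly and in all unordered pairs; fully
  vectorized (1000 mutations → 499,500 double mutants in ~1 s).
- **`epistasis_analysis`** — epistasis factor ε = observed/null per pair and
  parameter, fold-threshold significance, sign (positive/negative) and type
  (magnitude / sign / reciprocal sign) classification, prevalence summaries.
- **`analytic_km`** — closed-form ε surface for K_M in the simple mechanism,
  its exact sign condition sign(ε−1) = sign((α₁−β₁)(α₂−β₂)), ratio-grid
  scans and k₋₁/k₂ sweeps.
- **`experimental_correction`** — given measured microscopic rate constants
  for wt, two singles, and the double, separates *specific* epistasis
  (non-multiplicative rate constants) from *non-specific* epistasis (the
  kinetic map itself), via a corrected-null prediction.
- **`io_cli`** — `kinepi` command-line interface, provenance-stamped
  CSV/JSON output, deterministic fixture generation.

## Command line

```sh
# simulate a 1000-mutation library on the simple mechanism
kinepi simulate --mechanism simple --n 1000 --seed 1 --out run/
# -> run/mutations.csv, variants.csv, epistasis.csv, summary.json

# closed-form K_M epistasis surface over fold-effect ratios 0.01..100
kinepi grid --k-minus1 62.1 --k2 11.5 --out grid.csv

# maximum epsilon as k-1 departs from k2
kinepi sweep --multipliers 0.01 --multipliers 1 --multipliers 100 --out sweep.csv

# specific / non-specific decomposition of an experiment file
kinepi correct experiment.json --out report.json

# deterministic fixture inputs (profiles, small library, synthetic experiment)
kinepi fixtures --seed 1 --out fixtures/
```

Every CSV starts with a `# config: {...}` provenance line; read them with
`kinepi.io_cli.read_csv` (or `pandas.read_csv(..., comment="#")`).

## Library example

```python
from kinepi import (
    default_profile, rates_from_profile, kinetic_parameters,
    sample_mutations, build_variant_table, summarize,
)

profile = default_profile("simple")          # wild-type free energies
print(kinetic_parameters(rates_from_profile(profile)).as_dict())

effects = sample_mutations(1000, (-2, 2), "simple", seed=1)
table = build_variant_table(profile, effects)   # wt + singles + 499,500 pairs
summary = summarize(table, thresholds=(1.5, 2, 5, 10))
print(summary.prevalence_pct["efficiency"])     # % pairs epistatic per threshold
```

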