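# nutribalance

Compositional (log-ratio) analysis of plant ionomes. Leaf nutrient
concentrations are proportions of a whole, so statistics computed on raw
or plain-log values inherit closure artifacts: spurious correlation,
scale dependency and skewed distributions. `nutribalance` implements the
nutrient-balance workflow that avoids them:

- **core** — strictly positive compositions with explicit closure
  constant κ and unit bookkeeping; closure, filling value, alr/clr
  transforms, dual/amalgamated ratio combinatorics.
- **balances** — sequential binary partitions (SBPs), validation of the
  hierarchy rule, orthonormal contrast bases, forward/inverse ilr,
  balance dendrograms (JSON + Newick), the default 5-nutrient
  (N, P, K, Ca, Mg) leaf-ionome SBP with an optional filling-value row.
- **geometry** — Aitchison distance/norm and the log-Euclidean bias
  decomposition ε² = 𝒜² + D·(ln g(x)/g(y))², per pair and all-pairs.
- **diagnostics** — Anderson–Darling normality testing across raw / log /
  alr / ilr representations, scale-dependency correlation reports
  (sign flips, spurious negatives under sum closure), robust Mahalanobis
  outlier screening via minimum covariance determinant with chi-square
  cutoffs.
- **discriminant** — canonical discriminant analysis (generalized
  eigensolve of between vs pooled-within scatter), 95% data and
  mean-confidence ellipses, cross-validated misclassification; alr- and
  ilr-based analyses agree exactly on eigenvalues and CV error because
  canonical space is invariant to invertible linear maps of the inputs.
- **simulate** — logistic-normal (Gaussian-in-ilr) multi-group ionome
  generator with known ground truth, including an 8-group species panel
  with two "wild" groups at large Aitchison distance from six
  "domesticated" ones, optionally embedded in a dry-matter scale with a
  varying filling value.
- **cli / pipeline** — `nutribalance` command with `transform`,
  `distance`, `diagnose`, `da`, `simulate` and `run` subcommands; the
  pipeline writes a reproducibility manifest (input hash, seed,
  parameters) and is a pure function of input bytes + config + seed.

## CLI quick start

```sh
# synthesize the 8-species demo panel
nutribalance simulate --seed 1 -o synth/

# ilr balances with the default (N,P,K,Ca,Mg) SBP
nutribalance transform --kappa 1000 --unit g/kg \
    --representation ilr synth/ionomes.csv -o balances.csv

# paired Aitchison vs log-Euclidean distances with bias terms
nutribalance distance --kappa 1000 --unit g/kg synth/ionomes.csv -o dist.csv

# outlier screening + normality battery
nutribalance diagnose --kappa 1000 --unit g/kg --alpha 0.01 \
    synth/ionomes.csv -o diagnostics/

# canonical discriminant analysis across all four representations
nutribalance da --kappa 1000 --unit g/kg synth/ionomes.csv -o da/

# or everything at once from a config file
nutribalance run --config run.json
```

A custom SBP is a CSV with one column per part and cells in {−1, 0, +1};
each row's active set must be a group created by an earlier split
(`--sbp sbp.csv`).

## Conventions

- The +1 group of an SBP row is the numerator: a positive balance means
  its geometric mean exceeds the −1 group's.
- κ and unit are never rescaled implicitly; conversions are explicit
  (`convert_unit`), because raw-value covariance depends on the scale.
- Outlier masks are returned, never applied silently; screening defaults
  to ilr coordinates, per group.
- Zero or negative parts are rejected; `replace_below_detection` is an
  opt-in multiplicative-replacement hook for censored values.
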