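# parabuffer

Analysis of genetic buffering between duplicate (paralogous) genes:

- **ontology** — OBO/GAF parsing restricted to Biological Process (non-IEA),
  annotation-count propagation, information-content term similarity
  (Lin normalization, `icmax` alternative behind a flag), and a best-match
  GO divergence score per gene pair (`1 - max term-term similarity`).
- **interactions** — quantitative genetic-interaction tables, buffering
  classification (`score < 0 and p < 0.05`), buffering fractions and mean
  strengths, and two randomization null protocols (uniform assayed-pair
  sampling; random re-pairing of duplicate genes) with add-one empirical
  p-values.
- **divergence** — Ka/Ks via Nei–Gojobori (1986) pathway counting with the
  Jukes–Cantor correction (a reader for precomputed Ka/Ks tables takes
  precedence when supplied), aligned protein identity, and expression
  divergence (1 − Pearson r).
- **evolution** — Gaussian-window kernel density of Ks with mode detection
  (Silverman bandwidth), Pearson and first-order partial correlations, and
  the OLS regression of buffering strength on Ks below the saturation
  threshold (Ks ≤ 2).
- **predict** — feature vectors `[ka, identity, expression_divergence,
  go_div]`, an RBF-kernel SVM behind a decision-function contract, repeated
  stratified 3-fold cross-validation with fold-internal standardization and
  inner grid search, and a rank-statistic AUC.
- **structnet** — secondary-structure transition-probability vectors over
  {H, E, C} and their Jensen–Shannon discrepancy; shared-PPI-partner
  comparison with a 2×2 chi-square; protein-complex co-membership fractions.
- **synth** — deterministic generators for every input above, with planted
  background negative rates, buffering rates, a linear strength-vs-Ks decay,
  a bimodal Ks mixture, codon pairs mutated to planted Ka/Ks, correlated
  expression, and network/complex sharing at planted rates.
- **pipeline** — end-to-end orchestration producing a JSON report with
  provenance (config hash, seeds, exclusion counts).

## CLI

```sh
# write a complete synthetic input bundle
parabuffer synth --seed 1 --out bundle/

# batch GO divergence
parabuffer godiv --obo bundle/ontology.obo --gaf bundle/annotations.gaf \
    --pairs bundle/pairs.tsv --out godiv.tsv

# buffering calls + randomization nulls
parabuffer buffering --pairs bundle/pairs.tsv \
    --interactions bundle/interactions.tsv --controls 1000 --seed 1 \
    --out-prefix buf

# cross-validated backup-capacity prediction
parabuffer predict --features features.tsv --folds 3 --repeats 10 --seed 1 \
    --out cv.json

# the full pipeline on synthesized inputs
parabuffer run --synthesize --seed 1 --out out/
```

`parabuffer run --config config.yaml` accepts a YAML file with top-level
pipeline keys (`alpha`, `ks_max`, `n_controls`, `cv_repeats`,
`exclude_genes`, …) and a `synth:` section mirroring `SynthConfig` fields.

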