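# hisskit

Toolkit for rule-based severity scoring of hemorrhagic-trauma biomarker
panels. It covers the full pipeline:

- **`hisskit.domain`** — canonical types: the five-analyte panel
  (glucose mg/dL, lactate mmol/L, pH, potassium mmol/L, pO2 mmHg), the
  closed normal-band regime table (low / normal / high per analyte), and
  glucose unit conversion.
- **`hisskit.sfrp`** — synthetic patient generator: hidden severity
  seeds 0–4 (evenly allocated by default), per-level uniform biomarker
  sampling, regime-bleed noise filters (drift, adrenergic glucose
  response, late-onset acidosis, respiratory pO2 compensation, jitter),
  and potassium derived from pH via the 0.6 mmol/L-per-0.1-pH acid-base
  relation.
- **`hisskit.experts`** — a simulated five-member physician committee
  built on a deterministic derangement-grading rubric with per-expert
  weights, threshold shifts, score ceilings and per-act noise; fusion by
  majority vote (ties to higher severity) and by possibility labels
  (vote counts over the max count); intra-/inter-expert variability
  metrics. Shipped defaults are calibrated to ≈8.0% intra- and ≈20.6%
  inter-expert variability.
- **`hisskit.prbf`** — possibility rule-based classifier using function
  approximation: an evolutionary population of interval-condition rules
  with per-class linear consequents, trained online (cover / delta-rule
  update / GA / deletion), fused at inference by fitness-weighted
  averaging; empty match sets return the all-ones distribution of total
  ignorance.
- **`hisskit.bench`** — baseline classifiers (linear SVM, bagged
  decision trees with cross-entropy splits, one-hidden-layer softmax
  network), confusion/accuracy/per-class-TPR metrics, k-fold CV,
  learning curves over a fixed held-out test set, one-way ANOVA across
  classifiers, and a quadratic response surface predicting the
  (patients, experts) budget needed for a target accuracy.
- **`hisskit.io` / `hisskit.cli`** — CSV exchange format (undeclared
  scores round-trip as `UD`), JSON configs and model files, and the
  `hisskit` command line.

## Command line

```bash
hisskit generate --n 100 --seed 7 --out cohort.csv
hisskit score    --in cohort.csv --seed 7 --out scored.csv
hisskit fuse     --in scored.csv --out fused.csv          # adds mode, u0..u4
hisskit train prbf --in fused.csv --seed 7 --out model.json
hisskit evaluate --model model.json --in fused.csv --out report.json
hisskit curve    --in fused.csv --kind ebdt --sizes 30:80:5 --out curve.csv
hisskit size-predict --grid grid.csv --target 0.99 --out sizing.json
```

Every subcommand accepts `--seed` and `--config` (JSON/YAML) and logs
the seed and a config hash to stderr; outputs are reproducible from
(code, config, seed).

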