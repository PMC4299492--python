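# ebaflux

Integrated transcription–metabolism modeling for bacteria-scale gene
networks:

* **Linear transcriptional model** — per-gene ridge (optionally
  sign-constrained) regression of log2 expression on the expression of its
  transcription-factor regulators, with per-gene capacity bounds and
  wild-type statistics taken from the training compendium.
* **Expression balance analysis (EBA)** — a convex quadratic program that
  predicts the genome-wide expression profile under a perturbation
  scenario.  Each TF equation carries a slack; the QP minimizes the
  weighted sum of squared slacks subject to the linear model equations,
  capacity bounds, environmental TF fixings (via the signal-transduction
  layer) and genetic fixings (knockout → floor, over-expression → ceiling,
  rewiring → coefficient swap).
* **Signal transduction** — effector concentration changes shift TF
  expression linearly (`y_wt + omega * kappa * delta`, clamped) or switch a
  TF's regulatory activity off entirely.
* **Metabolic layer** — FBA/FVA linear programs over a stoichiometric
  model with gene–protein–reaction (GPR) rules, plus expression-gated flux
  bounds: FVA bound magnitudes are rescaled by each reaction's enzyme
  activity ratio (AND → min, OR → max over per-gene fold changes, gated by
  wild-type variability and capped).
* **Cost–benefit growth** — predicted relative growth
  `mu = max(0, B - c)`: metabolic benefit `B` (WT-normalized FBA growth
  under gated bounds) minus expression cost `c` (range-normalized mean
  deviation from the wild-type profile).
* **Evaluation** — per-array Pearson correlation scoring (global and
  local/regulatory-neighborhood) against an empirical random-profile null.
* **Experiment design** — greedy knockout ranking maximizing annotation-
  term coverage with a variability tie-break (submodular, carries the
  `1 - 1/e` guarantee).
* **Synthetic data** — seeded generators for every input artifact
  (scale-free signed network with ground-truth coefficients, steady-state
  compendium, toy metabolic chain wired to network genes, signal entries,
  random annotation), so the full pipeline is testable offline.

## Command line

Every stage is exposed through the `ebaflux` entry point
(`--help` on any subcommand for details):

```bash
# write a complete synthetic fixture suite
ebaflux simulate --preset small --seed 7 --out-dir fixtures/

# validate any artifact
ebaflux validate network fixtures/network.tsv

# fit the transcriptional model
ebaflux train --network fixtures/network.tsv \
    --expression fixtures/expression.tsv --meta fixtures/meta.tsv \
    --ridge 1e-6 --out model.json

# predict expression / growth for a scenario
ebaflux predict-expression --model model.json --sts fixtures/sts.tsv \
    --scenario fixtures/scenario_000.json --out profile.tsv
ebaflux predict-growth --reg-model model.json \
    --met-model fixtures/metabolic_model.json --sts fixtures/sts.tsv \
    --scenario fixtures/scenario_wt.json --out growth.json

# flux analysis and in-silico essentiality
ebaflux fba --model fixtures/metabolic_model.json
ebaflux fva --model fixtures/metabolic_model.json --out fva.tsv
ebaflux essentiality --met-model fixtures/metabolic_model.json \
    --reg-model model.json --gene g0012

# score a prediction against a measured array
ebaflux evaluate --pred profile.tsv --measured-array scn_000 \
    --expression fixtures/expression.tsv --meta fixtures/meta.tsv \
    --network fixtures/network.tsv --n-null 200 --seed 7

# greedy knockout design
ebaflux design --annotation fixtures/annotation.tsv \
    --network fixtures/network.tsv --expression fixtures/expression.tsv \
    --meta fixtures/meta.tsv --candidates g0006,g0007,g0008 --budget 2
```

Exit codes: `0` success, `2` input/validation error, `3` unrelaxed solver
infeasibility.  A JSON config file (`--config`) overrides defaults;
explicit flags override the config.

## File formats

All artifacts are plain text:

* network: TSV `regulator  target  sign  evidence` with sign in
  `{+, -, +/-}` and evidence in `{confirmed, strong, weak, inferred}`;
* expression: TSV matrix (first column gene ids, header row array ids,
  log2 values) plus a metadata TSV
  (`array_id  class  perturbation_kind  perturbed_genes  effectors`);
* metabolic model: JSON
  `{"metabolites": [...], "reactions": [{"id", "stoich", "lb", "ub",
  "gpr", "is_exchange"}], "biomass": "..."}` (SBML-L3/fbc accepted as a
  secondary path);
* signal table: TSV `tf  effector  type  kappa_or_brule`;
* annotation: TSV `term_id  level  gene_id`;
* scenario: JSON with `knockouts`, `overexpressions`, `rewirings`,
  `effectors`, `exchange_overrides`.

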