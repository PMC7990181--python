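# evorisk

Attribute tumor progression risk to mutational-phenotype ("evolutionary"),
driver-gene and clinical features.

The pipeline turns per-sample somatic variant calls (VCF) and clonal lineage
trees into quantitative evolutionary features — strand-collapsed substitution
rates, the 96 trinucleotide-context mutation rates, CNA/SV rate classes and
clone-tree statistics — predicts censored progression outcomes (overall
survival, disease-free survival) with an l0-stepwise Cox model under two-loop
(nested) cross-validation, and attributes the explainable fraction of
progression risk to each feature class through median-split log hazard
ratios.  A synthetic-cohort generator with known ground truth makes every
stage testable without external data.

## Layout

| module                 | role                                                                |
| ---------------------- | ------------------------------------------------------------------- |
| `genomic_io`           | VCF / FASTA / clone-tree JSON / clinical and outcome TSV I/O        |
| `synthetic_cohort`     | seeded cohort generator (variants, trees, clinical, survival)       |
| `evolutionary_features`| 6 substitution classes, 96 trinucleotide classes, CNA/SV rates, tree statistics |
| `annotation_features`  | driver-interval mutation rates, clinical encoding, matrix assembly  |
| `survival_core`        | Cox partial likelihood (Newton / lasso), concordance index, logrank, Kaplan-Meier |
| `selection_pipeline`   | collinearity pruning, step-wise l0 selection, nested CV, bootstrap importance, permutation control |
| `risk_attribution`     | median-split hazard ratios, log-HR fraction metrics, stratification reports |

Sign convention throughout: the hazard of sample *i* is
`h(t) * exp(-beta' X_i)` and the risk score is `eta_i = -beta' X_i`
(larger eta = higher risk).

## CLI

```sh
# 1. generate a synthetic cohort (VCFs, FASTA, clone trees, clinical, outcomes)
evorisk simulate --config sim.yaml --out cohort/

# 2. extract the tagged feature matrix
evorisk extract --cohort cohort/ --drivers drivers.tsv --endpoint OS --out feat

# 3. nested-CV run on a feature-class subset
evorisk select --features feat.features.tsv --classes feat.classes.tsv \
    --outcomes cohort/outcomes.tsv --feature-classes evolutionary,driver \
    --model l0 --seed 1 --out run_genomic

# 4. three-run risk attribution (evolutionary / +driver / full)
evorisk attribute --features feat.features.tsv --classes feat.classes.tsv \
    --outcomes cohort/outcomes.tsv --seed 1 --out attribution.json
```

`sim.yaml` holds `SimulationConfig` fields (cohort size, toy contigs,
signature mixture, rate priors, driver intervals with phenotype couplings,
clinical variables, true hazard coefficients, baseline hazard and censoring
families).  `drivers.tsv` is a BED-like TSV (`chrom  start  end  name`,
1-based inclusive).

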