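# trialomics

A tested, reusable pipeline for the exploratory analysis of a two-arm
randomized trial with paired pre/post plasma proteomes: per-protein linear
mixed models with treatment x response / treatment x time contrast testing,
compound rules calling arm-unique response markers and treatment targets,
panel ROC prediction, trial endpoint statistics (composite lesion response,
ORR/DCR, Kaplan–Meier, log-rank, hazard ratios), and a log-rank sample-size
calculator. A synthetic-data module generates cohorts and spectral-count
proteomes with known spike-in ground truth, so every downstream stage is
testable without access to patient data.

## Modules

| Module | Purpose |
| --- | --- |
| `trialomics.synthetic` | Cohort simulation (multinomial responses, exponential OS/PFS, lesion-level responses, censoring) and paired pre/post proteome generation with four spike-in archetypes restricted to one arm |
| `trialomics.preprocess` | `ProteinMatrix` container; detection filtering (drop proteins undetected in more than *k* samples), total-count normalization, log2 transform |
| `trialomics.lmm` | Dummy-coded designs with a per-patient random intercept, profiled-REML fitting, Wald contrast tests for four contrast families, Benjamini–Hochberg adjustment |
| `trialomics.markers` | Differential calls (raw p) and arm-unique marker/target calls (raw p AND (adjusted p OR \|coef\| threshold) AND interaction gate) |
| `trialomics.panel` | Zero-imputation of undetected panel proteins, mean-z panel scores, tie-aware ROC/AUC |
| `trialomics.trial` | Composite intrahepatic/extrahepatic response rule, ORR/DCR with exact CIs, chi-square/Fisher rate comparison, Kaplan–Meier, log-rank with O/E hazard ratio, Freedman/Schoenfeld sample size, Monte-Carlo power |

## Command line

```bash
# simulate a dataset from a YAML config (cohort: and proteome: maps)
trialomics simulate --config examples/config.yaml --out data/

# filter + normalize the count matrix
trialomics preprocess --matrix data/matrix.tsv --max-missing 40 --out data/norm.tsv

# per-protein mixed models and all contrast families
trialomics fit-lmm --matrix data/norm.tsv --annotation data/annotation.csv --out data/results.csv

# arm-unique response markers (pre-treatment) or treatment targets (pre/post)
trialomics call-markers --results data/results.csv --mode markers --out data/markers.csv
trialomics call-markers --results data/results.csv --mode targets --out data/targets.csv

# panel ROC on pre-treatment samples
trialomics roc --matrix data/norm.tsv --annotation data/annotation.csv \
    --panel P0001,P0002,P0003 --positive CR --out data/roc.csv

# endpoint report from a cohort table
trialomics trial-endpoints --cohort data/cohort.csv --out report.json

# log-rank sample-size design
trialomics design --median-control 8.2 --median-treatment 14.9
```

Example YAML config:

```yaml
cohort:
  n_per_arm: [53, 55]
  censor_prob: 0.1
  seed: 1
proteome:
  n_proteins: 300
  n_spiked_per_archetype: 5
  effect_size: 2.0
  dropout_prob: 0.05
  seed: 2
```

## Notes on conventions

- Missing matrix cells mean "undetected"; sample totals are computed over
  observed cells, and log2 uses a 1e-6 pseudocount.
- Contrast inference uses the large-sample z statistic; BH adjustment is
  applied per contrast family across proteins by default.
- A random-intercept variance estimated at the zero boundary falls back to
  the OLS covariance (flagged, not an error); rank-deficient per-protein
  designs after missing-data dropout are recorded as failed fits.
- Pair contrasts are oriented so that, e.g., "CR-PD" is positive when
  expression is higher in CR; unique calls report the upregulated cell.
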