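# comorbid-repurpose

Drug repurposing for complex diseases from Mendelian-disease comorbidity.
A drug is recommended as a candidate for a complex disease when it targets
a causal gene of a Mendelian disease clinically associated (comorbid) with
that complex disease. The package evaluates the candidates against
investigated/indicated drug-disease evidence with covariate-adjusted
logistic regression, gates the results with two degree-preserving
permutation nulls, prioritizes druggable Mendelian diseases and genes, and
combines comorbidity with two Mendelian-cancer genetic-similarity metrics
(driver-gene overlap and tissue co-expression).

## Inputs

Plain TSV with fixed headers (see `comorbid_repurpose.core.tables`):

| table                | columns |
|----------------------|---------|
| mendelian.tsv        | `mendelian_id`, `name`, `causal_genes` (pipe-joined) |
| complex_diseases.tsv | `complex_id`, `name`, `category` (one of cardiovascular, hormonal, immune, neoplasms, neurological, ophthalmological) |
| comorbidity.tsv      | `mendelian_id`, `complex_id` |
| drug_targets.tsv     | `drug_id`, `gene` (one row per link) |
| evidence.tsv         | `drug_id`, `complex_id`, `phase` (free-text trial phase) |
| indicated.tsv        | `drug_id`, `complex_id` |

For the cancer analyses additionally `drivers.tsv` (`cancer_id`, `gene`;
cancer ids must match complex-disease ids) and an expression TSV in long
form (`gene`, `tissue`, `value`) or wide gene × tissue form.

## CLI

All commands log record counts to stderr and write TSV results. A config
YAML lists the table paths (relative to the config file), a seed, and the
permutation count:

```sh
comorbid-repurpose simulate --seed 7 --out-dir world/          # synthetic bundle
comorbid-repurpose validate --config cfg.yaml
comorbid-repurpose candidates --config cfg.yaml \
    --candidates-out candidates.tsv --pairtable-out pairs.tsv
comorbid-repurpose enrich --pairtable pairs.tsv \
    --adjust category,n_targets --weights none --out enrichment.tsv
comorbid-repurpose permute --config cfg.yaml \
    --scheme comorbidity --n 1000 --seed 7 --out null_ors.tsv
comorbid-repurpose prioritize --config cfg.yaml --level disease \
    --n 1000 --seed 7 --out units.tsv
comorbid-repurpose similarity --config cfg.yaml --expr expr.tsv \
    --drivers drivers.tsv --out similarity.tsv
comorbid-repurpose combined --config cfg.yaml --similarity-table similarity.tsv \
    --strata-out strata.tsv --or-out combined_or.tsv
```

## Package layout

- `core/` — domain types, TSV IO with cross-reference validation, trial
  phase grouping (Phase I / II / III / Indicated / Unknown).
- `candidates.py` — candidate generation with per-(drug, disease)
  provenance, and the full drug × disease pair table under several outcome
  definitions (any evidence, indicated-only, per-phase, pooled phases).
- `enrichment.py` — logistic enrichment model (Wald CI/p), per-category
  and per-phase stratifications, balanced-weights variant, explicit
  perfect-separation sentinels.
- `permutation.py` — the two degree-preserving rewiring nulls and the
  empirical exceedance p-value (count / n, ties count).
- `druggability.py` — per-Mendelian-disease and per-gene enrichment with
  drug-target rewiring gates, and the rank-sum druggability comparison.
- `similarity.py` — hypergeometric gene-set overlap and Spearman tissue
  co-expression with Benjamini-Hochberg adjustment; either-metric call.
- `combined.py` — comorbidity × similarity support stratification of
  drug-cancer pairs and per-stratum enrichment.
- `synthetic.py` — full synthetic worlds with planted logistic effects and
  planted co-expression modules; ground truth saved for recovery tests.
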