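# snpsetarch

Data-driven SNP-set analysis for a two-disease (CHD / T2D) case–control
cohort: the pooled SNP × subject dosage matrix is decomposed into fuzzy
SNP × subject biclusters with nonsmooth nonnegative matrix factorization
(nsNMF), each set is tested for joint disease association with a kernel
score test (SKAT-style, Davies/Liu mixture-of-chi-square p-values),
significant sets are related to the four disease-pattern subgroups
(comorbid, CHD-only, T2D-only, none) by hypergeometric co-clustering with
Jaccard redundancy filtering, and the retained sets are organized into a
genotypic network by shared SNPs. A synthetic-cohort generator with
planted biclusters makes the whole pipeline testable end to end.

## Modules

| module | purpose |
|---|---|
| `snpsetarch.simulate` | synthetic cohorts with planted biclusters, exact disease-pattern counts, recovery scoring |
| `snpsetarch.io` | genotype TSV / PLINK .ped+.map / VCF readers and writers, phenotype and panel tables |
| `snpsetarch.prefilter` | QC (missingness, MAF, HWE exact test, call rate), per-SNP logistic prescreen, panel pooling, ancestry PCs |
| `snpsetarch.nsnmf` | nsNMF (X ≈ W·S·H, multiplicative KL updates), fraction-of-maximum set extraction, rank sweep |
| `snpsetarch.characterize` | per-set posterior descriptors (disease risk, panel composition, effect direction), purity summaries |
| `snpsetarch.skat` | covariate-adjusted logistic null, kernel score statistic, CF-inversion / Liu p-values |
| `snpsetarch.architecture` | phenotype sets, hypergeometric overlap, Jaccard redundancy filter, relation edges |
| `snpsetarch.network` | shared-SNP genotypic network, GraphML / edge-TSV export |
| `snpsetarch.replication` | sweep on a held-out cohort, hypergeometric discovery↔replication matching |
| `snpsetarch.pipeline`, `snpsetarch.cli` | staged orchestration with YAML config, manifests, deterministic seeding |

## CLI

Each pipeline stage is a subcommand; stages communicate through plain-text
artifacts in the output directory and write JSON manifests:

```bash
snpsetarch run-all --out pipeline_out --seed 7          # simulate → … → replicate
snpsetarch simulate --config config.yaml
snpsetarch validate --config config.yaml                # normalized config
```

A minimal `config.yaml` (all keys optional; defaults mirror the standard
thresholds — prescreen p < 5e-5, missingness 5%, MAF 1%, HWE 1e-6,
extraction τ = 0.6, redundancy JC > 0.8, α = 0.05):

```yaml
out_dir: pipeline_out
n_subjects: 441
pattern_counts: [61, 91, 97, 192]
theta: 0.5
k_min: 2
k_max: 16
seed: 7
```

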