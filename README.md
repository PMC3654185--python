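# famlink

Family-based statistical-genetics analysis chain for nuclear-family cohorts:

* **core_data** — PLINK-style `.ped`/`.map` and trait-CSV readers/writers,
  domain types (individuals, nuclear families, markers, cohorts), founder
  allele-frequency estimation.
* **synthetic_cohort** — seeded gene-dropping simulator: founder haplotype
  pools with a specified LD cluster, Haldane recombination, an
  additive/genotype-mean QTL plus a polygenic term, and an age-dependent
  binary disease driven by a liability with a Gompertz-like onset hazard.
* **ibd** — multipoint IBD for sibships via a hidden Markov model over
  inheritance vectors (forward–backward; per-meiosis Haldane bit-flip
  transitions), marginalised to per-pair P(IBD=0/1/2) and pihat on a cM grid.
* **vc_linkage** — univariate and bivariate variance-components linkage
  (Omega = sigma2_q·Pihat + sigma2_g·2Phi + sigma2_e·I), LOD curves with the
  ½χ²₀+½χ²₁ pointwise null, the Kaplan–Meier age-adjusted disease score, and
  locus-correlation (rho_q) tests.
* **association** — mixed-model quantitative association (LRT), GEE logistic
  association with exchangeable sibship clustering (model-based or robust
  SEs), two-population admixture estimation, step-wise conditional
  selection, region scans with a MAF plot filter.
* **linkage_partition** — percent of total and of linked-locus variance
  explained by SNPs (bivariate fit of trait vs genotype-adjusted residual),
  LOD_una/LOD_adj, the sigma2_q-equality LRT, rank-normalizing transform,
  and greedy step-wise linkage reduction.
* **ld_haplotype** — EM haplotype frequencies, pairwise D/D'/r² with
  profile-likelihood D' confidence intervals, confidence-interval haplotype
  blocks, greedy tag-SNP selection, zero-recombination family haplotype
  dosages, and haplotype-dosage association with a combination trend test.
* **cli** — a configuration-driven pipeline reproducing the full analysis
  surface on a simulated cohort.

## CLI

```sh
famlink all --out results/run1 --seed 1            # full pipeline
famlink scan --out results/scan --seed 1           # association scan only
famlink all --config run.yaml --out results --seed 2
```

`run.yaml` may override any `RunConfig` field, e.g.:

```yaml
n_families: 264
grid_step_cM: 2.0
maf_threshold: 0.05
tag_r2: 0.8
stages: [scan, linkage, ld, partition, table2, adjusted, haplotype]
```

Every output TSV carries the run seed in its header; identical config+seed
reproduces every artifact byte for byte.

## Acceptance

Acceptance is property-based (parameter recovery, type-I control, oracle
equivalence, closed forms, determinism) and lives in
`tests/test_acceptance.py`. The report script writes an empty target map
(there are no numeric targets to reproduce offline) after a seeded
self-check:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Notes

* GEE defaults to model-based standard errors to mirror the original
  analysis; robust (sandwich) errors are computed as well and recommended.
* The linked-variance-reduction test constrains
  sigma2_q(residual) == sigma2_q(trait) and uses a 1-df LRT; the constraint
  is recorded in the result metadata.
* No ascertainment correction is applied for disease-enriched sampling.
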