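# phapscore

Gene-level SNP-aggregation scoring for small pharmacogenomic GWAS cohorts.

Given genotypes, gene intervals, a stable-dose phenotype and a candidate-gene
list (the output of an external knowledge filter), `phapscore` runs an
end-to-end analysis:

1. **LD prune** — greedy filter so no retained variant pair exceeds a maximum
   pairwise dosage r² (default 0.2).
2. **Map** — assign variants to candidate genes within ±5 kbp of each gene
   boundary (BED coordinates), with optional manual overrides; genes without
   measured variants are dropped.
3. **Score** — per patient and gene, sum the negative log of the in-cohort
   frequency of the patient's observed genotype over the gene's SNPs
   (`--freq-mode allele` sums over the patient's two alleles instead).
   High scores mark carriers of uncommon variants.
4. **Associate** — univariate OLS of each SNP dosage and each gene score
   against continuous dose, Bonferroni-corrected.
5. **Extremes** — dichotomize patients at inclusive dose thresholds (low:
   ≤3 mg/day, high: ≥7 mg/day by default) and screen genes with pooled
   two-sample t-tests.
6. **Classify** — logistic regression on the discovered gene-score features,
   stratified 10-fold cross-validation, ROC/AUROC from pooled out-of-fold
   probabilities, and an empirical p-value against classifiers trained on
   random gene sets (default 100 replicates, so the smallest attainable
   p is 1/101).

A synthetic-cohort generator (`phapscore simulate`) produces
Hardy-Weinberg genotypes with configurable MAFs, local LD, and dose
phenotypes driven linearly by the minor-allele burden of planted effect
genes, so the whole pipeline is testable with known ground truth.

## Input formats

- **Genotypes**: VCF 4.x (GT field, diploid, biallelic records only) or a
  TSV dosage table — first column `sample_id`, one column per variant id,
  body of `0`/`1`/`2`/`NA` — with an optional companion metadata TSV
  (`variant_id`, `chrom`, `pos`, `ref_allele`, `alt_allele`).
- **Gene intervals**: BED4 (chrom, start, end, symbol), 0-based half-open.
- **Phenotypes**: TSV with columns `sample_id`, `dose_mg_per_day`.
- **Candidate genes**: one symbol per line, `#` comments allowed.
- **Overrides**: TSV with columns `variant_id`, `gene_symbol`; each row is
  assigned unconditionally.

## CLI

```sh
# synthetic cohort with known truth
phapscore simulate --config sim.yaml --out cohort/

# full pipeline from one config (flags override config keys)
phapscore run --config run.yaml --seed 1

# or stage by stage
phapscore prune --genotypes cohort/genotypes.vcf --max-r2 0.2 --out pruned/
phapscore map --genotypes cohort/genotypes.vcf --bed cohort/genes.bed \
    --gene-list cohort/candidate_genes.txt --keep pruned/kept_variants.tsv \
    --out map.tsv
phapscore score --genotypes cohort/genotypes.vcf --map map.tsv \
    --out-scores scores.tsv
phapscore assoc --level gene --scores scores.tsv \
    --phenotypes cohort/phenotypes.tsv --out gene_assoc.tsv
phapscore extremes --scores scores.tsv --phenotypes cohort/phenotypes.tsv \
    --low 3 --high 7 --out-dir extremes/
phapscore classify --scores scores.tsv --phenotypes cohort/phenotypes.tsv \
    --direction low --features nominal --folds 10 --null-reps 100 \
    --seed 1 --out-dir classify/
```

A `run.yaml` needs at least `genotypes`, `bed`, `phenotypes`, `gene_list`
and `out_dir`; all analysis parameters default to the standard values
(max_r2 0.2, window 5000 bp, alpha 0.05, thresholds 3/7 mg/day, 10 folds,
100 null replicates).  Every run writes a `manifest.json` echoing all
parameters, per-stage counts and correction thresholds; identical config and
seed reproduce all numeric outputs byte-for-byte.

## Tests and acceptance report

```sh
python -m pytest tests/              # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion
(threshold reproduction, scoring oracle equivalence, prune post-condition,
statistical calibration, parameter recovery, classifier sanity,
determinism).  `scripts/acceptance.py` recomputes the machine-checkable
target quantity from scratch and writes it as JSON.
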