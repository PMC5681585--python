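# cislmm

Cis-SNP set association testing for gene expression with a one-variance-component
linear mixed model.

For each gene, the expression vector `e` is modeled as
`e = X b + Z beta + eps` with per-SNP random effects `beta ~ N(0, tau^2 I)` over
the cis-SNPs `Z`, and the set association is tested as `H0: lambda = 0` with
`lambda = tau^2 / sigma^2`.  Because the parameter sits on the boundary, the
package provides:

- **eLRT** — an exact restricted-likelihood ratio test whose null distribution is
  simulated through the spectral representation of the projected genotype
  cross-product (`M` draws per eigenvalue spectrum);
- **aLRT** — a fast approximation that fits the simulated null with the mixture
  `phi * chi2_0 + (1 - phi) * kappa * chi2_1` from only `L` draws and computes
  tail probabilities in closed form, making genome-wide scans and very small
  p-values affordable;
- a variance-component **score test** (Liu moment-matched weighted chi-square);
- **BLUE** per-SNP weights for expression imputation and a PrediXcan-style
  gene-level association stage against an external genotyped cohort;
- an **eGene scan** (gene filtering, TSS-centered cis-windows, quantile
  normalization, Bonferroni control) and **LD-block enrichment** statistics;
- a simulation harness for type-I-error / power studies over a grid of
  effect-size variances and SNP-set sizes.

## Command line

```bash
cislmm simulate  --out-prefix scratch/toy --n 465 --p 100 --tau 0.1 --seed 1
cislmm scan      --genotypes geno.dosage.tsv --expression expr.tsv \
                 --annotation genes.gff3 --out results.tsv
cislmm null      --genotypes geno.dosage.tsv --out null_draws.tsv --draws-m 100000
cislmm weights   --genotypes geno.dosage.tsv --expression expr.tsv \
                 --annotation genes.tsv --out weights.tsv
cislmm predixcan --weights weights.tsv --genotypes cohort.vcf \
                 --phenotype pheno.tsv --out assoc.tsv
cislmm enrich    --results results.tsv --blocks blocks.bed --out folds.tsv \
                 --ztest-block MHC
cislmm power     --out power.tsv --replicates 10000 --draws-m 100000
```

Formats: genotypes as VCF (GT or DS) or dosage TSV
(`variant_id chrom pos ref alt <samples...>`); expression as genes x samples
TSV; annotation as GFF3 (`gene` features with `gene_id`/`gene_type`) or a
5-column TSV; LD blocks as BED (0-based half-open, converted internally to
1-based); phenotypes as two-column TSV.  All internal coordinates are 1-based;
sample alignment is always by ID.

## Library sketch

```python
from cislmm import spectral_decompose, fit_reml, simulate_null_draws, \
    fit_mixture, mixture_pvalue, blue_weights

sd   = spectral_decompose(Z, X, e)          # eigenvalues + rotated phenotype
fit  = fit_reml(sd)                         # lambda_hat, h2, LRT statistic T
null = simulate_null_draws(sd, M=100_000, seed=1)
mix  = fit_mixture(simulate_null_draws(sd, 10_000, seed=2))
p    = mixture_pvalue(fit.T, mix)           # aLRT p-value
w    = blue_weights(Z, X, e, fit)           # PrediXcan weights
```

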