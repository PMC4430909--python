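# ldblocks

Blockwise variable selection for genome-wide association studies (GWAS),
built on linkage disequilibrium (LD). Instead of testing or selecting
SNPs one at a time, the package looks for *LD blocks* — runs of adjacent
SNPs in mutual high LD — that are jointly associated with a continuous
phenotype, in three steps:

1. **LD-block clustering.** Adjacency-constrained Ward agglomeration of
   the p SNPs of a chromosome, using the similarity s(j, k) = r²(j, k)
   (EM maximum-likelihood haplotype-frequency r² from unphased
   genotypes). Only groups adjacent on the genome may merge, and the
   algorithm touches LD values lazily, so the p × p matrix is never
   stored. The merge cost is Ward's dispersion increase expressed through
   pairwise similarities:

       d(g, g') = (p_g p_g')/(p_g + p_g') ·
                  (S_gg/p_g² + S_g'g'/p_g'² − 2 S_gg'/(p_g p_g'))

   with W_G = p − Σ_g S_gg/p_g the within-group dispersion of a G-group
   partition.
2. **Choosing the number of blocks.** A modified (non-log) Gap
   statistic: Gap★(G) = (1/B) Σ_b (W_G^b − W_G), where each of the B
   reference data sets redraws every genotype column i.i.d. uniformly
   over its observed values. Ĝ is the smallest G with
   Gap★(G) ≥ Gap★(G+1) − s_{G+1}, s_G = (1+B)^(−1/2) sd_G.
3. **Block selection.** Group Lasso over the inferred blocks,

       argmin_β ‖y − Xβ‖₂² + λ Σ_g √p_g ‖β^g‖₂ ,

   which selects whole blocks (coefficients within a group are all zero
   or all nonzero). Comparators: Lasso, Elastic-Net (ridge penalty
   λ₂ = 0.8) and single-marker analysis (per-SNP OLS t-test), with
   optional unpenalized covariates.

It ships with the matching simulator (block-diagonal latent-Gaussian
genotypes thresholded at Hardy–Weinberg quantiles for a target minor
allele frequency; phenotypes y = Xβ + ε with ±1 causal coefficients and
noise calibrated to a target heritability R²) and partial-AUC (pAUC)
benchmarking under two truth definitions: SNP-level (causal SNPs) and
block-level (every SNP of a block containing a causal SNP).

Intended users: statistical geneticists and methodologists who want a
tested, reproducible implementation of LD-block-based group selection,
either as a Python library or from the shell.

## Worked example

`python examples/infer_ld_blocks.py` simulates 64 SNPs in 8 latent LD
blocks (ρ = 0.8, n = 300), clusters them and selects Ĝ:

```
true number of blocks : 8
selected G_hat        : 8
true block starts     : [0, 8, 16, 24, 32, 40, 48, 56]
inferred block starts : [0, 8, 16, 24, 32, 40, 48, 56]
exact recovery        : True
```

`python examples/benchmark_pauc.py` scores selectors by pAUC over 5
replicates (8 causal SNPs in one block of 8, ρ = 0.4, R² = 0.2):

```
                           mean    std
mode  method
block group-lasso-oracle  0.555  0.028
      lasso               0.316  0.029
      sma                 0.343  0.061
snp   group-lasso-oracle  0.555  0.028
      lasso               0.316  0.029
      sma                 0.343  0.061
```

Higher pAUC means better ranking of true positives at low false-positive
rates; with a fully causal block, group selection dominates SNP-wise
selection under both evaluation modes (SNP- and block-level truths
coincide here because every SNP of the causal block is causal). The
other examples show the Group Lasso fit (`fit_group_lasso.py`) and the
end-to-end PLINK pipeline (`plink_pipeline.py`).

## Command line

```
ldblocks simulate --scenario main --seed 1 --out-prefix sim/run1
ldblocks select-blocks --genotypes sim/run1 --seed 1 --out-dir out/
ldblocks fit --genotypes sim/run1 --phenotype sim/run1.pheno.tsv \
    --method group-lasso --blocks out/blocks_chr1.bed --out-dir out/
ldblocks evaluate --path out/path.tsv --truth sim/run1.truth.json \
    --mode block --out-dir out/
ldblocks pipeline --genotypes sim/run1 --phenotype sim/run1.pheno.tsv \
    --seed 1 --out-dir out/full
```

Inputs are PLINK bed/bim/fam triplets (or a headered samples × SNPs TSV
with NA for missing); the pipeline runs chromosome by chromosome,
filters SNPs with undefined LD, and imputes missing genotypes by the
per-SNP mode only after the clustering (which tolerates missing values).

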