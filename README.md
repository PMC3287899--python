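# nullsnp

Genome-wide association scans for quantitative traits, scored against a
resampled **null-SNP reference distribution** instead of a standardized test
statistic.

## The idea

Conventional single-SNP association tests standardize the observed genetic
effect by its estimated standard error (the Wald/t statistic `T`), then look
the result up in a known distribution and correct for the number of markers
tested. In a genome scan the phenotype is fixed — only the marker changes —
and the tens of thousands of unassociated SNPs themselves provide a natural
reference distribution, making both the standardization and the
multiple-testing correction unnecessary.

`nullsnp` implements this idea for a quantitative trait `y` with covariates
`x_1..x_p` and genotype scores `g ∈ {0, 1, 2}` (allele counts, AA=0, AB=1,
BB=2):

1. Residualize: `y*` = OLS residuals of `y` on an intercept and the
   covariates; `g*` likewise, per SNP, over that SNP's non-missing subset.
2. Score each SNP with the unstandardized statistic

   `S = (Σ_i g*_i y*_i)² / n*`

   where `n*` is the number of individuals with a non-missing genotype (the
   division keeps `S` on one scale while `n*` varies across the genome). No
   standard error is involved. For a 0/1 trait without covariates the
   cross-product reduces to `(n₁n₀/n)(ḡ₁ − ḡ₀)` — proportional to the
   counted-allele frequency difference between the phenotype groups.
3. Build the reference distribution once per scan: each of `K` iterations
   draws a SNP uniformly from a set of presumed-null SNPs and a random
   permutation of `y*`, and records `S⁽ᵏ⁾` for that SNP. Because the marker
   is drawn at random, the reference is the distribution of `S` at *an
   arbitrary null SNP*, so the p-value

   `p = (1 + #{k : S⁽ᵏ⁾ ≥ s}) / (K + 1)`

   is genome-wide by construction. The null set defaults to all analyzable
   SNPs and can instead be chosen by thresholding the parametric p-values or
   by a histogram-uniformity check.

The conventional standardized statistic `T` (genotype coefficient t statistic
from `y ~ 1 + covariates + g`, `n* − p − 2` df) is computed alongside for
comparison; on complete data the partial regression sum of squares of that
model ranks SNPs exactly like `T²`, while `S` deliberately ranks differently —
it weights the raw covariance rather than the correlation.

## Worked example

Simulate a 400-individual, 1,000-SNP panel with Sex/Age/Smoke covariate
effects and one causal SNP (index 250, `β = 0.8` trait SD, MAF pinned at
0.3), then scan it:

```sh
cat > demo.scenario <<EOF
n_individuals = 400
n_snps = 1000
seed = 7
causal = 250:0.8
fixed_maf = 250:0.3
EOF
nullsnp simulate --scenario demo.scenario --out-prefix demo
nullsnp scan --geno demo.geno.tsv --meta demo.snps.tsv \
    --pheno demo.pheno.tsv --id-col id --trait trait \
    --covars Sex,Age,Smoke --k 100000 --seed 8 --alpha 5e-4 \
    --out demo.results.tsv
```

The scan logs

```
INFO nullsnp.resampling: scan: n=400 individuals, m=1000 SNPs, null set 958,
    K=100000 (coverage 100.0/SNP), 1 SNP(s) with p_S < 0.0005
```

and the causal SNP's row in `demo.results.tsv` reads

```
snp_id   chrom  pos    maf       n_star  S        p_S           T        p_T           flagged
S000251  6      31494  0.295918  392     43.8885  9.999900e-06  9.98187  4.962604e-21  1
```

`p_S = 1/(K+1) = 1e-5` is the smallest p-value the resampling can produce:
the observed `S` exceeded all 100,000 null draws. `flagged = 1` marks
`p_S` below the reporting threshold `alpha`. The 42 SNPs missing from the
null set (958 of 1,000) are monomorphic-in-sample or otherwise unanalyzable;
they are carried through with `S = 0` and `T = NA` so the output has one row
per input SNP. A null-reference file (`demo.results.tsv.null.tsv`) records
the `K` resampled values with the seed and settings that produced them.

Genotypes can equally be given as a VCF (`--vcf panel.vcf`, GT fields,
biallelic SNVs). The same pipeline is available as library calls
(`nullsnp.genome_scan`, `nullsnp.make_null_panel`, ...).

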