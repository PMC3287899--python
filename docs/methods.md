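# Methods

## Model and procedure

For `n` unrelated individuals with quantitative trait `y`, covariates
`x_1..x_p`, and genotype scores `g ∈ {0,1,2}` counting one allele of a
biallelic SNP, the scan proceeds as follows.

**Residualization.** `y*` is the vector of OLS residuals of `y` on an
intercept plus the covariates, computed once per scan on the full cohort.
Per SNP, `g*` is the OLS residual of `g` on the same design, fitted only on
the individuals with an observed genotype; `n*` is the size of that subset.
Residuals of an intercept-containing fit have mean zero on their fitting
index, so no further centering terms appear in the statistic; when `y*` is
subset to a SNP's non-missing index its mean is removed again, since the
zero-mean property holds only on the full index. All least-squares solves use
a rank-revealing routine with a relative singular-value threshold of 1e-10;
rank-deficient designs are rejected with the collinear columns named.

**Statistic S.** `S = (Σ g*_i y*_i)² / n*`. The cross-product is the
numerator of the partial regression sum of squares for the regression *of
genotype on phenotype*; its denominator, the total sum of squares of `y*`,
is constant across a scan and is dropped. Division by `n*` keeps SNPs with
different missingness on one scale. The squared form is the default; an
`absolute` form `|Σ g*_i y*_i| / n*` is available (`--s-form`), and the two
give identical resampling p-values because the rank ordering is the same.

**Comparator T.** The t statistic of the genotype coefficient in
`y ~ 1 + x_1..x_p + g`, fitted on the non-missing subset, with a two-sided
p-value from a t distribution on `n* − p − 2` degrees of freedom. `--t-df`
overrides the reference distribution (not the coefficient or its SE) for
replication exercises against software using other conventions. On complete
data the partial regression SS of this model is a monotone transform of
`T²` (the total SS of `y*` being fixed), so the two rank SNPs identically;
`S` does not share this property — dropping the per-SNP `Σ g*²`
standardization is exactly what distinguishes it.

**Resampling reference.** One reference distribution serves the whole scan.
Each of `K` iterations pairs a SNP drawn uniformly with replacement from the
null set with a uniform random permutation of `y*` over all `n` individuals;
the permuted residuals are restricted to the drawn SNP's non-missing index,
re-centered there, and crossed with that SNP's precomputed `g*`. Permuting
over all `n` and then subsetting preserves exchangeability and lets a single
permutation scheme serve SNPs with arbitrary missingness patterns. The
p-value of an observed `s` is `(1 + #{S⁽ᵏ⁾ ≥ s})/(K + 1)` (add-one
estimator; ties count as exceedances), so p-values live in `[1/(K+1), 1]`
and are never zero. A `plain` `#{S⁽ᵏ⁾ ≥ s}/K` estimator is available for
sensitivity checks.

**Null set.** Default `all`: every analyzable SNP, appropriate when signals
are sparse and weak so the parametric p-value histogram is near-uniform.
`threshold` excludes SNPs with parametric p below a cutoff (default 0.01);
`histogram` applies a Kolmogorov–Smirnov uniformity check at level 0.05 and
falls back to the threshold exclusion only on rejection.

## Randomness and reproducibility

A single `numpy` Generator seeded from `--seed` drives the reference build.
The stream is consumed in a fixed, documented order: all `K` SNP indices are
drawn first; row permutations are then generated in batches grouped by SNP in
ascending panel order (the grouping enables vectorized `Generator.permuted`
batches without changing the sampled law). Results are bit-identical across
runs with the same inputs and seed. Monomorphic null SNPs contribute
`S⁽ᵏ⁾ = 0` without consuming permutation draws.

## Degenerate inputs

SNPs that are monomorphic on their non-missing subset, collinear with the
covariates, or observed in fewer than `p + 3` individuals cannot be tested.
They are carried through the scan with `S = 0`, sentinel (`NA`) `T`, and the
resulting `p_S = 1`, so the output has one row per input SNP; they are
excluded from the null set. These sentinel rows are placeholders, not test
results — calibration statements about p-value uniformity apply to the
analyzable SNPs.

## Synthetic panels

The generator emulates a mini-exome-style panel of unrelated individuals:
per-SNP allele frequencies drawn from a rare-heavy mixture (weights 0.45 /
0.25 / 0.30 on log-uniform bins 0.0014–0.01, 0.01–0.05, 0.05–0.5, floored at
`1/(2n)` so SNPs are polymorphic in expectation), genotypes i.i.d. under
Hardy–Weinberg proportions, i.i.d. genotype missingness (default rate 0.02,
so `n*` varies), and a linear trait
`y = Σ effect·covariate + Σ β·g + N(0, 1)` with Sex (binary, 0.5 SD),
Age (continuous standard-normal, 0.3 SD) and Smoke (binary, 0.25 SD)
analogues. Scenario defaults are 697 individuals and 24,487 SNPs, the scale
of the community dataset this class of method targets; tests and the
acceptance script use smaller panels (e.g. n=500, m=2,000) chosen so the
full suite runs in minutes on one CPU while leaving Monte-Carlo error well
inside the asserted tolerances.

Deliberately **not** emulated: linkage disequilibrium (SNPs are independent;
the statistic is marginal, so LD affects interpretation of neighboring hits,
not the per-SNP nulls), population structure, relatedness, and genotype
errors. Passing tests on these panels therefore validate the statistics,
the permutation machinery and the calibration of genome-wide p-values under
the stated sampling model — they say nothing about confounding robustness on
structured cohorts.

## Validation design choices

- **Exact oracle.** At n=6 the full 6! permutation null is enumerated and
  the Monte-Carlo p-value is required to match it within 0.01 at K=100,000.
- **Calibration.** On a null panel (n=500, m=2,000, K=200,000) resampling
  p-values of analyzable SNPs must pass a KS uniformity test at level 0.01
  and give type-I error within 3 binomial SE of 0.05.
- **K-stability.** All p-values in a scan share one reference ECDF, so their
  Monte-Carlo errors are strongly correlated across SNPs (coherent quantile
  blocks). The stable statement of "p-values barely move when K grows
  tenfold" is the uniform bound `max |p(K=1e5) − p(K=1e6)| ≤ 0.01` over
  p ≥ 1e-3, which the DKW inequality guarantees with probability > 99% at
  these K; per-SNP 2-SE band coverage is tracked only as a diagnostic
  because its panel-level fraction is an unstable functional of the shared
  reference.
- **Power.** A causal SNP at β = 1 trait SD, MAF 0.3, n=500 must be ranked
  first (by `p_S`, `S` breaking floor ties) in ≥ 95% of 20 replicates.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `K` | 100,000 | resampling iterations; p-value floor is `1/(K+1)`; per-SNP Monte-Carlo SE is `√(p(1−p)/K)` |
| `alpha` | 5e-4 | reporting threshold on the genome-wide resampling p-value |
| `null_method` / `null_cutoff` | `all` / 0.01 | how the presumed-null SNP set is chosen |
| `s_form` | `squared` | `S` convention; does not affect resampling p-values |
| `t_df` | `n*−p−2` | reference df for the comparator's p-value |
| `missing_rate` (generator) | 0.02 | i.i.d. genotype missingness |
| `noise_sd` (generator) | 1.0 | trait residual SD; effect sizes are in these units |

## Known limitations

- Dichotomous traits are handled only through the identity linking the
  cross-product to the group allele-frequency difference; no
  logistic/proportional-odds genotype model is provided.
- Exchangeability of `y*` is approximate: OLS residuals have mildly unequal
  leverage-dependent variances. At the panel sizes targeted (hundreds of
  individuals, a handful of covariates) the effect is negligible, but tiny
  n with high-leverage covariates would bias the permutation null.
- The null reference conditions on the observed phenotype realization;
  p-values of different SNPs are therefore correlated, which matters for
  joint statements (e.g. counting flagged SNPs) though not for per-SNP
  validity.
- No LD-aware interpretation, clumping, or stratification control.
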