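"""Genome-wide significance by null-SNP resampling.

The reference distribution for the unstandardized statistic ``S`` is built
once per scan: each of ``K`` iterations draws a SNP uniformly from a set of
presumed-null SNPs and a uniform random permutation of the covariate-adjusted
phenotype residuals ``y*``, and records ``S`` for that SNP against the
permuted residuals. Because the drawn SNP is random, the resulting null
distribution is that of *an arbitrary SNP* under no association, so a p-value
against it is genome-wide: no separate multiple-testing correction applies.

The empirical p-value uses the add-one estimator ``(1 + #{S^(k) >= s})/(K+1)``
with ties counted as exceedances, so the smallest attainable p-value is
``1/(K+1)`` and no p-value of zero is ever emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_stats import (
    GenotypeResiduals,
    ResidualVector,
    fit_covariate_residuals,
    genotype_residuals,
)
from .errors import ComputationError, ValidationError
from .io_formats import GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

__all__ = [
    "NullReference",
    "AssociationRecord",
    "ScanResult",
    "select_null_set",
    "build_null_distribution",
    "empirical_pvalue",
    "genome_scan",
    "iteration_coverage",
]

#: per-iteration permutation batches are capped at this many matrix elements
_BATCH_ELEMENTS = 8_000_000


@dataclass(frozen=True)
class NullReference:
    """K resampled null values of S, with provenance for reproducibility."""

    null_values: np.ndarray
    K: int
    null_snp_ids: frozenset
    seed: int
    s_form: str
    null_method: str = "all"
    _sorted: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.null_values, dtype=float)
        object.__setattr__(self, "null_values", vals)
        if vals.size != self.K:
            raise ValidationError("null_values length does not equal K")
        if self.s_form == "squared" and vals.size and vals.min() < 0:
            raise ValidationError("squared-form null values must be nonnegative")
        object.__setattr__(self, "_sorted", np.sort(vals))

    def count_geq(self, s) -> np.ndarray:
        """Number of null values >= s (weak inequality), vectorized over s."""
        idx = np.searchsorted(self._sorted, np.asarray(s, dtype=float), side="left")
        return self.K - idx


@dataclass(frozen=True)
class AssociationRecord:
    """Per-SNP scan output row."""

    snp_id: str
    chrom: str
    position: int
    maf: float
    n_star: int
    s_value: float
    s_pvalue: float
    t_value: float
    t_pvalue: float
    flagged: bool
    monomorphic: bool = False


@dataclass(frozen=True)
class ScanResult:
    records: tuple
    null_reference: NullReference

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "pos": [r.position for r in self.records],
                "maf": [r.maf for r in self.records],
                "n_star": [r.n_star for r in self.records],
                "S": [r.s_value for r in self.records],
                "p_S": [r.s_pvalue for r in self.records],
                "T": [r.t_value for r in self.records],
                "p_T": [r.t_pvalue for r in self.records],
                "flagged": [r.flagged for r in self.records],
                "monomorphic": [r.monomorphic for r in self.records],
            }
        )


def iteration_coverage(K: int, m: int) -> float:
    """Average number of resampling iterations per SNP, K/m — the diagnostic
    for whether the reference distribution samples the panel densely."""
    if m <= 0:
        raise ValidationError("m must be positive")
    return K / m


def select_null_set(
    t_pvalues: Mapping[str, float] | pd.Series,
    method: str = "all",
    cutoff: float = 0.01,
) -> frozenset:
    """Choose the SNPs presumed null, from their parametric (T) p-values.

    ``all`` keeps every analyzable SNP — appropriate when the p-value histogram
    looks uniform, as with weak or absent signals. ``threshold`` excludes SNPs
    with p < cutoff. ``histogram`` first tests the p-values for uniformity
    (Kolmogorov-Smirnov at level 0.05) and applies the threshold exclusion only
    if uniformity is rejected.
    """
    pv = pd.Series(t_pvalues, dtype=float).dropna()
    if pv.empty:
        raise ComputationError("no analyzable SNPs: cannot form a null set")
    if method == "all":
        return frozenset(pv.index)
    if method == "threshold":
        kept = pv.index[pv.to_numpy() >= cutoff]
        if not len(kept):
            raise ComputationError(
                f"every SNP has p < {cutoff}: null set would be empty"
            )
        return frozenset(kept)
    if method == "histogram":
        ks = stats.kstest(pv.to_numpy(), "uniform")
        if ks.pvalue < 0.05:
            logger.info(
                "p-value histogram deviates from uniform (KS p=%.3g); "
                "excluding SNPs with p < %g",
                ks.pvalue,
                cutoff,
            )
            return select_null_set(pv, "threshold", cutoff)
        logger.info("p-value histogram consistent with uniform (KS p=%.3g); keeping all SNPs", ks.pvalue)
        return frozenset(pv.index)
    raise ValidationError(f"unknown null-set method {method!r}")


def _prepare_genotype_residuals(
    genotypes: GenotypeMatrix, covariates, snp_ids: Iterable[str] | None = None
) -> dict[str, GenotypeResiduals]:
    wanted = None if snp_ids is None else set(snp_ids)
    out: dict[str, GenotypeResiduals] = {}
    for j, snp_id in enumerate(genotypes.snp_ids):
        if wanted is not None and snp_id not in wanted:
            continue
        out[snp_id] = genotype_residuals(genotypes.column(j), covariates)
    return out


def build_null_distribution(
    genotypes: GenotypeMatrix | None,
    covariates,
    y_star: ResidualVector,
    null_ids: Iterable[str],
    K: int,
    seed: int,
    s_form: str = "squared",
    precomputed: Mapping[str, GenotypeResiduals] | None = None,
    null_method: str = "all",
) -> NullReference:
    """Resample K null values of S from randomly chosen null SNPs.

    Each iteration pairs a SNP drawn uniformly (with replacement) from
    ``null_ids`` with a fresh uniform permutation of ``y*`` over all n
    individuals; the permuted residuals are subset to the SNP's non-missing
    index, re-centered there, and crossed with the SNP's precomputed ``g*``.

    The random stream is consumed in a fixed, documented order: all K SNP
    indices first, then row permutations generated in blocks grouped by SNP
    (ascending panel order). Results are bit-reproducible from ``seed``;
    monomorphic SNPs contribute S=0 without consuming permutation draws.
    """
    if K < 1:
        raise ValidationError("K must be at least 1")
    if s_form not in ("squared", "absolute"):
        raise ValidationError(f"unknown S form {s_form!r}")
    null_ids = list(dict.fromkeys(null_ids)) if not isinstance(null_ids, (set, frozenset)) else sorted(null_ids)
    if not null_ids:
        raise ValidationError("null_ids is empty: no null reference possible")
    if genotypes is not None:
        order = [s for s in genotypes.snp_ids if s in set(null_ids)]
        if len(order) != len(null_ids):
            missing = set(null_ids) - set(order)
            raise ValidationError(f"null SNP id(s) not in panel: {sorted(missing)[:5]}")
        null_ids = order
    if precomputed is None:
        if genotypes is None:
            raise ValidationError("need either a genotype matrix or precomputed residuals")
        precomputed = _prepare_genotype_residuals(genotypes, covariates, null_ids)

    n = len(y_star)
    y_full = y_star.values
    rng = np.random.default_rng(seed)
    snp_draws = rng.integers(0, len(null_ids), size=K)
    out = np.empty(K)
    for j, snp_id in enumerate(null_ids):
        rows = np.flatnonzero(snp_draws == j)
        if rows.size == 0:
            continue
        gr = precomputed[snp_id]
        if gr.monomorphic:
            out[rows] = 0.0
            continue
        idx = gr.residuals.index
        g_vals = gr.residuals.values
        complete = idx.size == n
        batch = max(1, _BATCH_ELEMENTS // n)
        for lo in range(0, rows.size, batch):
            block = rows[lo : lo + batch]
            perm = np.broadcast_to(y_full, (block.size, n)).copy()
            rng.permuted(perm, axis=1, out=perm)
            sub = perm if complete else perm[:, idx]
            sub = sub - sub.mean(axis=1, keepdims=True)
            cross = sub @ g_vals
            if s_form == "squared":
                out[block] = cross * cross / gr.n_star
            else:
                out[block] = np.abs(cross) / gr.n_star
    return NullReference(
        null_values=out,
        K=K,
        null_snp_ids=frozenset(null_ids),
        seed=int(seed),
        s_form=s_form,
        null_method=null_method,
    )


def empirical_pvalue(
    s_observed,
    ref: NullReference,
    estimator: str = "add_one",
    s_form: str | None = None,
):
    """Genome-wide empirical p-value of an observed S against the reference.

    ``add_one`` (default) returns ``(1 + #{S^(k) >= s}) / (K + 1)``, which is a
    valid p-value and never zero; ``plain`` returns ``#{S^(k) >= s} / K``.
    """
    if s_form is not None and s_form != ref.s_form:
        raise ValidationError(
            f"S was computed under form {s_form!r} but the reference uses {ref.s_form!r}"
        )
    count = ref.count_geq(s_observed)
    if estimator == "add_one":
        p = (1.0 + count) / (ref.K + 1.0)
    elif estimator == "plain":
        p = count / ref.K
    else:
        raise ValidationError(f"unknown p-value estimator {estimator!r}")
    return float(p) if np.ndim(s_observed) == 0 else p


def genome_scan(
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    trait: str,
    covariate_names: Sequence[str] = (),
    K: int = 100_000,
    seed: int = 0,
    null_method: str = "all",
    null_cutoff: float = 0.01,
    alpha: float = 5e-4,
    s_form: str = "squared",
    t_df: int | None = None,
    estimator: str = "add_one",
) -> ScanResult:
    """Scan every SNP: residualize, compute S and T, build one shared null
    reference, and assign each SNP its genome-wide resampling p-value.

    The resampling is done once regardless of the panel size; records with
    ``s_pvalue < alpha`` are flagged. Monomorphic/unanalyzable SNPs are carried
    through with S=0 and a sentinel (NaN) T so row counts match the input.
    """
    from .core_stats import statistic_S, statistic_T

    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    geno_ids = [str(s) for s in genotypes.individual_ids]
    pheno_ids = set(phenotypes.data.index)
    unmatched = [s for s in geno_ids if s not in pheno_ids]
    if unmatched:
        raise ValidationError(
            f"{len(unmatched)} genotyped individual(s) missing from the phenotype "
            f"table: {unmatched[:10]}"
        )
    extra = len(pheno_ids) - (len(geno_ids) - len(unmatched))
    if extra:
        logger.info("dropping %d phenotype row(s) without genotypes", extra)
    aligned = phenotypes.data.loc[geno_ids]
    y = aligned[trait].to_numpy(dtype=float) if trait in aligned.columns else None
    if y is None:
        raise ValidationError(f"trait column {trait!r} not present")
    cov = aligned[list(covariate_names)].to_numpy(dtype=float) if covariate_names else None

    y_star = fit_covariate_residuals(y, cov, covariate_names=covariate_names)

    n = genotypes.n_individuals
    p = len(covariate_names)
    residuals: dict[str, GenotypeResiduals] = {}
    per_snp: list[dict] = []
    t_pvalues: dict[str, float] = {}
    for j, snp_id in enumerate(genotypes.snp_ids):
        g = genotypes.column(j)
        obs = ~np.isnan(g)
        n_star = int(obs.sum())
        maf = float(np.nanmean(g) / 2.0) if n_star else float("nan")
        maf = min(maf, 1.0 - maf)
        meta = genotypes.snp_meta.iloc[j]
        entry = {
            "snp_id": snp_id,
            "chrom": str(meta["chrom"]),
            "pos": int(meta["pos"]),
            "maf": maf,
            "n_star": n_star,
        }
        if n_star < p + 2 or n_star - p - 2 < 1:
            entry.update(s=0.0, t=np.nan, t_p=np.nan, mono=True)
            per_snp.append(entry)
            continue
        gr = genotype_residuals(g, cov)
        residuals[snp_id] = gr
        if gr.monomorphic:
            entry.update(s=0.0, t=np.nan, t_p=np.nan, mono=True)
            per_snp.append(entry)
            continue
        y_sub = y_star.restrict(gr.residuals.index)
        s_val = statistic_S(gr.residuals, y_sub, gr.n_star, form=s_form)
        t_res = statistic_T(g, y, cov, t_df=t_df)
        entry.update(s=s_val, t=t_res.t_value, t_p=t_res.t_pvalue, mono=False)
        if np.isfinite(t_res.t_pvalue):
            t_pvalues[snp_id] = t_res.t_pvalue
        per_snp.append(entry)

    null_ids = select_null_set(t_pvalues, method=null_method, cutoff=null_cutoff)
    ref = build_null_distribution(
        genotypes,
        cov,
        y_star,
        null_ids,
        K=K,
        seed=seed,
        s_form=s_form,
        precomputed=residuals,
        null_method=null_method,
    )
    s_all = np.array([e["s"] for e in per_snp])
    p_all = empirical_pvalue(s_all, ref, estimator=estimator)
    records = tuple(
        AssociationRecord(
            snp_id=e["snp_id"],
            chrom=e["chrom"],
            position=e["pos"],
            maf=e["maf"],
            n_star=e["n_star"],
            s_value=e["s"],
            s_pvalue=float(p_all[i]),
            t_value=e["t"],
            t_pvalue=e["t_p"],
            flagged=bool(p_all[i] < alpha),
            monomorphic=e["mono"],
        )
        for i, e in enumerate(per_snp)
    )
    logger.info(
        "scan: n=%d individuals, m=%d SNPs, null set %d, K=%d (coverage %.1f/SNP), "
        "%d SNP(s) with p_S < %g",
        n,
        genotypes.n_snps,
        len(null_ids),
        K,
        iteration_coverage(K, genotypes.n_snps),
        int(sum(r.flagged for r in records)),
        alpha,
    )
    return ScanResult(records=records, null_reference=ref)
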