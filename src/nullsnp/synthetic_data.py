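"""Synthetic mini-exome-style panels with known truth.

Generates genotype/phenotype panels resembling a community mini-exome dataset
of unrelated individuals: hundreds of subjects, tens of thousands of SNPs with
a minor-allele-frequency spectrum running from common (~0.5) down to very rare
(~1/n), a continuous trait driven by Sex/Age/Smoke-style covariates plus
optional weak additive SNP effects, and per-SNP genotype missingness so the
non-missing count n* varies across the genome.

SNPs are simulated independently under Hardy-Weinberg proportions; linkage
disequilibrium and pedigree structure are deliberately not emulated — the
association method treats SNPs marginally, so LD would only change the
interpretation of neighboring hits, not the statistics under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import META_COLUMNS, GenotypeMatrix, PhenotypeTable

__all__ = [
    "SimulationScenario",
    "simulate_genotypes",
    "simulate_phenotype",
    "make_null_panel",
    "DEFAULT_MAF_BINS",
    "DEFAULT_COVARIATES",
]

#: (weight, low, high) MAF bins, log-uniform within each bin: a rare-heavy
#: exome-like spectrum spanning ~1/n singletonish variants up to MAF 0.5
DEFAULT_MAF_BINS: Tuple[Tuple[float, float, float], ...] = (
    (0.45, 0.0014, 0.01),
    (0.25, 0.01, 0.05),
    (0.30, 0.05, 0.5),
)

#: (name, type, effect in trait-SD units) — Sex/Age/Smoke analogues
DEFAULT_COVARIATES: Tuple[Tuple[str, str, float], ...] = (
    ("Sex", "binary", 0.5),
    ("Age", "continuous", 0.3),
    ("Smoke", "binary", 0.25),
)

_N_CHROMS = 22


@dataclass(frozen=True)
class SimulationScenario:
    """Everything needed to regenerate a panel bit-for-bit from one seed.

    Defaults mirror the application panel the method targets: 697 unrelated
    individuals, 24,487 SNPs, covariate-driven trait, no causal SNPs.
    """

    n_individuals: int = 697
    n_snps: int = 24_487
    maf_bins: Tuple[Tuple[float, float, float], ...] = DEFAULT_MAF_BINS
    missing_rate: float = 0.02
    covariate_spec: Tuple[Tuple[str, str, float], ...] = DEFAULT_COVARIATES
    causal_snps: Tuple[Tuple[int, float], ...] = ()
    fixed_mafs: Tuple[Tuple[int, float], ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be positive")
        if self.n_snps < 1:
            raise ValidationError("n_snps must be positive")
        if not (0.0 <= self.missing_rate < 0.5):
            raise ValidationError("missing_rate must lie in [0, 0.5)")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        for w, lo, hi in self.maf_bins:
            if not (0.0 < lo <= hi <= 0.5) or w < 0:
                raise ValidationError(f"invalid maf bin ({w}, {lo}, {hi})")
        if not self.maf_bins or sum(w for w, *_ in self.maf_bins) <= 0:
            raise ValidationError("maf_bins must carry positive total weight")
        for name, kind, _ in self.covariate_spec:
            if kind not in ("binary", "continuous"):
                raise ValidationError(f"covariate {name!r} has unknown type {kind!r}")
        for idx, beta in self.causal_snps:
            if not (0 <= idx < self.n_snps):
                raise ValidationError(
                    f"causal SNP index {idx} outside [0, {self.n_snps})"
                )
            float(beta)
        for idx, q in self.fixed_mafs:
            if not (0 <= idx < self.n_snps):
                raise ValidationError(f"fixed-MAF SNP index {idx} outside [0, {self.n_snps})")
            if not (0.0 < q <= 0.5):
                raise ValidationError(f"fixed MAF {q} outside (0, 0.5]")


def _draw_mafs(scenario: SimulationScenario, rng: np.random.Generator) -> np.ndarray:
    weights = np.array([w for w, *_ in scenario.maf_bins], dtype=float)
    weights /= weights.sum()
    bins = rng.choice(len(scenario.maf_bins), size=scenario.n_snps, p=weights)
    lows = np.array([lo for _, lo, _ in scenario.maf_bins])
    highs = np.array([hi for _, _, hi in scenario.maf_bins])
    u = rng.random(scenario.n_snps)
    q = np.exp(np.log(lows[bins]) + u * (np.log(highs[bins]) - np.log(lows[bins])))
    # keep simulated SNPs polymorphic in expectation; monomorphic *draws* are
    # retained so sentinel handling gets exercised downstream
    q = np.maximum(q, 1.0 / (2.0 * scenario.n_individuals))
    for idx, fixed in scenario.fixed_mafs:
        q[idx] = fixed
    return q


def simulate_genotypes(scenario: SimulationScenario) -> GenotypeMatrix:
    """Draw genotypes i.i.d. under Hardy-Weinberg at per-SNP allele frequency q.

    Genotype scores count the B (alt) allele: P(0,1,2) = ((1-q)^2, 2q(1-q), q^2).
    Entries are masked missing i.i.d. at ``missing_rate``. The true simulated
    frequency is kept in the metadata column ``true_q``.
    """
    rng = np.random.default_rng([scenario.seed, 0])
    n, m = scenario.n_individuals, scenario.n_snps
    q = _draw_mafs(scenario, rng)
    scores = rng.binomial(2, q[None, :], size=(n, m)).astype(float)
    if scenario.missing_rate > 0:
        scores[rng.random((n, m)) < scenario.missing_rate] = np.nan
    chrom = 1 + (np.arange(m) * _N_CHROMS) // m
    pos = np.empty(m, dtype=int)
    for c in range(1, _N_CHROMS + 1):
        on_c = chrom == c
        pos[on_c] = 10_000 + 977 * np.arange(on_c.sum())
    meta = pd.DataFrame(
        {
            "snp_id": [f"S{i + 1:06d}" for i in range(m)],
            "chrom": chrom.astype(str),
            "pos": pos,
            "ref_allele": "A",
            "alt_allele": "G",
            "counted_allele": "G",
        },
        columns=META_COLUMNS,
    )
    meta["true_q"] = q
    return GenotypeMatrix(
        scores=scores,
        individual_ids=np.array([f"I{i + 1:05d}" for i in range(n)], dtype=object),
        snp_meta=meta,
    )


def simulate_phenotype(
    genotypes: GenotypeMatrix, scenario: SimulationScenario
) -> PhenotypeTable:
    """Linear trait: intercept + covariate effects + additive SNP effects + noise.

    Missing causal genotypes enter trait generation at their expectation 2q
    (truth frequency when available, otherwise the observed mean), so the
    phenotype itself is complete. Covariates are returned alongside the trait.
    """
    rng = np.random.default_rng([scenario.seed, 1])
    n = genotypes.n_individuals
    columns: dict[str, np.ndarray] = {}
    y = np.zeros(n)
    for name, kind, effect in scenario.covariate_spec:
        x = (
            rng.integers(0, 2, n).astype(float)
            if kind == "binary"
            else rng.standard_normal(n)
        )
        columns[name] = x
        y = y + effect * x
    for idx, beta in scenario.causal_snps:
        g = genotypes.column(idx).copy()
        missing = np.isnan(g)
        if missing.any():
            if "true_q" in genotypes.snp_meta.columns:
                fill = 2.0 * float(genotypes.snp_meta["true_q"].iloc[idx])
            else:
                fill = float(np.nanmean(g))
            g[missing] = fill
        y = y + beta * g
    y = y + rng.normal(0.0, scenario.noise_sd, n)
    data = pd.DataFrame({"trait": y, **columns}, index=genotypes.individual_ids.astype(str))
    return PhenotypeTable(data=data)


def make_null_panel(n: int, m: int, seed: int) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Convenience null panel: no causal SNPs, active Sex/Age/Smoke-style
    covariates (so residualization is exercised), exome-like MAF spectrum."""
    scenario = SimulationScenario(n_individuals=n, n_snps=m, seed=seed)
    gm = simulate_genotypes(scenario)
    return gm, simulate_phenotype(gm, scenario)
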