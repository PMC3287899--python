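"""Covariate residualization and per-SNP association statistics.

Two statistics are computed for each SNP:

* ``S`` — an *unstandardized* measure of association: the squared cross-product
  of the covariate-adjusted phenotype residuals ``y*`` and genotype residuals
  ``g*``, scaled by the number of individuals with a non-missing genotype,

      S = (sum_i g*_i y*_i)^2 / n*.

  No standard error enters; significance is assessed genome-wide by the
  resampling machinery in :mod:`nullsnp.resampling`.

* ``T`` — the conventional standardized comparator: the t statistic of the
  genotype coefficient in the multiple linear regression of the phenotype on
  an intercept, the covariates, and the genotype score, with its two-sided
  p-value from a t distribution on ``n* - p - 2`` degrees of freedom.

Genotypes are scored as allele counts (AA=0, AB=1, BB=2); ``S`` is invariant
to which allele is counted, while ``T`` flips sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import linalg, stats

from .errors import ComputationError, ValidationError

__all__ = [
    "ResidualVector",
    "GenotypeResiduals",
    "SnpStatistic",
    "TResult",
    "fit_covariate_residuals",
    "genotype_residuals",
    "statistic_S",
    "statistic_T",
    "regression_ss",
]

#: relative singular-value threshold below which a design column is declared
#: linearly dependent on the others
RANK_TOL = 1e-10


@dataclass(frozen=True)
class ResidualVector:
    """OLS residuals of a phenotype or genotype after regressing out covariates.

    ``index`` holds the positional indices (into the cohort ordering) the
    residuals are defined on; for a phenotype residualized on complete data it
    is ``0..n-1``, for a genotype it is the non-missing subset.
    """

    values: np.ndarray
    source: str  # "phenotype" | "genotype"
    index: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "index", np.asarray(self.index, dtype=np.intp))
        if self.values.shape != self.index.shape:
            raise ValidationError("residual values and index have different lengths")
        if self.source not in ("phenotype", "genotype"):
            raise ValidationError(f"unknown residual source {self.source!r}")

    def __len__(self) -> int:
        return self.values.size

    def restrict(self, index: np.ndarray, recenter: bool = True) -> "ResidualVector":
        """Subset to positional ``index`` (into the full cohort) and re-center.

        Residual means are zero only on the index the regression was fitted on;
        after subsetting to a SNP's non-missing individuals the mean is removed
        again so the cross-product in ``S`` is taken between centered vectors.
        """
        index = np.asarray(index, dtype=np.intp)
        pos = {int(i): k for k, i in enumerate(self.index)}
        try:
            take = np.fromiter((pos[int(i)] for i in index), dtype=np.intp, count=index.size)
        except KeyError as exc:
            raise ValidationError(
                f"index {exc.args[0]} not covered by this residual vector"
            ) from None
        vals = self.values[take]
        if recenter and vals.size:
            vals = vals - vals.mean()
        return ResidualVector(values=vals, source=self.source, index=index)


@dataclass(frozen=True)
class GenotypeResiduals:
    """Genotype residuals ``g*`` on the non-missing subset, with its size ``n*``."""

    residuals: ResidualVector
    n_star: int
    monomorphic: bool = False


class TResult(NamedTuple):
    t_value: float
    t_pvalue: float
    n_star: int
    df: int


@dataclass(frozen=True)
class SnpStatistic:
    """Per-SNP association summary used by the scan."""

    snp_id: str
    n_star: int
    s_value: float
    t_value: float
    t_pvalue: float

    def __post_init__(self) -> None:
        if self.n_star <= 0:
            raise ValidationError(f"{self.snp_id}: n_star must be positive")
        if np.isfinite(self.s_value) and self.s_value < 0:
            raise ValidationError(f"{self.snp_id}: squared-form S cannot be negative")
        if np.isfinite(self.t_pvalue) and not (0.0 < self.t_pvalue <= 1.0):
            raise ValidationError(f"{self.snp_id}: t_pvalue outside (0, 1]")


def _as_covariate_matrix(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.empty((n, 0))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValidationError(
            f"covariate matrix has {cov.shape[0]} rows for {n} individuals"
        )
    return cov


def _column_names(names: Sequence[str] | None, p: int) -> list[str]:
    if names is None:
        return [f"x{j + 1}" for j in range(p)]
    return list(names)


def _check_design_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the dependent columns if ``X`` is rank deficient."""
    if X.shape[1] == 0:
        return
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.size else 0.0
    rank = int((diag > RANK_TOL * scale).sum()) if scale > 0 else 0
    if rank < X.shape[1]:
        bad = sorted(names[j] for j in piv[rank:])
        raise ValidationError(
            "design matrix is rank deficient; collinear column(s): " + ", ".join(bad)
        )


def _ols_residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=RANK_TOL)
    return y - X @ beta


def fit_covariate_residuals(
    values,
    covariates=None,
    *,
    covariate_names: Sequence[str] | None = None,
    source: str = "phenotype",
    index: np.ndarray | None = None,
) -> ResidualVector:
    """OLS residuals of ``values`` regressed on an intercept plus ``covariates``.

    With no covariates this is plain mean-centering. ``values`` and
    ``covariates`` must be complete on the supplied index; missing genotypes
    are handled upstream by :func:`genotype_residuals`.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    cov = _as_covariate_matrix(covariates, n)
    p = cov.shape[1]
    if np.isnan(y).any():
        raise ValidationError("values contain missing entries")
    if np.isnan(cov).any():
        raise ValidationError("covariates contain missing entries")
    if n < p + 1:
        raise ValidationError(f"{n} individuals cannot support {p} covariates plus intercept")
    X = np.column_stack([np.ones(n), cov])
    _check_design_rank(X, ["intercept"] + _column_names(covariate_names, p))
    resid = _ols_residuals(y, X)
    resid -= resid.mean()  # exact zero mean, not just to solver precision
    if index is None:
        index = np.arange(n)
    return ResidualVector(values=resid, source=source, index=np.asarray(index))


def genotype_residuals(
    g,
    covariates=None,
    *,
    covariate_names: Sequence[str] | None = None,
) -> GenotypeResiduals:
    """Residualize a genotype-score vector on covariates over its non-missing subset.

    The regression is fitted only on individuals with an observed genotype;
    ``n_star`` is the size of that subset. Monomorphic SNPs return all-zero
    residuals with ``monomorphic=True`` rather than raising, so scans can carry
    them through as sentinel records.
    """
    g = np.asarray(g, dtype=float)
    mask = ~np.isnan(g)
    idx = np.flatnonzero(mask)
    n_star = int(idx.size)
    cov_full = _as_covariate_matrix(covariates, g.size)
    p = cov_full.shape[1]
    if n_star < p + 2:
        raise ComputationError(
            f"unanalyzable SNP: only {n_star} non-missing genotypes for {p} covariates"
        )
    g_obs = g[idx]
    if np.ptp(g_obs) == 0.0:
        rv = ResidualVector(values=np.zeros(n_star), source="genotype", index=idx)
        return GenotypeResiduals(residuals=rv, n_star=n_star, monomorphic=True)
    rv = fit_covariate_residuals(
        g_obs,
        cov_full[idx] if p else None,
        covariate_names=covariate_names,
        source="genotype",
        index=idx,
    )
    return GenotypeResiduals(residuals=rv, n_star=n_star, monomorphic=False)


def statistic_S(
    g_star: ResidualVector,
    y_star: ResidualVector,
    n_star: int | None = None,
    form: str = "squared",
) -> float:
    """Unstandardized association statistic for one SNP.

    ``squared`` (default) returns ``(sum g* y*)^2 / n*``; ``absolute`` returns
    ``|sum g* y*| / n*``. The two are monotone transforms of each other, so
    resampling p-values are identical under either form.
    """
    if form not in ("squared", "absolute"):
        raise ValidationError(f"unknown S form {form!r}")
    if not np.array_equal(g_star.index, y_star.index):
        raise ValidationError(
            "g* and y* are defined on different individuals; restrict y* to the "
            "SNP's non-missing index first"
        )
    if n_star is None:
        n_star = len(g_star)
    if n_star <= 0:
        raise ValidationError("n_star must be positive")
    cross = float(g_star.values @ y_star.values)
    if form == "squared":
        return cross * cross / n_star
    return abs(cross) / n_star


def statistic_T(
    g,
    y,
    covariates=None,
    *,
    t_df: int | None = None,
) -> TResult:
    """Standardized comparator: t statistic for the genotype coefficient.

    Fits ``y ~ 1 + covariates + g`` over the non-missing genotype subset and
    returns the Wald t statistic with its two-sided p-value on ``n* - p - 2``
    degrees of freedom (``t_df`` overrides the reference distribution only).
    Monomorphic or covariate-collinear genotypes yield a NaN sentinel.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if g.shape != y.shape:
        raise ValidationError("genotype and trait vectors differ in length")
    if np.isnan(y).any():
        raise ValidationError("trait vector contains missing values")
    mask = ~np.isnan(g)
    idx = np.flatnonzero(mask)
    n_star = int(idx.size)
    cov_full = _as_covariate_matrix(covariates, g.size)
    p = cov_full.shape[1]
    df = n_star - p - 2
    if df < 1:
        raise ComputationError(
            f"unanalyzable SNP: {n_star} non-missing genotypes leave {df} df"
        )
    g_obs, y_obs = g[idx], y[idx]
    if np.ptp(g_obs) == 0.0:
        return TResult(np.nan, np.nan, n_star, df)
    X = np.column_stack([np.ones(n_star), cov_full[idx], g_obs])
    # collinearity of g with the covariates -> sentinel, not an exception
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if (diag <= RANK_TOL * diag.max()).any():
        return TResult(np.nan, np.nan, n_star, df)
    beta, _, _, _ = np.linalg.lstsq(X, y_obs, rcond=RANK_TOL)
    resid = y_obs - X @ beta
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    if se == 0.0:
        return TResult(np.nan, np.nan, n_star, df)
    t_value = float(beta[-1]) / se
    ref_df = df if t_df is None else int(t_df)
    t_pvalue = float(2.0 * stats.t.sf(abs(t_value), ref_df))
    return TResult(t_value, max(t_pvalue, np.finfo(float).tiny), n_star, df)


def regression_ss(g, y) -> float:
    """Partial regression sum of squares for the genotype-on-phenotype regression.

    Returns ``[sum (g_i - gbar)(y_i - ybar)]^2 / sum (y_i - ybar)^2``. The
    denominator is constant across a genome scan of a fixed phenotype, which is
    what motivates dropping it from ``S``.
    """
    g = np.asarray(g, dtype=float)
    y = np.asarray(y, dtype=float)
    if g.shape != y.shape:
        raise ValidationError("vectors differ in length")
    if np.isnan(g).any() or np.isnan(y).any():
        raise ValidationError("regression_ss requires complete vectors")
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    if ss_y == 0.0:
        raise ComputationError("constant trait: zero total sum of squares")
    cross = float((g - g.mean()) @ yc)
    return cross * cross / ss_y
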