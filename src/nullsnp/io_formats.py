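"""Genotype/phenotype containers and readers/writers for the supported text formats.

Supported inputs: VCF 4.x with GT genotypes (biallelic SNVs; other records are
skipped with a warning), a plain tab-separated SNP-by-individual score matrix
with a metadata sidecar, and a tab-separated phenotype/covariate table. Scan
results and null-reference distributions are written as tab-separated text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataFormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "read_vcf",
    "write_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_phenotype_table",
    "write_phenotype_table",
    "write_results",
    "write_null_reference",
]

META_COLUMNS = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele", "counted_allele"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count scores with per-SNP metadata.

    ``scores`` is a float matrix with entries in {0, 1, 2} and NaN for missing
    genotypes. ``counted_allele`` (a metadata column) records which allele the
    score counts; the statistic ``S`` is invariant to that orientation, and
    minor allele frequencies are reported as ``min(f, 1-f)`` regardless.
    """

    scores: np.ndarray
    individual_ids: np.ndarray
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.scores.ndim != 2:
            raise ValidationError("scores must be a 2-D individuals x SNPs matrix")
        n, m = self.scores.shape
        if self.individual_ids.size != n:
            raise ValidationError("individual_ids length does not match score rows")
        if len(self.snp_meta) != m:
            raise ValidationError("snp_meta rows do not match score columns")
        obs = self.scores[~np.isnan(self.scores)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValidationError("genotype scores outside {0, 1, 2, missing}")
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate individual ids")
        if self.snp_meta["snp_id"].duplicated().any():
            dup = self.snp_meta["snp_id"][self.snp_meta["snp_id"].duplicated()].iloc[0]
            raise ValidationError(f"duplicate SNP id {dup!r}")
        if (pd.to_numeric(self.snp_meta["pos"]) < 0).any():
            raise ValidationError("SNP positions must be nonnegative")
        self.snp_meta = self.snp_meta.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.scores.shape[0]

    @property
    def n_snps(self) -> int:
        return self.scores.shape[1]

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["snp_id"].to_numpy()

    def column(self, j: int) -> np.ndarray:
        return self.scores[:, j]

    def n_star(self) -> np.ndarray:
        """Non-missing genotype count per SNP."""
        return (~np.isnan(self.scores)).sum(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP, computed on non-missing genotypes."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.scores, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)


@dataclass
class PhenotypeTable:
    """Trait and covariate columns indexed by individual id."""

    data: pd.DataFrame  # index: individual ids (str)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValidationError("duplicate individual ids in phenotype table")
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)

    @property
    def individual_ids(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=object)

    def trait(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise ValidationError(f"trait column {name!r} not present")
        return self.data[name].to_numpy(dtype=float)

    def covariates(self, names) -> np.ndarray:
        missing = [c for c in names if c not in self.data.columns]
        if missing:
            raise ValidationError(f"covariate column(s) not present: {', '.join(missing)}")
        if not names:
            return np.empty((len(self.data), 0))
        return self.data[list(names)].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path) -> GenotypeMatrix:
    """Load GT genotypes from a VCF into allele-count scores (ALT counted).

    ``0/0 -> 0``, ``0/1``/``1/0 -> 1``, ``1/1 -> 2``, ``./. -> missing``;
    phased separators are accepted. Multiallelic and non-SNV records are
    skipped with a warning.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad files
        raise DataFormatError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise DataFormatError(f"VCF {path} has no sample columns (no GT data)")
    cols: list[np.ndarray] = []
    meta_rows = []
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            logger.warning(
                "skipping non-biallelic-SNV record %s:%s", variant.CHROM, variant.POS
            )
            continue
        gt = variant.gt_types.astype(float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.where(gt == 3, 2.0, gt)
        col[gt == 2] = np.nan
        cols.append(col)
        snp_id = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        meta_rows.append(
            (snp_id, str(variant.CHROM), int(variant.POS), variant.REF, variant.ALT[0], variant.ALT[0])
        )
    if not cols:
        raise DataFormatError(f"VCF {path} contains no usable biallelic SNV records")
    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    return GenotypeMatrix(
        scores=np.column_stack(cols),
        individual_ids=np.asarray(samples, dtype=object),
        snp_meta=meta,
    )


_GT_STRINGS = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write the matrix as a minimal VCF 4.2 with GT-only genotype fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=nullsnp\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        fh.write("\t".join(header + [str(s) for s in gm.individual_ids]) + "\n")
        for j, row in gm.snp_meta.iterrows():
            gts = [
                "./." if np.isnan(v) else _GT_STRINGS[v] for v in gm.scores[:, j]
            ]
            fields = [
                str(row["chrom"]),
                str(int(row["pos"])),
                str(row["snp_id"]),
                str(row["ref_allele"]),
                str(row["alt_allele"]),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            fh.write("\t".join(fields + gts) + "\n")


# ---------------------------------------------------------------------------
# Plain TSV genotype matrix + metadata sidecar


def read_genotype_tsv(path, meta_path) -> GenotypeMatrix:
    """Load a SNP-by-individual {0,1,2,NA} matrix plus its metadata sidecar.

    The matrix file has individual ids in the header row and SNP ids in the
    first column. The sidecar maps SNP id to chromosome/position (and
    optionally ref/alt alleles); SNPs without metadata get chrom "NA"/pos 0
    with a warning.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, na_values=["NA"])
    except (OSError, pd.errors.ParserError) as exc:
        raise DataFormatError(f"cannot read genotype matrix {path}: {exc}") from exc
    values = raw.to_numpy(dtype=object)
    scores = np.full(values.shape, np.nan)
    for (i, j), cell in np.ndenumerate(values):
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            continue
        if cell not in ("0", "1", "2"):
            raise DataFormatError(
                f"invalid genotype cell {cell!r} at SNP {raw.index[i]!r}, "
                f"individual {raw.columns[j]!r}"
            )
        scores[i, j] = float(cell)
    try:
        meta_raw = pd.read_csv(meta_path, sep="\t", dtype={"snp_id": str, "chrom": str})
    except (OSError, pd.errors.ParserError) as exc:
        raise DataFormatError(f"cannot read SNP metadata {meta_path}: {exc}") from exc
    if "snp_id" not in meta_raw.columns:
        raise DataFormatError(f"SNP metadata {meta_path} lacks a snp_id column")
    meta_raw = meta_raw.set_index("snp_id")
    rows = []
    n_unknown = 0
    for snp_id in raw.index:
        if snp_id in meta_raw.index:
            rec = meta_raw.loc[snp_id]
            rows.append(
                (
                    snp_id,
                    str(rec.get("chrom", "NA")),
                    int(rec.get("pos", 0)),
                    str(rec.get("ref_allele", "A")),
                    str(rec.get("alt_allele", "B")),
                    str(rec.get("counted_allele", rec.get("alt_allele", "B"))),
                )
            )
        else:
            n_unknown += 1
            rows.append((snp_id, "NA", 0, "A", "B", "B"))
    if n_unknown:
        logger.warning("%d SNP(s) lack metadata; chrom set to NA, pos to 0", n_unknown)
    meta = pd.DataFrame(rows, columns=META_COLUMNS)
    return GenotypeMatrix(
        scores=scores.T,  # file is SNP x individual; container is individual x SNP
        individual_ids=raw.columns.to_numpy(dtype=object),
        snp_meta=meta,
    )


def write_genotype_tsv(gm: GenotypeMatrix, path, meta_path) -> None:
    """Write the SNP-by-individual matrix and its metadata sidecar."""
    frame = pd.DataFrame(
        gm.scores.T,
        index=gm.snp_meta["snp_id"].astype(str),
        columns=[str(s) for s in gm.individual_ids],
    )
    # integer-looking cells, NA for missing
    out = frame.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.index.name = "snp_id"
    out.to_csv(path, sep="\t")
    gm.snp_meta[META_COLUMNS].to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenotype table


def read_phenotype_table(path, id_column, trait, covariates=()) -> PhenotypeTable:
    """Load a tab-separated phenotype table keeping the trait and covariates.

    Rows with a missing trait or covariate value are dropped (count logged).
    Two-level string covariates are mapped to 0/1 in lexicographic order
    (e.g. F -> 0, M -> 1), and the mapping is logged.
    """
    try:
        table = pd.read_csv(path, sep="\t", dtype={id_column: str} if id_column else None)
    except (OSError, pd.errors.ParserError) as exc:
        raise DataFormatError(f"cannot read phenotype table {path}: {exc}") from exc
    except ValueError as exc:
        raise DataFormatError(f"phenotype table {path}: {exc}") from exc
    if id_column not in table.columns:
        raise DataFormatError(f"id column {id_column!r} not found in {path}")
    wanted = [trait, *covariates]
    missing_cols = [c for c in wanted if c not in table.columns]
    if missing_cols:
        raise DataFormatError(f"column(s) not found in {path}: {', '.join(missing_cols)}")
    table = table.set_index(id_column)[wanted]
    for col in wanted:
        if table[col].dtype == object:
            levels = sorted(table[col].dropna().astype(str).unique())
            if len(levels) == 2:
                mapping = {levels[0]: 0.0, levels[1]: 1.0}
                logger.info("column %r mapped to 0/1: %s", col, mapping)
                table[col] = table[col].astype(str).map(mapping)
            else:
                try:
                    table[col] = pd.to_numeric(table[col])
                except (TypeError, ValueError):
                    raise DataFormatError(
                        f"column {col!r} is non-numeric with {len(levels)} levels"
                    ) from None
    before = len(table)
    table = table.dropna()
    dropped = before - len(table)
    if dropped:
        logger.info("dropped %d row(s) with missing trait/covariate values", dropped)
    if not len(table):
        raise DataFormatError(f"no usable rows left in {path}")
    return PhenotypeTable(data=table.astype(float))


def write_phenotype_table(pt: PhenotypeTable, path, id_column: str = "id") -> None:
    out = pt.data.copy()
    out.index.name = id_column
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Scan outputs


def write_results(frame: pd.DataFrame, path) -> None:
    """Write the per-SNP scan table (one row per input SNP, p-values in
    scientific notation, NA for sentinel T on monomorphic SNPs)."""
    cols = ["snp_id", "chrom", "pos", "maf", "n_star", "S", "p_S", "T", "p_T", "flagged"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in frame.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        str(rec.snp_id),
                        str(rec.chrom),
                        str(int(rec.pos)),
                        f"{rec.maf:.6g}",
                        str(int(rec.n_star)),
                        f"{rec.S:.6g}",
                        f"{rec.p_S:.6e}",
                        "NA" if np.isnan(rec.T) else f"{rec.T:.6g}",
                        "NA" if np.isnan(rec.p_T) else f"{rec.p_T:.6e}",
                        "1" if rec.flagged else "0",
                    ]
                )
                + "\n"
            )


def write_null_reference(ref, path) -> None:
    """Persist a null reference as two-column text with a descriptive header."""
    with open(path, "w") as fh:
        fh.write(f"# K={ref.K}\n")
        fh.write(f"# seed={ref.seed}\n")
        fh.write(f"# s_form={ref.s_form}\n")
        fh.write(f"# null_method={ref.null_method}\n")
        fh.write(f"# null_set_size={len(ref.null_snp_ids)}\n")
        fh.write("iteration\tS_value\n")
        np.savetxt(fh, np.column_stack([np.arange(ref.K), ref.null_values]),
                   fmt=("%d", "%.10g"), delimiter="\t")
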