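"""Case-control genotype data: ingestion, validation, and imputation.

The dataset contract consumed by every other module: an ``n_individuals x
m_snps`` matrix of biallelic genotypes coded 0/1/2 (minor-allele counts; the
analysis only needs a three-level categorical, so no allele-orientation logic
is attempted), a binary case/control phenotype, and unique SNP identifiers.
Missing genotypes are carried internally as the sentinel :data:`MISSING` and
must be imputed (modal genotype of the SNP over the pooled population) before
any information-theoretic weight is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "CASE",
    "CONTROL",
    "ValidationError",
    "GenotypeDataset",
    "read_genotypes",
    "write_genotypes",
    "read_plink_raw",
    "impute_missing",
    "class_counts",
]

#: Internal sentinel for a missing genotype call.
MISSING: int = -1
#: Phenotype codes (column order of every genotype-by-class count table).
CONTROL: int = 0
CASE: int = 1

_VALID_GENOTYPES = frozenset({0, 1, 2})
_MISSING_TOKENS = frozenset({"NA", ""})


class ValidationError(ValueError):
    """Raised when input data violates the dataset contract.

    The message names the offending row/column so malformed files can be
    located and fixed.
    """


@dataclass
class GenotypeDataset:
    """Genotype matrix plus binary phenotype for a case-control study.

    Parameters
    ----------
    snp_ids
        Unique identifier per SNP, aligned to the matrix columns.
    genotypes
        ``(n_individuals, m_snps)`` integer matrix with entries in
        ``{0, 1, 2, MISSING}``.
    phenotype
        Length-``n_individuals`` vector; ``1`` = case, ``0`` = control.
    individual_ids
        Optional per-row identifiers (defaults to ``ind0001``...).
    """

    snp_ids: list[str]
    genotypes: np.ndarray
    phenotype: np.ndarray
    individual_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        self.snp_ids = [str(s) for s in self.snp_ids]
        if self.genotypes.ndim != 2:
            raise ValidationError("genotype matrix must be 2-dimensional")
        n, m = self.genotypes.shape
        if m != len(self.snp_ids):
            raise ValidationError(
                f"{len(self.snp_ids)} SNP ids but {m} genotype columns"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            seen: set[str] = set()
            dup = next(s for s in self.snp_ids if s in seen or seen.add(s))
            raise ValidationError(f"duplicate SNP id {dup!r}")
        if self.phenotype.shape != (n,):
            raise ValidationError("phenotype length must equal number of rows")
        if n < 2:
            raise ValidationError("need at least 2 individuals")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid genotype value {int(self.genotypes[r, c])} at "
                f"row {r} (individual {self._row_id(int(r))}), "
                f"column {self.snp_ids[c]!r}"
            )
        if not np.isin(self.phenotype, (CONTROL, CASE)).all():
            r = int(np.argwhere(~np.isin(self.phenotype, (0, 1)))[0][0])
            raise ValidationError(f"phenotype at row {r} is not 0/1")
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValidationError(
                "both phenotype classes must be present "
                f"(cases={self.n_cases}, controls={self.n_controls})"
            )
        if not self.individual_ids:
            self.individual_ids = [f"ind{i + 1:04d}" for i in range(n)]
        elif len(self.individual_ids) != n:
            raise ValidationError("individual_ids length must equal row count")

    def _row_id(self, r: int) -> str:
        return self.individual_ids[r] if self.individual_ids else str(r)

    # -- basic shape accessors ------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == CONTROL).sum())

    @property
    def has_missing(self) -> bool:
        return bool((self.genotypes == MISSING).any())

    def copy(self) -> "GenotypeDataset":
        return replace(
            self,
            genotypes=self.genotypes.copy(),
            phenotype=self.phenotype.copy(),
            snp_ids=list(self.snp_ids),
            individual_ids=list(self.individual_ids),
        )

    def with_phenotype(self, phenotype: np.ndarray) -> "GenotypeDataset":
        """Same genotypes with a replacement phenotype (shares the matrix)."""
        return replace(self, phenotype=np.asarray(phenotype, dtype=np.int8))


def read_genotypes(path: str | Path, dialect: str = "tsv") -> GenotypeDataset:
    """Read a delimited genotype file into a validated dataset.

    Expected layout: header ``ID<sep>STATUS<sep><snp1>...<snpM>``, one row per
    individual. STATUS is 1 (case) or 0 (control); genotype cells are
    ``0``/``1``/``2`` with ``NA`` or an empty cell meaning missing.
    """
    sep = _sep(dialect)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = next((ln for ln in fh if not ln.startswith("#")), "")
    raw_cols = header.rstrip("\n").split(sep)
    if len(set(raw_cols)) != len(raw_cols):
        seen: set[str] = set()
        dup = next(s for s in raw_cols if s in seen or seen.add(s))
        raise ValidationError(f"duplicate SNP id {dup!r} in header")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     comment="#")
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "ID" or cols[1] != "STATUS":
        raise ValidationError(
            f"malformed header in {path.name}: expected 'ID{sep}STATUS"
            f"{sep}<snp ids>', got {cols[:3]}..."
        )
    snp_ids = cols[2:]
    if len(set(snp_ids)) != len(snp_ids):
        seen: set[str] = set()
        dup = next(s for s in snp_ids if s in seen or seen.add(s))
        raise ValidationError(f"duplicate SNP id {dup!r} in header")

    status = df["STATUS"].to_numpy()
    bad_status = ~np.isin(status, ("0", "1"))
    if bad_status.any():
        r = int(np.argwhere(bad_status)[0][0])
        raise ValidationError(
            f"STATUS {status[r]!r} at data row {r + 1} "
            f"(individual {df['ID'].iloc[r]!r}) is not 0/1"
        )
    phenotype = status.astype(np.int8)
    if (phenotype == CASE).all() or (phenotype == CONTROL).all():
        raise ValidationError(
            "single-class phenotype: file contains "
            + ("only cases" if phenotype[0] == CASE else "only controls")
        )

    raw = df[snp_ids].to_numpy()
    geno = np.full(raw.shape, MISSING, dtype=np.int8)
    for tok, val in (("0", 0), ("1", 1), ("2", 2)):
        geno[raw == tok] = val
    unknown = ~np.isin(raw, ("0", "1", "2", "NA", ""))
    if unknown.any():
        r, c = np.argwhere(unknown)[0]
        raise ValidationError(
            f"invalid genotype cell {raw[r, c]!r} at data row {int(r) + 1} "
            f"(individual {df['ID'].iloc[int(r)]!r}), column {snp_ids[c]!r}"
        )
    return GenotypeDataset(
        snp_ids=snp_ids,
        genotypes=geno,
        phenotype=phenotype,
        individual_ids=[str(x) for x in df["ID"]],
    )


def write_genotypes(ds: GenotypeDataset, path: str | Path,
                    dialect: str = "tsv", header_comment: str = "") -> None:
    """Write a dataset in the same delimited dialect ``read_genotypes`` reads."""
    sep = _sep(dialect)
    geno = ds.genotypes.astype(object)
    geno[ds.genotypes == MISSING] = "NA"
    df = pd.DataFrame(geno, columns=ds.snp_ids)
    df.insert(0, "STATUS", ds.phenotype)
    df.insert(0, "ID", ds.individual_ids)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)


def read_plink_raw(path: str | Path) -> GenotypeDataset:
    """Read a PLINK ``--recode A`` additive-coded ``.raw`` file.

    Layout: whitespace-delimited, columns FID IID PAT MAT SEX PHENOTYPE then
    one column per SNP (minor-allele dosage 0/1/2, NA for missing). PHENOTYPE
    uses PLINK's 2 = case, 1 = control convention.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    required = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != required:
        raise ValidationError(
            f"malformed .raw header: expected {required}, "
            f"got {list(df.columns[:6])}"
        )
    snp_ids = list(df.columns[6:])
    pheno_raw = df["PHENOTYPE"].to_numpy()
    bad = ~np.isin(pheno_raw, ("1", "2"))
    if bad.any():
        r = int(np.argwhere(bad)[0][0])
        raise ValidationError(
            f"PHENOTYPE {pheno_raw[r]!r} at data row {r + 1} is not 1/2"
        )
    phenotype = (pheno_raw == "2").astype(np.int8)
    raw = df[snp_ids].to_numpy()
    geno = np.full(raw.shape, MISSING, dtype=np.int8)
    for tok, val in (("0", 0), ("1", 1), ("2", 2)):
        geno[raw == tok] = val
    unknown = ~np.isin(raw, ("0", "1", "2", "NA"))
    if unknown.any():
        r, c = np.argwhere(unknown)[0]
        raise ValidationError(
            f"invalid genotype cell {raw[r, c]!r} at data row {int(r) + 1}, "
            f"column {snp_ids[c]!r}"
        )
    ids = [f"{f}_{i}" for f, i in zip(df["FID"], df["IID"])]
    return GenotypeDataset(snp_ids=snp_ids, genotypes=geno,
                           phenotype=phenotype, individual_ids=ids)


def impute_missing(ds: GenotypeDataset) -> GenotypeDataset:
    """Frequency-based imputation of missing genotypes.

    Each missing entry of a SNP is filled with that SNP's most common genotype
    over the pooled population (cases and controls together). Ties between
    equally common genotypes break toward the lowest genotype code, a fixed
    deterministic rule. Idempotent; all other entries are unchanged.
    """
    if not ds.has_missing:
        return ds
    geno = ds.genotypes.copy()
    for j in np.flatnonzero((geno == MISSING).any(axis=0)):
        col = geno[:, j]
        observed = col[col != MISSING]
        if observed.size == 0:
            raise ValidationError(
                f"SNP {ds.snp_ids[j]!r} has no observed genotypes; "
                "cannot impute an entirely missing column"
            )
        counts = np.bincount(observed, minlength=3)
        mode = int(np.argmax(counts))  # argmax returns lowest index on ties
        col[col == MISSING] = mode
    return replace(ds, genotypes=geno)


def class_counts(ds: GenotypeDataset,
                 snps: int | tuple[int, int]) -> np.ndarray:
    """Exact genotype-by-class contingency counts for one SNP or a pair.

    Returns a ``(3, 2)`` array for a single SNP index or a ``(9, 2)`` array
    for an ordered pair ``(i, j)`` where row ``3*g_i + g_j`` is the joint
    genotype. Column 0 counts controls, column 1 cases. The dataset must be
    imputed first.
    """
    if ds.has_missing:
        raise ValidationError("impute missing genotypes before counting")
    if isinstance(snps, tuple):
        i, j = snps
        _check_index(ds, i)
        _check_index(ds, j)
        codes = 3 * ds.genotypes[:, i].astype(np.intp) + ds.genotypes[:, j]
        k = 9
    else:
        _check_index(ds, snps)
        codes = ds.genotypes[:, snps].astype(np.intp)
        k = 3
    flat = 2 * codes + ds.phenotype
    return np.bincount(flat, minlength=2 * k).reshape(k, 2)


def _check_index(ds: GenotypeDataset, i: int) -> None:
    if not 0 <= i < ds.n_snps:
        raise IndexError(f"SNP index {i} out of range for m={ds.n_snps}")


def _sep(dialect: str) -> str:
    try:
        return {"tsv": "\t", "csv": ","}[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")
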