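"""Tabular formats consumed and produced by the pipeline.

Two dialects are used throughout:

* GWAS summary statistics: tab-separated, UTF-8, '.' decimal, one row per
  SNP, with a canonical header ``snp_id, chrom, pos, effect_allele,
  other_allele, eaf, beta, se, pval, n`` (``chrom``/``pos`` optional).
  Foreign headers can be renamed on read via ``column_map``.
* LD matrices: tab-separated square tables of r-squared values with SNP ids
  as the first row and first column.

Validation is strict: every violated row is reported with its 1-based file
line number, and reading fails rather than silently dropping rows.
"""

from __future__ import annotations

import dataclasses
import enum
import math
import os
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "TraitKind",
    "GwasRecord",
    "SummaryDataset",
    "LdMatrix",
    "read_summary_stats",
    "write_summary_stats",
    "read_ld_matrix",
    "write_ld_matrix",
    "REQUIRED_COLUMNS",
    "VALID_ALLELES",
]

VALID_ALLELES = frozenset("ACGT")

REQUIRED_COLUMNS = (
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)
OPTIONAL_COLUMNS = ("chrom", "pos")
CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)


class FormatError(ValueError):
    """A file does not conform to the expected tabular dialect."""


class ValidationError(ValueError):
    """Well-formed input whose values violate a domain invariant."""


class TraitKind(str, enum.Enum):
    BINARY_EXPOSURE = "binary_exposure"
    CONTINUOUS_EXPOSURE = "continuous_exposure"
    METABOLITE = "metabolite"


@dataclasses.dataclass(frozen=True)
class GwasRecord:
    """One SNP's association with one trait.

    ``beta`` is in trait units per copy of ``effect_allele`` (for
    metabolites: SD units of log concentration).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int
    chrom: str = ""
    pos: int = 0


def _check_row(row: Mapping, allow_missing_eaf: bool) -> list[str]:
    """Return human-readable messages for every invariant the row violates."""
    problems: list[str] = []
    ea = str(row["effect_allele"]).upper()
    oa = str(row["other_allele"]).upper()
    if ea not in VALID_ALLELES:
        problems.append(f"effect_allele {ea!r} not one of A/C/G/T")
    if oa not in VALID_ALLELES:
        problems.append(f"other_allele {oa!r} not one of A/C/G/T")
    if ea == oa:
        problems.append(f"effect_allele equals other_allele ({ea!r})")
    eaf = row["eaf"]
    if eaf is None or (isinstance(eaf, float) and math.isnan(eaf)):
        if not allow_missing_eaf:
            problems.append("eaf is missing")
    elif not 0.0 < float(eaf) < 1.0:
        problems.append(f"eaf {eaf} outside (0, 1)")
    if not float(row["se"]) > 0.0:
        problems.append(f"se {row['se']} not positive")
    if not 0.0 < float(row["pval"]) <= 1.0:
        problems.append(f"pval {row['pval']} outside (0, 1]")
    if not float(row["n"]) > 0:
        problems.append(f"n {row['n']} not positive")
    if math.isnan(float(row["beta"])):
        problems.append("beta is NaN")
    if "pos" in row and not (row["pos"] is None or float(row["pos"]) >= 0):
        problems.append(f"pos {row['pos']} negative")
    return problems


def validate_summary_table(
    table: pd.DataFrame, *, allow_missing_eaf: bool = True, line_offset: int = 2
) -> None:
    """Validate a canonical-header summary table; raise with line numbers.

    ``line_offset`` maps row 0 of the frame to its 1-based file line
    (header on line 1 means data starts at line 2).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    dup = table["snp_id"][table["snp_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            "duplicate snp_id(s): " + ", ".join(sorted(set(dup.astype(str))))
        )
    errors: list[str] = []
    for i, row in enumerate(table.to_dict("records")):
        for msg in _check_row(row, allow_missing_eaf):
            errors.append(f"line {i + line_offset}: {msg}")
    if errors:
        raise ValidationError("; ".join(errors))


@dataclasses.dataclass
class SummaryDataset:
    """An ordered set of GWAS records for one trait, keyed by ``snp_id``.

    ``source`` labels the GWAS sample the records came from (one of the
    four independent metabolite GWAS datasets, or the exposure GWAS).
    """

    trait_name: str
    trait_kind: TraitKind
    table: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        self.trait_kind = TraitKind(self.trait_kind)
        self.table = self.table.reset_index(drop=True)
        for col in ("effect_allele", "other_allele"):
            self.table[col] = self.table[col].astype(str).str.upper()
        validate_summary_table(self.table)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    @property
    def records(self) -> Iterator[GwasRecord]:
        cols = [c for c in CANONICAL_COLUMNS if c in self.table.columns]
        for row in self.table[cols].itertuples(index=False):
            d = row._asdict()
            yield GwasRecord(
                snp_id=str(d["snp_id"]),
                effect_allele=d["effect_allele"],
                other_allele=d["other_allele"],
                eaf=float(d["eaf"]),
                beta=float(d["beta"]),
                se=float(d["se"]),
                pval=float(d["pval"]),
                n=int(d["n"]),
                chrom=str(d.get("chrom", "")),
                pos=int(d.get("pos", 0)),
            )

    def replace_table(self, table: pd.DataFrame) -> "SummaryDataset":
        """A copy of this dataset with a different record table."""
        return SummaryDataset(
            trait_name=self.trait_name,
            trait_kind=self.trait_kind,
            table=table.reset_index(drop=True),
            source=self.source,
        )


def read_summary_stats(
    path: str | os.PathLike,
    trait_kind: TraitKind | str,
    *,
    trait_name: str | None = None,
    source: str = "",
    column_map: Mapping[str, str] | None = None,
) -> SummaryDataset:
    """Read a tab-separated summary-statistics table.

    ``column_map`` renames foreign headers to the canonical ones
    (``{"rsid": "snp_id", ...}``). Scientific notation is accepted for all
    numeric columns.
    """
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"snp_id": str, "chrom": str},
        float_precision="round_trip",
    )
    if column_map:
        table = table.rename(columns=dict(column_map))
    if trait_name is None:
        trait_name = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    return SummaryDataset(
        trait_name=trait_name, trait_kind=TraitKind(trait_kind), table=table, source=source
    )


def write_summary_stats(dataset: SummaryDataset, path: str | os.PathLike) -> None:
    """Write the canonical TSV dialect; full float precision (round-trips)."""
    cols = [c for c in CANONICAL_COLUMNS if c in dataset.table.columns]
    extra = [c for c in dataset.table.columns if c not in cols]
    # 17 significant digits: every IEEE double re-reads bit-exactly
    dataset.table[cols + extra].to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


@dataclasses.dataclass
class LdMatrix:
    """Symmetric r-squared matrix over a set of SNPs, unit diagonal."""

    snp_ids: list[str]
    r2: np.ndarray

    _SYMMETRY_TOL = 1e-8

    def __post_init__(self) -> None:
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.snp_ids)
        if self.r2.shape != (n, n):
            raise FormatError(
                f"LD matrix shape {self.r2.shape} does not match {n} SNP ids"
            )
        if len(set(self.snp_ids)) != n:
            raise ValidationError("duplicate snp_id in LD matrix")
        asym = np.abs(self.r2 - self.r2.T)
        if asym.size and asym.max() > self._SYMMETRY_TOL:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValidationError(
                f"LD matrix asymmetric at ({self.snp_ids[i]}, {self.snp_ids[j]}): "
                f"|{self.r2[i, j]} - {self.r2[j, i]}| > {self._SYMMETRY_TOL}"
            )
        bad = (self.r2 < 0) | (self.r2 > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"r2 entry ({self.snp_ids[i]}, {self.snp_ids[j]}) = "
                f"{self.r2[i, j]} outside [0, 1]"
            )
        if n and np.abs(np.diag(self.r2) - 1.0).max() > self._SYMMETRY_TOL:
            k = int(np.argmax(np.abs(np.diag(self.r2) - 1.0)))
            raise ValidationError(f"diagonal entry for {self.snp_ids[k]} is not 1")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self._index[a], self._index[b]])

    def subset(self, snp_ids: Sequence[str]) -> "LdMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LdMatrix(list(snp_ids), self.r2[np.ix_(idx, idx)])


def read_ld_matrix(path: str | os.PathLike) -> LdMatrix:
    """Read a square r-squared table with SNP ids as first row and column."""
    table = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    rows = [str(s) for s in table.index]
    cols = [str(s) for s in table.columns]
    if rows != cols:
        raise FormatError("LD matrix row and column labels differ")
    return LdMatrix(rows, table.to_numpy(dtype=float))


def write_ld_matrix(ld: LdMatrix, path: str | os.PathLike) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )
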