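"""Selection, filtering, orientation and strength of genetic instruments.

The selection pipeline is applied in a fixed order — genome-wide
significance filter, palindromic-SNP exclusion, greedy LD clumping, and
(for chronotype-style exposures) reorientation to the risk-increasing
allele — because permuting palindrome exclusion and clumping can change
which SNP survives a clump.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .io_formats import LdMatrix, SummaryDataset, ValidationError

__all__ = [
    "InstrumentSet",
    "filter_significant",
    "drop_palindromic",
    "is_palindromic",
    "ld_clump",
    "reorient_to_risk_allele",
    "instrument_strength",
    "select_instruments",
    "GENOME_WIDE_SIGNIFICANCE",
    "CLUMP_R2_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Conventional genome-wide significance threshold for instrument selection.
GENOME_WIDE_SIGNIFICANCE = 5e-8
#: Default linkage-disequilibrium pruning threshold (r-squared).
CLUMP_R2_THRESHOLD = 0.001

_PALINDROMIC_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclasses.dataclass
class InstrumentSet:
    """Instruments surviving selection for one exposure, with F statistics.

    ``total_f`` is the sum of per-SNP F = (beta/se)^2 over the retained
    instruments; large values (hundreds to thousands) indicate that weak
    instrument bias is unlikely to matter.
    """

    exposure_name: str
    dataset: SummaryDataset
    per_snp_f: dict[str, float]
    total_f: float

    def __len__(self) -> int:
        return len(self.dataset)


def filter_significant(
    dataset: SummaryDataset, threshold: float = GENOME_WIDE_SIGNIFICANCE
) -> SummaryDataset:
    """Keep records with ``pval`` strictly below ``threshold``, order preserved."""
    kept = dataset.table[dataset.table["pval"] < threshold]
    return dataset.replace_table(kept)


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True if the allele pair is strand-ambiguous (A/T or C/G)."""
    return {effect_allele.upper(), other_allele.upper()} in _PALINDROMIC_PAIRS


def drop_palindromic(dataset: SummaryDataset) -> SummaryDataset:
    """Remove strand-ambiguous (A/T, C/G) records, logging each removal."""
    mask = dataset.table.apply(
        lambda r: is_palindromic(r["effect_allele"], r["other_allele"]), axis=1
    ) if len(dataset.table) else pd.Series([], dtype=bool)
    for snp, ea, oa in dataset.table.loc[mask, ["snp_id", "effect_allele", "other_allele"]].itertuples(index=False):
        logger.info("dropping palindromic SNP %s (%s/%s)", snp, ea, oa)
    kept = dataset.table[~mask] if len(dataset.table) else dataset.table
    return dataset.replace_table(kept)


def ld_clump(
    dataset: SummaryDataset,
    ld: LdMatrix,
    r2_threshold: float = CLUMP_R2_THRESHOLD,
) -> SummaryDataset:
    """Greedy LD clumping against a supplied r-squared matrix.

    Repeatedly keeps the remaining record with the smallest p-value (ties
    broken by lexicographically smaller ``snp_id`` for determinism) and
    discards every remaining record with r-squared above ``r2_threshold``
    to any kept record. The result is ordered by selection order.
    """
    missing = [s for s in dataset.table["snp_id"] if s not in ld]
    if missing:
        raise ValidationError(
            "snp_id(s) absent from LD matrix: " + ", ".join(missing)
        )
    order = dataset.table.sort_values(
        ["pval", "snp_id"], kind="mergesort"
    ).index.to_list()
    discarded: set[int] = set()
    kept_rows: list[int] = []
    for idx in order:
        if idx in discarded:
            continue
        kept_rows.append(idx)
        snp = dataset.table.at[idx, "snp_id"]
        for jdx in order:
            if jdx == idx or jdx in discarded:
                continue
            if ld.r2_between(snp, dataset.table.at[jdx, "snp_id"]) > r2_threshold:
                discarded.add(jdx)
    return dataset.replace_table(dataset.table.loc[kept_rows])


def reorient_to_risk_allele(dataset: SummaryDataset) -> SummaryDataset:
    """Express every record on its trait-increasing allele.

    Records with negative ``beta`` have their alleles swapped, ``beta``
    negated and ``eaf`` complemented; others are returned unchanged. Used
    for chronotype-style exposures where the index category (evening
    preference) is defined by the direction of effect. Idempotent.
    """
    table = dataset.table.copy()
    flip = table["beta"] < 0
    ea = table.loc[flip, "effect_allele"].copy()
    table.loc[flip, "effect_allele"] = table.loc[flip, "other_allele"].to_numpy()
    table.loc[flip, "other_allele"] = ea.to_numpy()
    table.loc[flip, "beta"] = -table.loc[flip, "beta"]
    table.loc[flip, "eaf"] = 1.0 - table.loc[flip, "eaf"]
    return dataset.replace_table(table)


def instrument_strength(dataset: SummaryDataset) -> tuple[dict[str, float], float]:
    """Per-SNP F statistics (squared z-scores) and their sum.

    F_j = (beta_j / se_j)^2; ``total_f`` = sum over instruments.
    """
    if len(dataset) == 0:
        raise ValidationError("cannot compute instrument strength of an empty dataset")
    z = dataset.table["beta"].to_numpy() / dataset.table["se"].to_numpy()
    f = z**2
    per_snp = dict(zip(dataset.table["snp_id"], map(float, f)))
    return per_snp, float(f.sum())


def select_instruments(
    dataset: SummaryDataset,
    ld: LdMatrix,
    *,
    p_threshold: float = GENOME_WIDE_SIGNIFICANCE,
    r2_threshold: float = CLUMP_R2_THRESHOLD,
    reorient: bool = False,
) -> InstrumentSet:
    """Full selection pipeline: significance → palindrome drop → clump.

    ``reorient`` additionally re-expresses records on the risk-increasing
    allele after clumping (chronotype-style coding).
    """
    n0 = len(dataset)
    ds = filter_significant(dataset, p_threshold)
    logger.info("%s: %d/%d records genome-wide significant", dataset.trait_name, len(ds), n0)
    ds = drop_palindromic(ds)
    ds = ld_clump(ds, ld, r2_threshold)
    logger.info("%s: %d independent non-palindromic instruments", dataset.trait_name, len(ds))
    if reorient:
        ds = reorient_to_risk_allele(ds)
    per_snp_f, total_f = instrument_strength(ds) if len(ds) else ({}, 0.0)
    return InstrumentSet(
        exposure_name=dataset.trait_name,
        dataset=ds,
        per_snp_f=per_snp_f,
        total_f=total_f,
    )


def write_f_statistics(instruments: InstrumentSet, path) -> None:
    """Two-column TSV of per-SNP F values plus a ``total`` row."""
    rows = [{"snp_id": s, "f_stat": f} for s, f in instruments.per_snp_f.items()]
    rows.append({"snp_id": "total", "f_stat": instruments.total_f})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
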