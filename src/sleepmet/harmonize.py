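"""Alignment of exposure and outcome summary statistics to a common allele.

Two-sample MR requires that, for every instrument SNP, the SNP-exposure
and SNP-outcome effects are expressed with respect to the same effect
allele. Outcome records reported on the opposite allele have their beta
negated and allele frequency complemented; records reported on the other
strand are complemented first. Palindromic (A/T, C/G) SNPs are excluded
upstream, so strand resolution is unambiguous here and no frequency-based
inference is needed.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .instruments import InstrumentSet, is_palindromic
from .io_formats import SummaryDataset, ValidationError

__all__ = ["HarmonizedSet", "harmonize", "COMPLEMENT"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Columns of the harmonized per-SNP table.
HARMONIZED_COLUMNS = (
    "snp_id",
    "effect_allele",
    "other_allele",
    "beta_exp",
    "se_exp",
    "beta_out",
    "se_out",
    "eaf_exp",
    "eaf_out",
)


@dataclasses.dataclass
class HarmonizedSet:
    """Exposure/outcome associations aligned to a common effect allele.

    ``dropped`` lists ``(snp_id, reason)`` for every instrument SNP that
    could not be used: ``missing_in_outcome``, ``allele_mismatch``,
    ``palindromic`` or ``position_mismatch``.
    """

    exposure_name: str
    outcome_name: str
    table: pd.DataFrame
    dropped: list[tuple[str, str]] = dataclasses.field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)
        if len(self.table):
            if (self.table["se_exp"] <= 0).any() or (self.table["se_out"] <= 0).any():
                raise ValidationError("harmonized rows must have positive SEs")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_snps(self) -> int:
        return len(self.table)


def _complement_pair(ea: str, oa: str) -> tuple[str, str]:
    return COMPLEMENT[ea], COMPLEMENT[oa]


def harmonize(
    instruments: InstrumentSet,
    outcome: SummaryDataset,
    *,
    strict: bool = False,
) -> HarmonizedSet:
    """Align outcome records to the exposure instruments' effect alleles.

    For each instrument SNP found in the outcome dataset:

    * identical allele pair — kept as-is;
    * swapped alleles — outcome beta negated, outcome eaf complemented;
    * strand complement (or complement of the swap) — resolved as above
      after complementing the outcome alleles;
    * anything else — dropped with reason ``allele_mismatch``.

    ``strict`` additionally requires chrom/pos agreement when both sides
    carry them. Raises if no instrument SNP survives.
    """
    exp = instruments.dataset.table
    if len(exp) == 0:
        raise ValidationError("no instruments supplied to harmonization")
    out_by_snp = {r["snp_id"]: r for r in outcome.table.to_dict("records")}
    check_pos = (
        strict
        and {"chrom", "pos"} <= set(exp.columns)
        and {"chrom", "pos"} <= set(outcome.table.columns)
    )

    rows: list[dict] = []
    dropped: list[tuple[str, str]] = []
    for e in exp.to_dict("records"):
        snp = e["snp_id"]
        ea, oa = e["effect_allele"], e["other_allele"]
        if is_palindromic(ea, oa):
            dropped.append((snp, "palindromic"))
            continue
        o = out_by_snp.get(snp)
        if o is None:
            dropped.append((snp, "missing_in_outcome"))
            continue
        if check_pos and (str(o["chrom"]) != str(e["chrom"]) or int(o["pos"]) != int(e["pos"])):
            dropped.append((snp, "position_mismatch"))
            continue
        o_ea, o_oa = o["effect_allele"], o["other_allele"]
        if (o_ea, o_oa) not in {
            (ea, oa),
            (oa, ea),
            _complement_pair(ea, oa),
            _complement_pair(oa, ea),
        }:
            dropped.append((snp, "allele_mismatch"))
            continue
        # Strand complement first (a no-op for same-strand reports), then
        # decide aligned vs swapped. Unambiguous because palindromes are gone.
        if (o_ea, o_oa) in (_complement_pair(ea, oa), _complement_pair(oa, ea)):
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        if (o_ea, o_oa) == (ea, oa):
            beta_out, eaf_out = o["beta"], o["eaf"]
        else:  # (o_ea, o_oa) == (oa, ea)
            beta_out, eaf_out = -o["beta"], 1.0 - o["eaf"]
        rows.append(
            {
                "snp_id": snp,
                "effect_allele": ea,
                "other_allele": oa,
                "beta_exp": e["beta"],
                "se_exp": e["se"],
                "beta_out": beta_out,
                "se_out": o["se"],
                "eaf_exp": e["eaf"],
                "eaf_out": eaf_out,
            }
        )

    if not rows:
        raise ValidationError(
            f"no usable instruments after harmonizing {instruments.exposure_name} "
            f"with {outcome.trait_name}"
        )
    table = pd.DataFrame(rows, columns=list(HARMONIZED_COLUMNS))
    return HarmonizedSet(
        exposure_name=instruments.exposure_name,
        outcome_name=outcome.trait_name,
        table=table,
        dropped=dropped,
        source=outcome.source,
    )


def write_harmonized(hset: HarmonizedSet, path, dropped_path=None) -> None:
    hset.table.to_csv(path, sep="\t", index=False)
    if dropped_path is not None:
        pd.DataFrame(hset.dropped, columns=["snp_id", "reason"]).to_csv(
            dropped_path, sep="\t", index=False
        )
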