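"""Instrument selection: significance boundary, palindromes, clumping,
orientation and strength."""

import numpy as np
import pandas as pd
import pytest

from sleepmet import (
    LdMatrix,
    SummaryDataset,
    TraitKind,
    ValidationError,
    drop_palindromic,
    filter_significant,
    instrument_strength,
    ld_clump,
    reorient_to_risk_allele,
    select_instruments,
)
from sleepmet.instruments import is_palindromic
from conftest import make_summary_table
from oracles import greedy_clump_oracle


def _dataset(table: pd.DataFrame) -> SummaryDataset:
    return SummaryDataset("exp", TraitKind.BINARY_EXPOSURE, table)


class TestFilterSignificant:
    def test_strict_inequality_boundary(self, rng):
        table = make_summary_table(rng, 3)
        table["pval"] = [1e-9, 1e-7, 4.9e-8]
        kept = filter_significant(_dataset(table))
        assert kept.snp_ids == [table["snp_id"][0], table["snp_id"][2]]

    def test_threshold_itself_excluded(self, rng):
        table = make_summary_table(rng, 1)
        table["pval"] = [5e-8]
        assert len(filter_significant(_dataset(table))) == 0

    def test_empty_dataset_passthrough(self, rng):
        ds = _dataset(make_summary_table(rng, 5))
        empty = filter_significant(ds, threshold=1e-300)
        assert len(empty) == 0
        assert len(filter_significant(empty)) == 0

    def test_matches_brute_force_filter(self, rng):
        table = make_summary_table(rng, 1000)
        table["pval"] = rng.uniform(1e-10, 1e-6, size=1000)
        kept = filter_significant(_dataset(table))
        expected = [r["snp_id"] for r in table.to_dict("records") if r["pval"] < 5e-8]
        assert kept.snp_ids == expected


class TestDropPalindromic:
    @pytest.mark.parametrize(
        "ea, oa, palindromic",
        [("A", "T", True), ("T", "A", True), ("C", "G", True), ("G", "C", True),
         ("A", "G", False), ("G", "A", False), ("C", "T", False), ("A", "C", False)],
    )
    def test_definition(self, ea, oa, palindromic):
        assert is_palindromic(ea, oa) is palindromic

    def test_removes_only_palindromes(self, rng):
        table = make_summary_table(rng, 200)
        ds = drop_palindromic(_dataset(table))
        expected = [
            r["snp_id"]
            for r in table.to_dict("records")
            if {r["effect_allele"], r["other_allele"]} not in ({"A", "T"}, {"C", "G"})
        ]
        assert ds.snp_ids == expected

    def test_no_palindromes_unchanged(self, rng):
        table = make_summary_table(rng, 50, palindromic_ok=False)
        ds = drop_palindromic(_dataset(table))
        pd.testing.assert_frame_equal(ds.table, _dataset(table).table)


def _block_ld(n: int, blocks: list[list[int]], r2_in: float) -> LdMatrix:
    m = np.zeros((n, n))
    for block in blocks:
        for i in block:
            for j in block:
                m[i, j] = r2_in
    np.fill_diagonal(m, 1.0)
    return LdMatrix([f"rs{i}" for i in range(n)], m)


class TestLdClump:
    def test_pairwise_dominance(self, rng):
        table = make_summary_table(rng, 2)
        table["pval"] = [1e-10, 1e-9]
        ld = _block_ld(2, [[0, 1]], 1.0)
        kept = ld_clump(_dataset(table), ld)
        assert kept.snp_ids == [table["snp_id"][0]]

    def test_independent_snps_all_kept(self, rng):
        table = make_summary_table(rng, 5)
        ld = _block_ld(5, [], 0.0)
        assert len(ld_clump(_dataset(table), ld)) == 5

    def test_missing_snp_reported(self, rng):
        table = make_summary_table(rng, 3)
        ld = _block_ld(2, [], 0.0)
        with pytest.raises(ValidationError, match="rs2"):
            ld_clump(_dataset(table), ld)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_greedy_oracle_on_blocks(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        table = make_summary_table(rng, n)
        table["pval"] = rng.uniform(1e-12, 1e-6, size=n)
        blocks = [[0, 1, 2], [3, 4, 5, 6], [7, 8]]
        ld = _block_ld(n, blocks, rng.uniform(0.2, 1.0))
        kept = ld_clump(_dataset(table), ld, r2_threshold=0.001)
        expected = greedy_clump_oracle(
            list(table["snp_id"]),
            list(table["pval"]),
            ld.r2_between,
            0.001,
        )
        assert kept.snp_ids == expected

    def test_pval_ties_break_by_snp_id(self, rng):
        table = make_summary_table(rng, 2)
        table["snp_id"] = ["rsB", "rsA"]
        table["pval"] = [1e-9, 1e-9]
        ld = _block_ld(2, [[0, 1]], 0.9)
        ld = LdMatrix(["rsB", "rsA"], ld.r2)
        kept = ld_clump(_dataset(table), ld)
        assert kept.snp_ids == ["rsA"]


class TestReorient:
    def test_negative_beta_flipped(self, rng):
        table = make_summary_table(rng, 1)
        table.loc[0, ["effect_allele", "other_allele", "beta", "eaf"]] = ["A", "G", -0.02, 0.3]
        out = reorient_to_risk_allele(_dataset(table)).table.iloc[0]
        assert (out["effect_allele"], out["other_allele"]) == ("G", "A")
        assert out["beta"] == pytest.approx(0.02)
        assert out["eaf"] == pytest.approx(0.7)

    def test_idempotent(self, rng):
        ds = _dataset(make_summary_table(rng, 50))
        once = reorient_to_risk_allele(ds)
        twice = reorient_to_risk_allele(once)
        pd.testing.assert_frame_equal(once.table, twice.table)

    def test_all_positive_unchanged(self, rng):
        table = make_summary_table(rng, 20)
        table["beta"] = np.abs(table["beta"])
        ds = _dataset(table)
        pd.testing.assert_frame_equal(reorient_to_risk_allele(ds).table, ds.table)


class TestInstrumentStrength:
    def test_closed_form_single_snp(self, rng):
        table = make_summary_table(rng, 1)
        table.loc[0, ["beta", "se"]] = [2.0, 1.0]
        per_snp, total = instrument_strength(_dataset(table))
        assert total == pytest.approx(4.0)

    def test_sum_of_squared_z(self, rng):
        table = make_summary_table(rng, 2)
        table["beta"] = [0.3, 0.4]
        table["se"] = [0.1, 0.1]
        _, total = instrument_strength(_dataset(table))
        assert total == pytest.approx(25.0)

    def test_matches_independent_zsum(self, rng):
        table = make_summary_table(rng, 100)
        per_snp, total = instrument_strength(_dataset(table))
        expected = sum((b / s) ** 2 for b, s in zip(table["beta"], table["se"]))
        assert total == pytest.approx(expected, rel=1e-12)
        assert per_snp[table["snp_id"][7]] == pytest.approx(
            (table["beta"][7] / table["se"][7]) ** 2, rel=1e-12
        )

    def test_empty_dataset_errors(self, rng):
        ds = _dataset(make_summary_table(rng, 3))
        with pytest.raises(ValidationError):
            instrument_strength(ds.replace_table(ds.table.iloc[:0]))


class TestSelectionOrder:
    def test_pipeline_is_filter_then_palindrome_then_clump(self, rng):
        """The composed selector must equal the fixed-order composition.

        Clumping before palindrome removal could let a palindromic SNP
        shadow (discard) a non-palindromic one that the fixed order keeps,
        so the order is load-bearing and pinned here.
        """
        n = 30
        table = make_summary_table(rng, n)
        table["pval"] = rng.uniform(1e-12, 1e-7, size=n)
        blocks = [list(range(i, min(i + 3, n))) for i in range(0, n, 3)]
        ld = _block_ld(n, blocks, 0.8)
        ds = _dataset(table)
        inst = select_instruments(ds, ld)
        manual = ld_clump(drop_palindromic(filter_significant(ds)), ld)
        assert inst.dataset.snp_ids == manual.snp_ids
        # and every invariant of the selected set holds
        for r in inst.dataset.records:
            assert r.pval < 5e-8
            assert not is_palindromic(r.effect_allele, r.other_allele)
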