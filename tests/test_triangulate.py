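"""Triangulation layer: threshold, effective tests, verdicts, concordance."""

import os

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sleepmet import (
    ArmResult,
    SimConfig,
    ValidationError,
    classify_consistency,
    concordance,
    corrected_threshold,
    effective_tests_from_panel,
    render_outputs,
    simulate_amv_cohorts,
)
from sleepmet.triangulate import rows_to_frame
from oracles import simple_concordance_oracle

THRESH = corrected_threshold(0.05, 17)


class TestCorrectedThreshold:
    def test_published_value_to_two_significant_figures(self):
        assert f"{corrected_threshold(0.05, 17):.2g}" == "0.0029"

    def test_no_correction(self):
        assert corrected_threshold(0.05, 1) == pytest.approx(0.05)

    def test_plain_division(self):
        assert corrected_threshold(0.01, 4) == pytest.approx(0.0025)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1])
    def test_invalid_alpha(self, alpha):
        with pytest.raises(ValidationError):
            corrected_threshold(alpha, 17)


class TestEffectiveTests:
    def test_independent_panel_needs_almost_all_components(self, rng):
        t = 12
        panel = pd.DataFrame(rng.normal(size=(6000, t)))
        m = effective_tests_from_panel(panel, 0.95)
        assert abs(m - t) <= 1

    def test_rank_one_panel_collapses_to_one(self, rng):
        base = rng.normal(size=2000)
        panel = pd.DataFrame({f"m{i}": (i + 1.0) * base for i in range(5)})
        assert effective_tests_from_panel(panel, 0.95) == 1

    def test_synthetic_factor_panel_close_to_factor_count(self):
        """The generator's 17-factor/95% panel round-trips through the
        PCA estimate of effective tests."""
        cfg = SimConfig(seed=21, n_cohorts=1, n_per_cohort=5000)
        panel = simulate_amv_cohorts(cfg)[0][cfg.metabolite_names]
        panel = pd.DataFrame(np.log(panel.to_numpy()), columns=panel.columns)
        m = effective_tests_from_panel(panel, 0.95)
        assert m <= 17 + 2

    def test_zero_variance_column_rejected(self, rng):
        panel = pd.DataFrame({"a": rng.normal(size=100), "b": np.ones(100)})
        with pytest.raises(ValidationError, match="zero-variance"):
            effective_tests_from_panel(panel)


class TestClassifyConsistency:
    def test_citrate_pattern_is_consistent(self):
        """AMV passes the corrected threshold with a negative estimate; MR
        agrees in sign with p < 0.05 (CI excluding zero) -> consistent."""
        row = classify_consistency(
            "citrate",
            ArmResult(-0.08, 0.023, 0.0005),
            ArmResult(-0.03, 0.017, 0.03),
            THRESH,
        )
        assert row.amv_passes and not row.mr_passes
        assert row.verdict == "consistent"

    def test_direction_disagreement_not_consistent(self):
        row = classify_consistency(
            "met", ArmResult(0.2, 0.05, 1e-4), ArmResult(-0.1, 0.04, 0.01), THRESH
        )
        assert row.verdict == "not_consistent"

    def test_neither_arm_selected(self):
        row = classify_consistency(
            "met", ArmResult(0.1, 0.1, 0.5), ArmResult(0.1, 0.1, 0.4), THRESH
        )
        assert row.verdict == "not_selected"

    @pytest.mark.parametrize(
        "amv_p, mr_p, same_sign, expected",
        [
            # grid spanning the 0.0029 and 0.05 boundaries
            (0.001, 0.001, True, "consistent"),      # both pass
            (0.001, 0.001, False, "not_consistent"),  # both pass, signs differ
            (0.001, 0.03, True, "consistent"),        # selection + replication
            (0.001, 0.03, False, "not_consistent"),
            (0.001, 0.06, True, "not_consistent"),    # other arm p >= 0.05
            (0.03, 0.001, True, "consistent"),        # MR selects, AMV replicates
            (0.06, 0.001, True, "not_consistent"),
            (0.0030, 0.5, True, "not_selected"),      # just above 0.05/17
            (0.004, 0.004, True, "not_selected"),
        ],
    )
    def test_verdict_truth_table(self, amv_p, mr_p, same_sign, expected):
        mr_sign = 1.0 if same_sign else -1.0
        row = classify_consistency(
            "met",
            ArmResult(0.1, 0.05, amv_p),
            ArmResult(mr_sign * 0.1, 0.05, mr_p),
            THRESH,
        )
        assert row.verdict == expected

    def test_zero_estimate_never_similar_in_sign(self):
        row = classify_consistency(
            "met", ArmResult(0.1, 0.05, 1e-4), ArmResult(0.0, 0.05, 0.01), THRESH
        )
        assert row.verdict == "not_consistent"

    def test_arms_thresholded_independently(self):
        """Changing one arm's p-value never changes the other arm's flag."""
        a = classify_consistency(
            "met", ArmResult(0.1, 0.05, 0.001), ArmResult(0.1, 0.05, 0.5), THRESH
        )
        b = classify_consistency(
            "met", ArmResult(0.1, 0.05, 0.001), ArmResult(0.1, 0.05, 0.0001), THRESH
        )
        assert a.amv_passes == b.amv_passes is True
        assert a.mr_passes is False and b.mr_passes is True

    @given(
        amv_p=st.floats(1e-6, 1.0),
        mr_p=st.floats(1e-6, 1.0),
        alpha_small=st.floats(0.01, 0.05),
        alpha_big=st.floats(0.05, 0.2),
    )
    def test_verdict_monotone_in_threshold(self, amv_p, mr_p, alpha_small, alpha_big):
        """Raising alpha can only move rows from not_selected towards a
        selected verdict, never the reverse."""
        small = classify_consistency(
            "m", ArmResult(0.1, 0.05, amv_p), ArmResult(0.1, 0.05, mr_p),
            corrected_threshold(alpha_small, 17),
        )
        big = classify_consistency(
            "m", ArmResult(0.1, 0.05, amv_p), ArmResult(0.1, 0.05, mr_p),
            corrected_threshold(alpha_big, 17),
        )
        if small.verdict != "not_selected":
            assert big.verdict != "not_selected"


class TestConcordance:
    def test_perfect_concordance(self, rng):
        x = rng.normal(size=20)
        s = concordance(x, x)
        assert (s.slope, s.intercept, s.r2) == (
            pytest.approx(1.0),
            pytest.approx(0.0, abs=1e-12),
            pytest.approx(1.0),
        )

    def test_sign_reversal(self, rng):
        x = rng.normal(size=20)
        s = concordance(x, -x)
        assert s.slope == pytest.approx(-1.0)
        assert s.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_covariance_oracle(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=30), r.normal(size=30)
        s = concordance(x, y)
        slope, intercept, r2 = simple_concordance_oracle(x, y)
        assert s.slope == pytest.approx(slope, rel=1e-12)
        assert s.intercept == pytest.approx(intercept, rel=1e-12, abs=1e-15)
        assert s.r2 == pytest.approx(r2, rel=1e-12)

    def test_degenerate_amv_vector_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            concordance([0.1, 0.1, 0.1], [0.0, 0.1, 0.2])


class TestRenderOutputs:
    def _rows(self, rng, n):
        return [
            classify_consistency(
                f"met_{i:03d}",
                ArmResult(rng.normal(0, 0.05), 0.02, float(rng.uniform(1e-5, 1))),
                ArmResult(rng.normal(0, 0.05), 0.02, float(rng.uniform(1e-5, 1))),
                THRESH,
            )
            for i in range(n)
        ]

    def test_selected_table_is_exactly_the_passing_rows(self, rng, tmp_path):
        rows = self._rows(rng, 113)
        summary = concordance([r.amv_theta for r in rows], [r.mr_theta for r in rows])
        written = render_outputs(rows, summary, tmp_path, exposure="insomnia",
                                 make_plot=True)
        tri = pd.read_csv(written["triangulation"], sep="\t")
        sel = pd.read_csv(written["selected"], sep="\t")
        assert len(tri) == 113
        assert set(sel["metabolite"]) == {
            r.metabolite for r in rows if r.amv_passes or r.mr_passes
        }
        assert os.path.exists(written["scatter"])

    def test_empty_selection_writes_header_only(self, rng, tmp_path):
        rows = self._rows(rng, 5)
        for r in rows:
            r.amv_passes = r.mr_passes = False
        summary = concordance([r.amv_theta for r in rows], [r.mr_theta for r in rows])
        written = render_outputs(rows, summary, tmp_path, make_plot=False)
        sel = pd.read_csv(written["selected"], sep="\t")
        assert len(sel) == 0

    def test_two_runs_same_rows_byte_identical(self, rng, tmp_path):
        rows = self._rows(rng, 20)
        summary = concordance([r.amv_theta for r in rows], [r.mr_theta for r in rows])
        d1, d2 = tmp_path / "a", tmp_path / "b"
        w1 = render_outputs(rows, summary, d1, make_plot=False)
        w2 = render_outputs(rows, summary, d2, make_plot=False)
        for key in ("triangulation", "selected"):
            assert open(w1[key], "rb").read() == open(w2[key], "rb").read()

    def test_frame_round_trip_of_rows(self, rng):
        rows = self._rows(rng, 7)
        frame = rows_to_frame(rows)
        assert list(frame["metabolite"]) == [r.metabolite for r in rows]
        assert frame["verdict"].isin(
            ["consistent", "not_consistent", "not_selected"]
        ).all()
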