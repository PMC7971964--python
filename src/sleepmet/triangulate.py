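"""Triangulation of observational (AMV) and genetic (MR) evidence.

Both arms estimate the effect of a sleep exposure on each metabolite but
carry different bias structures: residual confounding and reverse
causation for the cross-sectional adjusted regression, horizontal
pleiotropy for MR. An association is *selected* when either arm passes a
Bonferroni threshold corrected for the effective number of independent
metabolomic tests (17 principal components explain ~95% of the panel's
variance, so 0.05/17 ~= 0.0029), treating that arm's result as a
hypothesized effect. The other arm is then *consistent* if its point
estimate has the same sign and its p-value is below 0.05. Agreement
across the whole panel is summarized by the least-squares line of MR
estimates on AMV estimates and its R-squared.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import ValidationError

__all__ = [
    "ArmResult",
    "TriangulationRow",
    "ConcordanceSummary",
    "corrected_threshold",
    "effective_tests_from_panel",
    "classify_consistency",
    "concordance",
    "render_outputs",
    "DEFAULT_EFFECTIVE_TESTS",
]

#: Effective number of independent tests for the 113-trait NMR panel,
#: taken as the number of principal components explaining ~95% of its
#: variance in prior work on the same platform.
DEFAULT_EFFECTIVE_TESTS = 17

VERDICT_CONSISTENT = "consistent"
VERDICT_NOT_CONSISTENT = "not_consistent"
VERDICT_NOT_SELECTED = "not_selected"


@dataclasses.dataclass(frozen=True)
class ArmResult:
    """One arm's (theta, se, pval) for a single metabolite."""

    theta: float
    se: float
    pval: float


@dataclasses.dataclass
class TriangulationRow:
    """Per-metabolite AMV and MR results with threshold flags and verdict."""

    metabolite: str
    amv_theta: float
    amv_se: float
    amv_pval: float
    mr_theta: float
    mr_se: float
    mr_pval: float
    amv_passes: bool
    mr_passes: bool
    verdict: str


@dataclasses.dataclass
class ConcordanceSummary:
    """Least-squares line of MR estimates on AMV estimates, with R^2."""

    slope: float
    intercept: float
    r2: float

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r2 <= 1 + 1e-12:
            raise ValidationError(f"R^2 = {self.r2} outside [0, 1]")
        self.r2 = min(1.0, max(0.0, self.r2))


def corrected_threshold(
    alpha: float = 0.05, effective_tests: int = DEFAULT_EFFECTIVE_TESTS
) -> float:
    """Bonferroni threshold alpha / effective_tests (0.05/17 ~= 0.0029)."""
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha {alpha} outside (0, 1)")
    if effective_tests < 1:
        raise ValidationError("effective_tests must be >= 1")
    return alpha / effective_tests


def effective_tests_from_panel(
    panel: pd.DataFrame, variance_target: float = 0.95
) -> int:
    """Effective test count of a metabolite panel by principal components.

    Returns the smallest number of principal components of the panel's
    correlation matrix whose cumulative explained-variance fraction
    reaches ``variance_target``.
    """
    if panel.shape[1] < 2:
        raise ValidationError("panel needs >= 2 metabolites")
    if panel.shape[0] < panel.shape[1]:
        raise ValidationError("panel needs at least as many rows as metabolites")
    x = panel.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = panel.columns[np.where(sd == 0)[0][0]]
        raise ValidationError(f"zero-variance metabolite column: {bad}")
    corr = np.corrcoef(x, rowvar=False)
    eigvals = np.linalg.eigvalsh(corr)[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    cum = np.cumsum(eigvals) / eigvals.sum()
    return int(np.searchsorted(cum, variance_target - 1e-12) + 1)


def classify_consistency(
    metabolite: str,
    amv: ArmResult | tuple,
    mr: ArmResult | tuple,
    threshold: float,
    secondary_alpha: float = 0.05,
) -> TriangulationRow:
    """Apply the selection-and-replication rule to one metabolite.

    Neither arm below ``threshold`` -> ``not_selected``. Otherwise the
    passing arm's result is the hypothesized effect and the verdict is
    ``consistent`` iff the other arm's estimate has the same (non-zero)
    sign and its p-value is below ``secondary_alpha``. When both arms pass
    the threshold, the rule is symmetric; opposite signs there are classed
    ``not_consistent``.
    """
    amv = ArmResult(*amv) if not isinstance(amv, ArmResult) else amv
    mr = ArmResult(*mr) if not isinstance(mr, ArmResult) else mr
    amv_passes = amv.pval < threshold
    mr_passes = mr.pval < threshold
    same_sign = np.sign(amv.theta) == np.sign(mr.theta) and amv.theta != 0 and mr.theta != 0
    if not (amv_passes or mr_passes):
        verdict = VERDICT_NOT_SELECTED
    elif amv_passes and mr_passes:
        verdict = VERDICT_CONSISTENT if same_sign else VERDICT_NOT_CONSISTENT
    else:
        other_p = mr.pval if amv_passes else amv.pval
        verdict = (
            VERDICT_CONSISTENT
            if same_sign and other_p < secondary_alpha
            else VERDICT_NOT_CONSISTENT
        )
    return TriangulationRow(
        metabolite=metabolite,
        amv_theta=amv.theta,
        amv_se=amv.se,
        amv_pval=amv.pval,
        mr_theta=mr.theta,
        mr_se=mr.se,
        mr_pval=mr.pval,
        amv_passes=bool(amv_passes),
        mr_passes=bool(mr_passes),
        verdict=verdict,
    )


def concordance(
    amv_thetas: Sequence[float], mr_thetas: Sequence[float]
) -> ConcordanceSummary:
    """OLS of MR estimates (response) on AMV estimates (regressor).

    Returns the fitted slope, intercept and R^2 across metabolites; a
    slope of 1 with intercept 0 would indicate perfect concordance.
    """
    x = np.asarray(amv_thetas, float)
    y = np.asarray(mr_thetas, float)
    if x.shape != y.shape:
        raise ValidationError("AMV and MR vectors differ in length")
    if len(x) < 3:
        raise ValidationError("concordance needs >= 3 metabolites")
    if np.all(x == x[0]):
        raise ValidationError("zero variance in AMV estimates")
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    r2 = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return ConcordanceSummary(slope=float(slope), intercept=float(intercept), r2=float(r2))


def rows_to_frame(rows: Sequence[TriangulationRow]) -> pd.DataFrame:
    cols = [
        "metabolite",
        "amv_theta",
        "amv_se",
        "amv_pval",
        "mr_theta",
        "mr_se",
        "mr_pval",
        "amv_passes",
        "mr_passes",
        "verdict",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in rows], columns=cols)


def render_outputs(
    rows: Sequence[TriangulationRow],
    summary: ConcordanceSummary,
    outdir: str | os.PathLike,
    *,
    exposure: str = "exposure",
    sensitivity: pd.DataFrame | None = None,
    make_plot: bool = True,
) -> dict[str, str]:
    """Write the triangulation tables and the concordance scatter plot.

    Produces ``triangulation_<exposure>.tsv`` (all metabolites),
    ``selected_<exposure>.tsv`` (rows passing the corrected threshold in
    either arm, joined with every MR method's estimate when a long-format
    ``sensitivity`` table is supplied), and a scatter of MR on AMV
    estimates with per-point 95% CI bars, the identity line and the
    fitted line annotated with R^2.
    """
    if not rows:
        raise ValidationError("no triangulation rows to render")
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    written: dict[str, str] = {}

    frame = rows_to_frame(rows)
    tri_path = os.path.join(outdir, f"triangulation_{exposure}.tsv")
    frame.to_csv(tri_path, sep="\t", index=False, float_format="%.17g")
    written["triangulation"] = tri_path

    selected = frame[frame["amv_passes"] | frame["mr_passes"]]
    if sensitivity is not None and len(selected):
        extra = sensitivity.pivot_table(
            index="outcome", columns="method", values=["theta", "se", "pval"],
            aggfunc="first",
        )
        extra.columns = [f"{m}_{v}" for v, m in extra.columns]
        selected = selected.join(extra, on="metabolite")
    sel_path = os.path.join(outdir, f"selected_{exposure}.tsv")
    selected.to_csv(sel_path, sep="\t", index=False, float_format="%.17g")
    written["selected"] = sel_path

    if make_plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5.5, 5.5))
        ax.errorbar(
            frame["amv_theta"],
            frame["mr_theta"],
            xerr=1.96 * frame["amv_se"],
            yerr=1.96 * frame["mr_se"],
            fmt="o",
            ms=3,
            lw=0.6,
            alpha=0.6,
            color="#3465a4",
        )
        lims = np.array(ax.get_xlim())
        ax.plot(lims, lims, color="grey", ls=":", lw=1, label="slope 1 (perfect concordance)")
        ax.plot(
            lims,
            summary.intercept + summary.slope * lims,
            color="crimson",
            ls="--",
            lw=1.2,
            label=f"fit: slope {summary.slope:.2f}, $R^2$ = {summary.r2:.2f}",
        )
        ax.set_xlabel("AMV estimate (SD per exposure unit)")
        ax.set_ylabel("MR (IVW) estimate (SD per exposure unit)")
        ax.set_title(f"AMV vs MR concordance: {exposure}")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        plot_path = os.path.join(outdir, f"scatter_{exposure}.png")
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
        written["scatter"] = plot_path

    return written
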