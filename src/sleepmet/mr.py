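"""Two-sample Mendelian-randomization estimators and diagnostics.

Given per-SNP exposure and outcome associations aligned to a common effect
allele, four estimators of the causal effect theta are provided:

* Wald ratio — single-SNP degenerate case, beta_out / beta_exp.
* IVW with multiplicative random effects — weighted least squares of
  beta_out on beta_exp through the origin with weights 1/se_out^2; the
  fixed-effect SE is inflated by max(1, sqrt(Q/(J-1))) so between-SNP
  heterogeneity widens, and never narrows, the confidence interval. This
  is the primary estimator.
* MR-Egger — the same regression with a free intercept; a non-zero
  intercept indicates directional horizontal pleiotropy and the slope is a
  pleiotropy-adjusted estimate. Inference uses the t distribution with
  J - 2 degrees of freedom.
* Weighted median — the median of per-SNP Wald ratios under first-order
  inverse-variance weights w_j = beta_exp_j^2 / se_out_j^2; consistent
  when more than half of the total weight comes from valid instruments.
  Its SE comes from a seeded parametric bootstrap.

Between-SNP heterogeneity is summarized by Cochran's Q with a chi-square
reference (J - 1 df for IVW, J - 2 for Egger).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet
from .io_formats import ValidationError

__all__ = [
    "MrEstimate",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "run_all_methods",
    "MIN_SNPS",
]

Z_95 = float(stats.norm.ppf(0.975))

#: Minimum instrument count per method.
MIN_SNPS = {"wald_ratio": 1, "ivw_mre": 2, "weighted_median": 2, "egger": 3}


@dataclasses.dataclass
class MrEstimate:
    """A causal-effect estimate with its uncertainty and diagnostics.

    ``theta`` is in SD units of log metabolite per exposure unit. Q-based
    heterogeneity fields are populated for IVW and Egger; the intercept
    fields only for Egger.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    exposure: str = ""
    outcome: str = ""
    source: str = ""
    primary: bool = False
    q_stat: float | None = None
    q_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError(f"{self.method}: SE must be positive")
        if not self.ci_low <= self.theta <= self.ci_high:
            raise ValidationError(f"{self.method}: CI does not bracket theta")


def _labels(hset: HarmonizedSet) -> dict:
    return {
        "exposure": hset.exposure_name,
        "outcome": hset.outcome_name,
        "source": hset.source,
    }


def _arrays(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    t = hset.table
    return (
        t["beta_exp"].to_numpy(float),
        t["se_exp"].to_numpy(float),
        t["beta_out"].to_numpy(float),
        t["se_out"].to_numpy(float),
    )


def wald_ratio(row: Mapping | "object") -> MrEstimate:
    """Single-SNP causal estimate beta_out / beta_exp.

    ``row`` is one harmonized row (mapping or attribute access). The SE is
    the first-order delta-method value se_out / |beta_exp|.
    """
    get = row.__getitem__ if hasattr(row, "__getitem__") else lambda k: getattr(row, k)
    beta_exp, beta_out, se_out = (float(get(k)) for k in ("beta_exp", "beta_out", "se_out"))
    if beta_exp == 0:
        raise ValidationError("wald_ratio undefined for beta_exp = 0")
    theta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    p = 2.0 * stats.norm.sf(abs(theta / se))
    return MrEstimate(
        method="wald_ratio",
        theta=theta,
        se=se,
        ci_low=theta - Z_95 * se,
        ci_high=theta + Z_95 * se,
        pval=float(p),
        n_snps=1,
    )


def ivw(hset: HarmonizedSet) -> MrEstimate:
    """Multiplicative random-effects inverse-variance-weighted estimate.

    Weighted least squares of beta_out on beta_exp through the origin with
    weights 1/se_out^2. Cochran's Q = sum_j w_j (theta_j - theta)^2 over
    per-SNP Wald ratios with w_j = beta_exp_j^2/se_out_j^2; the SE is the
    fixed-effect SE times max(1, sqrt(Q/(J-1))). Normal inference.
    """
    bx, _, by, sy = _arrays(hset)
    j = len(bx)
    if j < 2:
        raise ValidationError("IVW requires >= 2 SNPs; use wald_ratio for one SNP")
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    theta = float(np.sum(w * bx * by)) / denom
    se_fixed = denom**-0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    phi = max(1.0, np.sqrt(q / (j - 1)))
    se = se_fixed * phi
    p = 2.0 * stats.norm.sf(abs(theta / se))
    return MrEstimate(
        method="ivw_mre",
        theta=theta,
        se=se,
        ci_low=theta - Z_95 * se,
        ci_high=theta + Z_95 * se,
        pval=float(p),
        n_snps=j,
        q_stat=q,
        q_pval=float(stats.chi2.sf(q, j - 1)),
        primary=True,
        **_labels(hset),
    )


def egger(hset: HarmonizedSet) -> MrEstimate:
    """MR-Egger regression: free-intercept WLS of beta_out on beta_exp.

    Rows are first reoriented so every beta_exp is non-negative (both
    betas negated where needed), which makes the intercept interpretable
    as the average directional pleiotropic effect. SEs are inflated by
    max(1, sqrt(Q/(J-2))); slope and intercept p-values use t(J-2).
    """
    bx, _, by, sy = _arrays(hset)
    j = len(bx)
    if j < 3:
        raise ValidationError("MR-Egger requires >= 3 SNPs")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    if np.allclose(bx, bx[0]):
        raise ValidationError("MR-Egger slope unidentifiable: all beta_exp identical")
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    intercept, slope = float(coef[0]), float(coef[1])
    resid = by - x @ coef
    q = float(np.sum(w * resid**2))
    phi = max(1.0, np.sqrt(q / (j - 2)))
    cov_unscaled = np.linalg.inv(xtwx)
    se_int = float(np.sqrt(cov_unscaled[0, 0])) * phi
    se_slope = float(np.sqrt(cov_unscaled[1, 1])) * phi
    tq = float(stats.t.ppf(0.975, j - 2))
    p_slope = 2.0 * stats.t.sf(abs(slope / se_slope), j - 2)
    p_int = 2.0 * stats.t.sf(abs(intercept / se_int), j - 2)
    return MrEstimate(
        method="egger",
        theta=slope,
        se=se_slope,
        ci_low=slope - tq * se_slope,
        ci_high=slope + tq * se_slope,
        pval=float(p_slope),
        n_snps=j,
        q_stat=q,
        q_pval=float(stats.chi2.sf(q, j - 2)),
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_pval=float(p_int),
        **_labels(hset),
    )


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by interpolation over cumulative-weight midpoints.

    Ratios are sorted; the standardized cumulative weight midpoint of the
    j-th sorted ratio is p_j = (S_j - w_j/2) / S_J, and the estimate is
    the linear interpolation of ratio over p at p = 0.5.
    """
    order = np.argsort(ratios, kind="stable")
    r = np.asarray(ratios, float)[order]
    w = np.asarray(weights, float)[order]
    s = np.cumsum(w)
    p = (s - w / 2.0) / s[-1]
    return float(np.interp(0.5, p, r))


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int = 0
) -> MrEstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Per-SNP Wald ratios are weighted by w_j = beta_exp_j^2 / se_out_j^2
    (the inverse of the first-order ratio variance). The SE is the
    standard deviation of the estimate over ``n_boot`` draws in which
    beta_exp and beta_out are resampled from normal laws at their reported
    SEs. Normal CI and p-value.
    """
    bx, sx, by, sy = _arrays(hset)
    j = len(bx)
    if j < 2:
        raise ValidationError("weighted median requires >= 2 SNPs")
    if np.any(bx == 0):
        raise ValidationError("weighted median undefined when any beta_exp = 0")
    weights = bx**2 / sy**2
    theta = weighted_median_point(by / bx, weights)

    rng = np.random.default_rng(seed)
    bx_star = rng.normal(bx, sx, size=(n_boot, j))
    by_star = rng.normal(by, sy, size=(n_boot, j))
    boot = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx_star[b]
        bxb = np.where(bxb == 0, np.finfo(float).tiny, bxb)
        boot[b] = weighted_median_point(by_star[b] / bxb, bxb**2 / sy**2)
    se = float(np.std(boot, ddof=1))
    if se == 0:  # degenerate bootstrap (e.g. zero SEs in a toy input)
        se = np.finfo(float).tiny
    p = 2.0 * stats.norm.sf(abs(theta / se))
    return MrEstimate(
        method="weighted_median",
        theta=theta,
        se=se,
        ci_low=theta - Z_95 * se,
        ci_high=theta + Z_95 * se,
        pval=float(p),
        n_snps=j,
        **_labels(hset),
    )


def run_all_methods(
    hset: HarmonizedSet, seed: int = 0, n_boot: int = 1000
) -> list[MrEstimate]:
    """Every estimator whose minimum SNP count is met; IVW flagged primary.

    One SNP yields the Wald ratio alone; two SNPs add IVW and the weighted
    median (and drop the Wald ratio); three or more add MR-Egger.
    """
    j = hset.n_snps
    if j < 1:
        raise ValidationError("no SNPs to estimate from")
    if j == 1:
        est = wald_ratio(hset.table.iloc[0])
        est.exposure, est.outcome, est.source = (
            hset.exposure_name,
            hset.outcome_name,
            hset.source,
        )
        est.primary = True
        return [est]
    out = [ivw(hset)]
    if j >= 3:
        try:
            out.append(egger(hset))
        except ValidationError:
            pass  # slope unidentifiable (constant beta_exp); IVW/WM still valid
    out.append(weighted_median(hset, n_boot=n_boot, seed=seed))
    return out


def estimates_to_frame(estimates: Sequence[MrEstimate]):
    """Long-format table of estimates (one row per method)."""
    import pandas as pd

    cols = [
        "exposure",
        "outcome",
        "source",
        "method",
        "theta",
        "se",
        "ci_low",
        "ci_high",
        "pval",
        "n_snps",
        "q_stat",
        "q_pval",
        "egger_intercept",
        "egger_intercept_se",
        "egger_intercept_pval",
    ]
    return pd.DataFrame(
        [{c: getattr(e, c) for c in cols} for e in estimates], columns=cols
    )
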