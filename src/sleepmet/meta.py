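"""Inverse-variance meta-analysis across independent units.

Used twice in the pipeline: fixed-effect pooling of per-dataset MR
estimates across the four independent metabolite GWAS sources, and
fixed- plus random-effects (DerSimonian-Laird) pooling of per-cohort
adjusted-regression coefficients across the ten observational cohorts.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import ValidationError

__all__ = ["MetaEstimate", "fixed_effect_meta", "random_effect_meta"]

Z_95 = float(stats.norm.ppf(0.975))


@dataclasses.dataclass
class MetaEstimate:
    """Pooled estimate over k independent units.

    ``het_q`` is Cochran's Q over the input estimates with chi-square(k-1)
    reference; ``tau2`` is the DerSimonian-Laird between-unit variance
    (random-effects model only, zero under the fixed model).
    """

    pooled_theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    model: str
    het_q: float
    het_q_pval: float
    tau2: float
    k: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValidationError("meta-analysis SE must be positive")
        if self.tau2 < 0 or self.het_q < 0:
            raise ValidationError("tau2 and Q must be non-negative")
        if not self.ci_low <= self.pooled_theta <= self.ci_high:
            raise ValidationError("CI does not bracket pooled estimate")


def _unpack(estimates: Sequence) -> tuple[np.ndarray, np.ndarray]:
    if len(estimates) == 0:
        raise ValidationError("cannot meta-analyse an empty list")
    theta = np.array([float(e[0]) for e in estimates])
    se = np.array([float(e[1]) for e in estimates])
    if np.any(se <= 0):
        raise ValidationError("all input SEs must be positive")
    return theta, se


def fixed_effect_meta(estimates: Sequence[tuple[float, float]]) -> MetaEstimate:
    """Fixed-effect inverse-variance pooling of (theta, se) pairs.

    Weights 1/se^2; pooled = sum(w*theta)/sum(w); se = 1/sqrt(sum(w));
    Cochran's Q with chi-square(k-1) p-value (NaN for k = 1).
    """
    theta, se = _unpack(estimates)
    w = 1.0 / se**2
    pooled = float(np.sum(w * theta) / np.sum(w))
    se_pooled = float(np.sum(w)) ** -0.5
    q = float(np.sum(w * (theta - pooled) ** 2))
    k = len(theta)
    q_pval = float(stats.chi2.sf(q, k - 1)) if k > 1 else float("nan")
    p = 2.0 * stats.norm.sf(abs(pooled / se_pooled))
    return MetaEstimate(
        pooled_theta=pooled,
        se=se_pooled,
        ci_low=pooled - Z_95 * se_pooled,
        ci_high=pooled + Z_95 * se_pooled,
        pval=float(p),
        model="fixed",
        het_q=q,
        het_q_pval=q_pval,
        tau2=0.0,
        k=k,
    )


def random_effect_meta(estimates: Sequence[tuple[float, float]]) -> MetaEstimate:
    """DerSimonian-Laird random-effects pooling of (theta, se) pairs.

    tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w))) with
    fixed-effect weights w = 1/se^2, then re-weighted pooling with
    1/(se^2 + tau^2). Homogeneous inputs (Q <= k-1) reduce exactly to the
    fixed-effect result.
    """
    theta, se = _unpack(estimates)
    k = len(theta)
    if k < 2:
        raise ValidationError("random-effects meta-analysis requires k >= 2")
    w = 1.0 / se**2
    fixed_pooled = float(np.sum(w * theta) / np.sum(w))
    q = float(np.sum(w * (theta - fixed_pooled) ** 2))
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - (k - 1)) / c) if c > 0 else 0.0
    w_star = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_star * theta) / np.sum(w_star))
    se_pooled = float(np.sum(w_star)) ** -0.5
    p = 2.0 * stats.norm.sf(abs(pooled / se_pooled))
    return MetaEstimate(
        pooled_theta=pooled,
        se=se_pooled,
        ci_low=pooled - Z_95 * se_pooled,
        ci_high=pooled + Z_95 * se_pooled,
        pval=float(p),
        model="random_dl",
        het_q=q,
        het_q_pval=float(stats.chi2.sf(q, k - 1)),
        tau2=tau2,
        k=k,
    )
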