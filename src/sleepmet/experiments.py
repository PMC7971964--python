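"""Replicate simulation studies that characterize the pipeline.

These drivers run the full machinery — generator, instrument selection,
harmonization, estimators, meta-analysis — over many seeded replicates
and summarize estimator behaviour: bias and coverage under a known causal
effect, type-I error under the null, and the response of IVW, MR-Egger
and the weighted median to directional pleiotropy. They back both the
statistical test suite and the reproduction script.

Replicate sizes are desk-scale: instrument strength is set so the total
F-statistic lands in the published range (thousands), which is what
governs weak-instrument bias, while sample sizes stay small enough that
hundreds of replicates run in minutes on one CPU.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .harmonize import harmonize
from .instruments import InstrumentSet, instrument_strength, select_instruments
from .io_formats import SummaryDataset
from .meta import fixed_effect_meta
from .mr import egger, ivw, weighted_median
from .synthetic import SimConfig, simulate_two_sample_gwas

__all__ = [
    "derive_seed",
    "ivw_recovery_study",
    "ivw_type_i_error_study",
    "pleiotropy_sensitivity_study",
]


def derive_seed(seed: int, rep: int) -> int:
    """Deterministic per-replicate seed below 2^31."""
    return (1_000_003 * seed + 7_919 * rep + 13) % (2**31)


def _recovery_config(seed: int, theta: float) -> SimConfig:
    """Fifty clean, equally strong, independent instruments.

    h2 and n give per-SNP F ~ 140 (total ~7,000, the published order of
    magnitude), so weak-instrument attenuation is negligible against the
    bias tolerance.
    """
    return SimConfig(
        seed=seed,
        n_snps=50,
        block_size=1,
        exclude_palindromic_alleles=True,
        equal_gamma=True,
        instrument_h2=0.25,
        n_exposure_gwas=50_000,
        outcome_gwas_sizes=(24_925, 6_616, 4_734, 2_343),
        outcome_gwas_names=("d1", "d2", "d3", "d4"),
        n_metabolites=1,
        theta=[theta],
        pleiotropy_mode="none",
        pleiotropy_scale=0.0,
    )


def ivw_recovery_study(
    n_reps: int = 200, seed: int = 0, theta: float = 0.5
) -> dict[str, float]:
    """Bias and 95% CI coverage of the meta-analysed IVW estimate.

    Each replicate simulates a two-sample study with 50 valid instruments
    and no pleiotropy, runs the full selection pipeline, estimates IVW per
    outcome dataset, and pools the four estimates by fixed-effect
    meta-analysis. Bias is measured against the standardized-scale truth.
    """
    estimates = np.empty(n_reps)
    covered = np.empty(n_reps, dtype=bool)
    truths = np.empty(n_reps)
    total_f = np.empty(n_reps)
    for rep in range(n_reps):
        cfg = _recovery_config(derive_seed(seed, rep), theta)
        exposure, outcomes, ld, truth = simulate_two_sample_gwas(cfg)
        inst = select_instruments(exposure, ld)
        per_dataset = [ivw(harmonize(inst, ds)) for ds in outcomes]
        pooled = fixed_effect_meta([(e.theta, e.se) for e in per_dataset])
        estimates[rep] = pooled.pooled_theta
        target = float(truth.theta_sd[0])
        truths[rep] = target
        covered[rep] = pooled.ci_low <= target <= pooled.ci_high
        total_f[rep] = inst.total_f
    bias = estimates - truths
    return {
        "n_reps": n_reps,
        "theta": theta,
        "mean_theta_sd": float(truths.mean()),
        "mean_bias": float(bias.mean()),
        "mc_se_bias": float(bias.std(ddof=1) / np.sqrt(n_reps)),
        "coverage": float(covered.mean()),
        "mc_se_coverage": float(np.sqrt(0.95 * 0.05 / n_reps)),
        "mean_total_f": float(total_f.mean()),
        "n_instruments": 50,
    }


def ivw_type_i_error_study(n_reps: int = 500, seed: int = 0) -> dict[str, float]:
    """Rejection rate of the IVW 0.05-level test under theta = 0.

    Uses the generator's analytic fast path (summary estimates drawn from
    their asymptotic laws), appropriate for a large-n calibration check.
    """
    rejections = np.empty(n_reps, dtype=bool)
    for rep in range(n_reps):
        cfg = dataclasses.replace(
            _recovery_config(derive_seed(seed, rep), 0.0),
            analytic=True,
            n_exposure_gwas=50_000,
            outcome_gwas_sizes=(24_925,),
            outcome_gwas_names=("d1",),
        )
        exposure, outcomes, ld, _ = simulate_two_sample_gwas(cfg)
        inst = select_instruments(exposure, ld)
        est = ivw(harmonize(inst, outcomes[0]))
        rejections[rep] = est.pval < 0.05
    return {
        "n_reps": n_reps,
        "rejection_rate": float(rejections.mean()),
        "mc_se": float(np.sqrt(0.05 * 0.95 / n_reps)),
    }


def _pleiotropy_config(seed: int, theta: float) -> SimConfig:
    """Ten oriented instruments, four carrying directional pleiotropy.

    Valid SNPs hold > 50% of the weight on average, the weighted median's
    validity condition.
    """
    return SimConfig(
        seed=seed,
        n_snps=10,
        block_size=1,
        exclude_palindromic_alleles=True,
        gamma_positive=True,
        instrument_h2=0.15,
        n_exposure_gwas=20_000,
        outcome_gwas_sizes=(20_000,),
        outcome_gwas_names=("d1",),
        n_metabolites=1,
        theta=[theta],
        pleiotropy_mode="directional",
        pleiotropy_scale=0.1,
        pleiotropy_frac=0.4,
    )


def pleiotropy_sensitivity_study(
    n_reps: int = 200, seed: int = 0, theta: float = 0.3, n_boot: int = 200
) -> dict[str, float]:
    """IVW vs MR-Egger vs weighted median under directional pleiotropy.

    All ten instruments are harmonized directly (selection is not under
    test) and each estimator runs per replicate. Reported: mean Egger
    intercept, and the absolute bias of the IVW and weighted-median mean
    estimates against the standardized-scale truth.
    """
    ivw_est = np.empty(n_reps)
    wm_est = np.empty(n_reps)
    intercepts = np.empty(n_reps)
    truths = np.empty(n_reps)
    for rep in range(n_reps):
        cfg = _pleiotropy_config(derive_seed(seed, rep), theta)
        exposure, outcomes, _, truth = simulate_two_sample_gwas(cfg)
        per_snp_f, total_f = instrument_strength(exposure)
        inst = InstrumentSet(cfg.exposure_name, exposure, per_snp_f, total_f)
        hset = harmonize(inst, outcomes[0])
        ivw_est[rep] = ivw(hset).theta
        wm_est[rep] = weighted_median(
            hset, n_boot=n_boot, seed=derive_seed(seed + 1, rep)
        ).theta
        intercepts[rep] = egger(hset).egger_intercept
        truths[rep] = float(truth.theta_sd[0])
    target = float(truths.mean())
    return {
        "n_reps": n_reps,
        "theta_sd": target,
        "mean_egger_intercept": float(intercepts.mean()),
        "mc_se_intercept": float(intercepts.std(ddof=1) / np.sqrt(n_reps)),
        "ivw_mean": float(ivw_est.mean()),
        "wm_mean": float(wm_est.mean()),
        "ivw_abs_bias": float(abs(ivw_est.mean() - target)),
        "wm_abs_bias": float(abs(wm_est.mean() - target)),
        "mc_se_ivw": float(ivw_est.std(ddof=1) / np.sqrt(n_reps)),
        "mc_se_wm": float(wm_est.std(ddof=1) / np.sqrt(n_reps)),
    }
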