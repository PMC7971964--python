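"""Synthetic study generator: genotypes, sleep exposures, metabolites.

Everything the pipeline consumes can be generated from one explicit truth
record and a seed: two non-overlapping GWAS samples (exposure and
outcome), an LD matrix, and per-cohort observational tables.

Model
-----
* Genotypes are biallelic dosages at candidate instrument SNPs arranged in
  independent LD blocks; within a block, haplotypes are exchangeably
  correlated so that the dosage r-squared equals ``within_block_r2``.
* The sleep exposure follows a liability model: a standard-normal
  liability is the sum of a genetic component (variance ``instrument_h2``),
  a shared confounder U, age/sex/BMI effects, and residual noise. Binary
  exposures (insomnia-like: "usually" vs the rest) threshold the liability
  at the configured prevalence; continuous exposures map it to hours of
  sleep (mean 7.2, SD 1.1).
* Each of the 113 metabolites (log scale) is theta_t * exposure plus
  direct (pleiotropic) SNP effects, confounder and covariate effects, and
  correlated noise carried by ``n_factors`` latent factors holding
  ``factor_variance_target`` of the noise variance — mimicking an NMR
  panel in which ~17 components explain ~95% of total variance.
* Summary statistics are obtained by actually regressing phenotype on
  genotype SNP-by-SNP in each sample (binary exposures on the observed
  0/1 scale, metabolites standardized to SD units after log), so SEs,
  heterogeneity and weak-instrument behaviour emerge naturally. An
  analytic fast path instead draws estimates from their asymptotic laws
  for large-n property checks.

All randomness flows from ``SimConfig.seed`` through named sub-streams,
so adding one component never perturbs another's draws, and the same
config is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import os
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import LdMatrix, SummaryDataset, TraitKind

__all__ = [
    "CovariateEffects",
    "SimConfig",
    "SimTruth",
    "ConfigError",
    "simulate_two_sample_gwas",
    "simulate_amv_cohorts",
    "write_simulation",
]


class ConfigError(ValueError):
    """An invalid simulation configuration."""


_STREAMS = {
    "truth": 0,
    "exposure_sample": 1,
    "outcome_sample": 2,
    "cohort": 3,
    "analytic": 4,
}

_NONPALINDROMIC_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and {a, b} not in ({"A", "T"}, {"C", "G"})
]
_ALL_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]

#: Default per-metabolite causal effects: a handful of modest named
#: signals of both signs (SD units); the generator adds a diffuse
#: N(0, 0.025) background on top when no explicit theta is configured,
#: giving the sparse-hits-plus-partial-concordance regime the field
#: reports for sleep traits and NMR panels.
_DEFAULT_THETA_PATTERN = (0.06, -0.05, 0.08, -0.04, 0.05, -0.06)
_DEFAULT_THETA_BACKGROUND_SD = 0.025


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream], *extra))
    )


@dataclasses.dataclass(frozen=True)
class CovariateEffects:
    """Standardized-scale effects of (age, sex, BMI) on exposure liability
    and on every metabolite."""

    on_exposure: tuple[float, float, float] = (0.1, 0.05, 0.15)
    on_metabolites: tuple[float, float, float] = (0.05, 0.1, 0.2)


@dataclasses.dataclass
class SimConfig:
    """Explicit truth and sizes for one simulated study.

    Defaults mirror the study conditions the pipeline targets: 113
    metabolites with a 17-factor / 95%-variance correlation structure,
    four independent outcome GWAS samples with the published dataset
    sizes, ten observational cohorts totalling ~17k participants, and an
    insomnia-like binary exposure (prevalence 0.28). The exposure GWAS is
    run at a desk-scale n with ``instrument_h2`` sized so the total
    F-statistic lands in the published range (hundreds to ~14,000).
    """

    seed: int = 0
    # genome
    n_snps: int = 80
    block_size: int = 2
    within_block_r2: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    exclude_palindromic_alleles: bool = False
    # samples
    n_exposure_gwas: int = 20_000
    outcome_gwas_sizes: tuple[int, ...] = (24_925, 6_616, 4_734, 2_343)
    outcome_gwas_names: tuple[str, ...] = (
        "nmr_gwas_1",
        "nmr_gwas_2",
        "nmr_gwas_3",
        "nmr_gwas_4",
    )
    n_cohorts: int = 10
    n_per_cohort: int = 1_737
    # exposure model
    exposure_kind: str = "binary_liability"  # or "continuous_hours"
    exposure_name: str = "insomnia"
    exposure_prevalence: float = 0.28
    duration_mean: float = 7.2
    duration_sd: float = 1.1
    instrument_h2: float = 0.2
    equal_gamma: bool = False
    gamma_positive: bool = False  # orient every instrument exposure-increasing
    # outcome model
    n_metabolites: int = 113
    theta: np.ndarray | Sequence[float] | float | None = None
    pleiotropy_mode: str = "none"  # none | balanced | directional
    pleiotropy_scale: float = 0.0
    pleiotropy_frac: float = 0.3
    n_factors: int = 17
    factor_variance_target: float = 0.95
    # confounding: U loads on every metabolite with its own sign and
    # magnitude (scale u_on_metabolites), so residual confounding in the
    # observational arm varies across the panel as it does in real data
    u_on_exposure: float = 0.25
    u_on_metabolites: float = 0.05
    covariate_effects: CovariateEffects = dataclasses.field(
        default_factory=CovariateEffects
    )
    # output scale
    unit_variance_metabolites: bool = True
    noise_sd: float = 1.0  # residual SD when unit_variance_metabolites=False
    emit_concentrations: bool = True  # cohort tables on the natural scale
    # estimation path
    analytic: bool = False

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_metabolites < 1:
            raise ConfigError("n_snps and n_metabolites must be positive")
        if self.n_exposure_gwas < 10 or any(n < 10 for n in self.outcome_gwas_sizes):
            raise ConfigError("GWAS sample sizes must be positive (>= 10)")
        if len(self.outcome_gwas_sizes) != len(self.outcome_gwas_names):
            raise ConfigError("outcome_gwas_sizes and names differ in length")
        if self.n_cohorts < 1 or self.n_per_cohort < 10:
            raise ConfigError("cohort sizes must be positive (n_per_cohort >= 10)")
        if not 0.0 < self.exposure_prevalence < 1.0:
            raise ConfigError("exposure_prevalence must lie in (0, 1)")
        if not 0.0 <= self.factor_variance_target < 1.0:
            raise ConfigError("factor_variance_target must lie in [0, 1)")
        if self.exposure_kind not in ("binary_liability", "continuous_hours"):
            raise ConfigError(f"unknown exposure_kind {self.exposure_kind!r}")
        if self.pleiotropy_mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if min(self.instrument_h2, self.pleiotropy_scale, self.u_on_exposure**2) < 0:
            raise ConfigError("variance parameters must be non-negative")
        if not 0.0 <= self.within_block_r2 < 1.0:
            raise ConfigError("within_block_r2 must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi < 1.0:
            raise ConfigError("maf_range must satisfy 0 < lo <= hi < 1")
        c = self.covariate_effects
        lia_var = (
            self.instrument_h2
            + self.u_on_exposure**2
            + float(np.sum(np.square(c.on_exposure)))
        )
        if lia_var >= 1.0:
            raise ConfigError(
                f"exposure liability variance budget exceeded ({lia_var:.3f} >= 1)"
            )

    def theta_vector(self) -> np.ndarray:
        """Per-metabolite causal effects as a length-T array."""
        t = self.n_metabolites
        if self.theta is None:
            out = np.zeros(t)
            k = min(len(_DEFAULT_THETA_PATTERN), t)
            out[:k] = _DEFAULT_THETA_PATTERN[:k]
            return out
        if np.isscalar(self.theta):
            return np.full(t, float(self.theta))
        arr = np.asarray(self.theta, dtype=float)
        if arr.shape != (t,):
            raise ConfigError(f"theta must have length {t}, got {arr.shape}")
        return arr

    @property
    def metabolite_names(self) -> list[str]:
        return [f"met_{i + 1:03d}" for i in range(self.n_metabolites)]


@dataclasses.dataclass
class SimTruth:
    """The realized generative parameters, sufficient to score estimators.

    ``theta_sd`` is the causal effect on the *standardized* metabolite
    scale — theta divided by the population SD of the metabolite, which
    departs from 1 through exposure-confounder/covariate cross
    covariances. It is the estimand any SD-unit estimator targets.
    """

    snp_ids: list[str]
    chrom: list[str]
    pos: np.ndarray
    effect_allele: list[str]
    other_allele: list[str]
    maf: np.ndarray
    block_id: np.ndarray
    gamma: np.ndarray  # per-SNP effect on exposure liability
    alpha: np.ndarray  # J x T direct (pleiotropic) effects on metabolites
    theta: np.ndarray  # T causal effects, metabolite log-SD per exposure unit
    theta_sd: np.ndarray  # T causal effects on the standardized scale
    valid_instrument: np.ndarray  # J bool: no pleiotropic path
    loadings: np.ndarray  # T x n_factors unit-row factor loadings
    u_load: np.ndarray  # T per-metabolite confounder loadings
    liability_threshold: float
    metabolite_names: list[str]


# ---------------------------------------------------------------------------
# truth


def _draw_truth(config: SimConfig) -> SimTruth:
    rng = _rng(config.seed, "truth")
    j, t = config.n_snps, config.n_metabolites
    n_blocks = -(-j // config.block_size)
    block_id = np.repeat(np.arange(n_blocks), config.block_size)[:j]
    maf_block = rng.uniform(*config.maf_range, size=n_blocks)
    maf = maf_block[block_id]

    pairs = (
        _NONPALINDROMIC_PAIRS if config.exclude_palindromic_alleles else _ALL_PAIRS
    )
    pick = rng.integers(0, len(pairs), size=j)
    effect_allele = [pairs[k][0] for k in pick]
    other_allele = [pairs[k][1] for k in pick]

    var_g = 2.0 * maf * (1.0 - maf)
    if config.instrument_h2 > 0:
        raw = (
            rng.choice([-1.0, 1.0], size=j)
            if config.equal_gamma
            else rng.normal(size=j)
        )
        if config.gamma_positive:
            raw = np.abs(raw)
        gamma = raw * np.sqrt(config.instrument_h2 / np.sum(var_g * raw**2))
    else:
        gamma = np.zeros(j)
        rng.normal(size=j)  # keep stream alignment with the h2 > 0 branch

    theta = config.theta_vector()
    if config.theta is None:
        # diffuse background of small true effects on top of the named
        # signals; drawn here so it is part of the explicit truth record
        theta = theta + _DEFAULT_THETA_BACKGROUND_SD * rng.normal(size=t)

    alpha = np.zeros((j, t))
    n_pleio = int(round(config.pleiotropy_frac * j))
    pleio_idx = rng.choice(j, size=n_pleio, replace=False) if n_pleio else np.array([], int)
    if config.pleiotropy_mode != "none" and config.pleiotropy_scale > 0 and n_pleio:
        s = config.pleiotropy_scale
        if config.pleiotropy_mode == "balanced":
            alpha[pleio_idx, :] = rng.normal(0.0, s, size=(n_pleio, t))
        else:  # directional: mean alpha > 0
            alpha[pleio_idx, :] = rng.normal(s, s / 2.0, size=(n_pleio, t))
    valid = ~np.any(alpha != 0.0, axis=1)

    raw_load = rng.normal(size=(t, config.n_factors))
    loadings = raw_load / np.linalg.norm(raw_load, axis=1, keepdims=True)

    u_load = config.u_on_metabolites * rng.normal(size=t)

    c = float(stats.norm.ppf(1.0 - config.exposure_prevalence))

    # Estimand on the standardized metabolite scale. Cross covariances of
    # the observed exposure with U, covariates and pleiotropic SNPs push
    # the metabolite's population variance away from 1; theta_sd absorbs
    # that. (phi(c) is the liability->observed attenuation for binary
    # exposures; sex is treated as approximately normal here, an error of
    # order its cubed loading.)
    if config.unit_variance_metabolites:
        if config.exposure_kind == "binary_liability":
            lam = float(stats.norm.pdf(c))
        else:
            lam = config.duration_sd
        cov_xu = lam * config.u_on_exposure
        cov_xc = lam * np.asarray(config.covariate_effects.on_exposure)
        cov_xg = lam * gamma * var_g  # per-SNP cov(X, g_j)
        cross = (
            u_load * cov_xu
            + float(np.dot(config.covariate_effects.on_metabolites, cov_xc))
            + alpha.T @ cov_xg  # length T
        )
        var_t = 1.0 + 2.0 * theta * cross
        theta_sd = theta / np.sqrt(var_t)
    else:
        theta_sd = theta.copy()

    return SimTruth(
        snp_ids=[f"rs{1000 + i}" for i in range(j)],
        chrom=[str(1 + int(b) % 22) for b in block_id],
        pos=np.asarray(1_000_000 + 50_000 * np.arange(j)),
        effect_allele=effect_allele,
        other_allele=other_allele,
        maf=maf,
        block_id=block_id,
        gamma=gamma,
        alpha=alpha,
        theta=theta,
        theta_sd=theta_sd,
        valid_instrument=valid,
        loadings=loadings,
        u_load=u_load,
        liability_threshold=c,
        metabolite_names=config.metabolite_names,
    )


# ---------------------------------------------------------------------------
# individual-level machinery


def _genotypes(config: SimConfig, truth: SimTruth, n: int, rng: np.random.Generator) -> np.ndarray:
    """Dosage matrix (n x J) with exchangeable within-block LD.

    Each haplotype allele copies a block-common uniform with probability
    lambda = within_block_r2 ** (1/4), giving dosage r^2 equal to the
    target within blocks and zero between blocks.
    """
    j = config.n_snps
    lam = config.within_block_r2**0.25 if config.block_size > 1 else 0.0
    g = np.zeros((n, j), dtype=np.float64)
    n_blocks = int(truth.block_id.max()) + 1
    for _ in range(2):  # two haplotypes
        w = rng.random((n, j))
        if lam > 0:
            u_block = rng.random((n, n_blocks))
            use_common = rng.random((n, j)) < lam
            v = np.where(use_common, u_block[:, truth.block_id], w)
        else:
            v = w
        g += (v < truth.maf[None, :]).astype(np.float64)
    return g


def _covariates(n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Raw and standardized age/sex/BMI draws for one sample."""
    age_z = rng.normal(size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    bmi_z = rng.normal(size=n)
    return {
        "age": 55.0 + 10.0 * age_z,
        "sex": sex,
        "BMI": 26.5 + 4.0 * bmi_z,
        "age_z": age_z,
        "sex_c": 2.0 * (sex - 0.5),
        "bmi_z": bmi_z,
    }


def _exposure(
    config: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator,
    n: int,
    g: np.ndarray | None,
    cov: dict[str, np.ndarray],
    u: np.ndarray,
) -> np.ndarray:
    """Observed exposure (0/1 or hours) from the liability model.

    Without genotypes (observational cohorts) the genetic variance is
    replaced by extra residual noise so the liability stays standard
    normal and the prevalence is preserved.
    """
    ce = config.covariate_effects.on_exposure
    lia = (
        config.u_on_exposure * u
        + ce[0] * cov["age_z"]
        + ce[1] * cov["sex_c"]
        + ce[2] * cov["bmi_z"]
    )
    explained = config.u_on_exposure**2 + float(np.sum(np.square(ce)))
    if g is not None:
        lia = lia + (g - 2.0 * truth.maf[None, :]) @ truth.gamma
        explained += config.instrument_h2
    resid_sd = np.sqrt(max(0.0, 1.0 - explained))
    lia = lia + resid_sd * rng.normal(size=n)
    if config.exposure_kind == "binary_liability":
        return (lia > truth.liability_threshold).astype(float)
    return config.duration_mean + config.duration_sd * lia


def _metabolites(
    config: SimConfig,
    truth: SimTruth,
    rng: np.random.Generator,
    x: np.ndarray,
    g: np.ndarray | None,
    cov: dict[str, np.ndarray],
    u: np.ndarray,
) -> np.ndarray:
    """Log-scale metabolite matrix (n x T), population variance ~1 each."""
    n = len(x)
    t = config.n_metabolites
    theta = truth.theta
    cm = config.covariate_effects.on_metabolites
    var_x = (
        config.exposure_prevalence * (1.0 - config.exposure_prevalence)
        if config.exposure_kind == "binary_liability"
        else config.duration_sd**2
    )
    var_g = 2.0 * truth.maf * (1.0 - truth.maf)
    genetic_var = var_g @ truth.alpha**2  # length T; zero without pleiotropy
    explained = (
        theta**2 * var_x
        + genetic_var
        + truth.u_load**2
        + float(np.sum(np.square(cm)))
    )
    if config.unit_variance_metabolites:
        if np.any(explained >= 1.0):
            k = int(np.argmax(explained))
            raise ConfigError(
                f"metabolite variance budget exceeded for {truth.metabolite_names[k]} "
                f"({explained[k]:.3f} >= 1)"
            )
        noise_var = 1.0 - explained
    else:
        noise_var = np.full(t, config.noise_sd**2)

    y = np.outer(x, theta)
    if g is not None:
        y += (g - 2.0 * truth.maf[None, :]) @ truth.alpha
    y += np.outer(u, truth.u_load)
    y += np.outer(cov["age_z"], np.full(t, cm[0]))
    y += np.outer(cov["sex_c"], np.full(t, cm[1]))
    y += np.outer(cov["bmi_z"], np.full(t, cm[2]))

    fvt = config.factor_variance_target
    factors = rng.normal(size=(n, config.n_factors))
    y += (factors @ truth.loadings.T) * np.sqrt(fvt * noise_var)[None, :]
    y += rng.normal(size=(n, t)) * np.sqrt((1.0 - fvt) * noise_var)[None, :]
    return y


def _gwas_scan(
    g: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP simple linear regressions of every column of y on every SNP.

    Returns (beta, se, pval), each J x T, with two-sided p from t(n-2).
    """
    n = g.shape[0]
    gc = g - g.mean(axis=0, keepdims=True)
    yc = y - y.mean(axis=0, keepdims=True)
    sxx = np.sum(gc**2, axis=0)  # J
    if np.any(sxx == 0):
        raise ConfigError("monomorphic SNP in simulated sample; increase n or maf")
    syy = np.sum(yc**2, axis=0)  # T
    beta = (gc.T @ yc) / sxx[:, None]  # J x T
    sse = np.maximum(syy[None, :] - beta**2 * sxx[:, None], 0.0)
    se = np.sqrt(sse / (n - 2) / sxx[:, None])
    se = np.maximum(se, np.finfo(float).tiny)
    tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    return beta, se, np.maximum(pval, np.finfo(float).tiny)


def _summary_table(
    truth: SimTruth, beta: np.ndarray, se: np.ndarray, pval: np.ndarray,
    eaf: np.ndarray, n: int,
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": truth.snp_ids,
            "chrom": truth.chrom,
            "pos": truth.pos,
            "effect_allele": truth.effect_allele,
            "other_allele": truth.other_allele,
            "eaf": np.clip(eaf, 1e-6, 1 - 1e-6),
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )


# ---------------------------------------------------------------------------
# public generators


def _ld_matrix(config: SimConfig, truth: SimTruth) -> LdMatrix:
    same_block = truth.block_id[:, None] == truth.block_id[None, :]
    r2 = np.where(same_block, config.within_block_r2, 0.0)
    np.fill_diagonal(r2, 1.0)
    return LdMatrix(list(truth.snp_ids), r2)


def _exposure_scale_factor(config: SimConfig) -> float:
    """Liability -> observed-scale slope for the analytic path."""
    if config.exposure_kind == "binary_liability":
        return float(stats.norm.pdf(stats.norm.ppf(1.0 - config.exposure_prevalence)))
    return config.duration_sd


def _analytic_exposure(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    rng = _rng(config.seed, "analytic", 0)
    lam = _exposure_scale_factor(config)
    var_x = (
        config.exposure_prevalence * (1.0 - config.exposure_prevalence)
        if config.exposure_kind == "binary_liability"
        else config.duration_sd**2
    )
    var_g = 2.0 * truth.maf * (1.0 - truth.maf)
    b_true = lam * truth.gamma
    se = np.sqrt(var_x / (config.n_exposure_gwas * var_g))
    beta = rng.normal(b_true, se)
    pval = np.maximum(2.0 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny)
    return _summary_table(truth, beta, se, pval, truth.maf, config.n_exposure_gwas)


def _analytic_outcomes(
    config: SimConfig, truth: SimTruth
) -> list[SummaryDataset]:
    lam = _exposure_scale_factor(config)
    b_obs = lam * truth.gamma
    var_g = 2.0 * truth.maf * (1.0 - truth.maf)
    # 1/sd_t on the standardized scale; sd_t = theta_t/theta_sd_t, and 1
    # where theta_t = 0 (the cross-covariance terms vanish there).
    inv_sd = np.where(
        truth.theta != 0.0,
        truth.theta_sd / np.where(truth.theta == 0.0, 1.0, truth.theta),
        1.0,
    )
    out: list[SummaryDataset] = []
    for k, (name, n_out) in enumerate(
        zip(config.outcome_gwas_names, config.outcome_gwas_sizes)
    ):
        rng = _rng(config.seed, "analytic", 1, k)
        se = np.sqrt(1.0 / (n_out * var_g))
        for t_idx, met in enumerate(truth.metabolite_names):
            b_true = truth.theta_sd[t_idx] * b_obs + truth.alpha[:, t_idx] * inv_sd[t_idx]
            beta = rng.normal(b_true, se)
            pval = np.maximum(
                2.0 * stats.norm.sf(np.abs(beta / se)), np.finfo(float).tiny
            )
            out.append(
                SummaryDataset(
                    trait_name=met,
                    trait_kind=TraitKind.METABOLITE,
                    table=_summary_table(truth, beta, se, pval, truth.maf, n_out),
                    source=name,
                )
            )
    return out


def simulate_two_sample_gwas(
    config: SimConfig,
) -> tuple[SummaryDataset, list[SummaryDataset], LdMatrix, SimTruth]:
    """Generate non-overlapping exposure and outcome GWAS summary data.

    Returns the exposure dataset, a flat list of metabolite datasets
    (grouped by outcome GWAS source, ``source`` attribute set), the LD
    matrix of the simulated block structure, and the truth record. The
    exposure and every outcome sample are drawn independently (no sample
    overlap, as in a clean two-sample design).
    """
    truth = _draw_truth(config)
    ld = _ld_matrix(config, truth)

    if config.analytic:
        exp_table = _analytic_exposure(config, truth)
        exposure = SummaryDataset(
            trait_name=config.exposure_name,
            trait_kind=(
                TraitKind.BINARY_EXPOSURE
                if config.exposure_kind == "binary_liability"
                else TraitKind.CONTINUOUS_EXPOSURE
            ),
            table=exp_table,
            source="exposure_gwas",
        )
        return exposure, _analytic_outcomes(config, truth), ld, truth

    # exposure sample
    rng_a = _rng(config.seed, "exposure_sample")
    n_a = config.n_exposure_gwas
    g_a = _genotypes(config, truth, n_a, rng_a)
    cov_a = _covariates(n_a, rng_a)
    u_a = rng_a.normal(size=n_a)
    x_a = _exposure(config, truth, rng_a, n_a, g_a, cov_a, u_a)
    beta, se, pval = _gwas_scan(g_a, x_a[:, None])
    exposure = SummaryDataset(
        trait_name=config.exposure_name,
        trait_kind=(
            TraitKind.BINARY_EXPOSURE
            if config.exposure_kind == "binary_liability"
            else TraitKind.CONTINUOUS_EXPOSURE
        ),
        table=_summary_table(
            truth, beta[:, 0], se[:, 0], pval[:, 0], g_a.mean(axis=0) / 2.0, n_a
        ),
        source="exposure_gwas",
    )

    # outcome samples, each independent of the exposure sample and of
    # one another
    outcomes: list[SummaryDataset] = []
    for k, (name, n_b) in enumerate(
        zip(config.outcome_gwas_names, config.outcome_gwas_sizes)
    ):
        rng_b = _rng(config.seed, "outcome_sample", k)
        g_b = _genotypes(config, truth, n_b, rng_b)
        cov_b = _covariates(n_b, rng_b)
        u_b = rng_b.normal(size=n_b)
        x_b = _exposure(config, truth, rng_b, n_b, g_b, cov_b, u_b)
        y_b = _metabolites(config, truth, rng_b, x_b, g_b, cov_b, u_b)
        if config.unit_variance_metabolites:
            y_b = (y_b - y_b.mean(axis=0)) / y_b.std(axis=0, ddof=1)
        beta, se, pval = _gwas_scan(g_b, y_b)
        eaf_b = g_b.mean(axis=0) / 2.0
        for t_idx, met in enumerate(truth.metabolite_names):
            outcomes.append(
                SummaryDataset(
                    trait_name=met,
                    trait_kind=TraitKind.METABOLITE,
                    table=_summary_table(
                        truth, beta[:, t_idx], se[:, t_idx], pval[:, t_idx], eaf_b, n_b
                    ),
                    source=name,
                )
            )
    return exposure, outcomes, ld, truth


def simulate_amv_cohorts(config: SimConfig) -> list[pd.DataFrame]:
    """Per-cohort observational tables for the adjusted-regression arm.

    Each table has one row per participant with columns
    ``<exposure_name>, met_001..met_T, age, sex, BMI``. Metabolites are
    emitted as natural-scale concentrations (exp of the log value) when
    ``emit_concentrations`` is set, so the regression arm exercises its
    own log-transform and standardization; cohorts share the truth but
    have independent noise. Diabetes-like exclusions are assumed done
    upstream: tables are clean and complete.
    """
    truth = _draw_truth(config)
    tables: list[pd.DataFrame] = []
    for i in range(config.n_cohorts):
        rng = _rng(config.seed, "cohort", i)
        n = config.n_per_cohort
        cov = _covariates(n, rng)
        u = rng.normal(size=n)
        x = _exposure(config, truth, rng, n, None, cov, u)
        y = _metabolites(config, truth, rng, x, None, cov, u)
        if config.emit_concentrations:
            y = np.exp(y)
        table = pd.DataFrame(y, columns=truth.metabolite_names)
        table.insert(0, config.exposure_name, x)
        table["age"] = cov["age"]
        table["sex"] = cov["sex"]
        table["BMI"] = cov["BMI"]
        tables.append(table)
    return tables


# ---------------------------------------------------------------------------
# file emission


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["covariate_effects"] = {
        "on_exposure": list(config.covariate_effects.on_exposure),
        "on_metabolites": list(config.covariate_effects.on_metabolites),
    }
    if d["theta"] is not None:
        d["theta"] = np.asarray(config.theta_vector()).tolist()
    for key in ("outcome_gwas_sizes", "outcome_gwas_names", "maf_range"):
        d[key] = list(d[key])
    return d


def write_simulation(
    config: SimConfig,
    outdir: str | os.PathLike,
    *,
    exposure: SummaryDataset,
    outcomes: list[SummaryDataset],
    ld: LdMatrix,
    truth: SimTruth,
    cohorts: list[pd.DataFrame] | None = None,
) -> dict[str, object]:
    """Write a simulated study to disk in the pipeline's TSV dialects.

    Returns a manifest fragment mapping logical inputs to paths.
    """
    import yaml

    from .io_formats import write_ld_matrix, write_summary_stats

    outdir = os.fspath(outdir)
    os.makedirs(os.path.join(outdir, "outcomes"), exist_ok=True)
    paths: dict[str, object] = {}

    exp_path = os.path.join(outdir, f"{exposure.trait_name}.tsv")
    write_summary_stats(exposure, exp_path)
    paths["exposure"] = exp_path

    out_paths = []
    for ds in outcomes:
        p = os.path.join(outdir, "outcomes", f"{ds.source}__{ds.trait_name}.tsv")
        write_summary_stats(ds, p)
        out_paths.append(p)
    paths["outcomes"] = out_paths

    ld_path = os.path.join(outdir, "ld_matrix.tsv")
    write_ld_matrix(ld, ld_path)
    paths["ld_matrix"] = ld_path

    if cohorts is not None:
        os.makedirs(os.path.join(outdir, "cohorts"), exist_ok=True)
        cohort_paths = []
        for i, table in enumerate(cohorts):
            p = os.path.join(outdir, "cohorts", f"cohort_{i + 1:02d}.tsv")
            table.to_csv(p, sep="\t", index=False)
            cohort_paths.append(p)
        paths["cohorts"] = cohort_paths

    snp_truth = pd.DataFrame(
        {
            "snp_id": truth.snp_ids,
            "maf": truth.maf,
            "gamma": truth.gamma,
            "valid_instrument": truth.valid_instrument,
            "mean_alpha": truth.alpha.mean(axis=1),
        }
    )
    p = os.path.join(outdir, "truth_snps.tsv")
    snp_truth.to_csv(p, sep="\t", index=False)
    paths["truth_snps"] = p

    met_truth = pd.DataFrame(
        {
            "metabolite": truth.metabolite_names,
            "theta": truth.theta,
            "theta_sd": truth.theta_sd,
        }
    )
    p = os.path.join(outdir, "truth_metabolites.tsv")
    met_truth.to_csv(p, sep="\t", index=False)
    paths["truth_metabolites"] = p

    p = os.path.join(outdir, "sim_config.yaml")
    with open(p, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
    paths["sim_config"] = p
    return paths
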