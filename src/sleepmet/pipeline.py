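"""End-to-end orchestration: simulate/load → select → harmonize →
estimate → meta-analyse → observational arm → triangulate.

A run is driven by one :class:`RunConfig` (optionally read from YAML),
writes every intermediate artifact as TSV under a single run directory,
and records a manifest (config echo, seed, per-stage counts, versions)
for reproducibility. Identical config + seed yields byte-identical result
tables.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import os
from typing import Sequence

import pandas as pd

from . import __version__
from .amv import (
    assocs_to_frame,
    fit_cohort,
    meta_cohorts,
    prepare_metabolites,
)
from .harmonize import harmonize
from .instruments import select_instruments, write_f_statistics
from .io_formats import (
    LdMatrix,
    SummaryDataset,
    TraitKind,
    ValidationError,
    read_ld_matrix,
    read_summary_stats,
    write_summary_stats,
)
from .meta import fixed_effect_meta
from .mr import estimates_to_frame, run_all_methods
from .synthetic import (
    SimConfig,
    config_to_dict,
    simulate_amv_cohorts,
    simulate_two_sample_gwas,
    write_simulation,
)
from .triangulate import (
    ArmResult,
    classify_consistency,
    concordance,
    corrected_threshold,
    render_outputs,
    rows_to_frame,
)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage label."""


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either ``sim`` is set (all inputs generated) or the four path groups
    are: ``exposure_path``, ``outcome_paths``, ``ld_path`` and
    ``cohort_paths``. Analysis parameters default to the published
    choices: genome-wide significance 5e-8, clumping r^2 0.001, Bonferroni
    alpha 0.05 over 17 effective tests.
    """

    outdir: str = "sleepmet_run"
    sim: SimConfig | None = None
    exposure_path: str | None = None
    exposure_kind: str = "binary_exposure"
    outcome_paths: Sequence[str] = ()
    ld_path: str | None = None
    cohort_paths: Sequence[str] = ()
    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    alpha: float = 0.05
    effective_tests: int = 17
    n_boot: int = 1000
    reorient: bool = False
    seed: int | None = None
    write_inputs: bool = False
    make_plots: bool = True
    resume: bool = False

    def __post_init__(self) -> None:
        if self.sim is None and self.exposure_path is None:
            raise ValidationError(
                "RunConfig needs either a simulate block or input paths"
            )
        if self.sim is not None and self.seed is None:
            self.seed = self.sim.seed
        if self.seed is None:
            raise ValidationError("seed is mandatory whenever stochastic steps run")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_block = raw.pop("simulate", None)
        if sim_block is not None:
            from .synthetic import CovariateEffects

            ce = sim_block.pop("covariate_effects", None)
            if ce is not None:
                sim_block["covariate_effects"] = CovariateEffects(
                    on_exposure=tuple(ce.get("on_exposure", (0.1, 0.05, 0.15))),
                    on_metabolites=tuple(ce.get("on_metabolites", (0.05, 0.1, 0.2))),
                )
            for key in ("outcome_gwas_sizes", "outcome_gwas_names", "maf_range"):
                if key in sim_block:
                    sim_block[key] = tuple(sim_block[key])
            raw["sim"] = SimConfig(**sim_block)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)


def _wm_seed(base_seed: int, index: int) -> int:
    return (base_seed * 1_000_003 + 7919 * index + 1) % (2**31)


def _stage(name: str):
    """Decorator-free stage guard: wrap exceptions with the stage label."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def _load_or(path: str, resume: bool, compute):
    """Resume support: reload a completed stage's table instead of recomputing."""
    if resume and os.path.exists(path):
        logger.info("resume: loading %s", path)
        return pd.read_csv(path, sep="\t", float_precision="round_trip")
    frame = compute()
    # 17 significant digits so a resumed run reloads bit-exact values
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return frame


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in fixed order; returns the run manifest.

    Stage order: simulate/load → significance filter → palindrome drop →
    LD clump → (reorientation if configured) → harmonize per outcome
    dataset → MR per dataset → fixed-effect meta across datasets → AMV
    per cohort → meta across cohorts → triangulation.
    """
    outdir = os.fspath(config.outdir)
    os.makedirs(outdir, exist_ok=True)
    log_path = os.path.join(outdir, "run.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("sleepmet")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "counts": {},
        "outputs": {},
    }
    try:
        # ------------------------------------------------------------ inputs
        with _stage("inputs"):
            if config.sim is not None:
                exposure, outcomes, ld, truth = simulate_two_sample_gwas(config.sim)
                cohorts = simulate_amv_cohorts(config.sim)
                cohort_names = [f"cohort_{i + 1:02d}" for i in range(len(cohorts))]
                metabolite_cols = truth.metabolite_names
                exposure_col = config.sim.exposure_name
                log_metabolites = config.sim.emit_concentrations
                manifest["sim_config"] = config_to_dict(config.sim)
                if config.write_inputs:
                    manifest["inputs"] = write_simulation(
                        config.sim,
                        os.path.join(outdir, "inputs"),
                        exposure=exposure,
                        outcomes=outcomes,
                        ld=ld,
                        truth=truth,
                        cohorts=cohorts,
                    )
            else:
                exposure = read_summary_stats(
                    config.exposure_path, TraitKind(config.exposure_kind)
                )
                # outcome files follow the "<source>__<trait>.tsv" convention
                # write_simulation emits; a bare name means a single source
                outcomes = []
                for p in config.outcome_paths:
                    stem = os.path.splitext(os.path.basename(p))[0]
                    source, _, trait = stem.rpartition("__")
                    outcomes.append(
                        read_summary_stats(
                            p,
                            TraitKind.METABOLITE,
                            trait_name=trait or stem,
                            source=source,
                        )
                    )
                if not outcomes:
                    raise ValidationError("no outcome summary-statistics paths given")
                if config.ld_path is None:
                    raise ValidationError("LD matrix path required when clumping")
                ld = read_ld_matrix(config.ld_path)
                cohorts = [pd.read_csv(p, sep="\t") for p in config.cohort_paths]
                cohort_names = [
                    os.path.splitext(os.path.basename(p))[0] for p in config.cohort_paths
                ]
                exposure_col = exposure.trait_name
                metabolite_cols = sorted({ds.trait_name for ds in outcomes})
                log_metabolites = True

        # -------------------------------------------------------- instruments
        with _stage("instruments"):
            instruments = select_instruments(
                exposure,
                ld,
                p_threshold=config.p_threshold,
                r2_threshold=config.clump_r2,
                reorient=config.reorient,
            )
            if len(instruments) == 0:
                raise ValidationError("no instruments survive selection")
            write_summary_stats(
                instruments.dataset, os.path.join(outdir, "instruments.tsv")
            )
            write_f_statistics(instruments, os.path.join(outdir, "f_statistics.tsv"))
            manifest["counts"]["snps_in_exposure_gwas"] = len(exposure)
            manifest["counts"]["instruments_selected"] = len(instruments)
            manifest["counts"]["total_f"] = instruments.total_f

        # ------------------------------------------------- harmonize + MR
        with _stage("mr"):
            mr_path = os.path.join(outdir, "mr_estimates.tsv")

            def _compute_mr() -> pd.DataFrame:
                frames = []
                dropped_counts: dict[str, int] = {}
                for idx, ds in enumerate(outcomes):
                    hset = harmonize(instruments, ds)
                    for snp, reason in hset.dropped:
                        dropped_counts[reason] = dropped_counts.get(reason, 0) + 1
                    ests = run_all_methods(
                        hset, seed=_wm_seed(config.seed, idx), n_boot=config.n_boot
                    )
                    frames.append(estimates_to_frame(ests))
                manifest["counts"]["harmonization_drops"] = dropped_counts
                return pd.concat(frames, ignore_index=True)

            mr_estimates = _load_or(mr_path, config.resume, _compute_mr)
            manifest["outputs"]["mr_estimates"] = mr_path

            meta_path = os.path.join(outdir, "mr_meta.tsv")

            def _compute_meta() -> pd.DataFrame:
                rows = []
                for (met, method), grp in mr_estimates.groupby(["outcome", "method"]):
                    pooled = fixed_effect_meta(list(zip(grp["theta"], grp["se"])))
                    rows.append(
                        {
                            "exposure": grp["exposure"].iloc[0],
                            "outcome": met,
                            "method": method,
                            "theta": pooled.pooled_theta,
                            "se": pooled.se,
                            "ci_low": pooled.ci_low,
                            "ci_high": pooled.ci_high,
                            "pval": pooled.pval,
                            "k": pooled.k,
                            "het_q": pooled.het_q,
                            "het_q_pval": pooled.het_q_pval,
                        }
                    )
                return pd.DataFrame(rows).sort_values(["outcome", "method"]).reset_index(drop=True)

            mr_meta = _load_or(meta_path, config.resume, _compute_meta)
            manifest["outputs"]["mr_meta"] = meta_path
            manifest["counts"]["mr_estimates"] = len(mr_estimates)

        # ------------------------------------------------------------- AMV
        with _stage("amv"):
            amv_cohort_path = os.path.join(outdir, "amv_cohort.tsv")

            def _compute_amv() -> pd.DataFrame:
                assocs = []
                for name, table in zip(cohort_names, cohorts):
                    prepared = prepare_metabolites(
                        table, metabolite_cols, log=log_metabolites, standardize=True
                    )
                    for met in metabolite_cols:
                        assocs.append(
                            fit_cohort(prepared, exposure_col, met, cohort=name)
                        )
                return assocs_to_frame(assocs)

            amv_cohort = (
                _load_or(amv_cohort_path, config.resume, _compute_amv)
                if cohorts
                else pd.DataFrame()
            )
            manifest["outputs"]["amv_cohort"] = amv_cohort_path

            amv_meta_path = os.path.join(outdir, "amv_meta.tsv")

            def _compute_amv_meta() -> pd.DataFrame:
                from .amv import CohortAssoc

                rows = []
                for met, grp in amv_cohort.groupby("metabolite"):
                    assocs = [
                        CohortAssoc(
                            cohort=r["cohort"],
                            exposure=r["exposure"],
                            metabolite=r["metabolite"],
                            beta=r["beta"],
                            se=r["se"],
                            n=int(r["n"]),
                        )
                        for r in grp.to_dict("records")
                    ]
                    fixed, random = meta_cohorts(assocs)
                    for model, est in (("fixed", fixed), ("random_dl", random)):
                        if est is None:
                            continue
                        rows.append(
                            {
                                "exposure": assocs[0].exposure,
                                "metabolite": met,
                                "model": model,
                                "theta": est.pooled_theta,
                                "se": est.se,
                                "ci_low": est.ci_low,
                                "ci_high": est.ci_high,
                                "pval": est.pval,
                                "k": est.k,
                                "het_q": est.het_q,
                                "het_q_pval": est.het_q_pval,
                                "tau2": est.tau2,
                            }
                        )
                return (
                    pd.DataFrame(rows)
                    .sort_values(["metabolite", "model"])
                    .reset_index(drop=True)
                )

            amv_meta = (
                _load_or(amv_meta_path, config.resume, _compute_amv_meta)
                if len(amv_cohort)
                else pd.DataFrame()
            )
            manifest["outputs"]["amv_meta"] = amv_meta_path
            manifest["counts"]["amv_associations"] = len(amv_cohort)

        # --------------------------------------------------- triangulation
        with _stage("triangulation"):
            threshold = corrected_threshold(config.alpha, config.effective_tests)
            manifest["corrected_threshold"] = threshold
            ivw = mr_meta[mr_meta["method"].isin(["ivw_mre", "wald_ratio"])].set_index(
                "outcome"
            )
            amv_fixed = amv_meta[amv_meta["model"] == "fixed"].set_index("metabolite")
            shared = [m for m in metabolite_cols if m in ivw.index and m in amv_fixed.index]
            if not shared:
                raise ValidationError("no metabolite appears in both AMV and MR arms")
            rows = [
                classify_consistency(
                    met,
                    ArmResult(
                        float(amv_fixed.at[met, "theta"]),
                        float(amv_fixed.at[met, "se"]),
                        float(amv_fixed.at[met, "pval"]),
                    ),
                    ArmResult(
                        float(ivw.at[met, "theta"]),
                        float(ivw.at[met, "se"]),
                        float(ivw.at[met, "pval"]),
                    ),
                    threshold,
                )
                for met in shared
            ]
            summary = (
                concordance(
                    [r.amv_theta for r in rows], [r.mr_theta for r in rows]
                )
                if len(rows) >= 3
                else None
            )
            if summary is not None:
                written = render_outputs(
                    rows,
                    summary,
                    outdir,
                    exposure=exposure.trait_name,
                    sensitivity=mr_meta,
                    make_plot=config.make_plots,
                )
                manifest["outputs"].update(written)
                manifest["concordance"] = {
                    "slope": summary.slope,
                    "intercept": summary.intercept,
                    "r2": summary.r2,
                }
            else:
                frame = rows_to_frame(rows)
                p = os.path.join(outdir, f"triangulation_{exposure.trait_name}.tsv")
                frame.to_csv(p, sep="\t", index=False)
                manifest["outputs"]["triangulation"] = p
            verdicts = pd.Series([r.verdict for r in rows]).value_counts().to_dict()
            manifest["counts"]["verdicts"] = {k: int(v) for k, v in verdicts.items()}

        # --------------------------------------------------------- manifest
        import yaml

        manifest["timestamp"] = datetime.datetime.now().isoformat()
        with open(os.path.join(outdir, "manifest.yaml"), "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        return manifest
    finally:
        root.removeHandler(handler)
        handler.close()
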