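"""Orchestration of the full two-step analysis.

Step 1 scans the methylome for CpGs responsive to the exposure-proxy
genotype, selects hits at an FDR cutoff, and converts each hit into a
Wald-ratio estimate of the exposure's causal effect on methylation using an
external genotype-exposure summary statistic (two-sample design). Step 2
discovers cis-mQTL instruments for each hit, LD-clumps them, estimates the
instrument-outcome association in samples *disjoint* from the mQTL-discovery
samples (avoiding winner's-curse bias), forms the methylation-outcome Wald
ratio, and chains the two steps into a mediated effect per exposure
increment.

When one cohort plays both roles, :func:`partition_samples` splits it into a
methylation "discovery" arm and a genotype+outcome arm; real-data users
supply explicit ID lists instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from epimediate.cohort import CohortData
from epimediate.errors import ValidationError
from epimediate.instruments import (
    DEFAULT_CIS_WINDOW,
    DEFAULT_P_THRESHOLD,
    DEFAULT_R2_THRESHOLD,
    CisCandidate,
    find_cis_snps,
    ld_clump,
)
from epimediate.io import SummaryStat, write_results
from epimediate.mr import IVEstimate, MediatedEffect, mediated_effect, wald_ratio
from epimediate.mwas import AssociationResult, ScanReport, fit_cpg, run_mwas
from epimediate.simulate import OUTCOME_COLUMNS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the two-step run needs besides the cohort itself."""

    instrument: str
    exposure_stat: SummaryStat
    covariates_step1: list[str] = field(default_factory=list)
    covariates_mqtl: list[str] = field(default_factory=list)
    covariates_observational: list[str] = field(default_factory=list)
    outcome_columns: list[str] = field(default_factory=lambda: list(OUTCOME_COLUMNS))
    age_covariate: str = "age_testing"
    fdr_cutoff: float = 0.05
    top_k: int | None = None          # stress-test alternative to the FDR rule
    mqtl_window: int = DEFAULT_CIS_WINDOW
    mqtl_p_threshold: float = DEFAULT_P_THRESHOLD
    mqtl_r2: float = DEFAULT_R2_THRESHOLD
    snp_allowlist: list[str] | None = None
    exposure_increment: float = 10.0  # exposure units per reported mediated effect
    discovery_fraction: float = 0.15
    outlier_iqr_k: float | None = 3.0
    total_tests: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.discovery_fraction < 1.0):
            raise ValidationError("discovery_fraction must be in (0, 1)")
        if not (0.0 < self.fdr_cutoff <= 1.0):
            raise ValidationError("fdr_cutoff must be in (0, 1]")


@dataclass
class SamplePartition:
    """Disjoint discovery (methylation) and outcome (genotype+IQ) arms."""

    discovery_ids: list[str]
    outcome_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.discovery_ids) & set(self.outcome_ids)
        if overlap:
            raise ValidationError(
                f"partition arms overlap on {len(overlap)} sample(s), "
                f"e.g. {sorted(overlap)[:3]}"
            )


def partition_samples(sample_ids: Sequence[str], discovery_fraction: float,
                      seed: int) -> SamplePartition:
    """Seeded random split of a cohort into discovery and outcome arms."""
    ids = list(sample_ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_disc = max(1, int(round(discovery_fraction * len(ids))))
    if n_disc >= len(ids):
        raise ValidationError("discovery fraction leaves no outcome samples")
    disc = sorted(ids[i] for i in perm[:n_disc])
    outc = sorted(ids[i] for i in perm[n_disc:])
    return SamplePartition(discovery_ids=disc, outcome_ids=outc)


@dataclass
class Step2Record:
    """Step-2 output for one CpG: chosen instrument (if any), per-outcome IV
    and observational estimates, and mediated effects."""

    cpg_id: str
    status: str                        # "ok" or "non-instrumentable"
    instrument: CisCandidate | None
    candidates: list[CisCandidate]
    iv_estimates: list[IVEstimate]
    observational: list[AssociationResult]
    mediated: list[MediatedEffect]


def run_step1(cohort: CohortData, config: PipelineConfig,
              partition: SamplePartition | None = None
              ) -> tuple[ScanReport, list[IVEstimate]]:
    """MWAS on the discovery arm + one Wald ratio per FDR hit.

    The genotype-exposure coefficient comes from ``config.exposure_stat``
    (an external summary statistic, two-sample design); the genotype-
    methylation coefficient is each hit's scan beta. Returns an empty hit
    list when nothing passes the cutoff.
    """
    sub = (cohort.subset_samples(partition.discovery_ids)
           if partition is not None else cohort)
    report = run_mwas(sub, config.instrument,
                      covariate_names=config.covariates_step1,
                      outlier_iqr_k=config.outlier_iqr_k,
                      total_tests=config.total_tests)
    if config.top_k is not None:
        hits = report.results[: config.top_k]
    else:
        hits = report.hits(config.fdr_cutoff)
    ge = config.exposure_stat
    cohort_allele = cohort.genotypes.effect_allele_of(config.instrument)
    sign = 1.0
    if ge.variant_id == config.instrument and cohort_allele != ge.effect_allele:
        sign = -1.0  # scan betas count the opposite allele; flip to match
        logger.info("flipping scan betas to effect allele %s", ge.effect_allele)
    estimates = [
        wald_ratio(sign * h.beta, h.se, ge.beta, ge.se,
                   exposure=ge.trait, outcome=h.cpg_id,
                   instrument=config.instrument)
        for h in hits
    ]
    if not estimates:
        logger.info("step 1: no CpG passed q <= %.3g", config.fdr_cutoff)
    return report, estimates


def _ols_outcome(y: np.ndarray, x: np.ndarray, covars: np.ndarray | None,
                 label: str, outcome: str) -> AssociationResult:
    r = fit_cpg(y, x, covariates=covars, outlier_iqr_k=None, cpg_id=label)
    r.gene = outcome
    return r


def run_step2(cohort: CohortData, config: PipelineConfig,
              hits: Sequence[str], partition: SamplePartition,
              step1_estimates: Sequence[IVEstimate] = ()) -> list[Step2Record]:
    """cis-instrument discovery + outcome IV estimation for each step-1 hit.

    mQTL discovery and clumping run on the discovery arm; the instrument-
    outcome regressions (IQ on dosage, age-at-testing adjusted) run on the
    outcome arm only. The observational methylation-outcome regression, by
    contrast, needs methylation and therefore runs on the discovery arm with
    the full observational covariate list. A hit without any surviving cis
    instrument is reported as non-instrumentable and skipped.
    """
    if cohort.methylation is None:
        raise ValidationError("cohort has no methylation data")
    disc = cohort.subset_samples(partition.discovery_ids)
    outc = cohort.subset_samples(partition.outcome_ids)
    step1_by_cpg = {e.outcome: e for e in step1_estimates}

    cov_mqtl = (np.column_stack([disc.phenotypes.column(c)
                                 for c in config.covariates_mqtl])
                if config.covariates_mqtl else None)
    age_out = outc.phenotypes.column(config.age_covariate)[:, None]
    obs_cols = list(config.covariates_observational)
    cov_obs = (np.column_stack([disc.phenotypes.column(c) for c in obs_cols])
               if obs_cols else None)

    records: list[Step2Record] = []
    for cpg in hits:
        chrom, pos = disc.methylation.cpg_position(cpg)
        cands = find_cis_snps((chrom, pos), cpg, disc.genotypes,
                              disc.methylation.beta_of(cpg),
                              covariates=cov_mqtl,
                              window=config.mqtl_window,
                              p_threshold=config.mqtl_p_threshold,
                              outlier_iqr_k=config.outlier_iqr_k)
        if config.snp_allowlist is not None:
            cands = [c for c in cands if c.variant_id in config.snp_allowlist]
        independent = ld_clump(cands, disc.genotypes, r2_threshold=config.mqtl_r2)
        if not independent:
            logger.info("%s: no cis instrument (%d candidates pre-clump)",
                        cpg, len(cands))
            records.append(Step2Record(cpg_id=cpg, status="non-instrumentable",
                                       instrument=None, candidates=cands,
                                       iv_estimates=[], observational=[],
                                       mediated=[]))
            continue
        best = independent[0]
        dose_out = outc.genotypes.dosage_of(best.variant_id)
        meth_disc = disc.methylation.beta_of(cpg)
        ivs: list[IVEstimate] = []
        obs: list[AssociationResult] = []
        meds: list[MediatedEffect] = []
        for outcome in config.outcome_columns:
            go = _ols_outcome(outc.phenotypes.column(outcome), dose_out,
                              age_out, label=best.variant_id, outcome=outcome)
            iv = wald_ratio(go.beta, go.se, best.beta, best.se,
                            exposure=cpg, outcome=outcome,
                            instrument=best.variant_id)
            ivs.append(iv)
            obs.append(_ols_outcome(disc.phenotypes.column(outcome),
                                    meth_disc, cov_obs, label=cpg,
                                    outcome=outcome))
            if cpg in step1_by_cpg:
                meds.append(mediated_effect(step1_by_cpg[cpg], iv,
                                            increment=config.exposure_increment))
        records.append(Step2Record(cpg_id=cpg, status="ok", instrument=best,
                                   candidates=cands, iv_estimates=ivs,
                                   observational=obs, mediated=meds))
    return records


def _write_instruments(records: Sequence[Step2Record], cohort: CohortData,
                       path: Path) -> None:
    rows = []
    for rec in records:
        for c in rec.candidates:
            chrom, pos = cohort.genotypes.variant_position(c.variant_id)
            rows.append({
                "cpg_id": c.cpg_id,
                "gene": cohort.methylation.gene_of(c.cpg_id),
                "chromosome": chrom,
                "variant_id": c.variant_id,
                "maf": round(c.maf, 6),
                "position": pos,
                "distance": c.distance,
                "beta": c.beta, "se": c.se, "p": c.p,
                "selected": (rec.instrument is not None
                             and c.variant_id == rec.instrument.variant_id),
            })
    df = pd.DataFrame(rows, columns=["cpg_id", "gene", "chromosome",
                                     "variant_id", "maf", "position",
                                     "distance", "beta", "se", "p",
                                     "selected"])
    if len(df):
        df["p"] = df["p"].map(lambda v: f"{v:.6e}")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_mediated(records: Sequence[Step2Record],
                    step1_by_cpg: dict[str, IVEstimate], path: Path) -> None:
    rows = []
    for rec in records:
        for m in rec.mediated:
            rows.append({
                "cpg_id": m.cpg_id, "outcome": m.outcome,
                "instrument": rec.instrument.variant_id if rec.instrument else "NA",
                "step1_ratio": step1_by_cpg[m.cpg_id].ratio,
                "step2_ratio": next(iv.ratio for iv in rec.iv_estimates
                                    if iv.outcome == m.outcome),
                "exposure_increment": m.exposure_increment,
                "mediated_effect": m.value,
            })
    pd.DataFrame(rows, columns=["cpg_id", "outcome", "instrument",
                                "step1_ratio", "step2_ratio",
                                "exposure_increment", "mediated_effect"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_two_step(cohort: CohortData, config: PipelineConfig,
                 out_dir: str | Path) -> Path:
    """Execute step 1 then step 2, writing all artifacts into ``out_dir``.

    Outputs: ``scan.tsv`` (full MWAS), ``step1_iv.tsv``, ``instruments.tsv``,
    ``step2_iv.tsv``, ``observational.tsv``, ``mediated.tsv`` and
    ``run_summary.yaml``. Deterministic for a fixed config seed. On a stage
    failure, partial outputs are kept and the summary records the failed
    stage before the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        from importlib.metadata import version
        pkg_version = version("epimediate")
    except Exception:
        pkg_version = "unknown"
    summary: dict = {
        "package_version": pkg_version,
        "seed": config.seed,
        "instrument": config.instrument,
        "exposure_trait": config.exposure_stat.trait,
        "n_samples": cohort.n_samples,
        "status": "running",
        "failure_stage": None,
    }
    stage = "partition"
    try:
        partition = partition_samples(cohort.sample_ids,
                                      config.discovery_fraction, config.seed)
        summary["n_discovery"] = len(partition.discovery_ids)
        summary["n_outcome"] = len(partition.outcome_ids)
        (out / "partition_discovery.txt").write_text(
            "\n".join(partition.discovery_ids) + "\n")
        (out / "partition_outcome.txt").write_text(
            "\n".join(partition.outcome_ids) + "\n")

        stage = "step1"
        report, step1_ivs = run_step1(cohort, config, partition)
        summary["lambda_gc"] = round(report.lambda_gc, 6)
        summary["n_cpgs_tested"] = report.n_tested
        summary["n_probes_excluded"] = report.n_excluded_probes
        summary["n_fit_failures"] = report.n_failed_fits
        summary["n_step1_hits"] = len(step1_ivs)
        write_results(report.results, out / "scan.tsv")
        write_results(step1_ivs, out / "step1_iv.tsv")

        if not step1_ivs:
            summary["status"] = "no hits"
            return out

        stage = "step2"
        hits = [e.outcome for e in step1_ivs]
        records = run_step2(cohort, config, hits, partition,
                            step1_estimates=step1_ivs)
        step1_by_cpg = {e.outcome: e for e in step1_ivs}
        _write_instruments(records, cohort, out / "instruments.tsv")
        all_ivs = [iv for r in records for iv in r.iv_estimates]
        write_results(all_ivs, out / "step2_iv.tsv")
        write_results([o for r in records for o in r.observational],
                      out / "observational.tsv")
        _write_mediated(records, step1_by_cpg, out / "mediated.tsv")
        summary["n_instrumentable"] = sum(r.status == "ok" for r in records)
        summary["non_instrumentable_cpgs"] = [
            r.cpg_id for r in records if r.status != "ok"
        ]
        summary["n_mediated_effects"] = sum(len(r.mediated) for r in records)
        summary["status"] = "ok"
        return out
    except Exception:
        summary["status"] = "failed"
        summary["failure_stage"] = stage
        raise
    finally:
        (out / "run_summary.yaml").write_text(
            yaml.safe_dump(summary, sort_keys=True))
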