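"""Synthetic cohorts with the causal structure the two-step analysis assumes.

The generative chain is

    maternal genotype G --> circulating exposure X (pg/ml)
    X --> methylation beta at a few responsive CpGs (with cis-mQTL SNPs
          contributing independently)
    methylation --> IQ-scale outcomes

plus one latent "socioeconomic" confounder feeding exposure, methylation and
outcome, and observed covariates correlated with it so that covariate
adjustment removes part (not all) of the confounding. Instrument genotypes
are drawn under Hardy-Weinberg equilibrium at the configured minor-allele
frequency; methylation beta-values are kept in (0, 1) by passing a linear
predictor through a logistic squash centred at each CpG's baseline, scaled so
that small planted effects are locally effects on the proportion scale.

Ground truth is recorded in :class:`SimTruth`. Because the squash attenuates
large effects, the truth stores both the planted linear-scale coefficients
and the *realized* average causal effects, computed counterfactually by
re-evaluating the same noise draws under a shifted exposure (or an extra
instrument allele): the realized values are the estimands an IV analysis of
the cohort consistently targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy import special, stats

from epimediate.cohort import CohortData
from epimediate.errors import ValidationError
from epimediate.io import (
    BETA_EPS,
    GenotypeMatrix,
    MethylationMatrix,
    PhenotypeTable,
    SummaryStat,
)
import pandas as pd

#: covariate columns the generator emits, in the order phenotype tables carry them
DEFAULT_COVARIATES = [
    "mat_age", "mat_bmi", "mat_education", "smoking", "parity",
    "child_sex", "batch1", "batch2", "cellprop1", "cellprop2",
]

OUTCOME_COLUMNS = ["iq_total", "iq_verbal", "iq_performance"]


def _default_responsive() -> dict[str, float]:
    # methylation proportion per pg/ml; signs follow the motivating study's
    # hit pattern (one hypo-, two hypermethylated), magnitudes chosen to stay
    # in the locally linear regime of the logistic link (see docs/methods.md)
    return {"cg_resp01": -4e-4, "cg_resp02": 3e-4, "cg_resp03": 2e-4}


def _default_cis() -> dict[str, tuple[str, float, float]]:
    # CpG -> (SNP id, MAF, methylation proportion per allele); the first
    # responsive CpG deliberately has no cis instrument
    return {
        "cg_resp02": ("rs_cis02", 0.43, -0.26),
        "cg_resp03": ("rs_cis03", 0.40, -0.44),
    }


def _default_theta() -> dict[str, float]:
    # IQ points per methylation proportion (full 0-1 unit)
    return {"cg_resp02": 3.46, "cg_resp03": -2.26}


@dataclass
class SimParams:
    """Generator configuration; defaults give a strong-instrument cohort with
    instrument R-squared on the exposure of ~0.05."""

    n_samples: int = 2000
    n_cpgs: int = 5000
    instrument_id: str = "rs_instr"
    instrument_maf: float = 0.40
    beta_gx: float = 70.21          # pg/ml per effect allele
    exposure_mean: float = 400.0    # pg/ml
    responsive_cpg_effects: dict[str, float] = field(default_factory=_default_responsive)
    cis_snp_effects: dict[str, tuple[str, float, float]] = field(default_factory=_default_cis)
    theta_my: dict[str, float] = field(default_factory=_default_theta)
    conf_exposure: float = 50.0     # pg/ml per confounder SD
    conf_meth: float = 0.01         # methylation proportion per confounder SD
    conf_iq: float = 5.0            # IQ points per confounder SD
    sd_exposure: float = 206.0      # residual exposure SD, pg/ml
    sd_meth: float = 0.02           # residual methylation SD, proportion scale
    sd_iq: float = 14.1             # residual IQ SD
    n_null_cis_snps: int = 3        # no-effect SNPs placed in each cis window
    frac_sex_cpgs: float = 0.02     # background CpGs annotated to chromosome X
    panel_n: int = 3495             # independent exposure-panel sample size
    panel_maf: float | None = None  # panel instrument MAF; None = cohort MAF
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 10:
            raise ValidationError("n_samples must be at least 10")
        mafs = [self.instrument_maf] + [m for _, m, _ in self.cis_snp_effects.values()]
        if self.panel_maf is not None:
            mafs.append(self.panel_maf)
        for m in mafs:
            if not (0.0 < m < 0.5):
                raise ValidationError(f"MAF {m} outside (0, 0.5)")
        for name in ("sd_exposure", "sd_meth", "sd_iq"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_cpgs < len(self.responsive_cpg_effects):
            raise ValidationError(
                "n_cpgs smaller than the number of responsive CpGs"
            )
        unknown = set(self.cis_snp_effects) - set(self.responsive_cpg_effects)
        unknown |= set(self.theta_my) - set(self.responsive_cpg_effects)
        if unknown:
            raise ValidationError(
                f"cis/theta maps reference non-responsive CpGs: {sorted(unknown)}"
            )


@dataclass
class SimTruth:
    """Recorded ground truth for one generated cohort."""

    params: SimParams
    seed: int
    #: planted linear-scale exposure->methylation slopes (proportion per pg/ml)
    planted_exposure_meth: dict[str, float]
    #: realized average causal effect on each responsive CpG's beta-value,
    #: per pg/ml but measured over one instrument-allele's worth of exposure
    #: (beta_gx pg/ml) under identical noise -- the estimand a genotype-
    #: instrumented Wald ratio targets
    ace_exposure_meth: dict[str, float]
    #: realized average causal effect of one extra cis-SNP allele on beta
    ace_cis_meth: dict[str, float]
    #: IQ points per methylation proportion (exact; outcome link is linear)
    theta_my: dict[str, float]
    #: realized mediated effect on IQ per 10 pg/ml exposure, per CpG
    mediated_per_10pg: dict[str, float]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"]["cis_snp_effects"] = {
            k: list(v) for k, v in d["params"]["cis_snp_effects"].items()
        }
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _hwe_dosages(rng: np.random.Generator, n: int, maf: float) -> np.ndarray:
    return rng.binomial(2, maf, size=n).astype(float)


def _cpg_layout(params: SimParams) -> tuple[list[str], list[str], np.ndarray, list[str]]:
    """Assign IDs, chromosomes, 1-based positions and gene labels."""
    responsive = list(params.responsive_cpg_effects)
    n_bg = params.n_cpgs - len(responsive)
    n_sex = int(round(params.frac_sex_cpgs * n_bg))
    cpg_ids = responsive + [f"cg{k:08d}" for k in range(n_bg)]
    chroms: list[str] = []
    positions: list[int] = []
    genes: list[str] = []
    for i, c in enumerate(responsive):
        chroms.append(str(i % 22 + 1))
        positions.append(10_000_000 + 5_000_000 * (i // 22))
        genes.append(f"GENE_{c.upper()}")
    for k in range(n_bg):
        if k < n_sex:
            chroms.append("X")
            positions.append(1_000_000 + 1_000 * k)
        else:
            chroms.append(str(k % 22 + 1))
            positions.append(60_000_000 + 1_000 * k)
        genes.append("NA")
    return cpg_ids, chroms, np.asarray(positions), genes


def _snp_layout(params: SimParams, cpg_ids: list[str], cpg_chroms: list[str],
                cpg_pos: np.ndarray) -> tuple[list[str], list[str], list[int],
                                              list[str], list[float],
                                              dict[str, str]]:
    """Instrument + per-CpG cis SNPs (+ null cis SNPs) with positions.

    Returns (ids, chroms, positions, effect alleles, mafs, cpg->cis-SNP map).
    """
    ids = [params.instrument_id]
    chroms = ["19"]
    positions = [49_206_674]
    alleles = ["T"]
    mafs = [params.instrument_maf]
    cis_of: dict[str, str] = {}
    cpg_index = {c: i for i, c in enumerate(cpg_ids)}
    for cpg, (snp_id, maf, _beta) in params.cis_snp_effects.items():
        i = cpg_index[cpg]
        ids.append(snp_id)
        chroms.append(cpg_chroms[i])
        positions.append(int(cpg_pos[i]) + 50_000)
        alleles.append("T")
        mafs.append(maf)
        cis_of[cpg] = snp_id
        for k in range(params.n_null_cis_snps):
            ids.append(f"{snp_id}_null{k}")
            chroms.append(cpg_chroms[i])
            positions.append(int(cpg_pos[i]) + 200_000 * (k + 1))
            alleles.append("A")
            mafs.append(0.30)
    return ids, chroms, positions, alleles, mafs, cis_of


def _covariates(rng: np.random.Generator, n: int, conf: np.ndarray) -> pd.DataFrame:
    expit = special.expit
    return pd.DataFrame({
        "mat_age": 29.3 + 2.0 * conf + rng.normal(0, 4.0, n),
        "mat_bmi": 22.9 + 1.5 * conf + rng.normal(0, 3.0, n),
        "mat_education": rng.binomial(1, expit(-1.3 + 0.8 * conf)).astype(float),
        "smoking": rng.binomial(1, expit(-1.9 - 0.5 * conf)).astype(float),
        "parity": rng.poisson(0.8, n).astype(float),
        "child_sex": rng.binomial(1, 0.5, n).astype(float),
        "batch1": rng.normal(0, 1, n),
        "batch2": rng.normal(0, 1, n),
        "cellprop1": np.clip(0.55 + rng.normal(0, 0.05, n), 0.0, 1.0),
        "cellprop2": np.clip(0.25 + rng.normal(0, 0.04, n), 0.0, 1.0),
        "age_testing": 8.6 + rng.normal(0, 0.25, n),
    })


def simulate_cohort(params: SimParams) -> tuple[CohortData, SimTruth]:
    """Draw one cohort; bit-identical for a fixed ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    n_covariates = len(DEFAULT_COVARIATES) + 1
    if n < n_covariates + 4:
        raise ValidationError(
            f"n_samples={n} too small for the {n_covariates}-column design"
        )

    conf = rng.normal(0, 1, n)
    dose_instr = _hwe_dosages(rng, n, params.instrument_maf)

    exposure_noise = rng.normal(0, params.sd_exposure, n)
    intercept_x = params.exposure_mean - params.beta_gx * 2 * params.instrument_maf

    def exposure_given(dose: np.ndarray) -> np.ndarray:
        return intercept_x + params.beta_gx * dose + params.conf_exposure * conf + exposure_noise

    exposure = exposure_given(dose_instr)

    cpg_ids, cpg_chroms, cpg_pos, cpg_genes = _cpg_layout(params)
    snp_ids, snp_chroms, snp_pos, snp_alleles, snp_mafs, cis_of = _snp_layout(
        params, cpg_ids, cpg_chroms, cpg_pos
    )
    dosages = np.empty((n, len(snp_ids)))
    dosages[:, 0] = dose_instr
    for j in range(1, len(snp_ids)):
        dosages[:, j] = _hwe_dosages(rng, n, snp_mafs[j])
    snp_col = {s: j for j, s in enumerate(snp_ids)}

    covars = _covariates(rng, n, conf)

    baselines = rng.uniform(0.15, 0.85, params.n_cpgs)
    meth_noise = rng.normal(0, params.sd_meth, size=(n, params.n_cpgs))
    batch_coef = 0.003  # proportion-scale batch leakage into every CpG

    responsive = list(params.responsive_cpg_effects)
    slopes = np.zeros(params.n_cpgs)
    slopes[: len(responsive)] = [params.responsive_cpg_effects[c] for c in responsive]
    cis_term_center = np.zeros((n, params.n_cpgs))
    for c, (snp_id, maf, beta_cis) in params.cis_snp_effects.items():
        j = cpg_ids.index(c)
        cis_term_center[:, j] = beta_cis * (dosages[:, snp_col[snp_id]] - 2 * maf)

    def betas_given(x: np.ndarray, cis_shift: dict[str, float] | None = None) -> np.ndarray:
        """Beta matrix for exposure vector x under the stored noise draws."""
        scale = baselines * (1.0 - baselines)
        lin = (
            slopes[None, :] * (x - params.exposure_mean)[:, None]
            + cis_term_center
            + params.conf_meth * conf[:, None]
            + batch_coef * covars["batch1"].to_numpy()[:, None]
            + meth_noise
        )
        if cis_shift:
            lin = lin.copy()
            for c, delta in cis_shift.items():
                j = cpg_ids.index(c)
                lin[:, j] += delta
        eta = special.logit(baselines)[None, :] + lin / scale[None, :]
        return np.clip(special.expit(eta), BETA_EPS, 1.0 - BETA_EPS)

    betas = betas_given(exposure)

    # realized average causal effects via counterfactual contrasts; the
    # exposure is shifted by one allele's effect, the increment the
    # instrument actually induces
    delta_x = params.beta_gx
    betas_shift = betas_given(exposure + delta_x)
    ace_xm = {
        c: float(np.mean(betas_shift[:, cpg_ids.index(c)] - betas[:, cpg_ids.index(c)]) / delta_x)
        for c in responsive
    }
    ace_cis: dict[str, float] = {}
    for c, (_snp, _maf, beta_cis) in params.cis_snp_effects.items():
        shifted = betas_given(exposure, cis_shift={c: beta_cis})
        j = cpg_ids.index(c)
        ace_cis[c] = float(np.mean(shifted[:, j] - betas[:, j]))

    # outcomes: mean-100 IQ scale with a shared component across subscales
    theta = params.theta_my
    structural = np.zeros(n)
    for c, t in theta.items():
        col = betas[:, cpg_ids.index(c)]
        structural += t * (col - col.mean())
    shared = rng.normal(0, 0.7 * params.sd_iq, n)
    own_sd = params.sd_iq * np.sqrt(1 - 0.49)
    outcomes = {
        name: 100.0 + structural + params.conf_iq * conf + shared + rng.normal(0, own_sd, n)
        for name in OUTCOME_COLUMNS
    }

    sample_ids = [f"S{i:05d}" for i in range(n)]
    geno = GenotypeMatrix(
        sample_ids=sample_ids, variant_ids=snp_ids, dosages=dosages,
        effect_alleles=snp_alleles, chromosomes=snp_chroms,
        positions=np.asarray(snp_pos),
    )
    meth = MethylationMatrix(
        sample_ids=sample_ids, cpg_ids=cpg_ids, betas=betas,
        chromosomes=cpg_chroms, positions=cpg_pos, genes=cpg_genes,
    )
    pheno_df = covars.copy()
    pheno_df.insert(0, "exposure", exposure)
    # the latent confounder, recorded for calibration diagnostics; real
    # cohorts never observe it and default covariate lists exclude it
    pheno_df["ses_conf"] = conf
    for name, vals in outcomes.items():
        pheno_df[name] = vals
    pheno_df.index = pd.Index(sample_ids, name="sample_id")
    pheno = PhenotypeTable(pheno_df)

    truth = SimTruth(
        params=replace(params),
        seed=params.seed,
        planted_exposure_meth=dict(params.responsive_cpg_effects),
        ace_exposure_meth=ace_xm,
        ace_cis_meth=ace_cis,
        theta_my=dict(theta),
        mediated_per_10pg={
            c: ace_xm[c] * theta.get(c, 0.0) * 10.0 for c in responsive
        },
    )
    return CohortData(genotypes=geno, phenotypes=pheno, methylation=meth), truth


def simulate_two_sample_panel(params: SimParams) -> tuple[SummaryStat, CohortData, SimTruth]:
    """Two-sample design: the genotype-exposure statistic is *estimated* in an
    independent panel (optionally at a different MAF, mimicking a
    trans-ancestry summary-statistic source), while the methylation cohort is
    generated as in :func:`simulate_cohort`."""
    panel_maf = params.panel_maf if params.panel_maf is not None else params.instrument_maf
    rng = np.random.default_rng(params.seed + 500_009)
    dose = _hwe_dosages(rng, params.panel_n, panel_maf)
    conf = rng.normal(0, 1, params.panel_n)
    x = (params.exposure_mean - params.beta_gx * 2 * panel_maf
         + params.beta_gx * dose + params.conf_exposure * conf
         + rng.normal(0, params.sd_exposure, params.panel_n))
    if np.ptp(dose) == 0:
        raise ValidationError(
            "panel instrument is monomorphic; increase panel_n or MAF"
        )
    slope, intercept, _r, p, se = stats.linregress(dose, x)
    summary = SummaryStat(
        variant_id=params.instrument_id, trait="exposure", effect_allele="T",
        other_allele="A", beta=float(slope), se=float(se),
        n=params.panel_n, p=float(p),
    )
    cohort, truth = simulate_cohort(params)
    return summary, cohort, truth
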