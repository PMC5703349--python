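"""Methylome-wide association scan (step 1 of the two-step design).

One covariate-adjusted linear regression per CpG, with the per-probe QC
filters standard in EWAS practice (sex-chromosome removal, detection-p
filter, IQR-based sample outlier exclusion), a genomic-inflation diagnostic,
and Benjamini-Hochberg / Bonferroni multiple-testing adjustment against a
configurable test count.

The per-CpG fit is plain OLS of the methylation beta-value on the instrument
dosage plus covariates, with the two-sided p-value from the t distribution at
the residual degrees of freedom. The scan refits a fresh design for every CpG
because complete-case and outlier masks differ between probes; the linear
algebra is done directly (lstsq + explicit (X'X)^-1) to keep methylome-scale
scans fast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from epimediate.cohort import CohortData
from epimediate.errors import DegenerateInstrumentError, ValidationError
from epimediate.io import MethylationMatrix

logger = logging.getLogger(__name__)

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


@dataclass
class AssociationResult:
    """Per-CpG scan output: dosage coefficient on the methylation-proportion
    scale, its SE, t-test p, complete-case n, and adjusted p-values."""

    cpg_id: str
    beta: float
    se: float
    p: float
    n: int
    q_bh: float = float("nan")
    p_bonf: float = float("nan")
    chromosome: str = "NA"
    position: int = 0
    gene: str = "NA"


@dataclass
class ScanReport:
    """A full scan: per-CpG results (sorted by p ascending), the genomic
    inflation factor, and exclusion bookkeeping."""

    results: list[AssociationResult]
    lambda_gc: float
    n_tested: int
    n_excluded_probes: int
    n_failed_fits: int = 0

    def hits(self, fdr_cutoff: float = 0.05) -> list[AssociationResult]:
        return [r for r in self.results if r.q_bh <= fdr_cutoff]


def filter_probes(meth: MethylationMatrix,
                  detection_p: np.ndarray | None = None,
                  detection_threshold: float = 0.05,
                  max_failing_fraction: float = 0.0) -> MethylationMatrix:
    """Remove sex-chromosome probes and probes failing detection.

    ``detection_p`` is an optional samples x CpGs matrix aligned with
    ``meth``; a probe is dropped when the fraction of samples with detection
    p-value above ``detection_threshold`` exceeds ``max_failing_fraction``
    (default 0: any failing sample removes the probe). With no detection
    matrix only the sex-chromosome filter applies.
    """
    keep = ~meth.sex_chromosome
    n_sex = int((~keep).sum())
    n_det = 0
    if detection_p is not None:
        detection_p = np.asarray(detection_p, dtype=float)
        if detection_p.shape != meth.betas.shape:
            raise ValidationError(
                f"detection-p shape {detection_p.shape} does not match "
                f"beta matrix {meth.betas.shape}"
            )
        failing = np.mean(detection_p > detection_threshold, axis=0)
        det_keep = failing <= max_failing_fraction
        n_det = int((keep & ~det_keep).sum())
        keep &= det_keep
    if not keep.any():
        raise ValidationError("probe filtering removed every probe")
    kept_ids = [c for c, k in zip(meth.cpg_ids, keep) if k]
    logger.info("probe filter: %d sex-chromosome, %d detection-failed, %d retained",
                n_sex, n_det, len(kept_ids))
    out = meth.subset_cpgs(kept_ids)
    return out


def _outlier_mask(y: np.ndarray, k: float) -> np.ndarray:
    """True for values within k x IQR of the nearest quartile."""
    q1, q3 = np.percentile(y, [25, 75])
    iqr = q3 - q1
    return (y >= q1 - k * iqr) & (y <= q3 + k * iqr)


def fit_cpg(beta_vector: np.ndarray, dose: np.ndarray,
            covariates: np.ndarray | None = None,
            outlier_iqr_k: float | None = 3.0,
            cpg_id: str = "NA") -> AssociationResult:
    """OLS of one CpG's beta-values on instrument dosage plus covariates.

    Complete cases only; samples whose beta-value lies beyond
    ``outlier_iqr_k`` x IQR from the nearest quartile are excluded before the
    fit (pass None to disable). Raises
    :class:`~epimediate.errors.DegenerateInstrumentError` for constant dosage
    and :class:`~epimediate.errors.ValidationError` for rank-deficient or
    undersized designs.
    """
    y = np.asarray(beta_vector, dtype=float)
    d = np.asarray(dose, dtype=float)
    if y.shape != d.shape or y.ndim != 1:
        raise ValidationError("beta_vector and dose must be equal-length 1-D")
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != y.shape[0]:
            raise ValidationError("covariate rows do not match sample count")
    else:
        C = np.empty((y.shape[0], 0))

    mask = np.isfinite(y) & np.isfinite(d) & np.all(np.isfinite(C), axis=1)
    if outlier_iqr_k is not None and mask.sum() >= 4:
        sub = np.zeros_like(mask)
        sub[mask] = _outlier_mask(y[mask], outlier_iqr_k)
        mask &= sub
    y, d, C = y[mask], d[mask], C[mask]

    n = y.shape[0]
    k_cols = 2 + C.shape[1]
    if n < k_cols + 2:
        raise ValidationError(
            f"{cpg_id}: only {n} complete cases for a {k_cols}-column design"
        )
    if np.ptp(d) == 0:
        raise DegenerateInstrumentError(f"{cpg_id}: constant instrument dosage")

    X = np.column_stack([np.ones(n), d, C])
    coef, _res, rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    if rank < k_cols:
        raise ValidationError(f"{cpg_id}: rank-deficient design (rank {rank} < {k_cols})")
    resid = y - X @ coef
    df = n - k_cols
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    beta = float(coef[1])
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return AssociationResult(cpg_id=cpg_id, beta=beta, se=se, p=p, n=n)


def genomic_inflation(p_values: Sequence[float]) -> float:
    """Genomic inflation factor: median 1-df chi-square quantile of the
    observed p-values divided by the null chi-square median (0.4549...)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values supplied")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, 1)
    return float(np.median(chi) / CHI2_1DF_MEDIAN)


def adjust_bh(p_values: Sequence[float], n_tests: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values against ``n_tests`` comparisons.

    q_(i) = min_{j >= i} p_(j) * n_tests / j, capped at 1, mapped back to the
    input order. ``n_tests`` defaults to len(p_values) and must not be
    smaller than it.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if n_tests is None:
        n_tests = m
    if n_tests < m:
        raise ValidationError(f"n_tests={n_tests} smaller than {m} p-values")
    if m == 0:
        return np.empty(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n_tests / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def adjust_bonferroni(p_values, n_tests: int) -> np.ndarray | float:
    """Bonferroni adjustment min(1, p * n_tests); scalar in, scalar out."""
    scalar = np.isscalar(p_values)
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if n_tests < p.size:
        raise ValidationError(f"n_tests={n_tests} smaller than {p.size} p-values")
    out = np.minimum(1.0, p * n_tests)
    return float(out[0]) if scalar else out


def run_mwas(cohort: CohortData, instrument: str,
             covariate_names: Sequence[str] = (),
             detection_p: np.ndarray | None = None,
             outlier_iqr_k: float | None = 3.0,
             total_tests: int | None = None) -> ScanReport:
    """Scan every retained CpG for association with the instrument dosage.

    ``total_tests`` overrides the multiple-testing denominator (default: the
    number of CpGs actually tested). Per-CpG fit failures are logged,
    counted, and excluded from the report.
    """
    if cohort.methylation is None:
        raise ValidationError("cohort has no methylation data")
    cohort.phenotypes.require_columns(covariate_names)
    meth = filter_probes(cohort.methylation, detection_p=detection_p)
    n_excluded = cohort.methylation.n_cpgs - meth.n_cpgs
    dose = cohort.genotypes.dosage_of(instrument)
    C = (np.column_stack([cohort.phenotypes.column(c) for c in covariate_names])
         if covariate_names else None)

    results: list[AssociationResult] = []
    n_failed = 0
    for j, cpg in enumerate(meth.cpg_ids):
        try:
            r = fit_cpg(meth.betas[:, j], dose, covariates=C,
                        outlier_iqr_k=outlier_iqr_k, cpg_id=cpg)
        except (DegenerateInstrumentError, ValidationError) as exc:
            logger.warning("skipping %s: %s", cpg, exc)
            n_failed += 1
            continue
        r.chromosome = meth.chromosomes[j]
        r.position = int(meth.positions[j])
        r.gene = meth.genes[j]
        results.append(r)
    if not results:
        raise ValidationError("no CpG could be fitted")

    n_tested = len(results)
    denom = total_tests if total_tests is not None else n_tested
    pvals = np.array([r.p for r in results])
    q = adjust_bh(pvals, n_tests=denom)
    bonf = adjust_bonferroni(pvals, n_tests=denom)
    for r, qi, bi in zip(results, q, bonf):
        r.q_bh = float(qi)
        r.p_bonf = float(bi)
    results.sort(key=lambda r: (r.p, r.cpg_id))
    lam = genomic_inflation(np.clip(pvals, 1e-300, 1.0))
    logger.info("MWAS: %d CpGs tested, lambda=%.3f, %d excluded, %d failed",
                n_tested, lam, n_excluded, n_failed)
    return ScanReport(results=results, lambda_gc=lam, n_tested=n_tested,
                      n_excluded_probes=n_excluded, n_failed_fits=n_failed)
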