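"""Wald-ratio instrumental-variable estimation and MR power.

The single-instrument (Wald) ratio estimator divides the genotype-outcome
coefficient by the genotype-exposure coefficient:

    ratio = beta_GO / beta_GE

with the first-order delta-method standard error

    se = sqrt( se_GO^2 / beta_GE^2  +  beta_GO^2 * se_GE^2 / beta_GE^4 ).

In a two-sample design the two coefficients come from independent samples,
so their covariance term is exactly zero and the two-term formula above is
the full first-order expansion. IV p-values use the standard-normal
reference (large-sample), unlike the per-CpG scan which uses the t
distribution — the scan's residual degrees of freedom are known, the
ratio's are not.

Mediated effects chain two IV steps: the exposure's effect on the mediator
(step 1) times the mediator's effect on the outcome (step 2), scaled by an
exposure increment in natural units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from epimediate.errors import (
    ChainingError,
    DegenerateInstrumentError,
    HarmonizationError,
    ValidationError,
)
from epimediate.io import SummaryStat

logger = logging.getLogger(__name__)

#: |beta_GE| / se_GE below which an instrument is flagged weak (approx F = 9)
WEAK_INSTRUMENT_Z = 3.0


@dataclass
class IVEstimate:
    """One Wald-ratio causal estimate, outcome units per exposure unit."""

    exposure: str
    outcome: str
    instrument: str
    ratio: float
    se: float
    z: float
    p: float
    beta_go: float
    se_go: float
    beta_ge: float
    se_ge: float
    weak_instrument: bool = False


@dataclass(frozen=True)
class MediatedEffect:
    """Effect of the upstream exposure on the final outcome routed through
    one mediator CpG, per ``exposure_increment`` exposure units."""

    cpg_id: str
    outcome: str
    value: float
    exposure_increment: float


@dataclass(frozen=True)
class PowerSpec:
    """Design for an asymptotic two-sample MR power calculation."""

    n: int
    r2: float
    beta_std: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.r2 < 1.0):
            raise ValidationError(f"r2={self.r2} outside (0, 1)")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError(f"alpha={self.alpha} outside (0, 1)")
        if self.n < 1:
            raise ValidationError("n must be positive")


def wald_ratio(beta_go: float, se_go: float, beta_ge: float, se_ge: float,
               exposure: str = "exposure", outcome: str = "outcome",
               instrument: str = "NA") -> IVEstimate:
    """Wald ratio with first-order delta-method SE and normal p-value.

    ``beta_go``/``se_go`` is the genotype-outcome association and
    ``beta_ge``/``se_ge`` the genotype-exposure association, both per count
    of the *same* effect allele (see :func:`harmonize`).
    """
    for name, s in (("se_go", se_go), ("se_ge", se_ge)):
        if not np.isfinite(s) or s <= 0:
            raise ValidationError(f"{name} must be positive, got {s}")
    if beta_ge == 0:
        raise DegenerateInstrumentError(
            "genotype-exposure coefficient is zero; the ratio is undefined"
        )
    ratio = beta_go / beta_ge
    se = float(np.sqrt(se_go**2 / beta_ge**2
                       + beta_go**2 * se_ge**2 / beta_ge**4))
    z = ratio / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    weak = abs(beta_ge) / se_ge < WEAK_INSTRUMENT_Z
    if weak:
        logger.warning(
            "weak instrument %s: |beta_ge|/se_ge = %.2f < %.1f; the ratio "
            "estimate may be badly biased", instrument,
            abs(beta_ge) / se_ge, WEAK_INSTRUMENT_Z,
        )
    return IVEstimate(exposure=exposure, outcome=outcome, instrument=instrument,
                      ratio=float(ratio), se=se, z=float(z), p=p,
                      beta_go=float(beta_go), se_go=float(se_go),
                      beta_ge=float(beta_ge), se_ge=float(se_ge),
                      weak_instrument=weak)


def harmonize(go: SummaryStat, ge: SummaryStat) -> tuple[SummaryStat, SummaryStat, bool]:
    """Align two summary statistics to the same effect allele.

    Returns ``(go, ge, flipped)`` where the genotype-outcome beta has been
    negated if its effect allele is the genotype-exposure record's other
    allele. Raises :class:`HarmonizationError` when the alleles cannot be
    reconciled.
    """
    if go.variant_id != ge.variant_id:
        raise HarmonizationError(
            f"variant mismatch: {go.variant_id!r} vs {ge.variant_id!r}"
        )
    if go.effect_allele == ge.effect_allele:
        return go, ge, False
    if go.effect_allele == ge.other_allele or go.other_allele == ge.effect_allele:
        flipped = SummaryStat(
            variant_id=go.variant_id, trait=go.trait,
            effect_allele=ge.effect_allele,
            other_allele=go.effect_allele,
            beta=-go.beta, se=go.se, n=go.n, p=go.p,
        )
        return flipped, ge, True
    raise HarmonizationError(
        f"{go.variant_id}: alleles {go.effect_allele}/{go.other_allele} vs "
        f"{ge.effect_allele}/{ge.other_allele} cannot be reconciled"
    )


def mediated_effect(step1: IVEstimate, step2: IVEstimate,
                    increment: float = 10.0) -> MediatedEffect:
    """Product-of-ratios mediated effect per ``increment`` exposure units.

    ``step1`` estimates exposure -> mediator (its outcome label is the
    mediator CpG); ``step2`` estimates mediator -> outcome (its exposure
    label must be the same CpG).
    """
    if step1.outcome != step2.exposure:
        raise ChainingError(
            f"step-1 outcome {step1.outcome!r} does not match step-2 "
            f"exposure {step2.exposure!r}"
        )
    return MediatedEffect(
        cpg_id=step1.outcome,
        outcome=step2.outcome,
        value=step2.ratio * step1.ratio * increment,
        exposure_increment=increment,
    )


def mr_power(spec: PowerSpec) -> float:
    """Asymptotic power of a two-sided single-instrument MR test.

    power = Phi( |beta_std| * sqrt(n * r2) - z_{1-alpha/2} ), where
    ``beta_std`` is the standardized causal effect and ``r2`` the fraction of
    exposure variance the instrument explains. At beta_std = 0 this returns
    alpha/2 (one tail of the two-sided test).
    """
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = abs(spec.beta_std) * np.sqrt(spec.n * spec.r2)
    return float(stats.norm.cdf(ncp - z_crit))


def regression_power(f2: float, n: int, alpha: float) -> float:
    """Power of the 1-numerator-df F-test for one regression coefficient.

    Uses the noncentral F with noncentrality f2 * (n - 2) at level ``alpha``
    (Cohen's f-squared parametrization).
    """
    if f2 <= 0:
        raise ValidationError("f2 must be positive")
    if n < 3:
        raise ValidationError("n must be at least 3")
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha={alpha} outside (0, 1]")
    if alpha == 1.0:
        return 1.0
    df2 = n - 2
    crit = stats.f.isf(alpha, 1, df2)
    return float(stats.ncf.sf(crit, 1, df2, f2 * df2))
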