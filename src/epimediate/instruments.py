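"""cis-mQTL instrument discovery and LD clumping (step 2 of the design).

For a CpG of interest, every same-chromosome SNP within a symmetric window
(default +/- 1 Mb) is regressed against the CpG's methylation beta-values;
SNPs passing the association threshold (default p < 1e-7) are candidate
instruments. Greedy LD clumping then prunes the candidates to a mutually
near-independent set, keeping the most significant representative of each
linkage block. LD is the squared Pearson correlation of dosages in the
analysis sample itself — no external reference panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from epimediate.errors import DegenerateInstrumentError, ValidationError
from epimediate.io import GenotypeMatrix
from epimediate.mwas import fit_cpg

logger = logging.getLogger(__name__)

DEFAULT_CIS_WINDOW = 1_000_000   # bp each side, inclusive
DEFAULT_P_THRESHOLD = 1e-7
DEFAULT_R2_THRESHOLD = 0.1


@dataclass(frozen=True)
class CisCandidate:
    """One candidate cis-mQTL: SNP, signed distance to the CpG (SNP minus
    CpG position), its per-allele methylation effect, and sample MAF."""

    cpg_id: str
    variant_id: str
    distance: int
    beta: float
    se: float
    p: float
    maf: float


def _candidate_sort_key(c: CisCandidate) -> tuple[float, int, str]:
    # deterministic: p, then proximity, then lexicographic SNP id
    return (c.p, abs(c.distance), c.variant_id)


def find_cis_snps(cpg: tuple[str, int], cpg_id: str,
                  genotypes: GenotypeMatrix,
                  methylation: np.ndarray,
                  covariates: np.ndarray | None = None,
                  window: int = DEFAULT_CIS_WINDOW,
                  p_threshold: float = DEFAULT_P_THRESHOLD,
                  outlier_iqr_k: float | None = 3.0) -> list[CisCandidate]:
    """Scan the cis window of one CpG for mQTL SNPs.

    ``cpg`` is the (chromosome, 1-based position) of the CpG and
    ``methylation`` its per-sample beta-values aligned with ``genotypes``.
    Returns candidates with p below threshold, sorted by (p, |distance|,
    variant_id); an empty list (not an error) when nothing qualifies — a CpG
    without cis instruments is simply not instrumentable.
    """
    chrom, pos = str(cpg[0]), int(cpg[1])
    y = np.asarray(methylation, dtype=float)
    if y.shape[0] != genotypes.n_samples:
        raise ValidationError("methylation vector does not match genotype samples")
    out: list[CisCandidate] = []
    for j, snp in enumerate(genotypes.variant_ids):
        if genotypes.chromosomes[j] != chrom:
            continue
        distance = int(genotypes.positions[j]) - pos
        if abs(distance) > window:
            continue
        dose = genotypes.dosages[:, j]
        try:
            r = fit_cpg(y, dose, covariates=covariates,
                        outlier_iqr_k=outlier_iqr_k, cpg_id=cpg_id)
        except (DegenerateInstrumentError, ValidationError) as exc:
            logger.warning("cis scan %s ~ %s skipped: %s", cpg_id, snp, exc)
            continue
        if r.p < p_threshold:
            out.append(CisCandidate(
                cpg_id=cpg_id, variant_id=snp, distance=distance,
                beta=r.beta, se=r.se, p=r.p, maf=genotypes.maf(snp),
            ))
    out.sort(key=_candidate_sort_key)
    return out


def _dosage_r2(a: np.ndarray, b: np.ndarray) -> float:
    mask = np.isfinite(a) & np.isfinite(b)
    a, b = a[mask], b[mask]
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValidationError("r2 incomputable (constant or empty dosage)")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_clump(candidates: Sequence[CisCandidate], genotypes: GenotypeMatrix,
             r2_threshold: float = DEFAULT_R2_THRESHOLD) -> list[CisCandidate]:
    """Greedy LD clumping: repeatedly accept the most significant remaining
    candidate and drop everything whose squared dosage correlation with an
    accepted SNP exceeds ``r2_threshold``.

    The output is invariant to input order (candidates are re-sorted by the
    deterministic (p, |distance|, variant_id) key) and every returned pair
    has pairwise r-squared at or below the threshold. Candidates whose r2
    with an accepted SNP is incomputable (constant dosage) are dropped with
    a warning.
    """
    pool = sorted(candidates, key=_candidate_sort_key)
    accepted: list[CisCandidate] = []
    accepted_dose: list[np.ndarray] = []
    for cand in pool:
        dose = genotypes.dosage_of(cand.variant_id)
        try:
            if any(_dosage_r2(dose, d) > r2_threshold for d in accepted_dose):
                continue
        except ValidationError as exc:
            logger.warning("dropping %s from clump: %s", cand.variant_id, exc)
            continue
        if not accepted_dose and np.ptp(dose[np.isfinite(dose)]) == 0:
            logger.warning("dropping %s from clump: constant dosage", cand.variant_id)
            continue
        accepted.append(cand)
        accepted_dose.append(dose)
    return accepted
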