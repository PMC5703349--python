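"""Aligned per-cohort container joining genotypes, methylation, phenotypes."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from epimediate.errors import ValidationError
from epimediate.io import GenotypeMatrix, MethylationMatrix, PhenotypeTable


@dataclass
class CohortData:
    """One cohort's genotype dosages, methylation betas and phenotypes,
    row-aligned on a shared sample-ID order.

    Construct via :meth:`align` when the source tables may list samples in
    different orders or contain non-overlapping samples; the join intersects
    on sample IDs and preserves per-sample correspondence. ``methylation``
    may be None for outcome-only samples (genotype + phenotype, no array
    data), as in a two-step design's second-step arm.
    """

    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    methylation: MethylationMatrix | None = None

    def __post_init__(self) -> None:
        ids = self.genotypes.sample_ids
        if self.phenotypes.sample_ids != ids:
            raise ValidationError(
                "genotype and phenotype sample order differ; use "
                "CohortData.align() to join on sample IDs"
            )
        if self.methylation is not None and self.methylation.sample_ids != ids:
            raise ValidationError(
                "methylation sample order differs; use CohortData.align()"
            )

    @classmethod
    def align(cls, genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
              methylation: MethylationMatrix | None = None) -> "CohortData":
        """Intersect on sample IDs (genotype order wins) and row-align."""
        keep = set(phenotypes.sample_ids)
        if methylation is not None:
            keep &= set(methylation.sample_ids)
        ids = [s for s in genotypes.sample_ids if s in keep]
        if not ids:
            raise ValidationError("no samples shared across input tables")
        return cls(
            genotypes=genotypes.subset_samples(ids),
            phenotypes=phenotypes.subset_samples(ids),
            methylation=(methylation.subset_samples(ids)
                         if methylation is not None else None),
        )

    @property
    def sample_ids(self) -> list[str]:
        return self.genotypes.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CohortData":
        return CohortData(
            genotypes=self.genotypes.subset_samples(sample_ids),
            phenotypes=self.phenotypes.subset_samples(sample_ids),
            methylation=(self.methylation.subset_samples(sample_ids)
                         if self.methylation is not None else None),
        )
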