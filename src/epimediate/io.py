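"""Tabular input/output with strict schema validation.

All tables are tab-separated UTF-8 with one header row; missing values are
encoded ``NA``. Floats are written at 10 significant digits, so a write/read
round trip is an identity up to that precision. Positions are 1-based and
chromosome labels are plain strings without a ``chr`` prefix.

Layouts
-------
genotypes
    one row per variant: ``variant_id  chromosome  position  effect_allele``
    followed by one dosage column per sample (expected minor-allele count
    in [0, 2]).
methylation
    one row per CpG: ``cpg_id`` followed by one beta-value column per sample,
    plus a separate annotation table ``cpg_id  chromosome  position  gene``.
phenotypes
    one row per sample: ``sample_id`` followed by named numeric/categorical
    columns (exposure, outcomes, covariates).
summary statistics
    GWAS dialect: ``variant_id  trait  effect_allele  other_allele  beta  se
    n  p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from epimediate.errors import FormatError, ValidationError

#: load-time clamp applied to methylation beta-values so downstream logit
#: transforms are finite
BETA_EPS = 1e-6

_FLOAT_FMT = "%.10g"
_NA = "NA"

SEX_CHROMOSOMES = frozenset({"X", "Y", "23", "24", "XY"})


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dup = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"duplicate {what}: {dup!r}")


def _normalize_chrom(label: object) -> str:
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


def _chrom_sort_key(label: str) -> tuple[int, int, str]:
    try:
        return (0, int(label), "")
    except ValueError:
        return (1, 0, label)


@dataclass
class GenotypeMatrix:
    """Dosage matrix for a set of biallelic variants.

    ``dosages`` is samples x variants with entries in [0, 2] (expected count
    of the per-variant effect allele); NaN marks missing genotypes. Hard
    calls are simply dosages in {0, 1, 2}.
    """

    sample_ids: list[str]
    variant_ids: list[str]
    dosages: np.ndarray
    effect_alleles: list[str]
    chromosomes: list[str]
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        n_s, n_v = len(self.sample_ids), len(self.variant_ids)
        if self.dosages.shape != (n_s, n_v):
            raise ValidationError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{n_s} samples x {n_v} variants"
            )
        if not (len(self.effect_alleles) == len(self.chromosomes) == n_v
                and self.positions.shape == (n_v,)):
            raise ValidationError("per-variant metadata length mismatch")
        _check_unique(self.sample_ids, "sample_id")
        _check_unique(self.variant_ids, "variant_id")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]} for variant "
                f"{self.variant_ids[j]!r}, sample {self.sample_ids[i]!r} "
                "outside [0, 2]"
            )
        self.chromosomes = [_normalize_chrom(c) for c in self.chromosomes]
        self._variant_index = {v: k for k, v in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def dosage_of(self, variant_id: str) -> np.ndarray:
        try:
            j = self._variant_index[variant_id]
        except KeyError:
            raise ValidationError(f"unknown variant {variant_id!r}") from None
        return self.dosages[:, j]

    def variant_position(self, variant_id: str) -> tuple[str, int]:
        j = self._variant_index[variant_id]
        return self.chromosomes[j], int(self.positions[j])

    def effect_allele_of(self, variant_id: str) -> str:
        return self.effect_alleles[self._variant_index[variant_id]]

    def maf(self, variant_id: str) -> float:
        """Folded minor-allele frequency from observed dosages."""
        d = self.dosage_of(variant_id)
        f = float(np.nanmean(d)) / 2.0
        return min(f, 1.0 - f)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            variant_ids=list(self.variant_ids),
            dosages=self.dosages[rows],
            effect_alleles=list(self.effect_alleles),
            chromosomes=list(self.chromosomes),
            positions=self.positions.copy(),
        )


@dataclass
class MethylationMatrix:
    """Beta-value matrix (samples x CpGs) with per-CpG annotation.

    Beta-values are methylation proportions, clamped into
    (BETA_EPS, 1 - BETA_EPS) at construction.
    """

    sample_ids: list[str]
    cpg_ids: list[str]
    betas: np.ndarray
    chromosomes: list[str]
    positions: np.ndarray
    genes: list[str]
    sex_chromosome: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        self.positions = np.asarray(self.positions, dtype=int)
        n_s, n_c = len(self.sample_ids), len(self.cpg_ids)
        if self.betas.shape != (n_s, n_c):
            raise ValidationError(
                f"beta matrix shape {self.betas.shape} does not match "
                f"{n_s} samples x {n_c} CpGs"
            )
        if not (len(self.chromosomes) == len(self.genes) == n_c
                and self.positions.shape == (n_c,)):
            raise ValidationError("per-CpG annotation length mismatch")
        _check_unique(self.sample_ids, "sample_id")
        _check_unique(self.cpg_ids, "cpg_id")
        with np.errstate(invalid="ignore"):
            bad = (self.betas < 0) | (self.betas > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta-value {self.betas[i, j]} for CpG {self.cpg_ids[j]!r} "
                "outside [0, 1]"
            )
        self.betas = np.clip(self.betas, BETA_EPS, 1.0 - BETA_EPS)
        self.chromosomes = [_normalize_chrom(c) for c in self.chromosomes]
        if self.sex_chromosome is None:
            self.sex_chromosome = np.array(
                [c in SEX_CHROMOSOMES for c in self.chromosomes], dtype=bool
            )
        else:
            self.sex_chromosome = np.asarray(self.sex_chromosome, dtype=bool)
        self._cpg_index = {c: k for k, c in enumerate(self.cpg_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)

    def beta_of(self, cpg_id: str) -> np.ndarray:
        try:
            j = self._cpg_index[cpg_id]
        except KeyError:
            raise ValidationError(f"unknown CpG {cpg_id!r}") from None
        return self.betas[:, j]

    def cpg_position(self, cpg_id: str) -> tuple[str, int]:
        j = self._cpg_index[cpg_id]
        return self.chromosomes[j], int(self.positions[j])

    def gene_of(self, cpg_id: str) -> str:
        return self.genes[self._cpg_index[cpg_id]]

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "MethylationMatrix":
        cols = [self._cpg_index[c] for c in cpg_ids]
        return MethylationMatrix(
            sample_ids=list(self.sample_ids),
            cpg_ids=list(cpg_ids),
            betas=self.betas[:, cols],
            chromosomes=[self.chromosomes[j] for j in cols],
            positions=self.positions[cols],
            genes=[self.genes[j] for j in cols],
            sex_chromosome=self.sex_chromosome[cols],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return MethylationMatrix(
            sample_ids=list(sample_ids),
            cpg_ids=list(self.cpg_ids),
            betas=self.betas[rows],
            chromosomes=list(self.chromosomes),
            positions=self.positions.copy(),
            genes=list(self.genes),
            sex_chromosome=self.sex_chromosome.copy(),
        )


@dataclass
class PhenotypeTable:
    """Per-sample phenotypes and covariates, one row per sample."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample_id: {dup!r}")
        self.data.index = self.data.index.astype(str)
        self.data.index.name = "sample_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def column(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise ValidationError(f"phenotype column {name!r} not present")
        return self.data[name].to_numpy(dtype=float)

    def require_columns(self, names: Sequence[str]) -> None:
        missing = [n for n in names if n not in self.data.columns]
        if missing:
            raise ValidationError(f"missing phenotype columns: {missing}")

    def subset_samples(self, sample_ids: Sequence[str]) -> "PhenotypeTable":
        return PhenotypeTable(self.data.loc[list(sample_ids)].copy())


@dataclass(frozen=True)
class SummaryStat:
    """One (variant, trait) association from a GWAS-style summary table."""

    variant_id: str
    trait: str
    effect_allele: str
    beta: float
    se: float
    n: int
    p: float
    other_allele: str = _NA

    def __post_init__(self) -> None:
        if not np.isfinite(self.se) or self.se <= 0:
            raise ValidationError(
                f"standard error must be positive, got {self.se} "
                f"for {self.variant_id!r}"
            )
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(
                f"p-value {self.p} for {self.variant_id!r} outside [0, 1]"
            )


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={c: str for c in required
                                                if c.endswith("_id")},
                         na_values=[_NA], keep_default_na=False)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


_GENO_META = ["variant_id", "chromosome", "position", "effect_allele"]


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a variants-by-samples dosage TSV into a :class:`GenotypeMatrix`."""
    df = _read_tsv(path, _GENO_META)
    sample_cols = [c for c in df.columns if c not in _GENO_META]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns after variant metadata")
    try:
        dosages = df[sample_cols].astype(float).to_numpy().T
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric dosage value ({exc})") from exc
    return GenotypeMatrix(
        sample_ids=[str(c) for c in sample_cols],
        variant_ids=[str(v) for v in df["variant_id"]],
        dosages=dosages,
        effect_alleles=[str(a) for a in df["effect_allele"]],
        chromosomes=[str(c) for c in df["chromosome"]],
        positions=df["position"].astype(int).to_numpy(),
    )


def write_genotypes(geno: GenotypeMatrix, path: str | Path) -> None:
    meta = pd.DataFrame({
        "variant_id": geno.variant_ids,
        "chromosome": geno.chromosomes,
        "position": geno.positions,
        "effect_allele": geno.effect_alleles,
    })
    body = pd.DataFrame(geno.dosages.T, columns=geno.sample_ids)
    pd.concat([meta, body], axis=1).to_csv(
        path, sep="\t", index=False, na_rep=_NA, float_format=_FLOAT_FMT)


def read_methylation(matrix_path: str | Path,
                     annotation_path: str | Path) -> MethylationMatrix:
    """Read a CpGs-by-samples beta TSV plus its annotation table.

    Beta-values of exactly 0 or 1 are clamped to (BETA_EPS, 1 - BETA_EPS);
    values outside [0, 1] are rejected. Every CpG in the matrix must be
    annotated; the sex-chromosome flag is derived from the annotation
    chromosome label.
    """
    mat = _read_tsv(matrix_path, ["cpg_id"])
    ann = _read_tsv(annotation_path, ["cpg_id", "chromosome", "position", "gene"])
    sample_cols = [c for c in mat.columns if c != "cpg_id"]
    if not sample_cols:
        raise FormatError(f"{matrix_path}: no sample columns")
    ann = ann.set_index(ann["cpg_id"].astype(str))
    cpg_ids = [str(c) for c in mat["cpg_id"]]
    missing = [c for c in cpg_ids if c not in ann.index]
    if missing:
        raise ValidationError(
            f"CpG(s) present in matrix but absent from annotation: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    ann = ann.loc[cpg_ids]
    try:
        betas = mat[sample_cols].astype(float).to_numpy().T
    except ValueError as exc:
        raise FormatError(f"{matrix_path}: non-numeric beta-value ({exc})") from exc
    return MethylationMatrix(
        sample_ids=[str(c) for c in sample_cols],
        cpg_ids=cpg_ids,
        betas=betas,
        chromosomes=[str(c) for c in ann["chromosome"]],
        positions=ann["position"].astype(int).to_numpy(),
        genes=[_NA if pd.isna(g) else str(g) for g in ann["gene"]],
    )


def write_methylation(meth: MethylationMatrix, matrix_path: str | Path,
                      annotation_path: str | Path) -> None:
    mat = pd.concat([
        pd.DataFrame({"cpg_id": meth.cpg_ids}),
        pd.DataFrame(meth.betas.T, columns=meth.sample_ids),
    ], axis=1)
    mat.to_csv(matrix_path, sep="\t", index=False, na_rep=_NA,
               float_format=_FLOAT_FMT)
    ann = pd.DataFrame({
        "cpg_id": meth.cpg_ids,
        "chromosome": meth.chromosomes,
        "position": meth.positions,
        "gene": meth.genes,
    })
    ann.to_csv(annotation_path, sep="\t", index=False, na_rep=_NA)


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = _read_tsv(path, ["sample_id"])
    df = df.set_index(df["sample_id"].astype(str)).drop(columns=["sample_id"])
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        # keep genuinely non-numeric (categorical) columns as strings
        if converted.notna().sum() >= df[col].notna().sum():
            df[col] = converted
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path) -> None:
    pheno.data.to_csv(path, sep="\t", na_rep=_NA, float_format=_FLOAT_FMT)


_SUMSTAT_COLS = ["variant_id", "trait", "effect_allele", "other_allele",
                 "beta", "se", "n", "p"]


def read_summary_stats(path: str | Path) -> list[SummaryStat]:
    """Read GWAS-dialect summary statistics; ``other_allele`` is optional."""
    required = [c for c in _SUMSTAT_COLS if c != "other_allele"]
    df = _read_tsv(path, required)
    out: list[SummaryStat] = []
    for _, row in df.iterrows():
        other = row.get("other_allele", _NA)
        out.append(SummaryStat(
            variant_id=str(row["variant_id"]),
            trait=str(row["trait"]),
            effect_allele=str(row["effect_allele"]),
            other_allele=_NA if pd.isna(other) else str(other),
            beta=float(row["beta"]),
            se=float(row["se"]),
            n=int(row["n"]),
            p=float(row["p"]),
        ))
    return out


def write_summary_stats(stats: Sequence[SummaryStat], path: str | Path) -> None:
    df = pd.DataFrame([{
        "variant_id": s.variant_id, "trait": s.trait,
        "effect_allele": s.effect_allele, "other_allele": s.other_allele,
        "beta": s.beta, "se": s.se, "n": s.n, "p": s.p,
    } for s in stats], columns=_SUMSTAT_COLS)
    df["p"] = df["p"].map(lambda v: f"{v:.6e}")
    df.to_csv(path, sep="\t", index=False, na_rep=_NA,
              float_format=_FLOAT_FMT)


def write_results(records: Sequence, path: str | Path) -> None:
    """Write a homogeneous list of result records to TSV.

    Association results are ordered by (chromosome, position); IV estimates
    by (exposure, outcome, instrument). p-values are written in scientific
    notation. An empty list yields a header-only association table.
    """
    # local imports avoid a circular dependency at module load
    from epimediate.mwas import AssociationResult
    from epimediate.mr import IVEstimate

    kinds = {type(r) for r in records}
    if len(kinds) > 1:
        raise ValidationError(f"mixed record types: {sorted(k.__name__ for k in kinds)}")
    kind = kinds.pop() if kinds else AssociationResult

    if kind is AssociationResult:
        rows = sorted(records, key=lambda r: (_chrom_sort_key(r.chromosome),
                                              r.position, r.cpg_id))
        df = pd.DataFrame([{
            "cpg_id": r.cpg_id, "chromosome": r.chromosome,
            "position": r.position, "gene": r.gene, "beta": r.beta,
            "se": r.se, "p": r.p, "n": r.n, "q_bh": r.q_bh,
            "p_bonf": r.p_bonf,
        } for r in rows], columns=["cpg_id", "chromosome", "position",
                                   "gene", "beta", "se", "p", "n",
                                   "q_bh", "p_bonf"])
        for col in ("p", "q_bh", "p_bonf"):
            df[col] = df[col].map(lambda v: _NA if pd.isna(v) else f"{v:.6e}")
    elif kind is IVEstimate:
        rows = sorted(records, key=lambda r: (r.exposure, r.outcome,
                                              r.instrument))
        df = pd.DataFrame([{
            "exposure": r.exposure, "outcome": r.outcome,
            "instrument": r.instrument, "ratio": r.ratio, "se": r.se,
            "z": r.z, "p": r.p, "beta_go": r.beta_go, "se_go": r.se_go,
            "beta_ge": r.beta_ge, "se_ge": r.se_ge,
            "weak_instrument": r.weak_instrument,
        } for r in rows], columns=["exposure", "outcome", "instrument",
                                   "ratio", "se", "z", "p", "beta_go",
                                   "se_go", "beta_ge", "se_ge",
                                   "weak_instrument"])
        df["p"] = df["p"].map(lambda v: _NA if pd.isna(v) else f"{v:.6e}")
    else:
        raise ValidationError(f"unsupported record type {kind.__name__}")
    try:
        df.to_csv(path, sep="\t", index=False, na_rep=_NA,
                  float_format=_FLOAT_FMT)
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc
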