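"""Core containers shared across the pipeline.

Matrices are oriented samples x features (rows are samples) throughout the
in-memory API; on disk the methylation matrix is stored features x samples
(probes as rows, header row of sample IDs), matching array-data convention.
Genomic coordinates are 1-based and fully closed everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CELL_COUNT_COLUMNS = ("lymphocytes", "monocytes", "neutrophils", "eosinophils", "basophils")
TECHNICAL_COLUMNS = ("plate", "array", "array_position")


class FormatError(ValueError):
    """Raised when an input file or table violates its contract."""


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent configuration."""


@dataclass
class MethylationDataset:
    """Methylation beta values plus probe genomic annotation.

    ``beta`` is samples x probes with values in [0, 1].  ``probe_annotation``
    is indexed by probe id with columns ``chrom``, ``pos`` (1-based bp),
    ``snp_at_target`` (bool) and ``autosomal`` (bool), covering every column
    of ``beta``.
    """

    beta: pd.DataFrame
    probe_annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.beta.columns.duplicated().any():
            dups = self.beta.columns[self.beta.columns.duplicated()].tolist()
            raise FormatError(f"duplicate probe ids: {dups[:5]}")
        vals = self.beta.to_numpy()
        if not np.isfinite(vals).all():
            raise FormatError("non-finite beta values present")
        if (vals < 0).any() or (vals > 1).any():
            bad = np.argwhere((vals < 0) | (vals > 1))[0]
            raise FormatError(
                f"beta value out of [0, 1] at probe {self.beta.columns[bad[1]]!r}, "
                f"sample {self.beta.index[bad[0]]!r}: {vals[bad[0], bad[1]]}"
            )
        missing = self.beta.columns.difference(self.probe_annotation.index)
        if len(missing):
            raise FormatError(f"probes missing from annotation: {list(missing[:5])}")
        # align annotation to matrix column order
        self.probe_annotation = self.probe_annotation.loc[self.beta.columns]

    @property
    def sample_ids(self) -> list:
        return self.beta.index.tolist()

    @property
    def probe_ids(self) -> list:
        return self.beta.columns.tolist()


@dataclass
class GenotypeDataset:
    """Genotype dosages (effect-allele counts) plus SNP annotation.

    ``dosage`` is samples x SNPs in [0, 2]; NaN marks a missing call.
    ``snp_annotation`` is indexed by SNP id with columns ``chrom``, ``pos``,
    ``effect_allele``, ``other_allele``.
    """

    dosage: pd.DataFrame
    snp_annotation: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosage.columns.duplicated().any():
            raise FormatError("duplicate SNP ids in dosage matrix")
        vals = self.dosage.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
                raise FormatError("dosage outside [0, 2]")
        missing = self.dosage.columns.difference(self.snp_annotation.index)
        if len(missing):
            raise FormatError(f"SNPs missing from annotation: {list(missing[:5])}")
        ann = self.snp_annotation.loc[self.dosage.columns]
        same = ann["effect_allele"] == ann["other_allele"]
        if same.any():
            raise FormatError(f"effect allele equals other allele for {ann.index[same][:5].tolist()}")
        self.snp_annotation = ann

    @property
    def sample_ids(self) -> list:
        return self.dosage.index.tolist()

    @property
    def snp_ids(self) -> list:
        return self.dosage.columns.tolist()


@dataclass
class PhenotypeTable:
    """Per-sample phenotype, biological covariates and technical covariates.

    ``data`` is indexed by sample id.  Required columns: one or more trait
    columns (e.g. ``bmi``, ``height``), ``sex``, ``age``.  Optional: the five
    blood cell counts, plate/array/array_position, ``family_id``.
    """

    data: pd.DataFrame
    trait_columns: tuple = ("bmi",)

    def __post_init__(self) -> None:
        for col in (*self.trait_columns, "sex", "age"):
            if col not in self.data.columns:
                raise FormatError(f"phenotype table missing required column {col!r}")
        for trait in self.trait_columns:
            t = self.data[trait]
            if (t <= 0).any():
                raise FormatError(f"non-positive values in trait {trait!r}")

    @property
    def sample_ids(self) -> list:
        return self.data.index.tolist()

    def has_cell_counts(self) -> bool:
        return all(c in self.data.columns for c in CELL_COUNT_COLUMNS)


@dataclass
class ScoreWeights:
    """Per-feature weights driving profile-score construction.

    ``table`` is indexed by feature id with columns ``feature_kind`` ("cpg"
    or "snp"), ``weight`` and, for SNPs, ``effect_allele``.  ``source`` tags
    where the weights came from (e.g. a discovery MWAS).
    """

    table: pd.DataFrame
    source: str = ""

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids in weights: {dups[:5]}")
        if not np.isfinite(self.table["weight"].to_numpy(dtype=float)).all():
            raise FormatError("non-finite weights")
        bad = self.table["feature_kind"].isin(["cpg", "snp"])
        if not bad.all():
            raise FormatError(f"unknown feature_kind: {self.table['feature_kind'][~bad].unique()}")
        snps = self.table[self.table["feature_kind"] == "snp"]
        if len(snps):
            if "effect_allele" not in snps.columns or snps["effect_allele"].isna().any():
                raise FormatError("snp weights require an effect_allele column")

    def __len__(self) -> int:
        return len(self.table)

    def split_by_kind(self) -> dict:
        """Split a mixed weights table into per-kind ScoreWeights."""
        return {
            kind: ScoreWeights(sub.copy(), source=self.source)
            for kind, sub in self.table.groupby("feature_kind", sort=False)
        }


@dataclass
class MwasResult:
    """Per-probe association scan output.

    ``table`` is indexed by probe id with columns ``beta`` (effect per SD of
    probe on the Z-scale trait), ``se``, ``t``, ``p``, ``n``.
    """

    table: pd.DataFrame
    trait: str = ""
    covariates: tuple = ()

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            raise FormatError("duplicate probe ids in MWAS result")
        need = {"beta", "se", "t", "p", "n"}
        if not need.issubset(self.table.columns):
            raise FormatError(f"MWAS table missing columns {need - set(self.table.columns)}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ResidualizedMethylation:
    """Analysis-ready methylation: logit -> residualize -> inverse-normal.

    ``values`` is samples x probes of rank-based inverse-normal residuals;
    each column is marginally standard normal by construction.
    """

    values: pd.DataFrame
    adjustment_set: tuple
    probe_annotation: pd.DataFrame

    @property
    def sample_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def probe_ids(self) -> list:
        return self.values.columns.tolist()


@dataclass
class AdjustedPhenotype:
    """Standardized residual (Z score) of a trait after covariate adjustment."""

    z: pd.Series
    trait: str
    adjustment_set: tuple
    family_corrected: bool = False

    @property
    def sample_ids(self) -> list:
        return self.z.index.tolist()


@dataclass
class ProfileScore:
    """Per-sample weighted-sum score over CpG probes or SNPs."""

    scores: pd.Series
    feature_kind: str
    n_features_used: int
    n_features_dropped: int
    source: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy(dtype=float)).all():
            raise FormatError("non-finite profile scores")


@dataclass
class VariancePartition:
    """Adjusted R-squared of the four nested score models plus test p-values.

    Models: (1) trait ~ methylation score; (2) trait ~ genetic score;
    (3) trait ~ both; (4) trait ~ both + their product.  ``anova_p_interaction``
    is the F-test of model 4 against model 3.
    """

    adj_r2_mwas: float
    adj_r2_gwas: float
    adj_r2_additive: float
    adj_r2_interaction: float
    p_mwas_only: float
    p_gwas_only: float
    p_mwas_in_additive: float
    p_gwas_in_additive: float
    anova_p_interaction: float
    n: int
    raw_r2: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "adj_r2_mwas", "adj_r2_gwas", "adj_r2_additive", "adj_r2_interaction",
            "p_mwas_only", "p_gwas_only", "p_mwas_in_additive", "p_gwas_in_additive",
            "anova_p_interaction", "n")}
        d["raw_r2"] = dict(self.raw_r2)
        return d


@dataclass
class RelatednessMatrix:
    """SNP-derived genetic relationship matrix (off-diagonals ~ 2x kinship)."""

    values: np.ndarray
    sample_ids: list

    def __post_init__(self) -> None:
        a = np.asarray(self.values, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ConfigurationError("relatedness matrix must be square")
        if not np.allclose(a, a.T, atol=1e-10):
            raise ConfigurationError("relatedness matrix must be symmetric")
        self.values = a

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class InflationReport:
    """Genomic inflation diagnostics from phenotype permutations.

    ``m_effective`` is the effective number of independent probes implied by
    the spread of permutation lambdas: Var(lambda) = 2/M under independence,
    so M = 2 / sd(lambda)^2.
    """

    lambda_observed: float
    perm_lambdas: list
    perm_sd: float
    m_effective: float
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "lambda_observed": self.lambda_observed,
            "perm_lambdas": list(self.perm_lambdas),
            "perm_sd": self.perm_sd,
            "m_effective": self.m_effective,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


@dataclass
class MetaResult:
    """Fixed-effect meta-analysis over the probes common to two scans."""

    table: pd.DataFrame  # index probe_id; columns beta, se, p, n_total, n_studies

    @property
    def n_common(self) -> int:
        return len(self.table)
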