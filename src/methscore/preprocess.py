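"""Beta values to analysis-ready residuals; traits to Z scores.

The methylation pipeline order is fixed: probe filtering (non-autosomal and
SNP-at-target probes dropped), logit transform to M-values, per-probe
regression on technical variables (plate, array, array position) and
biological covariates (sex, age; cell counts in the sensitivity path), then
rank-based inverse-normal transform of the residuals.  Phenotypes are
regressed on sex and age and standardized to Z scores.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.special import ndtri
from scipy.stats import rankdata

from .datatypes import (
    CELL_COUNT_COLUMNS,
    TECHNICAL_COLUMNS,
    AdjustedPhenotype,
    ConfigurationError,
    FormatError,
    MethylationDataset,
    PhenotypeTable,
    ResidualizedMethylation,
)

logger = logging.getLogger(__name__)

BOUNDARY_EPS = 1e-6  # clamp for beta in {0, 1}; prevents infinite M-values


def filter_probes(dataset: MethylationDataset) -> MethylationDataset:
    """Drop non-autosomal probes and probes with a SNP at the target CpG."""
    ann = dataset.probe_annotation
    keep = ann["autosomal"].to_numpy() & ~ann["snp_at_target"].to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("probe filter dropped %d of %d probes", n_dropped, len(ann))
    if keep.sum() == 0:
        raise FormatError("probe filter removed every probe")
    kept = ann.index[keep]
    return MethylationDataset(
        beta=dataset.beta.loc[:, kept], probe_annotation=ann.loc[kept]
    )


def logit_beta(beta):
    """Elementwise log(beta / (1 - beta)); exact 0/1 clamped to the boundary eps."""
    values = np.asarray(beta, dtype=float)
    if not np.isfinite(values).all():
        raise FormatError("non-finite beta values")
    if (values < 0).any() or (values > 1).any():
        raise FormatError("beta values must lie in [0, 1]")
    n_clamped = int(((values == 0) | (values == 1)).sum())
    if n_clamped:
        logger.warning("clamped %d boundary beta values to [%g, %g]",
                       n_clamped, BOUNDARY_EPS, 1 - BOUNDARY_EPS)
    clipped = np.clip(values, BOUNDARY_EPS, 1 - BOUNDARY_EPS)
    m = np.log(clipped / (1 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    return m


def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + numeric covariates + one-hot categoricals (first level dropped)."""
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if s.isna().any():
            raise FormatError(f"covariate {col!r} has missing values")
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True, dtype=float)
            parts.append(dummies)
    return pd.concat(parts, axis=1)


def _aliased_columns(design: pd.DataFrame) -> list:
    """Design columns that are linear combinations of earlier ones."""
    x = design.to_numpy(dtype=float)
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    return [design.columns[piv[i]] for i in np.nonzero(diag <= tol)[0]]


def residualize(
    matrix: pd.DataFrame,
    covariates: pd.DataFrame | None,
    on_collinear: str = "error",
) -> pd.DataFrame:
    """Per-column OLS residuals of ``matrix`` on the covariate design.

    An empty covariate set reduces to column centering (intercept only).
    ``on_collinear`` controls aliased design columns: "error" (default)
    raises naming them; "drop" removes them with a warning — needed for
    nested technical factors (each array lies on exactly one plate, so plate
    dummies are spanned by array dummies), where the residual projection is
    still well-defined.
    """
    if covariates is not None and len(covariates.columns):
        covariates = covariates.loc[matrix.index]
        design = build_design(covariates)
    else:
        design = pd.DataFrame({"intercept": 1.0}, index=matrix.index)
    aliased = _aliased_columns(design)
    if aliased:
        if on_collinear == "error":
            raise ConfigurationError(
                f"design matrix is rank-deficient; collinear columns: {aliased}"
            )
        logger.warning("dropping %d aliased design columns (e.g. %s)",
                       len(aliased), aliased[:3])
        design = design.drop(columns=aliased)
    x = design.to_numpy(dtype=float)
    q, _ = np.linalg.qr(x)
    y = matrix.to_numpy(dtype=float)
    resid = y - q @ (q.T @ y)
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def inverse_normal(matrix: pd.DataFrame, offset: float = 0.375) -> pd.DataFrame:
    """Rank-based inverse-normal transform per column (Blom offset 3/8).

    Maps ranks to normal quantiles via ndtri((rank - c) / (n - 2c + 1)) with
    c = 3/8; ties get the average rank.  Constant columns have no rank
    ordering and are rejected.
    """
    y = matrix.to_numpy(dtype=float)
    if not np.isfinite(y).all():
        raise FormatError("non-finite residuals passed to inverse_normal")
    constant = y.std(axis=0) == 0
    if constant.any():
        names = list(matrix.columns[constant][:5])
        raise FormatError(f"constant columns have undefined ranks: {names}")
    n = y.shape[0]
    ranks = rankdata(y, axis=0, method="average")
    z = ndtri((ranks - offset) / (n - 2 * offset + 1))
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def preprocess_methylation(
    dataset: MethylationDataset,
    phenotypes: PhenotypeTable,
    include_cell_counts: bool = False,
) -> ResidualizedMethylation:
    """Full pipeline: filter -> logit -> residualize -> inverse-normal."""
    dataset = filter_probes(dataset)
    samples = dataset.beta.index
    pdata = phenotypes.data.loc[samples]
    adjustment = ["sex", "age"] + [c for c in TECHNICAL_COLUMNS if c in pdata.columns]
    if include_cell_counts:
        missing = [c for c in CELL_COUNT_COLUMNS if c not in pdata.columns]
        if missing:
            raise FormatError(f"cell-count adjustment requested but columns missing: {missing}")
        adjustment += list(CELL_COUNT_COLUMNS)
    m_values = logit_beta(dataset.beta)
    resid = residualize(m_values, pdata[adjustment], on_collinear="drop")
    transformed = inverse_normal(resid)
    return ResidualizedMethylation(
        values=transformed,
        adjustment_set=tuple(adjustment),
        probe_annotation=dataset.probe_annotation,
    )


def adjust_phenotype(phenotypes: PhenotypeTable, trait: str) -> AdjustedPhenotype:
    """Residual of trait ~ sex + age, standardized to a Z score."""
    pdata = phenotypes.data
    if trait not in pdata.columns:
        raise FormatError(f"trait {trait!r} not in phenotype table")
    y = pdata[[trait]].astype(float)
    resid = residualize(y, pdata[["sex", "age"]])[trait]
    sd = resid.std(ddof=1)
    # a trait that is an exact function of the covariates leaves only
    # floating-point residue; treat it as degenerate
    if not np.isfinite(sd) or sd <= 1e-8 * max(y[trait].std(ddof=1), 1e-300):
        raise ConfigurationError(
            f"trait {trait!r} has zero residual variance after sex/age adjustment"
        )
    z = resid / sd
    return AdjustedPhenotype(z=z, trait=trait, adjustment_set=("sex", "age"))
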