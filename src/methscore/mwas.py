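"""Per-probe association scan and genomic-inflation diagnostics.

Each probe (already logit-transformed, covariate-residualized and
inverse-normal transformed) is regressed against the sex/age-adjusted trait
Z score by simple OLS.  The inflation factor lambda is defined as the MEAN
1-df chi-square statistic across probes (not the conventional median-based
lambda; a median variant is available for comparison).  Permuting the
phenotype gives a null distribution of lambda whose spread measures the
effective number of independent probes: Var(lambda) = 2/M under
independence, hence M = 2 / sd(lambda)^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    AdjustedPhenotype,
    ConfigurationError,
    InflationReport,
    MwasResult,
    ResidualizedMethylation,
)

P_FLOOR = 1e-300  # underflow guard for two-sided p-values

# median of the 1-df chi-square distribution, for the median-based lambda
_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)


def _aligned(methylation: ResidualizedMethylation, phenotype: AdjustedPhenotype):
    x_ids = methylation.values.index
    if set(x_ids) != set(phenotype.z.index):
        raise ConfigurationError(
            "methylation and phenotype sample sets differ "
            f"({len(x_ids)} vs {len(phenotype.z)} samples)"
        )
    return methylation.values, phenotype.z.loc[x_ids]


def _scan(xc: np.ndarray, sxx: np.ndarray, y: np.ndarray):
    """Vectorized simple OLS of y on each centered probe column.

    Returns (beta, se, t, p) arrays; df = n - 2.
    """
    n = xc.shape[0]
    yc = y - y.mean()
    syy = float(yc @ yc)
    sxy = xc.T @ yc
    beta = sxy / sxx
    rss = np.maximum(syy - sxy * beta, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    p = np.clip(2.0 * stats.t.sf(np.abs(t), n - 2), P_FLOOR, 1.0)
    return beta, se, t, p


def run_mwas(
    methylation: ResidualizedMethylation, phenotype: AdjustedPhenotype
) -> MwasResult:
    """Per-probe OLS of the adjusted trait on each residualized probe."""
    values, z = _aligned(methylation, phenotype)
    n = len(z)
    if n < 10:
        raise ConfigurationError(f"need at least 10 samples, got {n}")
    x = values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    if (sxx == 0).any():
        bad = list(values.columns[sxx == 0][:5])
        raise ConfigurationError(f"constant probes in scan: {bad}")
    beta, se, t, p = _scan(xc, sxx, z.to_numpy(dtype=float))
    table = pd.DataFrame(
        {"beta": beta, "se": se, "t": t, "p": p, "n": n},
        index=values.columns.rename("probe_id"),
    )
    return MwasResult(table, trait=phenotype.trait, covariates=phenotype.adjustment_set)


def chi_square_from_p(p) -> np.ndarray:
    """1-df chi-square quantile of a two-sided p-value."""
    return stats.chi2.isf(np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0), 1)


def genomic_lambda(result: MwasResult, method: str = "mean") -> float:
    """Inflation factor over the scan: mean (canonical here) or median chi-square."""
    if len(result) == 0:
        raise ConfigurationError("empty MWAS result")
    chi2 = chi_square_from_p(result.table["p"].to_numpy())
    if method == "mean":
        return float(chi2.mean())
    if method == "median":
        return float(np.median(chi2) / _CHI2_1_MEDIAN)
    raise ConfigurationError(f"unknown lambda method {method!r}")


def effective_probes(perm_sd: float) -> float:
    """Effective number of independent probes M = 2 / sd(lambda)^2."""
    if not perm_sd > 0:
        raise ConfigurationError("perm_sd must be positive")
    return 2.0 / perm_sd**2


def permutation_lambda(
    methylation: ResidualizedMethylation,
    phenotype: AdjustedPhenotype,
    n_perm: int = 100,
    seed: int = 0,
) -> InflationReport:
    """Null distribution of lambda from seeded phenotype permutations.

    Only the phenotype vector is shuffled; covariate structure was already
    removed from both sides upstream.
    """
    if n_perm < 2:
        raise ConfigurationError("n_perm must be >= 2 for a defined SD")
    values, z = _aligned(methylation, phenotype)
    x = values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    sxx = np.einsum("ij,ij->j", xc, xc)
    y = z.to_numpy(dtype=float)
    _, _, _, p_obs = _scan(xc, sxx, y)
    lambda_observed = float(chi_square_from_p(p_obs).mean())
    rng = np.random.default_rng(seed)
    perm_lambdas = np.empty(n_perm)
    for k in range(n_perm):
        _, _, _, p_k = _scan(xc, sxx, rng.permutation(y))
        perm_lambdas[k] = chi_square_from_p(p_k).mean()
    perm_sd = float(perm_lambdas.std(ddof=1))
    return InflationReport(
        lambda_observed=lambda_observed,
        perm_lambdas=perm_lambdas.tolist(),
        perm_sd=perm_sd,
        m_effective=effective_probes(perm_sd),
        n_permutations=n_perm,
        seed=seed,
    )
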