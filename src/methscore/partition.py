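"""Variance partitioning of a trait over profile scores, and family correction.

Four nested OLS models quantify what the methylation score (model 1), the
genetic score (model 2), both together (model 3) and both plus their
product (model 4) explain of the adjusted trait, as adjusted R-squared.
An F-test of model 4 against model 3 asks whether the interaction adds
signal beyond the additive combination.

For cohorts with related samples, a SNP-derived genetic relationship matrix
(GRM) feeds a one-component linear mixed model y = mu + g + e with
g ~ N(0, sigma_g^2 K); REML is solved exactly by eigendecomposition of K and
a one-dimensional search over the variance ratio.  The trait handed to the
partition step is then y minus the BLUP of g, restandardized.  Off-diagonal
relatedness below 0.05 is zeroed beforehand so that distant relatedness does
not absorb phenotypic variance, and one member of any near-duplicate pair
(GRM off-diagonal > 0.95, i.e. MZ twins or sample duplicates) can be
excluded up front.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .datatypes import (
    AdjustedPhenotype,
    ConfigurationError,
    GenotypeDataset,
    ProfileScore,
    RelatednessMatrix,
    VariancePartition,
)

logger = logging.getLogger(__name__)

RELATEDNESS_CUTOFF = 0.05
MZ_CUTOFF = 0.95


def _as_series(x, name: str) -> pd.Series:
    if isinstance(x, AdjustedPhenotype):
        return x.z.rename(name)
    if isinstance(x, ProfileScore):
        return x.scores.rename(name)
    return pd.Series(x).rename(name)


def fit_partition(trait, mwas_score, gwas_score) -> VariancePartition:
    """Adjusted R-squared of the four nested models plus interaction ANOVA."""
    y = _as_series(trait, "trait")
    s1 = _as_series(mwas_score, "mwas_score")
    s2 = _as_series(gwas_score, "gwas_score")
    if set(y.index) != set(s1.index) or set(y.index) != set(s2.index):
        raise ConfigurationError("trait and score sample sets differ")
    s1, s2 = s1.loc[y.index], s2.loc[y.index]
    n = len(y)
    if n <= 5:
        raise ConfigurationError(f"need more than 5 samples, got {n}")
    r12 = np.corrcoef(s1, s2)[0, 1]
    if abs(r12) > 0.9999:
        raise ConfigurationError(f"scores are collinear (|r| = {abs(r12):.6f})")

    yv = y.to_numpy(dtype=float)
    x1 = sm.add_constant(pd.DataFrame({"mwas_score": s1}))
    x2 = sm.add_constant(pd.DataFrame({"gwas_score": s2}))
    x3 = sm.add_constant(pd.DataFrame({"mwas_score": s1, "gwas_score": s2}))
    x4 = sm.add_constant(
        pd.DataFrame({"mwas_score": s1, "gwas_score": s2, "interaction": s1 * s2})
    )
    m1 = sm.OLS(yv, x1).fit()
    m2 = sm.OLS(yv, x2).fit()
    m3 = sm.OLS(yv, x3).fit()
    m4 = sm.OLS(yv, x4).fit()

    raw = {"mwas": m1.rsquared, "gwas": m2.rsquared, "additive": m3.rsquared,
           "interaction": m4.rsquared}
    # nesting sanity: a submodel can never fit better
    if raw["additive"] < max(raw["mwas"], raw["gwas"]) - 1e-10 or (
        raw["interaction"] < raw["additive"] - 1e-10
    ):
        raise AssertionError("raw R^2 not monotone under model nesting")

    f_num = (m3.ssr - m4.ssr) / (m3.df_resid - m4.df_resid)
    f_stat = f_num / (m4.ssr / m4.df_resid)
    from scipy.stats import f as f_dist

    anova_p = float(f_dist.sf(f_stat, m3.df_resid - m4.df_resid, m4.df_resid))
    return VariancePartition(
        adj_r2_mwas=float(m1.rsquared_adj),
        adj_r2_gwas=float(m2.rsquared_adj),
        adj_r2_additive=float(m3.rsquared_adj),
        adj_r2_interaction=float(m4.rsquared_adj),
        p_mwas_only=float(m1.pvalues["mwas_score"]),
        p_gwas_only=float(m2.pvalues["gwas_score"]),
        p_mwas_in_additive=float(m3.pvalues["mwas_score"]),
        p_gwas_in_additive=float(m3.pvalues["gwas_score"]),
        anova_p_interaction=anova_p,
        n=n,
        raw_r2={k: float(v) for k, v in raw.items()},
    )


# --------------------------------------------------------------------------
# genetic relationship matrix
# --------------------------------------------------------------------------

def compute_grm(genotypes: GenotypeDataset) -> RelatednessMatrix:
    """GCTA-style GRM: A = Z Z' / m with z_ij = (x_ij - 2p_j) / sqrt(2 p_j (1-p_j))."""
    x = genotypes.dosage.to_numpy(dtype=float)
    col_means = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), col_means[np.newaxis, :], x)
    p = x.mean(axis=0) / 2.0
    usable = (p > 0) & (p < 1)
    if not usable.any():
        raise ConfigurationError("all SNPs are monomorphic; GRM undefined")
    n_skipped = int((~usable).sum())
    if n_skipped:
        logger.info("skipped %d monomorphic SNPs in GRM", n_skipped)
    m = int(usable.sum())
    if m < 100:
        logger.warning("only %d usable SNPs; GRM estimates will be noisy", m)
    xs, ps = x[:, usable], p[usable]
    z = (xs - 2 * ps) / np.sqrt(2 * ps * (1 - ps))
    a = (z @ z.T) / m
    return RelatednessMatrix(values=a, sample_ids=genotypes.sample_ids)


def threshold_grm(grm: RelatednessMatrix, cutoff: float = RELATEDNESS_CUTOFF) -> RelatednessMatrix:
    """Zero off-diagonal relatedness strictly below the cutoff; keep the diagonal."""
    a = grm.values.copy()
    off = ~np.eye(a.shape[0], dtype=bool)
    a[off & (a < cutoff)] = 0.0
    return RelatednessMatrix(values=a, sample_ids=list(grm.sample_ids))


def mz_duplicate_filter(grm: RelatednessMatrix, cutoff: float = MZ_CUTOFF) -> list:
    """Sample ids kept after removing one of each near-duplicate pair.

    Pairs with GRM off-diagonal above the cutoff share (nearly) a full
    genome — MZ twins or duplicated samples; the later sample of each pair
    is removed, greedily in index order.
    """
    a = grm.values
    n = a.shape[0]
    removed = np.zeros(n, dtype=bool)
    for i in range(n):
        if removed[i]:
            continue
        for j in range(i + 1, n):
            if not removed[j] and a[i, j] > cutoff:
                removed[j] = True
    kept = [s for s, r in zip(grm.sample_ids, removed) if not r]
    if removed.any():
        logger.info("removed %d near-duplicate samples (GRM > %.2f)", int(removed.sum()), cutoff)
    return kept


# --------------------------------------------------------------------------
# one-component REML and family correction
# --------------------------------------------------------------------------

@dataclass
class RemlResult:
    """One-GRM mixed-model variance components from REML."""

    sigma2_g: float
    sigma2_e: float
    h2: float
    h2_se: float
    loglik: float
    converged: bool


def _reml_profile(log_lam: float, d: np.ndarray, yt: np.ndarray, xt: np.ndarray):
    """Profiled REML log-likelihood at variance ratio lambda = exp(log_lam).

    K = U diag(d) U'; yt, xt are the rotated response and design.
    """
    lam = np.exp(log_lam)
    w = 1.0 / (lam * d + 1.0)
    xtwx = (xt * w) @ xt
    beta = (xt * w) @ yt / xtwx
    r = yt - xt * beta
    rwr = (r * w) @ r
    n, p = len(yt), 1
    ll = -0.5 * ((n - p) * np.log(rwr) + np.log(lam * d + 1.0).sum() + np.log(xtwx))
    return ll, beta, r, w, rwr


def reml_fit(y: np.ndarray, grm: RelatednessMatrix, return_extras: bool = False):
    """REML fit of y = mu + g + e; returns (RemlResult, blup_g).

    Exact for a single GRM: one eigendecomposition plus a bounded 1-D search
    over log(sigma_g^2 / sigma_e^2).  Negative GRM eigenvalues (possible
    after thresholding) are clipped at zero with a warning.
    """
    y = np.asarray(y, dtype=float)
    d, u = np.linalg.eigh(grm.values)
    if d.min() < -1e-8:
        logger.warning("GRM not PSD (min eigenvalue %.3g); clipping at 0", d.min())
    d = np.clip(d, 0.0, None)
    yt = u.T @ y
    xt = u.T @ np.ones_like(y)

    def neg(log_lam):
        return -_reml_profile(log_lam, d, yt, xt)[0]

    opt = minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-8})
    log_lam = float(opt.x)
    ll, beta, r, w, rwr = _reml_profile(log_lam, d, yt, xt)
    lam = np.exp(log_lam)
    n, p = len(y), 1
    sigma2_e = rwr / (n - p)
    sigma2_g = lam * sigma2_e
    h2 = lam / (1.0 + lam)
    at_boundary = log_lam <= -11.9 or log_lam >= 11.9

    # SE of h2 by numerical curvature of the profiled REML in the h2 scale
    h2_se = np.nan
    if not at_boundary:
        eps = 1e-4

        def ll_h2(h):
            h = min(max(h, 1e-10), 1 - 1e-10)
            return _reml_profile(np.log(h / (1.0 - h)), d, yt, xt)[0]

        curv = (ll_h2(h2 + eps) - 2.0 * ll_h2(h2) + ll_h2(h2 - eps)) / eps**2
        if curv < 0:
            h2_se = float(1.0 / np.sqrt(-curv))

    # BLUP of g: shrink the rotated residual by lam*d / (lam*d + 1)
    g_rot = (lam * d) * w * r
    blup = u @ g_rot
    result = RemlResult(
        sigma2_g=float(sigma2_g),
        sigma2_e=float(sigma2_e),
        h2=float(h2),
        h2_se=h2_se,
        loglik=float(ll),
        converged=bool(opt.success) and not at_boundary,
    )
    if return_extras:
        return result, blup, (lam, d, u, yt, xt, beta)
    return result, blup


def family_correct(
    trait: AdjustedPhenotype, grm: RelatednessMatrix, method: str = "whiten"
) -> AdjustedPhenotype:
    """Remove the family (polygenic) component from the trait, restandardized.

    ``method="whiten"`` (default) returns GLS-decorrelated residuals
    V^{-1/2}(y - mu) at the REML variance estimates, which leaves exactly
    zero residual correlation between relatives.  ``method="blup"`` returns
    the classical mixed-model residual y - mu - BLUP(g); note that BLUP
    residuals of relatives are negatively correlated (for a sib pair,
    roughly -sigma_g^2 * relatedness on the standardized scale), because the
    BLUP for each member borrows the other's phenotype.  Both reduce to the
    input when the GRM is the identity (no families): the variance split is
    then unidentifiable, but whitening/BLUP removal become a pure rescaling
    that restandardization undoes.
    """
    ids = list(grm.sample_ids)
    if set(ids) != set(trait.z.index):
        raise ConfigurationError("GRM and trait sample sets differ")
    if method not in ("whiten", "blup"):
        raise ConfigurationError(f"unknown family correction method {method!r}")
    y = trait.z.loc[ids].to_numpy(dtype=float)
    fit, blup, extras = reml_fit(y, grm, return_extras=True)
    if method == "blup":
        resid = y - y.mean() - blup
    else:
        lam, d, u, yt, xt, beta = extras
        w = 1.0 / np.sqrt(lam * d + 1.0)
        resid = u @ (w * (yt - xt * beta))
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ConfigurationError("family correction left a constant phenotype")
    z = pd.Series((resid - resid.mean()) / sd, index=pd.Index(ids, name="sample_id"))
    return AdjustedPhenotype(
        z=z,
        trait=trait.trait,
        adjustment_set=tuple(trait.adjustment_set) + ("family_structure",),
        family_corrected=True,
    )
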