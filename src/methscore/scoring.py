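"""Profile scores: weighted sums over selected CpG probes or SNPs.

The methylation score is computed on the residualized/inverse-normal scale
— the scale the weights were estimated on — so weight and feature agree in
units.  A beta-scale sensitivity variant is available by passing the raw
dataset.  The genetic score counts effect alleles, harmonizing strandless
allele labels against the weights file: a weight whose effect allele equals
the dataset's other allele contributes 2 - dosage; an unmatchable allele
pair drops the SNP with a logged count.  Missing dosages are mean-imputed
per SNP before scoring.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    ConfigurationError,
    GenotypeDataset,
    MethylationDataset,
    ProfileScore,
    ResidualizedMethylation,
    ScoreWeights,
)

logger = logging.getLogger(__name__)


def methylation_score(
    methylation: ResidualizedMethylation | MethylationDataset,
    weights: ScoreWeights,
) -> ProfileScore:
    """score_i = sum_j w_j * m_ij over the weight probes present in the matrix."""
    if isinstance(methylation, MethylationDataset):
        values = methylation.beta  # beta-scale sensitivity path
    else:
        values = methylation.values
    wtab = weights.table[weights.table["feature_kind"] == "cpg"]
    present = wtab.index.intersection(values.columns)
    n_dropped = len(wtab) - len(present)
    if n_dropped:
        logger.warning("%d of %d weight probes absent from methylation matrix", n_dropped, len(wtab))
    if len(present) == 0:
        raise ConfigurationError("no usable probes: weights and methylation share no probe ids")
    w = wtab.loc[present, "weight"].to_numpy(dtype=float)
    scores = values[present].to_numpy(dtype=float) @ w
    return ProfileScore(
        scores=pd.Series(scores, index=values.index, name="methylation_score"),
        feature_kind="cpg",
        n_features_used=len(present),
        n_features_dropped=n_dropped,
        source=weights.source,
    )


def genetic_score(genotypes: GenotypeDataset, weights: ScoreWeights) -> ProfileScore:
    """score_i = sum_j w_j * (effect-allele count)_ij after allele harmonization."""
    wtab = weights.table[weights.table["feature_kind"] == "snp"]
    ann = genotypes.snp_annotation
    used_cols, used_w, flipped, n_dropped = [], [], [], 0
    for snp, row in wtab.iterrows():
        if snp not in genotypes.dosage.columns:
            n_dropped += 1
            continue
        eff = row["effect_allele"]
        if eff == ann.at[snp, "effect_allele"]:
            flip = False
        elif eff == ann.at[snp, "other_allele"]:
            flip = True
        else:
            logger.warning(
                "SNP %s: weights effect allele %s matches neither dataset allele (%s/%s); dropped",
                snp, eff, ann.at[snp, "effect_allele"], ann.at[snp, "other_allele"],
            )
            n_dropped += 1
            continue
        used_cols.append(snp)
        used_w.append(float(row["weight"]))
        flipped.append(flip)
    if n_dropped:
        logger.info("dropped %d of %d weight SNPs during harmonization", n_dropped, len(wtab))
    if not used_cols:
        raise ConfigurationError("no matchable SNPs between weights and genotype data")
    d = genotypes.dosage[used_cols].to_numpy(dtype=float)
    col_means = np.nanmean(d, axis=0)
    nan_mask = np.isnan(d)
    if nan_mask.any():
        d = np.where(nan_mask, col_means[np.newaxis, :], d)
    flip_arr = np.asarray(flipped)
    d = np.where(flip_arr[np.newaxis, :], 2.0 - d, d)
    scores = d @ np.asarray(used_w)
    return ProfileScore(
        scores=pd.Series(scores, index=genotypes.dosage.index, name="genetic_score"),
        feature_kind="snp",
        n_features_used=len(used_cols),
        n_features_dropped=n_dropped,
        source=weights.source,
    )
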