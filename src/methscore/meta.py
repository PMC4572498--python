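"""Fixed-effect inverse-variance meta-analysis of two association scans.

Probes present in both scans are pooled with weights 1/se^2:
beta = sum(w b) / sum(w), se = 1 / sqrt(sum(w)), two-sided normal p.
Probe ids are taken as canonical array identifiers, so no strand or allele
harmonization applies.  Cochran's Q heterogeneity is available behind a
flag but not computed by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigurationError, MetaResult, MwasResult
from .mwas import P_FLOOR
from .selection import bonferroni_threshold

logger = logging.getLogger(__name__)


def fixed_effect_meta(a: MwasResult, b: MwasResult, heterogeneity: bool = False) -> MetaResult:
    """Inverse-variance pooling over the probes common to both scans."""
    common = a.table.index.intersection(b.table.index)
    if len(common) == 0:
        raise ConfigurationError(
            f"no overlapping probes: {len(a.table)} in study A, {len(b.table)} in study B"
        )
    ta, tb = a.table.loc[common], b.table.loc[common]
    wa = 1.0 / ta["se"].to_numpy() ** 2
    wb = 1.0 / tb["se"].to_numpy() ** 2
    wsum = wa + wb
    beta = (wa * ta["beta"].to_numpy() + wb * tb["beta"].to_numpy()) / wsum
    se = 1.0 / np.sqrt(wsum)
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR, 1.0)
    out = pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "p": p,
            "n_total": ta["n"].to_numpy() + tb["n"].to_numpy(),
            "n_studies": 2,
        },
        index=common.rename("probe_id"),
    )
    if heterogeneity:
        q = wa * (ta["beta"].to_numpy() - beta) ** 2 + wb * (tb["beta"].to_numpy() - beta) ** 2
        out["q"] = q
        out["q_p"] = stats.chi2.sf(q, 1)
    logger.info("meta-analysed %d common probes", len(common))
    return MetaResult(out)


def meta_select(meta: MetaResult, alpha: float = 0.05) -> list:
    """Probes passing Bonferroni over the common-probe count; may be empty."""
    threshold = bonferroni_threshold(meta.n_common, alpha)
    passing = meta.table.index[meta.table["p"] < threshold].tolist()
    if not passing:
        logger.warning("no probes pass the meta threshold p < %.3g", threshold)
    return passing
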