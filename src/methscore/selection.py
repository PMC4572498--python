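"""Probe selection: Bonferroni threshold and windowed correlation pruning.

Candidates are probes passing a Bonferroni-corrected p threshold (or an
explicit override, e.g. 1e-3 when the strict threshold yields too few
probes, as happens for traits with weak methylation signal).  Redundant
candidates are removed by a greedy most-significant-first sweep: a
candidate is kept only if no already-kept probe lies within the pruning
window on the same chromosome with absolute Pearson correlation (on the
residualized values) above the threshold.  Kept probes carry their scan
effect size as score weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, MwasResult, ResidualizedMethylation, ScoreWeights

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    alpha: float = 0.05
    p_threshold_override: float | None = None
    prune_window_bp: int = 500
    prune_r: float = 0.1
    window_mode: str = "pairwise"  # "pairwise" distance or fixed genomic "tile"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must lie in (0, 1)")
        if self.p_threshold_override is not None and not (0 < self.p_threshold_override < 1):
            raise ConfigurationError("p_threshold_override must lie in (0, 1)")
        if self.prune_window_bp < 0:
            raise ConfigurationError("prune_window_bp must be nonnegative")
        if self.window_mode not in ("pairwise", "tile"):
            raise ConfigurationError(f"unknown window_mode {self.window_mode!r}")


def bonferroni_threshold(n_probes: int, alpha: float = 0.05) -> float:
    """Per-test threshold alpha / n_probes."""
    if n_probes < 1:
        raise ConfigurationError("n_probes must be >= 1")
    if not (0 < alpha < 1):
        raise ConfigurationError("alpha must lie in (0, 1)")
    return alpha / n_probes


def _in_window(cfg: SelectionConfig, pos_a: int, pos_b: int) -> bool:
    if cfg.prune_window_bp == 0:
        return False  # a zero window contains no pair
    if cfg.window_mode == "pairwise":
        return abs(int(pos_a) - int(pos_b)) <= cfg.prune_window_bp
    return (int(pos_a) - 1) // cfg.prune_window_bp == (int(pos_b) - 1) // cfg.prune_window_bp


def prune_probes(
    results: MwasResult,
    methylation: ResidualizedMethylation,
    config: SelectionConfig | None = None,
) -> ScoreWeights:
    """Greedy pruning of Bonferroni-passing probes to a non-redundant set."""
    config = config or SelectionConfig()
    threshold = config.p_threshold_override
    if threshold is None:
        threshold = bonferroni_threshold(len(results), config.alpha)

    tab = results.table
    missing = tab.index.difference(methylation.values.columns)
    if len(missing):
        raise ConfigurationError(
            f"scan probes absent from methylation matrix: {list(missing[:5])}"
        )
    ann = methylation.probe_annotation
    cand = tab[tab["p"] < threshold].copy()
    cand["chrom"] = ann.loc[cand.index, "chrom"].astype(str)
    cand["pos"] = ann.loc[cand.index, "pos"].astype(int)
    if cand.empty:
        logger.warning("no probes pass p < %.3g; returning empty weights", threshold)
        return ScoreWeights(
            pd.DataFrame(
                {"feature_kind": pd.Series(dtype=str), "weight": pd.Series(dtype=float)},
                index=pd.Index([], name="feature_id"),
            ),
            source="mwas",
        )
    cand = cand.assign(_id=cand.index.astype(str)).sort_values(
        ["p", "chrom", "pos", "_id"], kind="mergesort"
    )
    values = methylation.values
    retained: list[str] = []
    for probe, row in cand.iterrows():
        conflict = False
        x = None
        for kept in retained:
            krow = cand.loc[kept]
            if krow["chrom"] != row["chrom"]:
                continue
            if not _in_window(config, row["pos"], krow["pos"]):
                continue
            if x is None:
                x = values[probe].to_numpy(dtype=float)
            r = np.corrcoef(x, values[kept].to_numpy(dtype=float))[0, 1]
            if abs(r) > config.prune_r:
                conflict = True
                break
        if not conflict:
            retained.append(probe)
    out = pd.DataFrame(
        {"feature_kind": "cpg", "weight": cand.loc[retained, "beta"].to_numpy(dtype=float)},
        index=pd.Index(retained, name="feature_id"),
    )
    logger.info("pruning kept %d of %d candidates (p < %.3g)", len(out), len(cand), threshold)
    return ScoreWeights(out, source="mwas")


def weights_from_candidates(
    candidate_ids, results: MwasResult, source: str = "external"
) -> ScoreWeights:
    """Cross-cohort mode: take an external probe list, pull weights from a scan.

    Supports the design where probes are selected in one study and weighted
    with effect sizes estimated in another; candidates absent from the scan
    are dropped with a logged count.
    """
    ids = pd.Index(pd.unique(pd.Series(list(candidate_ids))))
    present = ids.intersection(results.table.index)
    n_dropped = len(ids) - len(present)
    if n_dropped:
        logger.warning("%d of %d candidate probes absent from the weights scan", n_dropped, len(ids))
    if len(present) == 0:
        raise ConfigurationError("no candidate probes found in the weights scan")
    out = pd.DataFrame(
        {
            "feature_kind": "cpg",
            "weight": results.table.loc[present, "beta"].to_numpy(dtype=float),
        },
        index=pd.Index(present, name="feature_id"),
    )
    return ScoreWeights(out, source=source)
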