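import numpy as np
import pandas as pd
import pytest

import methscore as ms


@pytest.fixture(scope="session")
def small_cohort():
    """One modest cohort with signal, batch effects and cell confounding."""
    cfg = ms.SimulationConfig(
        n_samples=400, n_probes=300, n_snps=200, seed=3,
        batch_effect_sd=0.3, cellcount_confounding=0.3,
    )
    return ms.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """Residualized methylation, adjusted phenotype and MWAS for the cohort."""
    meth, geno, pheno, truth = small_cohort
    rm = ms.preprocess_methylation(meth, pheno)
    adj = ms.adjust_phenotype(pheno, "bmi")
    result = ms.run_mwas(rm, adj)
    return rm, adj, result


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort whose phenotype is independent of all features."""
    cfg = ms.SimulationConfig(
        n_samples=200, n_probes=2000, n_snps=50,
        var_genetic=0.0, var_methylation=0.0,
        n_causal_probes=0, n_causal_snps=0,
        within_block_r=0.0, seed=17,
    )
    return ms.simulate_cohort(cfg)


def make_residualized(values: np.ndarray, positions=None, chrom="1", probe_ids=None,
                      sample_ids=None) -> ms.ResidualizedMethylation:
    """Wrap a plain matrix as analysis-ready methylation for unit tests."""
    n, p = values.shape
    probe_ids = probe_ids or [f"cg{j:06d}" for j in range(p)]
    sample_ids = sample_ids or [f"S{i:04d}" for i in range(n)]
    positions = positions if positions is not None else 1 + 10_000 * np.arange(p)
    ann = pd.DataFrame(
        {"chrom": chrom, "pos": np.asarray(positions, dtype=int),
         "snp_at_target": False, "autosomal": True},
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ms.ResidualizedMethylation(
        values=pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"),
                            columns=probe_ids),
        adjustment_set=("sex", "age"),
        probe_annotation=ann,
    )


def make_phenotype(z: np.ndarray, sample_ids=None, trait="bmi") -> ms.AdjustedPhenotype:
    sample_ids = sample_ids or [f"S{i:04d}" for i in range(len(z))]
    return ms.AdjustedPhenotype(
        z=pd.Series(np.asarray(z, dtype=float), index=pd.Index(sample_ids, name="sample_id")),
        trait=trait,
        adjustment_set=("sex", "age"),
    )
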