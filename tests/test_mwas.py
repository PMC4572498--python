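"""Association scan, inflation lambda and permutation-based effective probes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methscore as ms
from methscore.datatypes import ConfigurationError

from conftest import make_phenotype, make_residualized


def _hand_ols(x, y):
    """Textbook simple-OLS oracle: slope, SE, t, two-sided p at n-2 df."""
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    beta = (xc @ yc) / (xc @ xc)
    rss = ((yc - beta * xc) ** 2).sum()
    se = np.sqrt(rss / (n - 2) / (xc @ xc))
    t = beta / se
    p = 2 * stats.t.sf(abs(t), n - 2)
    return beta, se, t, p


def test_scan_matches_hand_ols_on_worked_fixture():
    x = np.array(
        [[1.2, -0.3], [0.4, 0.8], [-0.9, 1.5], [0.1, -1.1], [-0.8, -0.9],
         [2.0, 0.2], [-1.4, 0.6], [0.3, -2.0], [0.9, 1.1], [-0.5, 0.4]]
    )
    y = np.array([0.7, -0.2, -1.3, 0.5, -0.6, 1.9, -1.1, 0.4, 1.0, -0.3])
    rm = make_residualized(x)
    result = ms.run_mwas(rm, make_phenotype(y))
    for j, probe in enumerate(rm.probe_ids):
        beta, se, t, p = _hand_ols(x[:, j], y)
        row = result.table.loc[probe]
        assert row["beta"] == pytest.approx(beta, rel=1e-12)
        assert row["se"] == pytest.approx(se, rel=1e-12)
        assert row["t"] == pytest.approx(t, rel=1e-12)
        assert row["p"] == pytest.approx(p, rel=1e-12)
        assert row["n"] == 10


def test_p_consistent_with_t_at_n_minus_2_df(small_pipeline):
    _, _, result = small_pipeline
    t = result.table["t"].to_numpy()
    n = int(result.table["n"].iloc[0])
    expected = 2 * stats.t.sf(np.abs(t), n - 2)
    np.testing.assert_allclose(result.table["p"].to_numpy(), expected, atol=1e-10)


def test_perfect_association_hits_p_floor():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(50, 3))
    y = x[:, 1].copy()
    result = ms.run_mwas(make_residualized(x), make_phenotype(y))
    row = result.table.iloc[1]
    assert row["beta"] == pytest.approx(1.0, abs=1e-12)
    assert row["p"] == pytest.approx(1e-300)  # underflow-guarded minimum, never zero


def test_null_pvalues_uniform(null_cohort):
    meth, _, pheno, _ = null_cohort
    rm = ms.preprocess_methylation(meth, pheno)
    adj = ms.adjust_phenotype(pheno, "bmi")
    result = ms.run_mwas(rm, adj)
    p = result.table["p"].to_numpy()
    n_probes = len(p)
    ks = stats.kstest(p, "uniform").statistic
    assert ks < 1.63 / np.sqrt(n_probes)  # alpha = 0.01 critical value


def test_sample_misalignment_rejected():
    rng = np.random.default_rng(1)
    rm = make_residualized(rng.normal(size=(20, 2)))
    z = make_phenotype(rng.normal(size=20), sample_ids=[f"X{i}" for i in range(20)])
    with pytest.raises(ConfigurationError, match="sample sets differ"):
        ms.run_mwas(rm, z)


def test_too_few_samples_rejected():
    rng = np.random.default_rng(2)
    rm = make_residualized(rng.normal(size=(5, 2)))
    with pytest.raises(ConfigurationError, match="at least 10"):
        ms.run_mwas(rm, make_phenotype(rng.normal(size=5)))


def _result_from_chi2(chi2_values):
    p = stats.chi2.sf(np.asarray(chi2_values, dtype=float), 1)
    table = pd.DataFrame(
        {"beta": 0.0, "se": 1.0, "t": np.sqrt(chi2_values), "p": p, "n": 1000},
        index=pd.Index([f"cg{i}" for i in range(len(p))], name="probe_id"),
    )
    return ms.MwasResult(table)


def test_lambda_of_unit_chi2_is_one():
    result = _result_from_chi2([1.0] * 7)
    assert ms.genomic_lambda(result) == pytest.approx(1.0, abs=1e-10)


def test_lambda_is_the_mean_chi2():
    result = _result_from_chi2([0.0, 2.0])
    assert ms.genomic_lambda(result) == pytest.approx(1.0, abs=1e-10)
    result2 = _result_from_chi2([1.0, 2.0, 6.0])
    assert ms.genomic_lambda(result2) == pytest.approx(3.0, abs=1e-10)


def test_median_lambda_variant():
    result = _result_from_chi2([0.1, stats.chi2.ppf(0.5, 1), 9.0])
    assert ms.genomic_lambda(result, method="median") == pytest.approx(1.0, abs=1e-10)


def test_lambda_invariant_to_probe_order(small_pipeline):
    _, _, result = small_pipeline
    shuffled = ms.MwasResult(result.table.sample(frac=1, random_state=0))
    assert ms.genomic_lambda(shuffled) == pytest.approx(ms.genomic_lambda(result), abs=1e-12)


def test_null_lambda_near_one(null_cohort):
    meth, _, pheno, _ = null_cohort
    rm = ms.preprocess_methylation(meth, pheno)
    adj = ms.adjust_phenotype(pheno, "bmi")
    lam = ms.genomic_lambda(ms.run_mwas(rm, adj))
    m_true = len(rm.probe_ids)  # independent probes by construction
    assert abs(lam - 1.0) < 3 * np.sqrt(2.0 / m_true)


@pytest.mark.parametrize("sd,expected", [(0.1, 200.0), (np.sqrt(2), 1.0), (0.05, 800.0)])
def test_effective_probes_identity(sd, expected):
    assert ms.effective_probes(sd) == pytest.approx(expected, rel=1e-12)


def test_effective_probes_requires_positive_sd():
    with pytest.raises(ConfigurationError):
        ms.effective_probes(0.0)


def test_permutation_requires_two_or_more(small_pipeline):
    rm, adj, _ = small_pipeline
    with pytest.raises(ConfigurationError, match="n_perm"):
        ms.permutation_lambda(rm, adj, n_perm=1)


def test_chunked_scan_equals_unchunked(small_pipeline):
    rm, adj, result = small_pipeline
    halves = []
    cols = list(rm.values.columns)
    for chunk in (cols[:100], cols[100:]):
        sub = ms.ResidualizedMethylation(
            values=rm.values[chunk], adjustment_set=rm.adjustment_set,
            probe_annotation=rm.probe_annotation.loc[chunk])
        halves.append(ms.run_mwas(sub, adj).table)
    combined = pd.concat(halves)
    pd.testing.assert_frame_equal(combined, result.table, check_exact=True)


def test_effective_probes_recovered_for_independent_probes():
    """With P independent probes, permutation spread implies M close to P."""
    cfg = ms.SimulationConfig(n_samples=400, n_probes=1000, n_snps=20,
                              var_genetic=0, var_methylation=0,
                              n_causal_probes=0, n_causal_snps=0,
                              within_block_r=0.0, seed=5)
    meth, _, pheno, _ = ms.simulate_cohort(cfg)
    rm = ms.preprocess_methylation(meth, pheno)
    adj = ms.adjust_phenotype(pheno, "bmi")
    report = ms.permutation_lambda(rm, adj, n_perm=200, seed=5)
    assert 1000 / 1.5 < report.m_effective < 1000 * 1.5
    assert report.m_effective == pytest.approx(2.0 / report.perm_sd**2, rel=1e-12)
    # under the null the permutation lambdas centre on 1
    mean_lam = np.mean(report.perm_lambdas)
    assert abs(mean_lam - 1.0) < 3 * report.perm_sd / np.sqrt(report.n_permutations)


def test_effective_probes_shrink_with_block_correlation():
    m_eff = {}
    for r in (0.0, 0.5, 0.9):
        cfg = ms.SimulationConfig(n_samples=300, n_probes=500, n_snps=20,
                                  var_genetic=0, var_methylation=0,
                                  n_causal_probes=0, n_causal_snps=0,
                                  within_block_r=r, probes_per_block=5, seed=7)
        meth, _, pheno, _ = ms.simulate_cohort(cfg)
        rm = ms.preprocess_methylation(meth, pheno)
        adj = ms.adjust_phenotype(pheno, "bmi")
        m_eff[r] = ms.permutation_lambda(rm, adj, n_perm=100, seed=7).m_effective
    assert m_eff[0.0] > m_eff[0.5] > m_eff[0.9]
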