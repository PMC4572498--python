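"""Nested-model variance partition, GRM estimation and REML family correction."""

import numpy as np
import pandas as pd
import pytest

import methscore as ms
from methscore.datatypes import ConfigurationError

from conftest import make_phenotype


def _score(values, name, ids=None):
    ids = ids or [f"S{i:04d}" for i in range(len(values))]
    return pd.Series(np.asarray(values, dtype=float),
                     index=pd.Index(ids, name="sample_id"), name=name)


def test_trait_identical_to_score_gives_full_r2():
    rng = np.random.default_rng(0)
    s1 = rng.normal(size=100)
    s2 = rng.normal(size=100)
    vp = ms.fit_partition(make_phenotype(s1, sample_ids=[f"S{i:04d}" for i in range(100)]),
                          _score(s1, "m"), _score(s2, "g"))
    assert vp.adj_r2_mwas == pytest.approx(1.0, abs=1e-10)
    assert vp.adj_r2_additive == pytest.approx(1.0, abs=1e-10)
    assert vp.p_mwas_only < 1e-100


def test_noise_scores_centre_on_zero_and_may_be_negative():
    rng = np.random.default_rng(1)
    vals = []
    for _ in range(60):
        y = rng.normal(size=100)
        vp = ms.fit_partition(
            make_phenotype(y, sample_ids=[f"S{i:04d}" for i in range(100)]),
            _score(rng.normal(size=100), "m"), _score(rng.normal(size=100), "g"))
        vals.append(vp.adj_r2_mwas)
    vals = np.asarray(vals)
    assert vals.min() < 0  # negative adjusted R^2 is reported as-is
    assert abs(vals.mean()) < 0.01


def test_adjusted_r2_formula_and_nesting():
    rng = np.random.default_rng(2)
    n = 200
    s1, s2 = rng.normal(size=n), rng.normal(size=n)
    y = 0.3 * s1 + 0.2 * s2 + rng.normal(size=n)
    vp = ms.fit_partition(make_phenotype(y, sample_ids=[f"S{i:04d}" for i in range(n)]),
                          _score(s1, "m"), _score(s2, "g"))
    raw = vp.raw_r2
    assert raw["additive"] >= max(raw["mwas"], raw["gwas"]) - 1e-12
    assert raw["interaction"] >= raw["additive"] - 1e-12
    # adjusted R^2 = 1 - (1-R^2)(n-1)/(n-k-1)
    assert vp.adj_r2_additive == pytest.approx(
        1 - (1 - raw["additive"]) * (n - 1) / (n - 2 - 1), abs=1e-12)
    assert vp.adj_r2_mwas == pytest.approx(
        1 - (1 - raw["mwas"]) * (n - 1) / (n - 1 - 1), abs=1e-12)


def test_partition_invariant_to_affine_score_rescaling():
    rng = np.random.default_rng(3)
    n = 150
    s1, s2 = rng.normal(size=n), rng.normal(size=n)
    y = 0.4 * s1 - 0.3 * s2 + 0.2 * s1 * s2 + rng.normal(size=n)
    ids = [f"S{i:04d}" for i in range(n)]
    ph = make_phenotype(y, sample_ids=ids)
    a = ms.fit_partition(ph, _score(s1, "m", ids), _score(s2, "g", ids))
    b = ms.fit_partition(ph, _score(10 * s1 + 3, "m", ids), _score(-0.5 * s2 + 1, "g", ids))
    for attr in ("adj_r2_mwas", "adj_r2_gwas", "adj_r2_additive", "adj_r2_interaction",
                 "anova_p_interaction", "p_mwas_in_additive", "p_gwas_in_additive"):
        assert getattr(a, attr) == pytest.approx(getattr(b, attr), abs=1e-10)


def test_collinear_scores_rejected():
    rng = np.random.default_rng(4)
    s = rng.normal(size=50)
    ids = [f"S{i:04d}" for i in range(50)]
    with pytest.raises(ConfigurationError, match="collinear"):
        ms.fit_partition(make_phenotype(rng.normal(size=50), sample_ids=ids),
                         _score(s, "m", ids), _score(2 * s + 1, "g", ids))


def test_additive_components_recovered():
    cfg = ms.SimulationConfig(n_samples=1500, n_probes=250, n_snps=100,
                              var_genetic=0.08, var_methylation=0.07,
                              n_causal_probes=10, n_causal_snps=20, seed=40)
    meth, geno, pheno, truth = ms.simulate_cohort(cfg)
    rm = ms.preprocess_methylation(meth, pheno)
    adj = ms.adjust_phenotype(pheno, "bmi")
    w_cpg = pd.DataFrame({"feature_kind": "cpg", "weight": truth.true_probe_effects},
                         index=pd.Index(truth.causal_probe_ids, name="feature_id"))
    s1 = ms.methylation_score(rm, ms.ScoreWeights(w_cpg, source="truth"))
    w_snp = pd.DataFrame(
        {"feature_kind": "snp", "weight": truth.true_snp_effects,
         "effect_allele": geno.snp_annotation.loc[truth.causal_snp_ids, "effect_allele"]},
        index=pd.Index(truth.causal_snp_ids, name="feature_id"))
    s2 = ms.genetic_score(geno, ms.ScoreWeights(w_snp, source="truth"))
    vp = ms.fit_partition(adj, s1, s2)
    assert vp.adj_r2_mwas == pytest.approx(0.07, abs=0.03)
    assert vp.adj_r2_gwas == pytest.approx(0.08, abs=0.03)
    assert vp.adj_r2_additive == pytest.approx(0.15, abs=0.04)
    assert vp.p_mwas_in_additive < 0.05 and vp.p_gwas_in_additive < 0.05


# ----------------------------------------------------------------------
# GRM
# ----------------------------------------------------------------------

def test_grm_single_het_snp_contributes_zero():
    geno = ms.GenotypeDataset(
        dosage=pd.DataFrame([[1.0], [1.0]], index=pd.Index(["S1", "S2"]), columns=["rs1"]),
        snp_annotation=pd.DataFrame(
            {"chrom": "1", "pos": [100], "effect_allele": ["G"], "other_allele": ["A"]},
            index=pd.Index(["rs1"])))
    grm = ms.compute_grm(geno)
    assert grm.values[0, 1] == pytest.approx(0.0, abs=1e-12)


def test_grm_duplicated_sample_near_one():
    cfg = ms.SimulationConfig(n_samples=100, n_probes=20, n_snps=5000,
                              family_structure="mz_pairs", seed=50,
                              n_causal_probes=2, n_causal_snps=10)
    _, geno, _, _ = ms.simulate_cohort(cfg)
    grm = ms.compute_grm(geno)
    dups = np.array([grm.values[k, k + 1] for k in range(0, 100, 2)])
    for k in range(0, 100, 2):
        # identical genotype rows make the off-diagonal equal the diagonal
        assert grm.values[k, k + 1] == pytest.approx(grm.values[k, k], abs=1e-9)
    # each entry is a mean of m standardized-genotype squares: E = 1,
    # per-pair SD ~ sqrt((E[z^4]-1)/m) ~ 0.025 at m = 5000
    assert abs(dups.mean() - 1.0) < 0.02
    assert np.abs(dups - 1.0).max() < 0.15


def test_grm_unrelated_off_diagonals_small():
    cfg = ms.SimulationConfig(n_samples=80, n_probes=20, n_snps=4000, seed=51,
                              n_causal_probes=2, n_causal_snps=10)
    _, geno, _, _ = ms.simulate_cohort(cfg)
    a = ms.compute_grm(geno).values
    off = a[~np.eye(80, dtype=bool)]
    assert np.abs(off).mean() < 2 / np.sqrt(4000)
    assert np.abs(off).max() < 8 / np.sqrt(4000)


def test_grm_all_monomorphic_rejected():
    geno = ms.GenotypeDataset(
        dosage=pd.DataFrame(np.zeros((5, 3)), index=pd.Index([f"S{i}" for i in range(5)]),
                            columns=["a", "b", "c"]),
        snp_annotation=pd.DataFrame(
            {"chrom": "1", "pos": [1, 2, 3], "effect_allele": list("GGG"),
             "other_allele": list("AAA")}, index=pd.Index(["a", "b", "c"])))
    with pytest.raises(ConfigurationError, match="monomorphic"):
        ms.compute_grm(geno)


def test_threshold_grm_boundary_is_strict():
    a = np.array([[1.0, 0.049, 0.05], [0.049, 1.0, 0.2], [0.05, 0.2, 1.0]])
    grm = ms.RelatednessMatrix(a, ["S1", "S2", "S3"])
    out = ms.threshold_grm(grm, cutoff=0.05)
    assert out.values[0, 1] == 0.0          # 0.049 < 0.05 -> zeroed
    assert out.values[0, 2] == 0.05         # exactly 0.05 retained
    assert out.values[1, 2] == 0.2
    np.testing.assert_array_equal(np.diag(out.values), np.diag(a))
    ident = ms.threshold_grm(ms.RelatednessMatrix(np.eye(4), list("abcd")))
    np.testing.assert_array_equal(ident.values, np.eye(4))


def test_mz_filter_removes_exactly_one_per_pair():
    # enough SNPs that duplicate-pair GRM entries sit safely above the
    # 0.95 cutoff (per-entry SD shrinks as 1/sqrt(m))
    cfg = ms.SimulationConfig(n_samples=60, n_probes=20, n_snps=30000,
                              family_structure="mz_pairs", seed=52,
                              n_causal_probes=2, n_causal_snps=10)
    _, geno, _, _ = ms.simulate_cohort(cfg)
    grm = ms.compute_grm(geno)
    kept = ms.mz_duplicate_filter(grm)
    assert len(kept) == 60 - 30


# ----------------------------------------------------------------------
# REML family correction
# ----------------------------------------------------------------------

def test_identity_grm_leaves_phenotype_unchanged():
    rng = np.random.default_rng(5)
    ids = [f"S{i:04d}" for i in range(80)]
    z = rng.normal(size=80)
    ph = make_phenotype(z, sample_ids=ids)
    out = ms.family_correct(ph, ms.RelatednessMatrix(np.eye(80), ids))
    expected = (z - z.mean()) / z.std(ddof=1)
    np.testing.assert_allclose(out.z.to_numpy(), expected, atol=1e-10)
    assert out.family_corrected


def test_reml_recovers_sib_pair_heritability():
    cfg = ms.SimulationConfig(n_samples=600, n_probes=30, n_snps=1000,
                              var_genetic=0.5, var_methylation=0.0,
                              n_causal_probes=0, n_causal_snps=1000,
                              family_structure="sib_pairs", seed=53)
    _, geno, pheno, _ = ms.simulate_cohort(cfg)
    adj = ms.adjust_phenotype(pheno, "bmi")
    grm = ms.threshold_grm(ms.compute_grm(geno))
    fit, _ = ms.reml_fit(adj.z.to_numpy(), grm)
    assert fit.converged
    assert abs(fit.h2 - 0.5) < 3 * fit.h2_se


def test_family_correction_removes_within_family_correlation():
    cfg = ms.SimulationConfig(n_samples=400, n_probes=30, n_snps=1000,
                              var_genetic=0.5, var_methylation=0.0,
                              n_causal_probes=0, n_causal_snps=1000,
                              family_structure="sib_pairs", seed=54)
    _, geno, pheno, truth = ms.simulate_cohort(cfg)
    adj = ms.adjust_phenotype(pheno, "bmi")
    grm = ms.threshold_grm(ms.compute_grm(geno))

    def pair_icc(z):
        fam = pd.Series(truth.family_assignments)
        df = pd.DataFrame({"z": z, "fam": fam.loc[z.index]})
        sizes = df.groupby("fam").size()
        pairs = df[df["fam"].isin(sizes[sizes == 2].index)]
        a = pairs.groupby("fam")["z"].first()
        b = pairs.groupby("fam")["z"].last()
        return np.corrcoef(a, b)[0, 1]

    assert pair_icc(adj.z) > 0.1  # families are genuinely correlated before
    corrected = ms.family_correct(adj, grm)
    assert abs(pair_icc(corrected.z)) < 0.1


def test_blup_residual_variant_available():
    rng = np.random.default_rng(6)
    ids = [f"S{i:04d}" for i in range(60)]
    ph = make_phenotype(rng.normal(size=60), sample_ids=ids)
    grm = ms.RelatednessMatrix(np.eye(60), ids)
    out = ms.family_correct(ph, grm, method="blup")
    assert out.z.std(ddof=1) == pytest.approx(1.0)
    with pytest.raises(ConfigurationError):
        ms.family_correct(ph, grm, method="other")
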