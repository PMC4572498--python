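"""Synthetic cohorts with the structure the scoring pipeline assumes.

The generator emulates a blood-methylation cohort: CpG probes arranged in
correlated blocks along one synthetic chromosome, SNP genotypes in
Hardy-Weinberg proportions, and a quantitative trait (BMI or height) built
from a polygenic component, a methylation-linked component and residual
noise at configurable variance fractions.  Optional layers add cell-count
confounding, plate/array batch shifts and family structure (trios, sib
pairs, MZ twin pairs) with Mendelian genotype transmission.

Every cohort carries a :class:`SyntheticTruth` recording the causal features,
their effects and the realized variance fractions, so downstream estimators
can be tested for parameter recovery rather than just for running.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import (
    CELL_COUNT_COLUMNS,
    ConfigurationError,
    GenotypeDataset,
    MethylationDataset,
    PhenotypeTable,
)

# block starts are spaced far enough apart that probes in different blocks
# can never fall inside the same pruning window
_BLOCK_GAP_FACTOR = 10

_TRAIT_PARAMS = {
    # intercept, per-unit sex effect, per-year age effect, residual SD
    "bmi": dict(intercept=23.0, sex_effect=1.0, age_effect=0.05, resid_sd=4.2),
    "height": dict(intercept=170.0, sex_effect=-12.0, age_effect=-0.05, resid_sd=6.5),
}

# baseline mean and SD for the five blood cell counts (10^9 cells/L)
_CELL_PARAMS = {
    "lymphocytes": (2.0, 0.5),
    "monocytes": (0.5, 0.15),
    "neutrophils": (4.0, 1.2),
    "eosinophils": (0.2, 0.1),
    "basophils": (0.05, 0.03),
}


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic cohort.

    Defaults describe a modest adult cohort: 750 samples (a typical
    single-cohort analysis size), probes in blocks of 5 spanning at most
    500 bp with within-block correlation 0.5, and genetic / methylation
    variance fractions of 0.08 / 0.07 on the covariate-adjusted trait.
    """

    n_samples: int = 750
    n_probes: int = 2000
    n_snps: int = 500
    block_size_bp: int = 500
    probes_per_block: int = 5
    within_block_r: float = 0.5
    var_genetic: float = 0.08
    var_methylation: float = 0.07
    n_causal_probes: int = 10
    n_causal_snps: int = 20
    family_structure: str = "unrelated"  # unrelated | trios | sib_pairs | mz_pairs
    cellcount_confounding: float = 0.0
    batch_effect_sd: float = 0.0
    meqtl_effect: float = 0.0
    trait: str = "bmi"
    mean_age: float = 45.5
    sd_age: float = 13.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_blocks(self) -> int:
        return int(np.ceil(self.n_probes / self.probes_per_block))

    def validate(self) -> None:
        if min(self.n_samples, self.n_probes, self.n_snps) <= 0:
            raise ConfigurationError("sample, probe and SNP counts must be positive")
        if self.probes_per_block < 1:
            raise ConfigurationError("probes_per_block must be >= 1")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ConfigurationError("within_block_r must lie in [0, 1)")
        if self.var_genetic < 0 or self.var_methylation < 0:
            raise ConfigurationError("variance fractions must be nonnegative")
        if self.var_genetic + self.var_methylation > 1.0:
            raise ConfigurationError(
                f"var_genetic + var_methylation = "
                f"{self.var_genetic + self.var_methylation} exceeds 1"
            )
        if self.n_causal_probes > self.n_probes:
            raise ConfigurationError("n_causal_probes exceeds n_probes")
        if self.n_causal_probes > self.n_blocks:
            raise ConfigurationError(
                "causal probes are placed one per block; n_causal_probes "
                f"({self.n_causal_probes}) exceeds the number of blocks ({self.n_blocks})"
            )
        if self.n_causal_snps > self.n_snps:
            raise ConfigurationError("n_causal_snps exceeds n_snps")
        if self.family_structure not in ("unrelated", "trios", "sib_pairs", "mz_pairs"):
            raise ConfigurationError(f"unknown family_structure {self.family_structure!r}")
        if self.batch_effect_sd < 0:
            raise ConfigurationError("batch_effect_sd must be nonnegative")
        if self.trait not in _TRAIT_PARAMS:
            raise ConfigurationError(f"unknown trait {self.trait!r}")


@dataclass
class SyntheticTruth:
    """Ground truth attached to a simulated cohort for recovery tests."""

    causal_probe_ids: list
    causal_snp_ids: list
    true_probe_effects: np.ndarray
    true_snp_effects: np.ndarray
    realized_var_genetic: float
    realized_var_methylation: float
    family_assignments: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "causal_probe_ids": list(self.causal_probe_ids),
            "causal_snp_ids": list(self.causal_snp_ids),
            "true_probe_effects": np.asarray(self.true_probe_effects).tolist(),
            "true_snp_effects": np.asarray(self.true_snp_effects).tolist(),
            "realized_var_genetic": float(self.realized_var_genetic),
            "realized_var_methylation": float(self.realized_var_methylation),
            "family_assignments": dict(self.family_assignments),
        }


def _mendelian_child(rng: np.random.Generator, father: np.ndarray, mother: np.ndarray) -> np.ndarray:
    """One offspring genotype row: one allele transmitted per parent."""
    a = rng.random(father.shape) < father / 2.0
    b = rng.random(mother.shape) < mother / 2.0
    return (a.astype(np.int8) + b.astype(np.int8))


def _simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator):
    """Genotype matrix, per-SNP MAFs and the sample->family map."""
    mafs = rng.uniform(0.05, 0.5, cfg.n_snps)
    n = cfg.n_samples

    def founders(k: int) -> np.ndarray:
        return rng.binomial(2, mafs, size=(k, cfg.n_snps)).astype(np.int8)

    families: dict[int, str] = {}
    if cfg.family_structure == "unrelated":
        geno = founders(n)
        for i in range(n):
            families[i] = f"F{i + 1:05d}"
    elif cfg.family_structure == "mz_pairs":
        n_pairs = n // 2
        pair_geno = founders(n_pairs + n % 2)
        rows, fam_idx = [], 0
        for p in range(n_pairs):
            rows.extend([pair_geno[p], pair_geno[p]])
            families[2 * p] = families[2 * p + 1] = f"F{p + 1:05d}"
            fam_idx = p + 1
        if n % 2:
            rows.append(pair_geno[n_pairs])
            families[n - 1] = f"F{fam_idx + 1:05d}"
        geno = np.vstack(rows)
    elif cfg.family_structure == "sib_pairs":
        n_pairs = n // 2
        rows = []
        for p in range(n_pairs):
            father, mother = founders(2)
            rows.append(_mendelian_child(rng, father, mother))
            rows.append(_mendelian_child(rng, father, mother))
            families[2 * p] = families[2 * p + 1] = f"F{p + 1:05d}"
        if n % 2:
            rows.append(founders(1)[0])
            families[n - 1] = f"F{n_pairs + 1:05d}"
        geno = np.vstack(rows)
    else:  # trios: father, mother, child
        rows, i, fam = [], 0, 0
        while i < n:
            fam += 1
            father, mother = founders(2)
            for g in (father, mother, _mendelian_child(rng, father, mother))[: n - i]:
                rows.append(g)
                families[i] = f"F{fam:05d}"
                i += 1
        geno = np.vstack(rows)
    return geno.astype(np.int8), mafs, families


def _rescale_to_variance(x: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale a component so its sample variance equals target_var exactly."""
    v = x.var(ddof=1)
    if target_var == 0 or v == 0:
        return np.zeros_like(x)
    return x * np.sqrt(target_var / v)


def simulate_cohort(cfg: SimulationConfig):
    """Generate one cohort.

    Returns ``(methylation, genotypes, phenotypes, truth)``.  The same config
    (including seed) always returns bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"S{i + 1:05d}" for i in range(n)]

    # --- genotypes -------------------------------------------------------
    geno, mafs, fam_idx = _simulate_genotypes(cfg, rng)
    snp_ids = [f"snp{j + 1:06d}" for j in range(cfg.n_snps)]
    allele_pairs = np.array([["A", "G"], ["C", "T"], ["G", "A"], ["T", "C"]])
    pair_choice = rng.integers(0, 4, cfg.n_snps)
    snp_annotation = pd.DataFrame(
        {
            "chrom": "1",
            "pos": 2_000_000 + 1_000 * np.arange(cfg.n_snps),
            "effect_allele": allele_pairs[pair_choice, 1],
            "other_allele": allele_pairs[pair_choice, 0],
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )

    # --- probe placement -------------------------------------------------
    n_blocks = cfg.n_blocks
    block_of = np.arange(cfg.n_probes) // cfg.probes_per_block
    within = np.arange(cfg.n_probes) % cfg.probes_per_block
    span = max(cfg.probes_per_block - 1, 1)
    stride = cfg.block_size_bp * _BLOCK_GAP_FACTOR
    pos = 1 + block_of * stride + (within * cfg.block_size_bp) // span
    probe_ids = [f"cg{j + 1:08d}" for j in range(cfg.n_probes)]
    probe_annotation = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos.astype(np.int64),
            "snp_at_target": False,
            "autosomal": True,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    # --- latent methylation: shared block factor gives equicorrelation ---
    r = cfg.within_block_r
    block_factor = rng.standard_normal((n, n_blocks))
    latent = np.sqrt(r) * block_factor[:, block_of] + np.sqrt(1.0 - r) * rng.standard_normal(
        (n, cfg.n_probes)
    )

    # meQTL layer: each causal SNP (cycled) pushes on one random probe
    if cfg.meqtl_effect != 0.0 and cfg.n_causal_snps > 0:
        targets = rng.choice(cfg.n_probes, size=cfg.n_causal_snps, replace=False)
        snp_for = rng.choice(cfg.n_snps, size=cfg.n_causal_snps, replace=False)
        for t, s in zip(targets, snp_for):
            d = geno[:, s].astype(float)
            latent[:, t] += cfg.meqtl_effect * (d - d.mean())

    # --- phenotype components -------------------------------------------
    causal_blocks = rng.choice(n_blocks, size=cfg.n_causal_probes, replace=False)
    causal_probes = np.sort(causal_blocks * cfg.probes_per_block)
    causal_probes = causal_probes[causal_probes < cfg.n_probes]
    probe_w = rng.standard_normal(len(causal_probes))
    m_raw = latent[:, causal_probes] @ probe_w if len(causal_probes) else np.zeros(n)
    # rescale effects so the component hits the target sample variance exactly
    s_m = np.sqrt(cfg.var_methylation / m_raw.var(ddof=1)) if m_raw.var(ddof=1) > 0 else 0.0
    probe_w, m_comp = probe_w * s_m, m_raw * s_m

    causal_snps = np.sort(rng.choice(cfg.n_snps, size=cfg.n_causal_snps, replace=False))
    snp_w = rng.standard_normal(len(causal_snps))
    geno_c = geno[:, causal_snps].astype(float)
    g_raw = (geno_c - geno_c.mean(axis=0)) @ snp_w if len(causal_snps) else np.zeros(n)
    s_g = np.sqrt(cfg.var_genetic / g_raw.var(ddof=1)) if g_raw.var(ddof=1) > 0 else 0.0
    snp_w, g_comp = snp_w * s_g, g_raw * s_g

    resid_frac = 1.0 - cfg.var_genetic - cfg.var_methylation
    e_comp = _rescale_to_variance(rng.standard_normal(n), resid_frac)
    y_z = g_comp + m_comp + e_comp
    var_y = y_z.var(ddof=1)
    truth = SyntheticTruth(
        causal_probe_ids=[probe_ids[j] for j in causal_probes],
        causal_snp_ids=[snp_ids[j] for j in causal_snps],
        true_probe_effects=probe_w,
        true_snp_effects=snp_w,
        realized_var_genetic=float(g_comp.var(ddof=1) / var_y) if var_y > 0 else 0.0,
        realized_var_methylation=float(m_comp.var(ddof=1) / var_y) if var_y > 0 else 0.0,
        family_assignments={sample_ids[i]: f for i, f in fam_idx.items()},
    )

    # --- covariates, trait on its natural scale -------------------------
    sex = rng.integers(0, 2, n)
    age = np.clip(rng.normal(cfg.mean_age, cfg.sd_age, n), 18.0, None)
    tp = _TRAIT_PARAMS[cfg.trait]
    trait = tp["intercept"] + tp["sex_effect"] * sex + tp["age_effect"] * age + tp["resid_sd"] * y_z

    # --- technical layout + batch shifts on the latent scale -------------
    plate = np.arange(n) // 96
    array = np.arange(n) // 12
    array_position = np.arange(n) % 12 + 1
    noisy = latent
    if cfg.batch_effect_sd > 0:
        plate_shift = rng.normal(0.0, cfg.batch_effect_sd, (plate.max() + 1, cfg.n_probes))
        array_shift = rng.normal(0.0, cfg.batch_effect_sd / 2.0, (array.max() + 1, cfg.n_probes))
        noisy = latent + plate_shift[plate] + array_shift[array]

    # probe-specific baseline methylation level, then squash to (0, 1)
    mu = rng.normal(0.0, 1.5, cfg.n_probes)
    beta = expit(mu + noisy)

    # --- cell counts correlated with the trait ---------------------------
    cells = {}
    for name, (mean_c, sd_c) in _CELL_PARAMS.items():
        base = rng.normal(mean_c, sd_c, n)
        cells[name] = np.clip(base + cfg.cellcount_confounding * sd_c * y_z, 0.0, None)

    pheno = pd.DataFrame(
        {
            cfg.trait: trait,
            "sex": sex,
            "age": age,
            **cells,
            "plate": [f"P{p + 1:03d}" for p in plate],
            "array": [f"A{a + 1:04d}" for a in array],
            "array_position": array_position,
            "family_id": [truth.family_assignments[s] for s in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    methylation = MethylationDataset(
        beta=pd.DataFrame(beta, index=pd.Index(sample_ids, name="sample_id"), columns=probe_ids),
        probe_annotation=probe_annotation,
    )
    genotypes = GenotypeDataset(
        dosage=pd.DataFrame(
            geno.astype(float), index=pd.Index(sample_ids, name="sample_id"), columns=snp_ids
        ),
        snp_annotation=snp_annotation,
    )
    phenotypes = PhenotypeTable(pheno, trait_columns=(cfg.trait,))
    return methylation, genotypes, phenotypes, truth
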