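"""Readers and writers for every file the pipeline touches.

All tabular formats are plain TSV; genotypes can additionally round-trip
through minimal VCF (GT genotypes only).  Every reader validates its input
and fails loudly — there is no silent coercion.  Genomic positions are
1-based and fully closed in every file, including the BED-like probe
annotation (documented here because BED proper is 0-based half-open).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    FormatError,
    GenotypeDataset,
    MethylationDataset,
    MwasResult,
    PhenotypeTable,
    ScoreWeights,
)
from .simulate import SyntheticTruth

logger = logging.getLogger(__name__)

MWAS_COLUMNS = ["feature_id", "beta", "se", "t", "p", "n"]


def _as_samples_by_features(mat: pd.DataFrame) -> pd.DataFrame:
    """Transpose a features-x-samples file matrix to the in-memory layout."""
    out = mat.T
    out.index.name = "sample_id"
    out.columns.name = None
    return out


# --------------------------------------------------------------------------
# methylation matrix + probe annotation
# --------------------------------------------------------------------------

def write_methylation(dataset: MethylationDataset, matrix_path, annotation_path) -> None:
    """Write beta matrix (probes x samples) and BED-like annotation TSV."""
    dataset.beta.T.rename_axis("probe_id").to_csv(matrix_path, sep="\t")
    ann = dataset.probe_annotation.copy()
    ann["snp_at_target"] = ann["snp_at_target"].astype(int)
    ann["autosomal"] = ann["autosomal"].astype(int)
    ann.rename_axis("probe_id").to_csv(annotation_path, sep="\t")


def read_methylation(matrix_path, annotation_path) -> MethylationDataset:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if mat.index.duplicated().any():
        raise FormatError(f"duplicate probe ids in {matrix_path}")
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype={"chrom": str})
    for col in ("chrom", "pos"):
        if col not in ann.columns:
            raise FormatError(f"annotation {annotation_path} missing column {col!r}")
    for col, default in (("snp_at_target", False), ("autosomal", True)):
        ann[col] = ann[col].astype(bool) if col in ann.columns else default
    return MethylationDataset(beta=_as_samples_by_features(mat), probe_annotation=ann)


# --------------------------------------------------------------------------
# genotypes: dosage TSV and minimal VCF
# --------------------------------------------------------------------------

def write_dosage(dataset: GenotypeDataset, matrix_path, annotation_path) -> None:
    """Write dosage matrix (SNPs x samples) and SNP annotation TSV."""
    dataset.dosage.T.rename_axis("snp_id").to_csv(matrix_path, sep="\t")
    dataset.snp_annotation.rename_axis("snp_id").to_csv(annotation_path, sep="\t")


def read_dosage(matrix_path, annotation_path) -> GenotypeDataset:
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype={"chrom": str})
    return GenotypeDataset(dosage=_as_samples_by_features(mat), snp_annotation=ann)


def write_vcf(dataset: GenotypeDataset, path) -> None:
    """Write hard-call genotypes as a minimal VCF (GT only, ALT = effect allele)."""
    dos = dataset.dosage.to_numpy(dtype=float)
    nonmiss = dos[~np.isnan(dos)]
    if not np.all(nonmiss == np.round(nonmiss)):
        raise FormatError("VCF output requires integer dosages; use write_dosage for imputed data")
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    samples = dataset.sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        ann = dataset.snp_annotation
        for j, snp in enumerate(dataset.dosage.columns):
            row = ann.loc[snp]
            gts = "\t".join(
                "./." if np.isnan(d) else gt_map[int(d)] for d in dos[:, j]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp}\t{row['other_allele']}\t"
                f"{row['effect_allele']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeDataset:
    """Read a VCF; ALT is taken as the effect allele. Multi-allelic records are skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, eff, oth, rows = [], [], [], [], [], []
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            continue
        dos = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:2] if a >= 0]
            if alleles:
                dos[i] = float(sum(alleles))
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        chroms.append(str(variant.CHROM))
        poss.append(int(variant.POS))
        eff.append(variant.ALT[0])
        oth.append(variant.REF)
        rows.append(dos)
    if n_multi:
        logger.warning("skipped %d multi-allelic records in %s", n_multi, path)
    if not ids:
        raise FormatError(f"no usable biallelic records in {path}")
    dosage = pd.DataFrame(
        np.vstack(rows).T, index=pd.Index(samples, name="sample_id"), columns=ids
    )
    ann = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "effect_allele": eff, "other_allele": oth},
        index=pd.Index(ids, name="snp_id"),
    )
    return GenotypeDataset(dosage=dosage, snp_annotation=ann)


def read_genotypes(path, annotation_path=None) -> GenotypeDataset:
    """Dispatch on extension: ``.vcf`` or a dosage TSV (+ annotation TSV)."""
    path = Path(path)
    if path.suffix == ".vcf":
        return read_vcf(path)
    if annotation_path is None:
        raise FormatError("dosage TSV input requires an annotation path")
    return read_dosage(path, annotation_path)


# --------------------------------------------------------------------------
# phenotypes, weights, MWAS results, scores, truth
# --------------------------------------------------------------------------

def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.rename_axis("sample_id").to_csv(path, sep="\t")


def read_phenotypes(path, trait_columns=("bmi",)) -> PhenotypeTable:
    data = pd.read_csv(path, sep="\t", index_col=0)
    return PhenotypeTable(data, trait_columns=tuple(trait_columns))


def write_weights(weights: ScoreWeights, path) -> None:
    tab = weights.table.copy()
    if "effect_allele" not in tab.columns:
        tab["effect_allele"] = ""
    tab["source"] = weights.source
    tab.rename_axis("feature_id").to_csv(path, sep="\t")


def read_weights(path) -> ScoreWeights:
    tab = pd.read_csv(path, sep="\t", index_col=0, dtype={"effect_allele": str})
    if tab.index.duplicated().any():
        raise FormatError(f"duplicate feature ids in {path}")
    for col in ("feature_kind", "weight"):
        if col not in tab.columns:
            raise FormatError(f"weights file {path} missing column {col!r}")
    source = ""
    if "source" in tab.columns:
        vals = tab["source"].dropna().unique()
        source = str(vals[0]) if len(vals) else ""
        tab = tab.drop(columns="source")
    return ScoreWeights(tab, source=source)


def write_mwas(result: MwasResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# trait={result.trait}\n")
        fh.write(f"# covariates={','.join(result.covariates)}\n")
        result.table.rename_axis("feature_id").to_csv(fh, sep="\t")


def read_mwas(path) -> MwasResult:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        tab = pd.read_csv(fh, sep="\t", index_col=0)
    if tab.index.duplicated().any():
        raise FormatError(f"duplicate probe ids in {path}")
    covs = tuple(c for c in meta.get("covariates", "").split(",") if c)
    return MwasResult(tab, trait=meta.get("trait", ""), covariates=covs)


def write_scores(scores: pd.Series, path) -> None:
    scores.rename("score").rename_axis("sample_id").to_csv(path, sep="\t")


def read_scores(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["score"]


def write_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SyntheticTruth(
        causal_probe_ids=d["causal_probe_ids"],
        causal_snp_ids=d["causal_snp_ids"],
        true_probe_effects=np.asarray(d["true_probe_effects"]),
        true_snp_effects=np.asarray(d["true_snp_effects"]),
        realized_var_genetic=d["realized_var_genetic"],
        realized_var_methylation=d["realized_var_methylation"],
        family_assignments=d["family_assignments"],
    )


def write_residualized(rm, matrix_path, annotation_path) -> None:
    """Write an analysis-ready (residualized/INT) matrix, probes x samples."""
    from .datatypes import ResidualizedMethylation  # noqa: F401  (type of rm)

    with open(matrix_path, "w") as fh:
        fh.write(f"# adjustment_set={','.join(rm.adjustment_set)}\n")
        rm.values.T.rename_axis("probe_id").to_csv(fh, sep="\t")
    ann = rm.probe_annotation.copy()
    for col in ("snp_at_target", "autosomal"):
        if col in ann.columns:
            ann[col] = ann[col].astype(int)
    ann.rename_axis("probe_id").to_csv(annotation_path, sep="\t")


def read_residualized(matrix_path, annotation_path):
    from .datatypes import ResidualizedMethylation

    adjustment: tuple = ()
    with open(matrix_path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            if key.strip() == "adjustment_set":
                adjustment = tuple(c for c in val.split(",") if c)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        mat = pd.read_csv(fh, sep="\t", index_col=0)
    ann = pd.read_csv(annotation_path, sep="\t", index_col=0, dtype={"chrom": str})
    return ResidualizedMethylation(
        values=_as_samples_by_features(mat),
        adjustment_set=adjustment,
        probe_annotation=ann.loc[mat.index],
    )


def write_adjusted_phenotype(adj, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# trait={adj.trait}\n")
        fh.write(f"# adjustment_set={','.join(adj.adjustment_set)}\n")
        fh.write(f"# family_corrected={int(adj.family_corrected)}\n")
        adj.z.rename("z").rename_axis("sample_id").to_csv(fh, sep="\t")


def read_adjusted_phenotype(path):
    from .datatypes import AdjustedPhenotype

    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        z = pd.read_csv(fh, sep="\t", index_col=0)["z"]
    return AdjustedPhenotype(
        z=z,
        trait=meta.get("trait", ""),
        adjustment_set=tuple(c for c in meta.get("adjustment_set", "").split(",") if c),
        family_corrected=bool(int(meta.get("family_corrected", "0"))),
    )


def write_cohort(methylation, genotypes, phenotypes, truth, out_dir) -> dict:
    """Write one simulated cohort in the formats the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "methylation": out / "methylation.tsv",
        "annotation": out / "probes.bedlike.tsv",
        "vcf": out / "genotypes.vcf",
        "dosage": out / "dosage.tsv",
        "snp_annotation": out / "snps.tsv",
        "phenotypes": out / "phenotypes.tsv",
        "truth": out / "truth.json",
    }
    write_methylation(methylation, paths["methylation"], paths["annotation"])
    write_vcf(genotypes, paths["vcf"])
    write_dosage(genotypes, paths["dosage"], paths["snp_annotation"])
    write_phenotypes(phenotypes, paths["phenotypes"])
    write_truth(truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}


def load_config(path) -> dict:
    """Load the shared YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must be a YAML mapping")
    return cfg
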