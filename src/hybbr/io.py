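"""Readers and writers for genotype, phenotype, pedigree and config files.

Supported genotype sources: PLINK .bed/.bim/.fam, plain TSV dosage tables
(rows = animals, columns = variants) with an optional variant-info TSV,
and VCF (GT-field dosages, biallelic sites only; requires cyvcf2).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_model import GenotypeMatrix, Pedigree, VarianceComponents

logger = logging.getLogger(__name__)

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> dosage of allele 2 (A1 in .bim is the counted allele
# here, matching dosage-of-ALT conventions after allele harmonization)
_PLINK_CODE = {0: 2.0, 1: np.nan, 2: 1.0, 3: 0.0}


def read_dosage_tsv(dosage_path, variant_info_path=None) -> GenotypeMatrix:
    """TSV dosage matrix: first column animal_id, remaining columns variants."""
    df = pd.read_csv(dosage_path, sep="\t", dtype={0: str})
    sample_ids = df.iloc[:, 0].to_numpy()
    dos = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    variant_ids = np.asarray(df.columns[1:], dtype=object)
    if variant_info_path is not None:
        info = pd.read_csv(variant_info_path, sep="\t",
                           dtype={"variant_id": str, "chrom": str})
        info = info.set_index("variant_id").loc[variant_ids]
        chrom = info["chrom"].to_numpy()
        pos = info["pos_bp"].to_numpy(dtype=np.int64)
    else:
        chrom = np.array(["1"] * len(variant_ids), dtype=object)
        pos = np.arange(1, len(variant_ids) + 1, dtype=np.int64)
    return GenotypeMatrix(dos, variant_ids, chrom, pos, sample_ids)


def write_dosage_tsv(geno: GenotypeMatrix, dosage_path, variant_info_path=None):
    df = pd.DataFrame(geno.dosages, columns=geno.variant_ids)
    df.insert(0, "animal_id", geno.sample_ids)
    df.to_csv(dosage_path, sep="\t", index=False, na_rep="NA")
    if variant_info_path is not None:
        pd.DataFrame({
            "variant_id": geno.variant_ids,
            "chrom": geno.chrom,
            "pos_bp": geno.pos_bp,
        }).to_csv(variant_info_path, sep="\t", index=False)


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset (variant-major .bed).

    Decodes the 2-bit codes directly: per variant, one byte packs four
    samples (low bits first); 00=hom A1 (dosage 2), 01=missing,
    10=het, 11=hom A2 (dosage 0).
    """
    prefix = str(prefix)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "variant_id", "cm", "pos_bp", "a1", "a2"],
                      dtype={"chrom": str, "variant_id": str})
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "sire", "dam", "sex", "pheno"],
                      dtype=str)
    n, m = len(fam), len(bim)
    raw = Path(prefix + ".bed").read_bytes()
    if raw[:3] != _PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed is not a variant-major PLINK bed file")
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_variant * m:
        raise ValueError("bed file size inconsistent with bim/fam dimensions")
    body = body.reshape(m, bytes_per_variant)
    # unpack 2-bit fields: sample j lives in byte j//4, bits (j%4)*2
    shifts = (np.arange(n) % 4) * 2
    codes = (body[:, np.arange(n) // 4] >> shifts) & 0b11
    lut = np.array([_PLINK_CODE[c] for c in range(4)])
    dosages = lut[codes].T  # n x m
    return GenotypeMatrix(dosages, bim["variant_id"].to_numpy(),
                          bim["chrom"].to_numpy(),
                          bim["pos_bp"].to_numpy(np.int64),
                          fam["iid"].to_numpy())


def read_vcf(path) -> GenotypeMatrix:
    """Dosage matrix from the GT field of a VCF; biallelic sites only."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    dos, vids, chroms, poss = [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic site %s:%d", var.CHROM,
                           var.POS)
            continue
        gt = np.asarray(var.genotype.array())[:, :2].astype(float)
        gt[gt < 0] = np.nan
        dos.append(np.nansum(gt, axis=1) + np.where(np.isnan(gt).all(axis=1),
                                                    np.nan, 0.0))
        vids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
    return GenotypeMatrix(np.column_stack(dos), np.asarray(vids, dtype=object),
                          np.asarray(chroms, dtype=object),
                          np.asarray(poss, dtype=np.int64), samples)


def read_phenotypes(path) -> pd.DataFrame:
    """Phenotype TSV: animal_id, trait, sex, breed, d, r[, weight]."""
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    required = {"animal_id", "trait"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def write_phenotypes(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return Pedigree.from_frame(df)


def read_variance_components(path) -> VarianceComponents:
    """Variance-component config: YAML/flat key-value text."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    kwargs = {k: float(v) for k, v in cfg.items()
              if k in ("sigma_g2", "sigma_a2", "sigma_e2", "t", "c")}
    return VarianceComponents(**kwargs)


def write_variance_components(vc: VarianceComponents, path):
    with open(path, "w") as fh:
        yaml.safe_dump({"sigma_g2": float(vc.sigma_g2),
                        "sigma_a2": float(vc.sigma_a2),
                        "sigma_e2": float(vc.sigma_e2),
                        "t": float(vc.t), "c": float(vc.c)}, fh)


def write_snp_effects(path, variant_ids, chrom, pos_bp, g_mean, P):
    out = pd.DataFrame({
        "variant_id": variant_ids, "chrom": chrom, "pos_bp": pos_bp,
        "g_mean": g_mean,
        "P1": P[:, 0], "P2": P[:, 1], "P3": P[:, 2], "P4": P[:, 3],
    })
    out.to_csv(path, sep="\t", index=False)
    return out


def read_snp_effects(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str})


def write_gebv(path, animal_ids, gebv):
    pd.DataFrame({"animal_id": animal_ids, "gebv": gebv}).to_csv(
        path, sep="\t", index=False)
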