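"""Readers and writers for the plain-text interchange formats.

VCF v4.2 subset: CHROM, POS, ID, REF, ALT, QUAL, FILTER, INFO (MQ=, DP=),
FORMAT GT with diploid genotypes 0/0, 0/1, 1/1, ./. (phased separators
accepted on input and treated as unphased).  Pedigree, phenotype and duo
tables are TSV; 0 denotes an unknown parent.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import MISSING, Pedigree, PhenotypeSet, VariantTable


def read_vcf(path: str | Path) -> VariantTable:
    """Read the VCF subset into a :class:`VariantTable`.

    GT is mapped to ALT-dosage (0/1 and 1/0 both give 1); missing calls
    become the MISSING sentinel.  Multi-allelic records are retained with a
    comma-joined ALT so the QC multi-allelic rule can remove and count them.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosages = []
    for var in vcf:
        alt = ",".join(var.ALT) if var.ALT else "."
        info_mq = var.INFO.get("MQ")
        info_dp = var.INFO.get("DP")
        rows.append(
            {
                "chrom": var.CHROM,
                "pos": var.POS,
                "ref": var.REF,
                "alt": alt,
                "qual": var.QUAL if var.QUAL is not None else np.nan,
                "mq": float(info_mq) if info_mq is not None else np.nan,
                "dp": float(info_dp) if info_dp is not None else np.nan,
            }
        )
        g = np.empty(len(samples), dtype=np.int8)
        for i, call in enumerate(var.genotypes):
            a = [x for x in call[:-1] if x >= 0]
            g[i] = sum(1 for x in a if x > 0) if len(a) == 2 else MISSING
        dosages.append(g)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "qual", "mq", "dp"])
    genotypes = (
        np.column_stack(dosages) if dosages else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return VariantTable(sites=sites, genotypes=genotypes, sample_ids=samples)


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(vt: VariantTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="Mapping quality">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(vt.sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.sample_ids)
            + "\n"
        )
        for j, row in vt.sites.iterrows():
            qual = "." if pd.isna(row["qual"]) else f"{row['qual']:g}"
            info = []
            if not pd.isna(row["mq"]):
                info.append(f"MQ={row['mq']:g}")
            if not pd.isna(row["dp"]):
                info.append(f"DP={int(row['dp'])}")
            gts = "\t".join(_GT[int(g)] for g in vt.genotypes[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual}\tPASS\t{';'.join(info) or '.'}\tGT\t{gts}\n"
            )


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    rec = pedigree.records[["id", "sire", "dam"]].fillna("0")
    rec.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | Path, duos: list[tuple[str, str]] | None = None) -> Pedigree:
    rec = pd.read_csv(path, sep="\t", dtype=str)
    rec["sire"] = rec["sire"].replace("0", np.nan)
    rec["dam"] = rec["dam"].replace("0", np.nan)
    if "sex" not in rec.columns:
        rec["sex"] = None
    return Pedigree(records=rec, duos=duos or [])


def write_phenotypes(phen: PhenotypeSet, path: str | Path) -> None:
    pd.DataFrame({"id": phen.ids, "value": phen.values, "weight": phen.weights}).to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path: str | Path, trait_name: str = "trait") -> PhenotypeSet:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    return PhenotypeSet(
        ids=list(df["id"]),
        values=df["value"].to_numpy(float),
        weights=df["weight"].to_numpy(float),
        trait_name=trait_name,
    )


def write_duos(duos: list[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(duos, columns=["sire_id", "son_id"]).to_csv(path, sep="\t", index=False)


def read_duos(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(zip(df["sire_id"], df["son_id"]))
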