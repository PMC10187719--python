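"""Readers and writers for the cohort's on-disk formats.

Three plain-text files describe a cohort: a VCF 4.2 with a DS (dosage)
FORMAT field, a tab-delimited GWAS summary-statistics table
(SNP CHR BP A1 A2 BETA SE P MAF), and a FAM-like phenotype/pedigree table
(FID IID FATHER MOTHER SEX STATUS AGE APOE, with APOE coded "34" for
e3/e4 and "0" missing).  Writing is plain text; VCF parsing goes through
cyvcf2.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import GenotypePanel

__all__ = [
    "write_cohort",
    "write_vcf",
    "read_vcf_dosages",
    "write_summary_stats",
    "read_summary_stats",
    "write_pedigree",
    "read_pedigree",
]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=famprs
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">
"""


def write_vcf(panel: GenotypePanel, path: str) -> None:
    """Write the panel as a VCF 4.2 with per-sample DS dosages.

    The counted allele (a1) is emitted as ALT so that DS equals the stored
    dosage of the effect allele.
    """
    snps = panel.snps
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in dict.fromkeys(snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.iids)
            + "\n"
        )
        dos = panel.dosages
        for j in range(len(snps)):
            row = snps.iloc[j]
            vals = "\t".join(_fmt_ds(v) for v in dos[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['snp']}\t{row['a2']}\t"
                f"{row['a1']}\t.\t.\t.\tDS\t{vals}\n"
            )


def _fmt_ds(v: float) -> str:
    if np.isnan(v):
        return "."
    if float(v).is_integer():
        return str(int(v))
    return f"{v:.4f}"


def read_vcf_dosages(path: str) -> GenotypePanel:
    """Load a DS-format VCF into a :class:`GenotypePanel` (block/true_beta
    metadata are not stored in VCF and come back as -1/0)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    iids = np.array(vcf.samples)
    ids, chroms, poss, a1s, a2s, columns = [], [], [], [], [], []
    for rec in vcf:
        ids.append(rec.ID)
        chroms.append(str(rec.CHROM))
        poss.append(rec.POS)
        a2s.append(rec.REF)
        a1s.append(rec.ALT[0] if rec.ALT else ".")
        ds = rec.format("DS")
        columns.append(
            np.full(len(iids), np.nan, dtype=np.float32)
            if ds is None
            else ds[:, 0].astype(np.float32)
        )
    dosages = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((len(iids), 0), dtype=np.float32)
    )
    with np.errstate(invalid="ignore"):
        maf = np.nanmean(dosages, axis=0) / 2.0 if len(ids) else np.array([])
        maf = np.minimum(maf, 1.0 - maf)
    snps = pd.DataFrame(
        {
            "snp": ids,
            "chrom": chroms,
            "pos": poss,
            "a1": a1s,
            "a2": a2s,
            "maf": maf,
            "block": -1,
            "true_beta": 0.0,
        }
    )
    return GenotypePanel(snps=snps, dosages=dosages, iids=iids)


def write_summary_stats(stats: pd.DataFrame, path: str) -> None:
    cols = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "MAF"]
    stats[cols].to_csv(path, sep="\t", index=False)


def read_summary_stats(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = {"SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "MAF"} - set(
        df.columns
    )
    if missing:
        raise ValueError(f"summary stats missing columns: {sorted(missing)}")
    return df


_PED_COLS = ["FID", "IID", "FATHER", "MOTHER", "SEX", "STATUS", "AGE", "APOE"]


def write_pedigree(cohort: pd.DataFrame, path: str) -> None:
    """FAM-like phenotype table; STATUS is 2=affected, 1=unaffected."""
    if len(cohort) == 0:
        pd.DataFrame(columns=_PED_COLS).to_csv(path, sep="\t", index=False)
        return
    out = pd.DataFrame(
        {
            "FID": cohort["fid"],
            "IID": cohort["iid"],
            "FATHER": cohort["father"],
            "MOTHER": cohort["mother"],
            "SEX": cohort["sex"],
            "STATUS": np.where(cohort["affected"], 2, 1),
            "AGE": cohort["age"].round(2),
            "APOE": cohort["apoe"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str, "APOE": str})
    missing = set(_PED_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree missing columns: {sorted(missing)}")
    df["affected"] = df["STATUS"] == 2
    df["e4"] = df["APOE"].str.count("4").fillna(0).astype(int)
    df["e2"] = df["APOE"].str.count("2").fillna(0).astype(int)
    return df


def write_cohort(
    cohort: pd.DataFrame,
    panel: GenotypePanel | None,
    stats: pd.DataFrame | None,
    out_dir: str,
) -> dict[str, str]:
    """Emit the cohort's file set into ``out_dir``; returns name -> path."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    ped = os.path.join(out_dir, "cohort.fam.tsv")
    write_pedigree(cohort, ped)
    paths["pedigree"] = ped
    if panel is not None:
        vcf = os.path.join(out_dir, "genotypes.vcf")
        write_vcf(panel, vcf)
        paths["vcf"] = vcf
    if stats is not None:
        ss = os.path.join(out_dir, "sumstats.tsv")
        write_summary_stats(stats, ss)
        paths["sumstats"] = ss
    return paths
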