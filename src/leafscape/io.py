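"""Reading and writing the package's exchange formats.

Genotypes travel either as a plain TSV matrix (rows = individuals,
columns = SNPs, codes 0/1/2 with ``NA`` for missing) or as minimal
VCF v4.2 with a GT field only; reading VCF uses cyvcf2 when available and
falls back to a small text parser otherwise (the files written here are
GT-only and unphased).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from leafscape.errors import ShapeError
from leafscape.genomics import MISSING, GenotypeMatrix

__all__ = [
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
]


def write_genotypes_tsv(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        np.where(G.codes == MISSING, np.nan, G.codes),
        index=pd.Index(G.sample_ids, name="sample"),
        columns=G.snp_ids,
    )
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")
    meta = pd.DataFrame({"snp": G.snp_ids, "chrom": G.chrom, "pos": G.pos})
    meta.to_csv(str(path) + ".snps", sep="\t", index=False)


def read_genotypes_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    codes = df.to_numpy(dtype=float)
    codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
    try:
        meta = pd.read_csv(str(path) + ".snps", sep="\t", dtype={"chrom": str})
        chrom = meta["chrom"].to_numpy(dtype=object)
        pos = meta["pos"].to_numpy(dtype=np.int64)
    except FileNotFoundError:
        chrom = np.array(["1"] * df.shape[1], dtype=object)
        pos = np.arange(1, df.shape[1] + 1, dtype=np.int64)
    return GenotypeMatrix(
        codes=codes,
        sample_ids=list(df.index),
        snp_ids=list(df.columns),
        chrom=chrom,
        pos=pos,
    )


_GT_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def write_genotypes_vcf(G: GenotypeMatrix, path) -> None:
    """Minimal VCF v4.2 with a GT field only (unphased, REF=A, ALT=T)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for ch in dict.fromkeys(str(c) for c in G.chrom):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(G.n_snps):
            fields = [
                str(G.chrom[j]),
                str(int(G.pos[j])),
                str(G.snp_ids[j]),
                "A",
                "T",
                ".",
                ".",
                ".",
                "GT",
            ]
            fields.extend(gt_str[int(c)] for c in G.codes[:, j])
            fh.write("\t".join(fields) + "\n")


def _read_vcf_text(path) -> GenotypeMatrix:
    samples = None
    rows, snp_ids, chroms, poss = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            if samples is None:
                raise ShapeError("VCF header line missing")
            parts = line.split("\t")
            chroms.append(parts[0])
            poss.append(int(parts[1]))
            snp_ids.append(parts[2] if parts[2] != "." else f"{parts[0]}:{parts[1]}")
            fmt = parts[8].split(":")
            gt_i = fmt.index("GT")
            row = []
            for entry in parts[9:]:
                gt = entry.split(":")[gt_i].replace("|", "/")
                if "." in gt:
                    row.append(MISSING)
                else:
                    a, b = (int(x) for x in gt.split("/"))
                    row.append(_GT_CODE.get((a, b), MISSING))
            rows.append(row)
    codes = np.array(rows, dtype=np.int8).T
    return GenotypeMatrix(
        codes=codes,
        sample_ids=samples,
        snp_ids=snp_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
    )


def read_genotypes_vcf(path) -> GenotypeMatrix:
    """Read a biallelic GT-only VCF into a genotype matrix."""
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path), gts012=True)  # 0/1/2 dosage, 3 = missing
    samples = list(vcf.samples)
    rows, snp_ids, chroms, poss = [], [], [], []
    for var in vcf:
        chroms.append(var.CHROM)
        poss.append(var.POS)
        snp_ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        # gt_types is a view into a buffer reused across variants: copy it
        rows.append(np.array(var.gt_types, dtype=np.int16))
    vcf.close()
    codes = np.array(rows).T
    codes = np.where(codes == 3, MISSING, codes).astype(np.int8)
    return GenotypeMatrix(
        codes=codes,
        sample_ids=samples,
        snp_ids=snp_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
    )
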