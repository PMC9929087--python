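"""Reading and writing genotype datasets (PLINK bed/bim/fam, VCF, label TSV).

The PLINK codec handles the v1.9 SNP-major binary layout directly with numpy
bit operations.  VCF parsing is delegated to cyvcf2; only biallelic diploid
SNP records are accepted.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, recode_additive

PathLike = Union[str, os.PathLike]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit PLINK codes -> additive code (count of A1/alt alleles minus one);
# binary 01 is the missing call
_BED_DECODE = np.array([1, MISSING, 0, -1], dtype=np.int8)
# inverse: alt-allele count 0/1/2 -> two-bit code; missing handled separately
_BED_ENCODE = {0: 3, 1: 2, 2: 0, MISSING: 1}


class FormatError(ValueError):
    """Malformed file content (bad magic bytes, bad genotype field)."""


class ConsistencyError(ValueError):
    """bed/bim/fam files disagree with each other."""


def read_plink(prefix: PathLike) -> GenotypeMatrix:
    """Read a PLINK v1.9 bed/bim/fam trio into a :class:`GenotypeMatrix`.

    The bim A1 allele is taken as the alternate allele, so the additive code
    is (count of A1) - 1.  Variant order follows the .bim file; positions
    stay 1-based.
    """
    prefix = Path(prefix)
    bed_path, bim_path, fam_path = (
        prefix.with_suffix(prefix.suffix + ext) for ext in (".bed", ".bim", ".fam")
    )
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise ConsistencyError(f"missing PLINK member file: {p}")

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)

    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes {raw[:3]!r} (want SNP-major v1.9)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise ConsistencyError(
            f"{bed_path}: {body.size} data bytes, expected {bytes_per_snp * m} "
            f"for {n} samples x {m} SNPs"
        )
    blocks = body.reshape(m, bytes_per_snp)
    # expand each byte into its four 2-bit fields, sample-within-byte order LSB first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (blocks[:, :, None] >> shifts) & 0b11  # m x bytes x 4
    codes = _BED_DECODE[two_bit.reshape(m, -1)[:, :n]]  # m x n
    values = np.ascontiguousarray(codes.T)

    variants = pd.DataFrame(
        {
            "chrom": bim["chrom"],
            "id": bim["id"],
            "pos": bim["pos"],
            "ref": bim["a2"],
            "alt": bim["a1"],
        }
    )
    return GenotypeMatrix(values=values, sample_ids=fam["iid"].tolist(), variants=variants)


def write_plink(g: GenotypeMatrix, prefix: PathLike) -> None:
    """Write a bed/bim/fam trio (v1.9 SNP-major) for ``g``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.shape

    bim = pd.DataFrame(
        {
            "chrom": g.variants["chrom"],
            "id": g.variants["id"],
            "cm": 0,
            "pos": g.variants["pos"],
            "a1": g.variants["alt"],
            "a2": g.variants["ref"],
        }
    )
    bim.to_csv(prefix.with_suffix(prefix.suffix + ".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": g.sample_ids,
            "iid": g.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(prefix.suffix + ".fam"), sep="\t", header=False, index=False)

    counts = g.values.astype(np.int64) + 1
    counts[g.values == MISSING] = MISSING
    lut = np.zeros(5, dtype=np.uint8)
    for cnt, code in _BED_ENCODE.items():
        lut[cnt + 2] = code  # shift keys {-2,0,1,2} into valid indices
    two_bit = lut[(counts + 2).T]  # m x n
    pad = (-n) % 4
    if pad:
        two_bit = np.hstack([two_bit, np.zeros((m, pad), dtype=np.uint8)])
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (two_bit.reshape(m, -1, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(prefix.suffix + ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_vcf(path: PathLike, skip_multiallelic: bool = True) -> GenotypeMatrix:
    """Read biallelic diploid SNP records from a VCF into additive codes.

    GT 0/0 -> -1, 0/1 or 1/0 -> 0, 1/1 -> 1, ./. -> -2.  Multiallelic
    records are skipped when ``skip_multiallelic`` else rejected; a
    non-diploid GT always raises :class:`FormatError`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    rows, records = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            if skip_multiallelic:
                continue
            raise FormatError(f"multiallelic record at {var.CHROM}:{var.POS}")
        codes = np.empty(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]  # trailing element is the phased flag
            if len(alleles) != 2:
                raise FormatError(
                    f"non-diploid GT for sample {sample_ids[i]} at {var.CHROM}:{var.POS}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                codes[i] = MISSING
            else:
                codes[i] = int(alleles[0] > 0) + int(alleles[1] > 0) - 1
        rows.append(codes)
        records.append(
            {
                "chrom": str(var.CHROM),
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    vcf.close()
    if not records:
        raise FormatError(f"{path}: no usable biallelic SNP records")
    return GenotypeMatrix(
        values=np.vstack(rows).T,
        sample_ids=sample_ids,
        variants=pd.DataFrame(records),
    )


_GT_STRINGS = {-2: "./.", -1: "0/0", 0: "0/1", 1: "1/1"}


def write_vcf(g: GenotypeMatrix, path: PathLike) -> None:
    """Write ``g`` as an uncompressed VCF v4.2 with GT-only records."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, rec in g.variants.iterrows():
            gts = "\t".join(_GT_STRINGS[int(v)] for v in g.values[:, j])
            fh.write(
                f"{rec['chrom']}\t{rec['pos']}\t{rec['id']}\t{rec['ref']}\t"
                f"{rec['alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_labels(path: PathLike) -> pd.DataFrame:
    """Read a two- (or three-) column TSV: sample_id, label[, super_label]."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least two tab-separated columns")
    df = df.iloc[:, :3]
    df.columns = ["sample_id", "label", "super_label"][: df.shape[1]]
    return df


def write_labels(g: GenotypeMatrix, path: PathLike) -> None:
    if g.labels is None:
        raise ValueError("genotype matrix carries no labels")
    cols = {"sample_id": g.sample_ids, "label": g.labels}
    if g.super_labels is not None:
        cols["super_label"] = g.super_labels
    pd.DataFrame(cols).to_csv(path, sep="\t", header=False, index=False)


def attach_labels(g: GenotypeMatrix, labels: pd.DataFrame) -> GenotypeMatrix:
    """Attach population labels from a label table, matching on sample id."""
    table = labels.set_index("sample_id")
    missing = [s for s in g.sample_ids if s not in table.index]
    if missing:
        raise ConsistencyError(f"labels missing for samples: {missing[:5]}")
    out = g.copy()
    out.labels = table.loc[g.sample_ids, "label"].to_numpy(dtype=object)
    if "super_label" in table.columns:
        out.super_labels = table.loc[g.sample_ids, "super_label"].to_numpy(dtype=object)
    return out
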