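"""VCF v4.2 input/output for the genotype matrix (FORMAT GT:DP:GQ).

Reading goes through cyvcf2; multi-allelic records are split into
bi-allelic records at load, with dosage counted per split alternate.
Writing emits plain VCF text (phased genotypes when haplotypes are known).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MISSING, VARIANT_COLUMNS

_HEADER = """\
##fileformat=VCFv4.2
##source=h2scan
##contig=<ID={chrom},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    chrom = matrix.variants["chrom"].iloc[0] if matrix.n_variants else "chr17"
    length = int(matrix.variants["pos"].max()) + 1000 if matrix.n_variants else 1000
    lines = [_HEADER.format(chrom=chrom, length=length)]
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(cols + matrix.samples) + "\n")
    phased = matrix.phased
    for j in range(matrix.n_variants):
        v = matrix.variants.iloc[j]
        fields = [str(v["chrom"]), str(int(v["pos"])), str(v["id"]), str(v["ref"]),
                  str(v["alt"]), ".", "PASS", ".", "GT:DP:GQ"]
        for i in range(matrix.n_samples):
            d = matrix.dosage[i, j]
            if d == MISSING:
                gt = "./."
            elif phased is not None:
                gt = f"{phased[i, 0, j]}|{phased[i, 1, j]}"
            else:
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(d)]
            fields.append(f"{gt}:{matrix.depth[i, j]}:{matrix.quality[i, j]}")
        lines.append("\t".join(fields) + "\n")
    path.write_text("".join(lines))


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix, splitting multi-allelic records."""
    from cyvcf2 import VCF  # deferred: import cost and optional at runtime

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n = len(samples)
    rows, dos_cols, dp_cols, gq_cols = [], [], [], []
    for rec in vcf:
        gts = rec.genotypes  # [a1, a2, phased] per sample
        dp = rec.format("DP")
        gq = rec.format("GQ")
        dp = np.full(n, -1) if dp is None else dp.reshape(n, -1)[:, 0].astype(np.int64)
        gq = np.full(n, -1) if gq is None else gq.reshape(n, -1)[:, 0].astype(np.int64)
        for k, alt in enumerate(rec.ALT, start=1):
            dos = np.empty(n, dtype=np.int8)
            for i, g in enumerate(gts):
                a1, a2 = g[0], g[1]
                if a1 < 0 or a2 < 0:
                    dos[i] = MISSING
                else:
                    dos[i] = int(a1 == k) + int(a2 == k)
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}"
            if len(rec.ALT) > 1:
                vid = f"{vid}_{alt}" if rec.ID else vid
            rows.append(
                (rec.CHROM, rec.POS, vid, rec.REF, alt, len(rec.REF) != len(alt))
            )
            dos_cols.append(dos)
            dp_cols.append(np.clip(dp, 0, None).astype(np.int32))
            gq_cols.append(np.clip(gq, 0, None).astype(np.int32))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    m = len(variants)
    if m == 0:
        return GenotypeMatrix(
            samples=samples,
            variants=variants,
            dosage=np.empty((n, 0), np.int8),
            depth=np.empty((n, 0), np.int32),
            quality=np.empty((n, 0), np.int32),
        )
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].to_numpy()))
    variants = variants.iloc[order].reset_index(drop=True)
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        dosage=np.stack(dos_cols, axis=1)[:, order],
        depth=np.stack(dp_cols, axis=1)[:, order],
        quality=np.stack(gq_cols, axis=1)[:, order],
    )


def write_bed(intervals, path: str | Path) -> None:
    Path(path).write_text("".join(iv.to_bed_line() + "\n" for iv in intervals))
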