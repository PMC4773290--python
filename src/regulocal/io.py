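"""Readers and writers for the pipeline's on-disk formats.

VCF v4.2 (GT only) for genotypes, 4-column BED for annotation tracks,
TSV summary statistics (`variant chrom pos ref alt beta se p n maf trait`),
TSV B-allele fractions (`sample variant treatment baf`), plain FASTA for the
reference sequence.  VCF reading goes through cyvcf2; FASTA through pyfaidx.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

SUMMARY_STAT_COLUMNS = ["variant", "chrom", "pos", "ref", "alt", "beta", "se", "p", "n", "maf", "trait"]
BAF_COLUMNS = ["sample", "variant", "treatment", "baf"]


def write_vcf(
    path: str | Path,
    chrom: str,
    positions: Sequence[int],
    ids: Sequence[str],
    refs: Sequence[str],
    alts: Sequence[str],
    genotypes: np.ndarray,
    samples: Sequence[str],
) -> Path:
    """Write a minimal VCF v4.2 with unphased GT calls, sorted by position."""
    path = Path(path)
    order = np.argsort(np.asarray(positions), kind="stable")
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in order:
            calls = "\t".join(gt_strings[int(d)] for d in genotypes[:, j])
            fh.write(f"{chrom}\t{positions[j]}\t{ids[j]}\t{refs[j]}\t{alts[j]}\t.\tPASS\t.\tGT\t{calls}\n")
    return path


def read_vcf(path: str | Path):
    """Read genotype dosages from a VCF via cyvcf2.

    Returns (variants DataFrame with variant/chrom/pos/ref/alt, dosage array
    of shape (n_samples, n_variants) with -1 for missing, sample list).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, columns = [], []
    for rec in vcf:
        rows.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS, rec.REF, rec.ALT[0] if rec.ALT else "."))
        gts = rec.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        dos = np.where(gts == 3, 2, np.where(gts == 2, -1, gts))
        columns.append(dos.astype(np.int8))
    variants = pd.DataFrame(rows, columns=["variant", "chrom", "pos", "ref", "alt"])
    dosages = (
        np.stack(columns, axis=1) if columns else np.empty((len(samples), 0), dtype=np.int8)
    )
    return variants, dosages, samples


def write_bed(path: str | Path, intervals: Sequence[tuple[str, int, int, str]]) -> Path:
    """Write (chrom, start, end, track) intervals as 4-column BED."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, start, end, track in sorted(intervals, key=lambda r: (r[0], r[1])):
            fh.write(f"{chrom}\t{start}\t{end}\t{track}\n")
    return path


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a 3/4-column BED; a missing name column becomes the file stem."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(track=path.stem)
    df.columns = ["chrom", "start", "end", "track"]
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_fasta_reference(
    path: str | Path,
    chrom: str,
    length: int,
    positions: Sequence[int] = (),
    ref_alleles: Sequence[str] = (),
    seed: int = 0,
) -> Path:
    """Write a random reference sequence carrying given ref bases at positions."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(list("ACGT"), size=length)
    for pos, base in zip(positions, ref_alleles):
        seq[pos - 1] = base
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        s = "".join(seq)
        for i in range(0, length, 60):
            fh.write(s[i:i + 60] + "\n")
    return path


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a summary-statistics TSV; `variant` is required, others optional."""
    df = pd.read_csv(path, sep="\t")
    if "variant" not in df.columns:
        raise ValueError(f"{path}: summary-stat TSV must have a 'variant' column")
    return df


def write_summary_stats(path: str | Path, df: pd.DataFrame) -> Path:
    path = Path(path)
    cols = [c for c in SUMMARY_STAT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, sep="\t", index=False)
    return path


def read_baf(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(BAF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: BAF TSV missing columns {sorted(missing)}")
    bad = df[(df["baf"] < 0) | (df["baf"] > 1)]
    if len(bad):
        raise ValueError(f"{path}: BAF outside [0,1] for {len(bad)} rows")
    return df


def read_phenotype(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "value"} <= set(df.columns):
        raise ValueError(f"{path}: phenotype TSV needs columns 'sample' and 'value'")
    return df
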