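"""Read alignment, variant, and sequence files into the pipeline's tables.

Internal conventions: coordinates are 0-based half-open except SNP
positions, which stay 1-based as in VCF.  Window tables tile each
chromosome without overlap; a read is assigned to the window containing
its leftmost aligned base.  The pipeline is equally happy starting from
TSV window counts and TSV SNP counts (the simulator's output format), so
no alignment files are needed for testing.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from ._io import read_table, write_table
from .normalize import gc_normalize

__all__ = [
    "count_windows",
    "gc_per_window",
    "load_snp_counts",
    "load_snp_counts_tsv",
    "build_reference",
    "read_windows",
    "write_windows",
]


def count_windows(bam_path: str | Path, window_size: int = 200,
                  min_mapq: int = 20) -> pd.DataFrame:
    """Count reads per fixed window from a coordinate-sorted BAM/SAM file.

    Each primary, non-duplicate, mapped alignment with mapping quality at
    least ``min_mapq`` is counted once, in the window containing its
    leftmost aligned base.  Windows follow the header's chromosome order.

    Returns a table (chrom, start, end, count); GC fractions are attached
    separately with :func:`gc_per_window`.
    """
    import pysam

    mode = "r" if str(bam_path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(bam_path), mode) as af:
        lengths = dict(zip(af.references, af.lengths))
        counts = {
            chrom: np.zeros(int(np.ceil(length / window_size)), dtype=np.int64)
            for chrom, length in lengths.items()
        }
        for read in af:
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate or read.mapping_quality < min_mapq):
                continue
            counts[read.reference_name][read.reference_start // window_size] += 1

    frames = []
    for chrom, length in lengths.items():
        starts = np.arange(0, length, window_size)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + window_size, length),
            "count": counts[chrom],
        }))
    return pd.concat(frames, ignore_index=True)


def gc_per_window(fasta_path: str | Path, window_size: int = 200,
                  max_n_frac: float = 0.5) -> pd.DataFrame:
    """GC fraction per window from an (indexed) FASTA.

    gc = (G+C) / (A+C+G+T) over the window; windows where more than
    ``max_n_frac`` of bases are not ACGT (assembly gaps) get a missing GC.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(fasta_path))
    frames = []
    for chrom in fasta.keys():
        seq = str(fasta[chrom][:]).upper()
        length = len(seq)
        starts = np.arange(0, length, window_size)
        gc = np.full(len(starts), np.nan)
        for i, s in enumerate(starts):
            chunk = seq[s:s + window_size]
            acgt = sum(chunk.count(b) for b in "ACGT")
            if acgt < (1.0 - max_n_frac) * len(chunk) or acgt == 0:
                continue
            gc[i] = (chunk.count("G") + chunk.count("C")) / acgt
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + window_size, length),
            "gc": gc,
        }))
    return pd.concat(frames, ignore_index=True)


def attach_gc(windows: pd.DataFrame, gc: pd.DataFrame) -> pd.DataFrame:
    """Join a GC table onto a window-count table on (chrom, start)."""
    merged = windows.merge(gc[["chrom", "start", "gc"]], on=["chrom", "start"], how="left")
    return merged


def load_snp_counts(vcf_path: str | Path, dbsnp_positions: set[tuple[str, int]] | None = None,
                    ) -> pd.DataFrame:
    """Allele counts of biallelic SNVs from a VCF with AD-style depths.

    Only biallelic single-nucleotide records are kept; if a dbSNP position
    set ``{(chrom, pos_1based), ...}`` is given, records elsewhere are
    dropped.  Records without allele depths are skipped with a counted
    warning.  Returns (chrom, pos, countA, countB, in_dbsnp).
    """
    from cyvcf2 import VCF

    rows = []
    skipped = 0
    for var in VCF(str(vcf_path)):
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        key = (var.CHROM, var.POS)
        in_db = dbsnp_positions is None or key in dbsnp_positions
        if not in_db:
            continue
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None or ad.shape[1] < 2:
            skipped += 1
            continue
        count_a, count_b = int(ad[0][0]), int(ad[0][1])
        if count_a < 0 or count_b < 0 or count_a + count_b < 1:
            skipped += 1
            continue
        rows.append((var.CHROM, var.POS, count_a, count_b, True))
    if skipped:
        warnings.warn(f"skipped {skipped} VCF records without usable allele depths")
    return pd.DataFrame(rows, columns=["chrom", "pos", "countA", "countB", "in_dbsnp"])


def load_snp_counts_tsv(path: str | Path) -> pd.DataFrame:
    """SNP allele counts from the simulator's TSV dialect."""
    df = read_table(path)
    required = {"chrom", "pos", "countA", "countB"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns: {sorted(missing)}")
    return df


def build_reference(samples: list[pd.DataFrame], floor: float = 0.1,
                    gc_bin_width: float = 0.01, min_group: int = 100) -> pd.DataFrame:
    """Positional reference profile from one or more diploid samples.

    Each sample is GC-normalized, rescaled to mean 1 over non-missing
    windows, and the per-window values are averaged across samples.
    Windows whose averaged value falls below ``floor`` are marked missing
    (unreliable denominators).  All samples must share the window tiling.

    Returns (chrom, start, end, mean_normalized_count).
    """
    if not samples:
        raise ValueError("at least one diploid sample required")
    base = samples[0][["chrom", "start", "end"]].reset_index(drop=True)
    values = []
    for k, sample in enumerate(samples):
        grid = sample[["chrom", "start"]].reset_index(drop=True)
        if len(grid) != len(base) or not grid.equals(base[["chrom", "start"]]):
            diff = None
            n = min(len(grid), len(base))
            neq = (grid["chrom"].to_numpy()[:n] != base["chrom"].to_numpy()[:n]) | (
                grid["start"].to_numpy()[:n] != base["start"].to_numpy()[:n])
            if neq.any():
                i = int(np.flatnonzero(neq)[0])
                diff = f"{grid['chrom'].iloc[i]}:{grid['start'].iloc[i]}"
            raise ValueError(
                f"sample {k} window tiling differs from sample 0"
                + (f" (first discordant window {diff})" if diff else " (length mismatch)")
            )
        norm = gc_normalize(sample, gc_bin_width=gc_bin_width, min_group=min_group)["norm"]
        norm = norm / norm.mean(skipna=True)
        values.append(norm.to_numpy())
    mean = np.nanmean(np.vstack(values), axis=0)
    with np.errstate(invalid="ignore"):
        mean[mean < floor] = np.nan
    out = base.copy()
    out["mean_normalized_count"] = mean
    return out


def write_windows(windows: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    write_table(windows, path, params)


def read_windows(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {"chrom", "start", "end", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"window table missing columns: {sorted(missing)}")
    return df
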