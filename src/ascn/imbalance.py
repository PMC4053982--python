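"""Heterozygous-SNP selection and the per-segment allelic imbalance ratio.

The allelic imbalance ratio of a segment is

    (sum_high - sum_low) / sum_high

where sum_high and sum_low add up, over all heterozygous SNPs in the
segment, the read count of each SNP's more and less observed allele.
Summing reads rather than averaging per-SNP fractions weights every SNP
by its coverage.  The ratio is 0 for perfectly balanced alleles and 1
for complete loss of heterozygosity, but at finite depth the max/min
ordering gives it a positive bias even for balanced segments, which is
why downstream calling anchors on the empirically observed ratio of the
balanced-diploid cluster rather than on 0.

Heterozygous SNPs are best identified from a patient-matched normal
(constitutive heterozygosity), in which case the tumor counts are used
as-is even when the tumor shows one allele only (true LOH).  Without a
normal, a SNP is kept when it is at a known polymorphic position and the
tumor itself shows both alleles; this biases the ratio downward in LOH
regions at low coverage and the matched-normal mode is preferred.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._io import write_table

__all__ = ["call_heterozygous", "allelic_imbalance_ratio", "attach_imbalance",
           "write_segments_ai"]


def call_heterozygous(
    snps: pd.DataFrame,
    matched_normal: bool | None = None,
    min_depth: int = 5,
    min_minor_fraction: float = 0.2,
) -> pd.DataFrame:
    """Select informative heterozygous SNPs and orient counts as high/low.

    With a matched normal (columns ``normal_countA``/``normal_countB``),
    a SNP is constitutively heterozygous when the normal has depth at
    least ``min_depth`` and a minor-allele fraction at least
    ``min_minor_fraction``.  Without one, a SNP is kept when flagged as a
    known polymorphism (``in_dbsnp`` column, if present) and both tumor
    alleles are observed at least once.

    Returns (chrom, pos, count_high, count_low), dropping SNPs with no
    tumor reads.
    """
    if matched_normal is None:
        matched_normal = {"normal_countA", "normal_countB"}.issubset(snps.columns)
    a = snps["countA"].to_numpy(dtype=float)
    b = snps["countB"].to_numpy(dtype=float)

    if matched_normal:
        na = snps["normal_countA"].to_numpy(dtype=float)
        nb = snps["normal_countB"].to_numpy(dtype=float)
        depth = na + nb
        with np.errstate(invalid="ignore", divide="ignore"):
            minor_frac = np.minimum(na, nb) / depth
        keep = (depth >= min_depth) & (minor_frac >= min_minor_fraction)
    else:
        keep = (a >= 1) & (b >= 1)
        if "in_dbsnp" in snps.columns:
            keep &= snps["in_dbsnp"].to_numpy(dtype=bool)
    keep &= a + b >= 1

    out = pd.DataFrame({
        "chrom": snps["chrom"].to_numpy()[keep],
        "pos": snps["pos"].to_numpy()[keep],
        "count_high": np.maximum(a, b)[keep].astype(np.int64),
        "count_low": np.minimum(a, b)[keep].astype(np.int64),
    })
    return out


def allelic_imbalance_ratio(het_snps: pd.DataFrame) -> float:
    """(sum_high - sum_low) / sum_high over a set of heterozygous SNPs.

    Undefined (nan) for an empty set — never silently 0, since a missing
    ratio and a balanced ratio mean different things.
    """
    if len(het_snps) == 0:
        return float("nan")
    s_high = float(het_snps["count_high"].sum())
    s_low = float(het_snps["count_low"].sum())
    if s_high <= 0:
        return float("nan")
    return (s_high - s_low) / s_high


def attach_imbalance(segments: pd.DataFrame, het_snps: pd.DataFrame,
                     min_snps: int = 10) -> pd.DataFrame:
    """Assign SNPs to segments and compute per-segment imbalance ratios.

    Each SNP lands in the unique segment whose half-open interval contains
    its (1-based) position; SNPs outside all segments are dropped with a
    count in the ``n_snps_outside`` DataFrame attribute.  Segments with
    fewer than ``min_snps`` SNPs get a missing ratio — single-SNP ratios
    are sampling noise, not signal.

    Adds ai_ratio, sum_high, sum_low, n_het_snps columns.
    """
    out = segments.copy()
    sum_high = np.zeros(len(out))
    sum_low = np.zeros(len(out))
    n_snp = np.zeros(len(out), dtype=int)

    assigned = np.zeros(len(het_snps), dtype=bool)
    if len(het_snps):
        s_chrom = het_snps["chrom"].to_numpy()
        pos0 = het_snps["pos"].to_numpy() - 1  # 0-based
        high = het_snps["count_high"].to_numpy()
        low = het_snps["count_low"].to_numpy()
        for k, seg in enumerate(out.itertuples(index=False)):
            sel = (s_chrom == seg.chrom) & (pos0 >= seg.start) & (pos0 < seg.end)
            if sel.any():
                assigned |= sel
                sum_high[k] = high[sel].sum()
                sum_low[k] = low[sel].sum()
                n_snp[k] = int(sel.sum())

    with np.errstate(invalid="ignore", divide="ignore"):
        ai = (sum_high - sum_low) / sum_high
    ai[(n_snp < min_snps) | (sum_high <= 0)] = np.nan
    out["ai_ratio"] = ai
    out["sum_high"] = sum_high.astype(np.int64)
    out["sum_low"] = sum_low.astype(np.int64)
    out["n_het_snps"] = n_snp
    out.attrs["n_snps_outside"] = int((~assigned).sum()) if len(het_snps) else 0
    return out


def write_segments_ai(segments: pd.DataFrame, path: str | Path,
                      params: dict | None = None) -> None:
    write_table(segments, path, params)
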