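"""Synthetic tumor/normal simulator with known allele-specific copy number.

The generative model mirrors how read depth arises from a mixture of tumor
and normal cells.  At tumor cell fraction ``t`` (purity) and local total
copy number ``n``, the DNA content of the mixture relative to a diploid
sample is ``(t*n + (1-t)*2) / 2``.  Window read counts are Poisson (or
gamma-overdispersed Poisson) with mean

    mean_coverage * gc_bias(gc) * (t*n + 2*(1-t)) / 2          (tumor)
    mean_coverage * gc_bias(gc)                                 (normal)

Heterozygous SNPs get a Poisson read depth scaled by the same local DNA
content, and the reads split between the two alleles binomially with
allele fraction

    f_A = (t*c_A + (1-t)) / (t*n + 2*(1-t))

where ``c_A`` is the copy number of the homolog carrying allele A (the
major homolog ``n - m`` or the minor homolog ``m``, chosen with equal
probability per SNP since real data are unphased).

``total_cn`` may be non-integer for a segment, in which case it is read as
the mean DNA content of a heterogeneous (chromothripsis-like) region.

In-silico dilution (:func:`dilute_reads`) thins and mixes reads from a
pure tumor sample and a matched normal so that the expected tumor:normal
read ratio is ``t*P : (1-t)*2`` for target purity ``t`` and tumor ploidy
``P``, while total coverage stays at the tumor sample's original level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._io import read_table, write_table

__all__ = [
    "SimulationConfig",
    "default_gc_bias",
    "default_tumor_profile",
    "arms_from_profile",
    "allele_fraction",
    "simulate_windows",
    "simulate_het_snps",
    "dilute_reads",
    "read_profile",
    "write_profile",
]


def default_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Quadratic GC bias peaking at GC 0.45, clipped to the range [0.6, 1.2].

    Coverage in short-read libraries falls off at both GC extremes; a
    smooth bump around 45% GC is a reasonable caricature of the Illumina
    pattern and gives the GC-normalization stage real work to do.
    """
    gc = np.asarray(gc, dtype=float)
    return np.maximum(1.2 - 9.6 * (gc - 0.45) ** 2, 0.6)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic tumor/normal generator.

    purity:
        Tumor cell fraction in [0, 1].
    mean_coverage:
        Expected reads per window at copy-neutral diploid DNA content;
        also the expected per-SNP read depth at diploid.  30 corresponds
        to a well-covered whole genome, 4 to the shallow end.
    normal_coverage:
        Expected reads per window in the matched normal; defaults to
        ``mean_coverage``.
    window_size:
        Window width in bp (200 matches short-read depth granularity).
    gc_bias:
        Mapping GC fraction -> multiplicative bias (> 0).  ``None`` uses
        :func:`default_gc_bias`.
    snp_density:
        Expected heterozygous SNPs per kb (0.5 approximates the usable
        fraction of the ~1/1.5kb human heterozygous-site density after
        dbSNP filtering).
    overdispersion:
        Variance inflation of read counts relative to Poisson (1 = pure
        Poisson; > 1 uses a negative binomial with variance
        ``overdispersion * mean``).
    seed:
        Seed for all randomness; identical seeds give identical output.
    """

    purity: float = 1.0
    mean_coverage: float = 30.0
    normal_coverage: float | None = None
    window_size: int = 200
    gc_bias: Callable[[np.ndarray], np.ndarray] | None = None
    snp_density: float = 0.5
    overdispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must be in [0, 1], got {self.purity}")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if self.overdispersion < 1.0:
            raise ValueError("overdispersion must be >= 1")

    @property
    def bias_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        return self.gc_bias if self.gc_bias is not None else default_gc_bias

    @property
    def normal_cov(self) -> float:
        return self.normal_coverage if self.normal_coverage is not None else self.mean_coverage


def default_tumor_profile() -> pd.DataFrame:
    """A fixed ~300 Mb aneuploid genome covering the common copy states.

    Six 50-Mb chromosomes, two 25-Mb arms each, segments of 7-25 Mb with
    allele-specific states drawn from {1m0, 2m0, 2m1, 3m0, 3m1, 4m1, 4m2}.
    The balanced-diploid state 2m1 dominates (184/300 Mb), so the genome
    median of normalized coverage anchors at total copy 2.  The
    length-weighted average total copy number is 682/300 = 2.2733.
    """
    mb = 1_000_000
    rows = []

    def arm(chrom, arm_name, offset, pieces):
        pos = offset
        for length, n, m in pieces:
            rows.append((chrom, arm_name, pos, pos + length * mb, n, m))
            pos += length * mb

    arm("chr1", "p", 0, [(25, 2, 1)])
    arm("chr1", "q", 25 * mb, [(10, 2, 1), (15, 3, 1)])
    arm("chr2", "p", 0, [(12, 1, 0), (13, 2, 1)])
    arm("chr2", "q", 25 * mb, [(25, 2, 0)])
    arm("chr3", "p", 0, [(8, 2, 1), (17, 4, 2)])
    arm("chr3", "q", 25 * mb, [(10, 3, 0), (15, 2, 1)])
    arm("chr4", "p", 0, [(25, 2, 1)])
    arm("chr4", "q", 25 * mb, [(7, 4, 1), (18, 2, 1)])
    arm("chr5", "p", 0, [(15, 2, 1), (10, 3, 1)])
    arm("chr5", "q", 25 * mb, [(25, 2, 1)])
    arm("chr6", "p", 0, [(9, 2, 0), (16, 2, 1)])
    arm("chr6", "q", 25 * mb, [(11, 3, 0), (14, 2, 1)])

    return pd.DataFrame(rows, columns=["chrom", "arm", "start", "end", "total_cn", "minor_cn"])


def validate_profile(profile: pd.DataFrame) -> None:
    """Check structural invariants of a ground-truth copy-number profile."""
    required = {"chrom", "arm", "start", "end", "total_cn", "minor_cn"}
    missing = required - set(profile.columns)
    if missing:
        raise ValueError(f"profile missing columns: {sorted(missing)}")
    if (profile["end"] <= profile["start"]).any():
        raise ValueError("profile has segments with end <= start")
    if (profile["minor_cn"] < 0).any() or (profile["total_cn"] < 0).any():
        raise ValueError("copy numbers must be non-negative")
    bad = profile["minor_cn"] > profile["total_cn"] - profile["minor_cn"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"minor_cn exceeds total_cn - minor_cn at profile row {i}: "
            "the minor homolog must be the less abundant one"
        )
    for chrom, grp in profile.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
            raise ValueError(f"profile segments overlap on {chrom}")


def arms_from_profile(profile: pd.DataFrame) -> pd.DataFrame:
    """Derive chromosome-arm boundary definitions from a profile.

    Returns the 5-column arm table (chrom, p_start, centromere_start,
    centromere_end, chrom_end).  The centromere is the zero-width boundary
    between the last p segment and the first q segment; a chromosome with
    only one arm gets a degenerate boundary at the respective end.
    """
    rows = []
    for chrom, grp in profile.groupby("chrom", sort=False):
        g = grp.sort_values("start")
        p = g[g["arm"] == "p"]
        q = g[g["arm"] == "q"]
        start = int(g["start"].min())
        end = int(g["end"].max())
        if len(p) and len(q):
            cen = int(p["end"].max())
            cen2 = int(q["start"].min())
        elif len(p):
            cen = cen2 = end
        else:
            cen = cen2 = start
        rows.append((chrom, start, cen, cen2, end))
    return pd.DataFrame(
        rows, columns=["chrom", "p_start", "centromere_start", "centromere_end", "chrom_end"]
    )


def allele_fraction(purity: float, total_cn: float, cn_allele: float) -> float:
    """Expected read fraction of an allele carried by ``cn_allele`` tumor copies.

    The normal cells contribute one copy of each allele, the tumor cells
    ``cn_allele`` of this allele out of ``total_cn`` in all:

        f = (t*c + (1-t)) / (t*n + 2*(1-t))
    """
    num = purity * cn_allele + (1.0 - purity)
    den = purity * total_cn + 2.0 * (1.0 - purity)
    if den <= 0:
        raise ValueError("zero DNA content: purity and total_cn are both 0")
    return num / den


def _draw_counts(rng: np.random.Generator, mean: np.ndarray, overdispersion: float) -> np.ndarray:
    """Poisson counts, or negative binomial when variance inflation is requested."""
    mean = np.asarray(mean, dtype=float)
    if overdispersion == 1.0:
        return rng.poisson(mean)
    # NB with variance = od * mean: p = 1/od, r = mean/(od-1)
    p = 1.0 / overdispersion
    r = np.maximum(mean, 1e-12) / (overdispersion - 1.0)
    return rng.negative_binomial(r, p)


def _synthetic_gc(n: int, rng: np.random.Generator) -> np.ndarray:
    """Spatially correlated GC track: smoothed noise around 0.45."""
    raw = rng.normal(size=n + 49)
    smooth = np.convolve(raw, np.ones(50) / 50.0, mode="valid")
    sd = smooth.std()
    if sd > 0:
        smooth = smooth / sd
    return np.clip(0.45 + 0.06 * smooth, 0.25, 0.65)


def _profile_per_window(profile: pd.DataFrame, chrom: str, starts: np.ndarray,
                        window_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Total and minor copy number of the profile segment containing each window."""
    total = np.full(len(starts), np.nan)
    minor = np.full(len(starts), np.nan)
    for _, seg in profile[profile["chrom"] == chrom].iterrows():
        sel = (starts >= seg["start"]) & (starts < seg["end"])
        total[sel] = seg["total_cn"]
        minor[sel] = seg["minor_cn"]
    if np.isnan(total).any():
        i = int(np.flatnonzero(np.isnan(total))[0])
        raise ValueError(
            f"window {chrom}:{int(starts[i])}-{int(starts[i]) + window_size} "
            "is not covered by any profile segment"
        )
    return total, minor


def simulate_windows(
    profile: pd.DataFrame,
    config: SimulationConfig,
    reference_gc: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate tumor and matched-normal window read counts.

    Parameters
    ----------
    profile:
        Ground-truth copy-number table (chrom, arm, start, end, total_cn,
        minor_cn) covering every window to be simulated.
    config:
        Generator settings; see :class:`SimulationConfig`.
    reference_gc:
        Optional table (chrom, start, end, gc) defining the window grid
        and GC fractions.  By default windows tile each profile chromosome
        and GC is a smooth synthetic track.

    Returns
    -------
    (tumor, normal):
        Two window tables (chrom, start, end, count, gc) on the same grid.
    """
    validate_profile(profile)
    rng = np.random.default_rng(config.seed)
    ws = config.window_size
    bias = config.bias_fn

    frames_t, frames_n = [], []
    for chrom in profile["chrom"].drop_duplicates():
        if reference_gc is not None:
            grid = reference_gc[reference_gc["chrom"] == chrom]
            starts = grid["start"].to_numpy()
            ends = grid["end"].to_numpy()
            gc = grid["gc"].to_numpy(dtype=float)
        else:
            chrom_end = int(profile.loc[profile["chrom"] == chrom, "end"].max())
            chrom_start = int(profile.loc[profile["chrom"] == chrom, "start"].min())
            starts = np.arange(chrom_start, chrom_end, ws)
            ends = np.minimum(starts + ws, chrom_end)
            gc = _synthetic_gc(len(starts), rng)

        total, _ = _profile_per_window(profile, chrom, starts, ws)
        b = bias(gc)
        if (b[np.isfinite(gc)] <= 0).any():
            raise ValueError("gc_bias must be strictly positive on the observed GC range")
        dna = (config.purity * total + 2.0 * (1.0 - config.purity)) / 2.0
        mean_t = config.mean_coverage * b * dna
        mean_n = config.normal_cov * b
        frames_t.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "count": _draw_counts(rng, mean_t, config.overdispersion), "gc": gc,
        }))
        frames_n.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "count": _draw_counts(rng, mean_n, config.overdispersion), "gc": gc,
        }))
    tumor = pd.concat(frames_t, ignore_index=True)
    normal = pd.concat(frames_n, ignore_index=True)
    return tumor, normal


def simulate_het_snps(profile: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Simulate allele counts at constitutively heterozygous SNP positions.

    Positions are uniform within each profile segment with expected count
    ``length * snp_density / 1000``.  Tumor depth is Poisson scaled by
    local DNA content; allele A sits on the major or minor homolog with
    probability 1/2 each.  Matched-normal counts at the same positions are
    Poisson at ``normal_coverage`` depth split 50:50.

    Returns a table (chrom, pos, countA, countB, normal_countA,
    normal_countB, true_total, true_minor) with ``pos`` 1-based.
    """
    validate_profile(profile)
    if config.snp_density <= 0:
        raise ValueError("snp_density must be positive")
    rng = np.random.default_rng(config.seed + 1)
    t = config.purity

    frames = []
    for _, seg in profile.iterrows():
        length = seg["end"] - seg["start"]
        n_snps = rng.poisson(length * config.snp_density / 1000.0)
        if n_snps == 0:
            continue
        pos = np.sort(rng.integers(seg["start"], seg["end"], size=n_snps)) + 1  # 1-based
        n, m = float(seg["total_cn"]), float(seg["minor_cn"])
        dna = (t * n + 2.0 * (1.0 - t)) / 2.0
        depth = rng.poisson(config.mean_coverage * dna, size=n_snps)
        on_major = rng.random(n_snps) < 0.5
        cn_a = np.where(on_major, n - m, m)
        f_a = (t * cn_a + (1.0 - t)) / (t * n + 2.0 * (1.0 - t))
        count_a = rng.binomial(depth, f_a)
        depth_n = rng.poisson(config.normal_cov, size=n_snps)
        normal_a = rng.binomial(depth_n, 0.5)
        frames.append(pd.DataFrame({
            "chrom": seg["chrom"], "pos": pos,
            "countA": count_a, "countB": depth - count_a,
            "normal_countA": normal_a, "normal_countB": depth_n - normal_a,
            "true_total": n, "true_minor": m,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "countA", "countB",
                                     "normal_countA", "normal_countB",
                                     "true_total", "true_minor"])
    return pd.concat(frames, ignore_index=True)


def _mixture_weight(target_purity: float, tumor_ploidy: float) -> float:
    """Tumor DNA fraction of a mixture at the given purity and tumor ploidy."""
    t, p = target_purity, tumor_ploidy
    den = t * p + 2.0 * (1.0 - t)
    return t * p / den if den > 0 else 0.0


def dilute_reads(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    target_purity: float,
    tumor_ploidy: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Mix tumor and matched-normal reads by independent binomial thinning.

    Works on window-count tables (column ``count``) and on SNP allele-count
    tables (columns ``countA``/``countB``); both inputs must be on the same
    window or SNP grid.  Tumor reads are kept with probability ``w`` and
    normal reads with probability ``(1-w) * C_t / C_n``, where ``w`` is the
    tumor DNA fraction implied by the target purity and tumor ploidy and
    ``C_t``/``C_n`` are the samples' mean coverages, so the expected
    tumor:normal read ratio is ``t*P : (1-t)*2`` and expected total
    coverage equals the tumor sample's original coverage.
    """
    if not 0.0 <= target_purity <= 1.0:
        raise ValueError("target_purity must be in [0, 1]")
    count_cols = [c for c in ("count", "countA", "countB") if c in tumor.columns]
    if not count_cols:
        raise ValueError("no count columns found (expected 'count' or 'countA'/'countB')")
    if len(tumor) != len(normal):
        raise ValueError("tumor and normal tables are not on the same grid")

    c_t = float(sum(tumor[c].mean() for c in count_cols))
    c_n = float(sum(normal[c].mean() for c in count_cols))
    w = _mixture_weight(target_purity, tumor_ploidy)
    q_t = w
    q_n = (1.0 - w) * c_t / c_n if c_n > 0 else np.inf
    if q_n > 1.0 + 1e-12:
        # Max achievable purity: solve (1-w*) * c_t = c_n for w*, then invert
        # w = t*P / (t*P + 2*(1-t)) for t.
        w_star = max(1.0 - c_n / c_t, 0.0)
        t_star = 2.0 * w_star / (tumor_ploidy * (1.0 - w_star) + 2.0 * w_star)
        raise ValueError(
            f"normal coverage ({c_n:.2f}) too low to dilute to purity "
            f"{target_purity}; maximum achievable purity is {t_star:.3f}"
        )

    rng = np.random.default_rng(seed)
    out = tumor.copy()
    for c in count_cols:
        kept_t = rng.binomial(tumor[c].to_numpy().astype(np.int64), q_t)
        kept_n = rng.binomial(normal[c].to_numpy().astype(np.int64), min(q_n, 1.0))
        out[c] = kept_t + kept_n
    return out


def write_profile(profile: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    write_table(profile, path, params)


def read_profile(path: str | Path) -> pd.DataFrame:
    profile = read_table(path)
    validate_profile(profile)
    return profile
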