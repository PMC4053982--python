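"""GC and positional bias removal, and 10-kb binning of normalized coverage.

GC normalization groups 200-bp windows by GC fraction (1-percentage-point
groups by default) and divides each window's read count by its group mean,
which removes the smooth, platform-dependent relationship between GC
content and coverage without assuming its shape.  Positional
normalization then divides by a diploid reference profile (a panel of
diploid genomes, or the GC-normalized patient-matched normal), removing
position-specific bias shared across libraries.  Finally the per-window
ratios are averaged into fixed 10-kb bins along each chromosome arm —
arms are binned independently so no bin straddles a centromere — and the
genome-wide median of the non-missing bins is rescaled to 1.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from ._io import read_table, write_table

__all__ = [
    "gc_normalize",
    "positional_normalize",
    "reference_from_normal",
    "bin_ratios",
    "read_arms",
    "read_bins",
    "write_bins",
]


def gc_normalize(windows: pd.DataFrame, gc_bin_width: float = 0.01,
                 min_group: int = 100) -> pd.DataFrame:
    """Divide each window count by the mean count of its GC group.

    Groups narrower than ``gc_bin_width`` in GC fraction with fewer than
    ``min_group`` windows fall back to the global mean (their own mean is
    too noisy to be a denominator).  Windows with missing GC, or in a
    group whose mean is 0, get a missing normalized value.

    Returns a copy of ``windows`` with an added ``norm`` column.
    """
    out = windows.copy()
    count = out["count"].to_numpy(dtype=float)
    gc = out["gc"].to_numpy(dtype=float) if "gc" in out.columns else np.full(len(out), np.nan)
    present = np.isfinite(gc)

    norm = np.full(len(out), np.nan)
    if present.any():
        group = np.floor(gc[present] / gc_bin_width).astype(np.int64)
        df = pd.DataFrame({"group": group, "count": count[present]})
        stats = df.groupby("group")["count"].agg(["mean", "size"])
        global_mean = count[present].mean()
        denom = stats["mean"].where(stats["size"] >= min_group, global_mean)
        denom = denom.where(denom > 0, np.nan)
        norm[present] = count[present] / denom.reindex(group).to_numpy()
    out["norm"] = norm
    return out


def reference_from_normal(normal_windows: pd.DataFrame, floor: float = 0.1,
                          gc_bin_width: float = 0.01, min_group: int = 100) -> pd.DataFrame:
    """Use a patient-matched normal as a single-sample positional reference."""
    from .ingest import build_reference

    return build_reference([normal_windows], floor=floor,
                           gc_bin_width=gc_bin_width, min_group=min_group)


def positional_normalize(sample: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-window ratio of GC-normalized sample to the reference profile.

    ``sample`` must carry a ``norm`` column (from :func:`gc_normalize`)
    and share the reference's window tiling.  The ratio is missing where
    either side is missing.  Returns a copy with an added ``ratio`` column.
    """
    if "norm" not in sample.columns:
        raise ValueError("sample must be GC-normalized first (missing 'norm' column)")
    if len(sample) != len(reference):
        raise ValueError("sample and reference window tilings differ in length")
    s_key = sample[["chrom", "start"]].reset_index(drop=True)
    r_key = reference[["chrom", "start"]].reset_index(drop=True)
    if not s_key.equals(r_key):
        neq = (s_key["chrom"].to_numpy() != r_key["chrom"].to_numpy()) | (
            s_key["start"].to_numpy() != r_key["start"].to_numpy())
        i = int(np.flatnonzero(neq)[0])
        raise ValueError(
            f"window tiling mismatch at {s_key['chrom'].iloc[i]}:{s_key['start'].iloc[i]}"
        )
    out = sample.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio"] = out["norm"].to_numpy() / reference["mean_normalized_count"].to_numpy()
    return out


def read_arms(path: str | Path) -> pd.DataFrame:
    """Chromosome-arm boundaries from a 4- or 5-column TSV.

    Columns: chrom, p_start, centromere_start, centromere_end[, chrom_end].
    A missing chrom_end means the q arm runs to the last window seen.
    """
    df = read_table(path)
    required = {"chrom", "p_start", "centromere_start", "centromere_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"arm table missing columns: {sorted(missing)}")
    if "chrom_end" not in df.columns:
        df["chrom_end"] = np.nan
    return df


def bin_ratios(windows: pd.DataFrame, arms: pd.DataFrame, bin_size: int = 10_000,
               min_window_frac: float = 0.5) -> pd.DataFrame:
    """Average per-window ratios into fixed bins along each chromosome arm.

    A bin's ratio is the mean of its non-missing window ratios and is
    missing when fewer than ``min_window_frac`` of the bin's windows have
    one.  Bins are laid out from each arm's start, so arms are binned
    independently and centromeres are never straddled.  After binning, all
    ratios are divided by the genome-wide median of non-missing bins, so a
    copy-number-neutral majority of the genome sits at 1.

    Returns (chrom, arm, start, end, ratio, n_windows_used).
    """
    if "ratio" not in windows.columns:
        raise ValueError("windows must carry a 'ratio' column (positional_normalize)")
    window_size = int((windows["end"] - windows["start"]).mode().iloc[0])
    expected_per_bin = bin_size / window_size

    arm_rows = []
    for _, a in arms.iterrows():
        arm_rows.append((a["chrom"], "p", int(a["p_start"]), int(a["centromere_start"])))
        chrom_end = a.get("chrom_end", np.nan)
        q_end = int(chrom_end) if np.isfinite(chrom_end) else None
        arm_rows.append((a["chrom"], "q", int(a["centromere_end"]), q_end))

    frames = []
    dropped = 0
    seen = np.zeros(len(windows), dtype=bool)
    starts_all = windows["start"].to_numpy()
    chrom_all = windows["chrom"].to_numpy()
    ratio_all = windows["ratio"].to_numpy(dtype=float)

    for chrom, arm, a_start, a_end in arm_rows:
        on_chrom = chrom_all == chrom
        if a_end is None:
            a_end = int(windows.loc[on_chrom, "end"].max()) if on_chrom.any() else a_start
        if a_end <= a_start:
            continue
        sel = on_chrom & (starts_all >= a_start) & (starts_all < a_end)
        seen |= sel
        if not sel.any():
            continue
        rel = (starts_all[sel] - a_start) // bin_size
        df = pd.DataFrame({"bin": rel, "ratio": ratio_all[sel]})
        agg = df.groupby("bin")["ratio"].agg(mean="mean", n="count")
        agg.loc[agg["n"] < min_window_frac * expected_per_bin, "mean"] = np.nan
        bin_start = a_start + agg.index.to_numpy() * bin_size
        frames.append(pd.DataFrame({
            "chrom": chrom, "arm": arm,
            "start": bin_start,
            "end": np.minimum(bin_start + bin_size, a_end),
            "ratio": agg["mean"].to_numpy(),
            "n_windows_used": agg["n"].to_numpy(),
        }))

    dropped = int((~seen).sum())
    if dropped:
        import warnings

        warnings.warn(f"{dropped} windows fall outside all chromosome arms and were dropped")
    if not frames:
        raise ValueError("no windows fall inside any chromosome arm")
    bins = pd.concat(frames, ignore_index=True)
    med = np.nanmedian(bins["ratio"].to_numpy())
    if not np.isfinite(med) or med <= 0:
        raise ValueError("cannot rescale: genome-wide median bin ratio is not positive")
    bins["ratio"] = bins["ratio"] / med
    return bins


def write_bins(bins: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    write_table(bins, path, params)


def read_bins(path: str | Path) -> pd.DataFrame:
    df = read_table(path)
    required = {"chrom", "arm", "start", "end", "ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"bin table missing columns: {sorted(missing)}")
    return df
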