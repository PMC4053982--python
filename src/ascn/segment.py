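"""Circular binary segmentation (CBS) of binned normalized coverage.

Each chromosome arm is partitioned recursively: the best circular arc is
the pair (i, j) maximizing the two-sample t statistic between the bins
inside the arc [i, j) and the rest of the current segment, and the split
is accepted when the permutation p-value of that maximum is below
``alpha``.  Permutations compare against the same max-t statistic; a
conservative Bonferroni bound on the p-value short-circuits clearly
significant (or hopeless) cases so full permutation runs are only needed
near the decision boundary.  After recursion, adjacent segments whose
means differ by less than ``undo_sd`` noise standard deviations are
re-merged, which removes low-amplitude spurious splits while leaving real
copy-number steps (several SDs tall) intact.

The untransformed ratio is segmented (not log2): the downstream calling
model is linear in normalized coverage, one coverage step per copy.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._io import read_table, write_table

__all__ = ["cbs_segment", "segment_genome", "attach_bins", "read_segments", "write_segments"]

SEGMENT_COLUMNS = ["chrom", "arm", "start", "end", "n_bins", "mean_ratio", "low_confidence"]


def _max_circular_t(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Exhaustive scan for the arc [i, j) maximizing |t| against its complement.

    Only arcs leaving every resulting piece at least ``min_width`` bins
    (or empty) are considered.  Ties break toward the leftmost (smallest
    width, then smallest start) arc.  Returns (t_max, i, j); t_max is nan
    when no valid arc exists or the segment is constant.
    """
    L = len(x)
    sd = x.std(ddof=1) if L > 1 else 0.0
    # effectively-constant segments (sd at float-rounding scale) have no signal
    if L < 2 * min_width or not np.isfinite(sd) or sd <= 1e-10 * max(1.0, abs(x.mean())):
        return (np.nan, 0, L)
    S = np.concatenate([[0.0], np.cumsum(x)])
    total = S[-1]
    best_t, best_i, best_j = -np.inf, 0, L
    idx_all = np.arange(L + 1)
    for k in range(min_width, L - min_width + 1):
        arc = S[k:] - S[: L + 1 - k]  # arc sums for i = 0 .. L-k
        i = idx_all[: L + 1 - k]
        j = i + k
        mean_in = arc / k
        mean_out = (total - arc) / (L - k)
        t = np.abs(mean_in - mean_out) / (sd * np.sqrt(1.0 / k + 1.0 / (L - k)))
        # pieces [0,i) and [j,L) must be empty or >= min_width
        valid = ((i == 0) | (i >= min_width)) & ((j == L) | (j <= L - min_width))
        t = np.where(valid, t, -np.inf)
        m = int(np.argmax(t))
        if t[m] > best_t:
            best_t, best_i, best_j = float(t[m]), int(i[m]), int(j[m])
    if not np.isfinite(best_t):
        return (np.nan, 0, L)
    return best_t, best_i, best_j


def _perm_max_t_block(perms: np.ndarray, sd: float, min_width: int) -> np.ndarray:
    """Max circular |t| per row of a block of permuted segments."""
    B, L = perms.shape
    S = np.concatenate([np.zeros((B, 1)), np.cumsum(perms, axis=1)], axis=1)
    total = S[:, -1:]
    best = np.full(B, -np.inf)
    for k in range(min_width, L - min_width + 1):
        arc = S[:, k:] - S[:, : L + 1 - k]
        i = np.arange(L + 1 - k)
        j = i + k
        valid = ((i == 0) | (i >= min_width)) & ((j == L) | (j <= L - min_width))
        if not valid.any():
            continue
        t = np.abs(arc / k - (total - arc) / (L - k)) / (
            sd * np.sqrt(1.0 / k + 1.0 / (L - k)))
        t[:, ~valid] = -np.inf
        np.maximum(best, t.max(axis=1), out=best)
    return best


def _split_significant(x: np.ndarray, t_obs: float, alpha: float, n_perm: int,
                       min_width: int, rng: np.random.Generator,
                       block: int = 64) -> bool:
    """Permutation test of the max-t statistic, with conservative shortcuts.

    A Bonferroni bound over all considered arcs (t tail with L-2 df)
    decides clear cases without permuting; otherwise permutations run in
    blocks and stop as soon as the exceedance count proves p >= alpha.
    """
    L = len(x)
    if not np.isfinite(t_obs):
        return False
    n_arcs = sum(L + 1 - k for k in range(min_width, L - min_width + 1))
    p_bonf = min(1.0, 2.0 * n_arcs * sps.t.sf(t_obs, df=max(L - 2, 1)))
    if p_bonf < alpha:
        return True

    sd = x.std(ddof=1)
    limit = alpha * n_perm
    # Sequential early rejection: once 20 permutations have exceeded t_obs,
    # the p-value estimate is bounded far above any alpha with
    # alpha * n_perm >= 20, so the remaining permutations cannot change the
    # decision in practice.  The exact rule (exceed > alpha * n_perm) still
    # applies for small n_perm.
    early_cap = 20 if limit >= 20 else np.inf
    exceed = 0
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        perms = rng.permuted(np.tile(x, (b, 1)), axis=1)
        best = _perm_max_t_block(perms, sd, min_width)
        exceed += int((best >= t_obs).sum())
        done += b
        if exceed > limit or exceed >= early_cap:
            return False
    return exceed < limit


def _undo_small_splits(x: np.ndarray, breaks: list[int], undo_sd: float) -> list[int]:
    """Re-merge adjacent segments whose mean difference is below undo_sd * sigma.

    sigma is the per-bin noise SD, estimated robustly from successive
    differences (MAD-based) so that real copy-number steps do not inflate it.
    """
    if undo_sd <= 0 or len(breaks) <= 2:
        return breaks
    d = np.diff(x)
    if len(d) == 0:
        return breaks
    sigma = 1.4826 * np.median(np.abs(d)) / np.sqrt(2.0)
    if sigma == 0:
        return breaks
    breaks = list(breaks)
    while len(breaks) > 2:
        means = [x[breaks[a]:breaks[a + 1]].mean() for a in range(len(breaks) - 1)]
        gaps = np.abs(np.diff(means))
        m = int(np.argmin(gaps))
        if gaps[m] < undo_sd * sigma:
            del breaks[m + 1]
        else:
            break
    return breaks


def cbs_segment(
    bins: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 10_000,
    min_bins: int = 5,
    undo_sd: float = 3.0,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Segment the bins of a single chromosome arm.

    Missing bins are skipped (segments may span them); segment
    coordinates snap to the outermost member bins.  An arm with fewer
    than ``min_bins`` usable bins becomes one segment flagged
    ``low_confidence``.  Permutation decisions are deterministic for a
    given ``rng`` seed or Generator.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    usable = bins[np.isfinite(bins["ratio"].to_numpy(dtype=float))].reset_index(drop=True)
    if usable.empty:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    chrom = usable["chrom"].iloc[0]
    arm = usable["arm"].iloc[0] if "arm" in usable.columns else ""
    x = usable["ratio"].to_numpy(dtype=float)
    L = len(x)

    if L < min_bins:
        return pd.DataFrame([{
            "chrom": chrom, "arm": arm,
            "start": int(usable["start"].iloc[0]), "end": int(usable["end"].iloc[-1]),
            "n_bins": L, "mean_ratio": float(x.mean()), "low_confidence": True,
        }])

    pieces: list[tuple[int, int]] = []
    stack = [(0, L)]
    while stack:
        lo, hi = stack.pop()
        sub = x[lo:hi]
        t_obs, i, j = _max_circular_t(sub, min_bins)
        if not np.isfinite(t_obs) or not _split_significant(
                sub, t_obs, alpha, n_perm, min_bins, rng):
            pieces.append((lo, hi))
            continue
        cuts = sorted({c for c in (i, j) if 0 < c < hi - lo})
        bounds = [lo] + [lo + c for c in cuts] + [hi]
        for a in range(len(bounds) - 1, 0, -1):
            stack.append((bounds[a - 1], bounds[a]))
    pieces.sort()

    breaks = [p[0] for p in pieces] + [L]
    breaks = _undo_small_splits(x, breaks, undo_sd)

    rows = []
    for a in range(len(breaks) - 1):
        lo, hi = breaks[a], breaks[a + 1]
        rows.append({
            "chrom": chrom, "arm": arm,
            "start": int(usable["start"].iloc[lo]), "end": int(usable["end"].iloc[hi - 1]),
            "n_bins": hi - lo, "mean_ratio": float(x[lo:hi].mean()),
            "low_confidence": False,
        })
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def segment_genome(bins: pd.DataFrame, alpha: float = 0.01, n_perm: int = 10_000,
                   min_bins: int = 5, undo_sd: float = 3.0, seed: int = 0) -> pd.DataFrame:
    """Apply :func:`cbs_segment` to every chromosome arm, in input order."""
    rng = np.random.default_rng(seed)
    frames = []
    for (_, _), grp in bins.groupby(["chrom", "arm"], sort=False):
        seg = cbs_segment(grp, alpha=alpha, n_perm=n_perm, min_bins=min_bins,
                          undo_sd=undo_sd, rng=rng)
        if not seg.empty:
            frames.append(seg)
    if not frames:
        return pd.DataFrame(columns=SEGMENT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def attach_bins(segments: pd.DataFrame, bins: pd.DataFrame) -> pd.DataFrame:
    """Recompute each segment's mean_ratio from its member bins.

    A non-missing bin that falls inside no segment of its arm is an
    error: segments are expected to tile the usable extent of each arm.
    """
    out = segments.copy()
    means = np.full(len(out), np.nan)
    counts = np.zeros(len(out), dtype=int)
    assigned = np.zeros(len(bins), dtype=bool)
    b_chrom = bins["chrom"].to_numpy()
    b_arm = bins["arm"].to_numpy() if "arm" in bins.columns else np.full(len(bins), "")
    b_start = bins["start"].to_numpy()
    b_ratio = bins["ratio"].to_numpy(dtype=float)
    usable = np.isfinite(b_ratio)
    for k, seg in enumerate(out.itertuples(index=False)):
        sel = (b_chrom == seg.chrom) & (b_arm == seg.arm) & \
              (b_start >= seg.start) & (b_start < seg.end) & usable
        assigned |= sel
        if sel.any():
            means[k] = b_ratio[sel].mean()
            counts[k] = int(sel.sum())
    orphan = usable & ~assigned
    if orphan.any():
        i = int(np.flatnonzero(orphan)[0])
        raise ValueError(f"bin {b_chrom[i]}:{int(b_start[i])} is not covered by any segment")
    out["mean_ratio"] = means
    out["n_bins"] = counts
    return out


def write_segments(segments: pd.DataFrame, path: str | Path,
                   params: dict | None = None) -> None:
    write_table(segments, path, params)


def read_segments(path: str | Path) -> pd.DataFrame:
    return read_table(path)
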