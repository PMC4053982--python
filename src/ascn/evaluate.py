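"""Performance evaluation against a gold standard, and genome comparison.

Called segments are matched to gold-standard segments (e.g. an
array-based allele-specific analysis, or simulation truth): a call
qualifies when it is at least ``min_len`` long and a single gold segment
covers at least ``min_overlap_frac`` of its length.  Per copy-number
state (n, m), exact total-and-minor matching over the matched pairs
yields a confusion table — each matched segment contributes exactly one
of tp/tn/fp/fn to every state — from which sensitivity
(100*tp/(tp+fn)) and specificity (100*tn/(tn+fp)) are reported to one
decimal.

Two called genomes can also be compared base-pair-wise by gain / loss /
unchanged status relative to each sample's own neutral copy number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "match_segments",
    "truth_labels",
    "confusion_by_state",
    "sensitivity",
    "specificity",
    "genome_agreement",
]


def _best_single_overlap(call, gold: pd.DataFrame) -> tuple[float, int | None]:
    """Largest overlap of a call with any single gold segment, in bp."""
    g = gold[gold["chrom"] == call.chrom]
    if g.empty:
        return 0.0, None
    ov = np.minimum(g["end"].to_numpy(), call.end) - np.maximum(g["start"].to_numpy(), call.start)
    k = int(np.argmax(ov))
    return float(max(ov[k], 0)), g.index[k]


def match_segments(
    calls: pd.DataFrame,
    gold: pd.DataFrame,
    min_len: float = 1_000_000,
    min_overlap_frac: float = 0.75,
    exclude_chroms: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Pair called segments with gold segments for exact-state scoring.

    Returns the qualifying calls with ``gold_total``/``gold_minor``
    columns attached.  ``exclude_chroms`` removes chromosomes known to
    differ between the two sources (e.g. culture divergence) before
    matching.
    """
    rows = []
    for call in calls.itertuples(index=False):
        if call.chrom in exclude_chroms:
            continue
        length = call.end - call.start
        if length < min_len:
            continue
        ov, gi = _best_single_overlap(call, gold)
        if gi is None or ov / length < min_overlap_frac:
            continue
        rec = call._asdict()
        rec["gold_total"] = gold.at[gi, "total_cn"]
        rec["gold_minor"] = gold.at[gi, "minor_cn"]
        rows.append(rec)
    return pd.DataFrame(rows)


def truth_labels(segments: pd.DataFrame, gold: pd.DataFrame,
                 min_overlap_frac: float = 0.75) -> pd.DataFrame:
    """Per-segment (total_cn, minor_cn) of the dominating gold segment.

    Row-aligned with ``segments``; nan where no single gold segment
    covers the required fraction.  Used to calibrate calling anchors on
    simulated data, where the labels are the simulation truth.
    """
    total = np.full(len(segments), np.nan)
    minor = np.full(len(segments), np.nan)
    for k, seg in enumerate(segments.itertuples(index=False)):
        length = seg.end - seg.start
        if length <= 0:
            continue
        ov, gi = _best_single_overlap(seg, gold)
        if gi is not None and ov / length >= min_overlap_frac:
            total[k] = gold.at[gi, "total_cn"]
            minor[k] = gold.at[gi, "minor_cn"]
    return pd.DataFrame({"total_cn": total, "minor_cn": minor}, index=segments.index)


def sensitivity(tp: int, fn: int) -> float:
    """100 * tp / (tp + fn), to one decimal; nan when undefined."""
    if tp + fn == 0:
        return float("nan")
    return round(100.0 * tp / (tp + fn), 1)


def specificity(tn: int, fp: int) -> float:
    """100 * tn / (tn + fp), to one decimal; nan when undefined."""
    if tn + fp == 0:
        return float("nan")
    return round(100.0 * tn / (tn + fp), 1)


def confusion_by_state(matched: pd.DataFrame) -> pd.DataFrame:
    """Exact-state confusion counts over matched call/gold pairs.

    For each state (n, m) present in either source, a matched pair is a
    true positive when both sides are (n, m), a false negative when only
    the gold side is, a false positive when only the call side is, and a
    true negative otherwise.  Row sums are identical across states.
    """
    if matched.empty:
        return pd.DataFrame(columns=["total_cn", "minor_cn", "tp", "tn", "fp", "fn",
                                     "sensitivity", "specificity"])
    call_state = list(zip(matched["total_cn"], matched["minor_cn"]))
    gold_state = list(zip(matched["gold_total"], matched["gold_minor"]))
    states = sorted(set(call_state) | set(gold_state),
                    key=lambda s: (float(s[0]), float(s[1])))
    rows = []
    for state in states:
        is_call = np.array([s == state for s in call_state])
        is_gold = np.array([s == state for s in gold_state])
        tp = int((is_call & is_gold).sum())
        fn = int((~is_call & is_gold).sum())
        fp = int((is_call & ~is_gold).sum())
        tn = int((~is_call & ~is_gold).sum())
        rows.append({
            "total_cn": state[0], "minor_cn": state[1],
            "tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "sensitivity": sensitivity(tp, fn),
            "specificity": specificity(tn, fp),
        })
    return pd.DataFrame(rows)


def _classify(calls: pd.DataFrame, neutral: float) -> list[tuple[str, int, int, int]]:
    out = []
    for c in calls.itertuples(index=False):
        if pd.isna(c.total_cn):
            continue
        status = int(np.sign(c.total_cn - neutral))
        out.append((c.chrom, int(c.start), int(c.end), status))
    return out


def genome_agreement(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
                     neutral_cn_a: float, neutral_cn_b: float) -> float:
    """Fraction of compared base pairs with concordant gain/loss/unchanged status.

    Each base is classified relative to its sample's neutral copy number
    (typically the nearest integer to that sample's average ploidy);
    only bases called in both samples are compared.
    """
    a = _classify(calls_a, neutral_cn_a)
    b = _classify(calls_b, neutral_cn_b)
    agree = 0
    compared = 0
    for chrom in {x[0] for x in a} & {x[0] for x in b}:
        sa = [x for x in a if x[0] == chrom]
        sb = [x for x in b if x[0] == chrom]
        edges = sorted({x[1] for x in sa + sb} | {x[2] for x in sa + sb})
        for lo, hi in zip(edges[:-1], edges[1:]):
            stat_a = next((s for _, s0, e0, s in sa if s0 <= lo and hi <= e0), None)
            stat_b = next((s for _, s0, e0, s in sb if s0 <= lo and hi <= e0), None)
            if stat_a is None or stat_b is None:
                continue
            compared += hi - lo
            if stat_a == stat_b:
                agree += hi - lo
    if compared == 0:
        return float("nan")
    return agree / compared
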