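"""Allele-specific copy number calling and purity/ploidy estimation.

Segments live in a two-dimensional space: normalized coverage (x) and
allelic imbalance ratio (y).  Copy-number states (n, m) — n total copies,
m copies of the minor homolog — form a lattice of clusters in this space.
Calling requires an initial read-off of the cluster pattern, exactly the
quantities an analyst takes from the diagnostic scatter plot:

- ``delta_obs``:  the coverage difference corresponding to one copy,
- ``cn2_ratio``:  the coverage of the total-copy-2 cluster,
- ``ai_2m1``:     the imbalance ratio of the balanced-diploid cluster,
- ``ai_2m0``:     the imbalance ratio of the diploid-LOH cluster.

Expected coverage of state (n, m) is ``cn2_ratio + (n-2)*delta_obs``.
Expected imbalance comes from a generative model of the max/min allele
counts: at tumor cell fraction p, a heterozygous SNP in an (n, m) region
has major-allele fraction f = (p*(n-m) + (1-p)) / (p*n + 2*(1-p)); with
read depth d, the allele-count difference A - B is approximately normal
with mean d*(2f - 1) and variance d, so the per-SNP |A - B| is folded
normal and the pooled segment ratio is

    ai(n, m) = 2*E|A - B| / (d + E|A - B|).

The two free parameters — a noise-scale kappa multiplying sqrt(d) and
the implied purity p — are calibrated so the model reproduces the two
user anchors ai_2m1 and ai_2m0 exactly.  This absorbs the positive
finite-depth bias of the max/min estimator, which grows as depth falls.
When no anchor depth is available the model degenerates (kappa -> 0 for
ai_2m1 = 0) to the ideal, bias-free lattice

    ideal_ai(n, m) = p*(n - 2m) / (p*(n - m) + (1 - p)),

and a purely algebraic anchor interpolation is used instead.

From the calls, average tumor ploidy is the length-weighted mean total
copy number; the expected one-copy coverage step in a pure tumor is
1/ploidy; the ratio of observed to expected step is the tumor DNA
fraction; and inverting the two-population mixture (normal cells
diploid) turns DNA fraction into tumor cell fraction:

    cellfrac = 1 / (1 + (ploidy/2) * (1/dnafrac - 1)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import erf

from ._io import write_table

__all__ = [
    "SampleModel",
    "expected_cluster",
    "assign_copy_numbers",
    "average_ploidy",
    "delta_expected",
    "tumor_dna_fraction",
    "cell_fraction",
    "dna_fraction_from_mixture",
    "estimate_sample",
    "fit_anchors",
    "write_calls",
]


@dataclass
class SampleModel:
    """Calling anchors and derived sample-level estimates.

    The four anchors are inputs (read from the scatter plot, or
    calibrated from labeled segments); ploidy, DNA fraction and cell
    fraction are filled in by :func:`estimate_sample` after calling.
    ``anchor_depth`` is the mean heterozygous-SNP read depth of the
    copy-2 clusters; when present, the depth-aware imbalance bias model
    is used.
    """

    delta_obs: float
    cn2_ratio: float
    ai_2m1: float
    ai_2m0: float
    max_cn: int = 8
    anchor_depth: float | None = None
    ploidy_tum: float | None = None
    delta_exp: float | None = None
    dnafrac_tum: float | None = None
    cellfrac_tum: float | None = None

    def __post_init__(self) -> None:
        if self.delta_obs <= 0:
            raise ValueError("delta_obs must be positive")
        if not 0.0 <= self.ai_2m1 < self.ai_2m0 <= 1.0:
            raise ValueError("anchors must satisfy 0 <= ai_2m1 < ai_2m0 <= 1")

    @property
    def ai_scale(self) -> float:
        """Natural unit of the imbalance axis: half the 2m1-to-2m0 span."""
        return (self.ai_2m0 - self.ai_2m1) / 2.0

    def implied_purity(self) -> float:
        """Tumor cell fraction implied by the two imbalance anchors."""
        if self.anchor_depth is not None:
            _, p = _calibrate_bias(self.ai_2m1, self.ai_2m0, self.anchor_depth)
            return p
        ai_adj = (self.ai_2m0 - self.ai_2m1) / (1.0 - self.ai_2m1)
        return ai_adj / (2.0 - ai_adj)


def _folded_normal_mean(mu: float, sigma: float) -> float:
    """E|X| for X ~ Normal(mu, sigma^2)."""
    if sigma <= 0:
        return abs(mu)
    z = mu / (sigma * math.sqrt(2.0))
    return sigma * math.sqrt(2.0 / math.pi) * math.exp(-z * z) + mu * erf(z)


def _pooled_ai(mu: float, sigma: float, depth: float) -> float:
    """Segment-level imbalance ratio implied by the per-SNP |A-B| model."""
    f = _folded_normal_mean(mu, sigma)
    return 2.0 * f / (depth + f)


def _calibrate_bias(ai_2m1: float, ai_2m0: float, depth: float) -> tuple[float, float]:
    """Solve (kappa, purity) so the depth model reproduces both anchors.

    At (2,1) the allele counts are balanced, so the observed ratio is
    pure noise: F = ai_2m1*d/(2-ai_2m1) gives kappa in closed form.  At
    (2,0) the difference mean is d*p while the SD stays kappa*sqrt(d)
    (Poisson-thinned alleles are independent), so p solves a monotone
    1-D equation.
    """
    f21 = ai_2m1 * depth / (2.0 - ai_2m1)
    kappa = f21 / (math.sqrt(depth) * math.sqrt(2.0 / math.pi)) if depth > 0 else 0.0
    sigma = kappa * math.sqrt(depth)

    def g(p: float) -> float:
        return _pooled_ai(depth * p, sigma, depth) - ai_2m0

    if g(1.0) <= 0:
        return kappa, 1.0
    if g(0.0) >= 0:
        return kappa, 0.0
    return kappa, brentq(g, 0.0, 1.0, xtol=1e-14)


def expected_cluster(total_cn: int, minor_cn: int, model: SampleModel,
                     ) -> tuple[float, float]:
    """Expected (normalized coverage, imbalance ratio) of state (n, m).

    The coverage coordinate is linear: one ``delta_obs`` per copy away
    from the copy-2 cluster.  The imbalance coordinate reproduces the
    anchors exactly — (2,1) -> ai_2m1, (2,0) -> ai_2m0 — and
    interpolates the remaining lattice with the bias model described in
    the module docstring.  For n = 0 there are no alleles to compare and
    the imbalance is undefined (nan).
    """
    n, m = total_cn, minor_cn
    if not (0 <= m <= n - m if n > 0 else m == 0):
        raise ValueError(f"invalid state ({n},{m}): need 0 <= m <= n - m")
    ratio = model.cn2_ratio + (n - 2) * model.delta_obs
    if n == 0:
        return ratio, float("nan")

    if model.anchor_depth is not None and model.anchor_depth > 0:
        kappa, p = _calibrate_bias(model.ai_2m1, model.ai_2m0, model.anchor_depth)
        dna = p * n + 2.0 * (1.0 - p)
        if dna <= 0:
            return ratio, float("nan")
        f = (p * (n - m) + (1.0 - p)) / dna
        d_n = model.anchor_depth * dna / 2.0
        ai = _pooled_ai(d_n * (2.0 * f - 1.0), kappa * math.sqrt(d_n), d_n)
        return ratio, float(ai)

    # algebraic fallback: de-bias the anchors, invert for purity, and
    # map the ideal lattice back through the 2m1 offset
    ai_adj = (model.ai_2m0 - model.ai_2m1) / (1.0 - model.ai_2m1)
    p = ai_adj / (2.0 - ai_adj)
    denom = p * (n - m) + (1.0 - p)
    ideal = p * (n - 2 * m) / denom if denom > 0 else 1.0
    ai = model.ai_2m1 + (1.0 - model.ai_2m1) * ideal
    return ratio, float(ai)


def _lattice(max_cn: int) -> list[tuple[int, int]]:
    """All (n, m) states up to max_cn, ordered for lower-n/higher-m tie-breaks."""
    states = []
    for n in range(0, max_cn + 1):
        for m in range(n // 2, -1, -1):
            states.append((n, m))
    return states


def assign_copy_numbers(segments: pd.DataFrame, model: SampleModel) -> pd.DataFrame:
    """Assign each segment the lattice state minimizing a scaled distance.

    The distance normalizes each axis by its natural unit — one copy on
    the coverage axis, half the 2m1-to-2m0 span on the imbalance axis:

        d^2 = ((ratio - e_ratio)/delta_obs)^2 + ((ai - e_ai)/s_ai)^2

    Segments without a usable imbalance ratio are matched on coverage
    alone and their minor copy number is reported missing.  Ties break
    toward lower total, then higher minor, copy number.  The continuous
    coverage-implied copy number ``n_continuous`` is reported alongside
    for regions (heterogeneous, chromothripsis-like) where integer states
    are not the right description, and calls above ``max_cn`` rely on it.
    """
    states = _lattice(model.max_cn)
    exp = {s: expected_cluster(s[0], s[1], model) for s in states}
    s_ai = model.ai_scale

    ratios = segments["mean_ratio"].to_numpy(dtype=float)
    ais = segments["ai_ratio"].to_numpy(dtype=float) if "ai_ratio" in segments.columns \
        else np.full(len(segments), np.nan)

    total = np.zeros(len(segments), dtype=np.int64)
    minor = np.full(len(segments), np.nan)
    dist = np.full(len(segments), np.nan)
    for k in range(len(segments)):
        r, ai = ratios[k], ais[k]
        if not np.isfinite(r):
            total[k] = -1
            continue
        use_ai = np.isfinite(ai)
        best, best_d = None, np.inf
        for (n, m) in states:
            er, ea = exp[(n, m)]
            d2 = ((r - er) / model.delta_obs) ** 2
            if use_ai and np.isfinite(ea):
                d2 += ((ai - ea) / s_ai) ** 2
            if d2 < best_d:
                best, best_d = (n, m), d2
        total[k] = best[0]
        minor[k] = best[1] if use_ai else np.nan
        dist[k] = math.sqrt(best_d)

    out = segments.copy()
    out["total_cn"] = total
    out["minor_cn"] = pd.array(minor, dtype="Int64")
    out["n_continuous"] = 2.0 + (ratios - model.cn2_ratio) / model.delta_obs
    out["distance"] = dist
    out.loc[out["total_cn"] < 0, "total_cn"] = pd.NA
    out["total_cn"] = out["total_cn"].astype("Int64")
    return out


def average_ploidy(calls: pd.DataFrame) -> float:
    """Length-weighted mean total copy number over called segments."""
    ok = calls["total_cn"].notna() & np.isfinite(calls["mean_ratio"].to_numpy(dtype=float))
    if not ok.any():
        raise ValueError("no called segments to average")
    length = (calls.loc[ok, "end"] - calls.loc[ok, "start"]).to_numpy(dtype=float)
    n = calls.loc[ok, "total_cn"].to_numpy(dtype=float)
    return float((length * n).sum() / length.sum())


def delta_expected(ploidy_tum: float) -> float:
    """Coverage step per copy expected in a pure tumor: 1 / ploidy."""
    if ploidy_tum <= 0:
        raise ValueError("ploidy must be positive")
    return 1.0 / ploidy_tum


def tumor_dna_fraction(delta_obs: float, delta_exp: float) -> float:
    """Fraction of sample DNA that is tumor-derived: delta_obs / delta_exp.

    ``delta_obs`` must be on the scale where the genome-average
    normalized coverage is 1.  Clipped into (0, 1].
    """
    if delta_obs <= 0 or delta_exp <= 0:
        raise ValueError("delta_obs and delta_exp must be positive")
    return float(min(delta_obs / delta_exp, 1.0))


def cell_fraction(dnafrac_tum: float, ploidy_tum: float) -> float:
    """Tumor cell fraction from DNA fraction, assuming diploid normal cells."""
    if not 0.0 < dnafrac_tum <= 1.0:
        raise ValueError("dnafrac_tum must be in (0, 1]")
    if ploidy_tum <= 0:
        raise ValueError("ploidy must be positive")
    return 1.0 / (1.0 + (ploidy_tum / 2.0) * (1.0 / dnafrac_tum - 1.0))


def dna_fraction_from_mixture(cellfrac_tum: float, ploidy_tum: float) -> float:
    """Forward mixture: DNA fraction of a sample with the given purity and ploidy."""
    t, p = cellfrac_tum, ploidy_tum
    den = t * p + (1.0 - t) * 2.0
    if den <= 0:
        raise ValueError("mixture has no DNA")
    return t * p / den


def estimate_sample(model: SampleModel, calls: pd.DataFrame) -> SampleModel:
    """Fill in ploidy, DNA fraction and cell fraction from the calls.

    ``delta_obs`` is measured on the plot's arbitrary normalized-coverage
    scale; dividing by the length-weighted mean coverage of the called
    genome moves it to the scale where the genome average is 1, which is
    what the DNA-fraction relation assumes.
    """
    ploidy = average_ploidy(calls)
    d_exp = delta_expected(ploidy)
    ok = calls["total_cn"].notna() & np.isfinite(calls["mean_ratio"].to_numpy(dtype=float))
    length = (calls.loc[ok, "end"] - calls.loc[ok, "start"]).to_numpy(dtype=float)
    mean_cov = float((length * calls.loc[ok, "mean_ratio"].to_numpy(dtype=float)).sum()
                     / length.sum())
    dnafrac = tumor_dna_fraction(model.delta_obs / mean_cov, d_exp)
    cellfrac = cell_fraction(dnafrac, ploidy)
    return replace(model, ploidy_tum=ploidy, delta_exp=d_exp,
                   dnafrac_tum=dnafrac, cellfrac_tum=cellfrac)


def fit_anchors(segments: pd.DataFrame, labels: pd.DataFrame,
                max_cn: int = 8) -> SampleModel:
    """Calibrate the calling anchors from segments with known (n, m) labels.

    This mirrors what an analyst reads off the scatter plot, using
    labeled clusters instead of eyes: ``delta_obs`` and ``cn2_ratio``
    come from a length-weighted linear fit of segment coverage against
    total copy number; the imbalance anchors are the pooled ratios of
    the labeled (2,1) and (2,0) clusters; the anchor depth is the mean
    heterozygous-SNP depth over copy-2 segments.

    ``labels`` must align row-wise with ``segments`` and carry
    ``total_cn``/``minor_cn`` columns (nan = unlabeled).
    """
    if len(labels) != len(segments):
        raise ValueError("labels must align with segments")
    n_true = labels["total_cn"].to_numpy(dtype=float)
    m_true = labels["minor_cn"].to_numpy(dtype=float)
    ratio = segments["mean_ratio"].to_numpy(dtype=float)
    length = (segments["end"] - segments["start"]).to_numpy(dtype=float)
    ok = np.isfinite(n_true) & np.isfinite(ratio)
    if ok.sum() < 2 or len(np.unique(n_true[ok])) < 2:
        raise ValueError("need labeled segments at two or more total copy numbers")
    slope, intercept = np.polyfit(n_true[ok], ratio[ok], 1, w=np.sqrt(length[ok]))
    if slope <= 0:
        raise ValueError("fitted coverage step per copy is not positive")

    def pooled_ai(mask: np.ndarray) -> float:
        sh = segments.loc[mask, "sum_high"].sum()
        sl = segments.loc[mask, "sum_low"].sum()
        return (sh - sl) / sh if sh > 0 else float("nan")

    is21 = ok & (n_true == 2) & (m_true == 1)
    is20 = ok & (n_true == 2) & (m_true == 0)
    if not is21.any() or not is20.any():
        raise ValueError("anchor calibration needs labeled (2,1) and (2,0) segments")
    ai21 = pooled_ai(is21)
    ai20 = pooled_ai(is20)

    cn2 = ok & (n_true == 2)
    reads = (segments.loc[cn2, "sum_high"] + segments.loc[cn2, "sum_low"]).sum()
    n_snps = segments.loc[cn2, "n_het_snps"].sum()
    depth = float(reads / n_snps) if n_snps > 0 else None

    return SampleModel(delta_obs=float(slope), cn2_ratio=float(intercept + 2 * slope),
                       ai_2m1=float(ai21), ai_2m0=float(ai20),
                       max_cn=max_cn, anchor_depth=depth)


def write_calls(calls: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    write_table(calls, path, params)
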