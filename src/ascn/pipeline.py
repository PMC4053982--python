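"""End-to-end orchestration of the analysis stages.

The workflow is deliberately two-phase, mirroring how the method is used
in practice:

1. ``plot_stage``: window counts -> GC normalization -> positional
   normalization against a diploid reference -> 10-kb binning per arm ->
   CBS segmentation -> per-segment allelic imbalance.  Its output is the
   segment table behind the diagnostic scatter plot.
2. ``call_stage``: given the four calling anchors (read off the plot, or
   calibrated from labeled segments), assign allele-specific copy
   numbers and estimate average ploidy, tumor DNA fraction and tumor
   cell fraction.

Both phases are deterministic for a given seed and parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import callcn, imbalance, normalize, segment

__all__ = ["PipelineParams", "plot_stage", "call_stage"]


@dataclass
class PipelineParams:
    """Every tunable of the plot stage, with its documented default."""

    gc_bin_width: float = 0.01
    min_gc_group: int = 100
    bin_size: int = 10_000
    min_window_frac: float = 0.5
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 10_000
    cbs_min_bins: int = 5
    cbs_undo_sd: float = 3.0
    het_min_depth: int = 5
    het_min_minor_fraction: float = 0.2
    min_snps: int = 10
    seed: int = 0


def plot_stage(
    tumor_windows: pd.DataFrame,
    reference: pd.DataFrame,
    arms: pd.DataFrame,
    snps: pd.DataFrame | None = None,
    params: PipelineParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize, bin, segment, and attach allelic imbalance.

    Returns (bins, segments); the segments carry mean_ratio and, when
    SNP counts are supplied, ai_ratio / sum_high / sum_low / n_het_snps.
    """
    p = params or PipelineParams()
    gc_normed = normalize.gc_normalize(tumor_windows, gc_bin_width=p.gc_bin_width,
                                       min_group=p.min_gc_group)
    ratios = normalize.positional_normalize(gc_normed, reference)
    bins = normalize.bin_ratios(ratios, arms, bin_size=p.bin_size,
                                min_window_frac=p.min_window_frac)
    segments = segment.segment_genome(bins, alpha=p.cbs_alpha, n_perm=p.cbs_n_perm,
                                      min_bins=p.cbs_min_bins, undo_sd=p.cbs_undo_sd,
                                      seed=p.seed)
    if snps is not None:
        het = imbalance.call_heterozygous(snps, min_depth=p.het_min_depth,
                                          min_minor_fraction=p.het_min_minor_fraction)
        segments = imbalance.attach_imbalance(segments, het, min_snps=p.min_snps)
    return bins, segments


def call_stage(segments: pd.DataFrame, model: callcn.SampleModel,
               ) -> tuple[pd.DataFrame, callcn.SampleModel]:
    """Assign copy numbers and fill in the sample-level estimates."""
    calls = callcn.assign_copy_numbers(segments, model)
    fitted = callcn.estimate_sample(model, calls)
    return calls, fitted
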