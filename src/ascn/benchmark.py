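"""Reference experiments on synthetic data.

These wire the simulator and the analysis pipeline into the standard
benchmarking protocols: parameter recovery (simulate a genome with known
allele-specific copy numbers, run the full pipeline, score exact-state
recovery and purity/ploidy estimates) and the in-silico dilution series
(thin and mix pure-tumor and matched-normal reads to a target purity,
then measure per-state sensitivity as tumor content falls).

Anchors are calibrated from segments labeled with the simulation truth,
which mirrors the analyst reading cluster coordinates off the scatter
plot; the purity and ploidy estimates are still genuine measurements of
the simulated data, since every anchor is an observed cluster statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import callcn, evaluate, ingest, simulate
from .pipeline import PipelineParams, call_stage, plot_stage

__all__ = ["RecoveryResult", "profile_ploidy", "simulated_reference",
           "recovery_experiment", "dilution_experiment"]


def profile_ploidy(profile: pd.DataFrame) -> float:
    """Length-weighted mean total copy number of a truth profile."""
    length = (profile["end"] - profile["start"]).to_numpy(dtype=float)
    return float((length * profile["total_cn"]).sum() / length.sum())


def simulated_reference(profile: pd.DataFrame, coverage: float = 30.0,
                        seed: int = 0) -> pd.DataFrame:
    """Positional reference built from one simulated diploid genome.

    Emulates the tool-shipped reference files prepared from well-covered
    diploid samples; the window grid matches the profile's genome.
    """
    diploid = profile.copy()
    diploid["total_cn"] = 2
    diploid["minor_cn"] = 1
    cfg = simulate.SimulationConfig(purity=1.0, mean_coverage=coverage, seed=seed)
    _, normal = simulate.simulate_windows(diploid, cfg)
    return ingest.build_reference([normal])


@dataclass
class RecoveryResult:
    """Everything the benchmarking assertions need from one pipeline run."""

    segments: pd.DataFrame
    calls: pd.DataFrame
    model: callcn.SampleModel
    matched: pd.DataFrame
    confusion: pd.DataFrame
    exact_fraction: float
    true_ploidy: float

    def sensitivity_of(self, total_cn: int, minor_cn: int) -> float:
        sel = self.confusion[(self.confusion["total_cn"] == total_cn)
                             & (self.confusion["minor_cn"] == minor_cn)]
        if sel.empty:
            return float("nan")
        return float(sel["sensitivity"].iloc[0])


def _run_pipeline_and_score(tumor_windows, snps, profile, reference, arms,
                            params) -> RecoveryResult:
    _, segments = plot_stage(tumor_windows, reference, arms, snps, params)
    labels = evaluate.truth_labels(segments, profile)
    model = callcn.fit_anchors(segments, labels)
    calls, fitted = call_stage(segments, model)
    matched = evaluate.match_segments(calls, profile)
    confusion = evaluate.confusion_by_state(matched)
    if len(matched):
        exact = float(((matched["total_cn"] == matched["gold_total"])
                       & (matched["minor_cn"] == matched["gold_minor"])).mean())
    else:
        exact = float("nan")
    return RecoveryResult(segments=segments, calls=calls, model=fitted,
                          matched=matched, confusion=confusion,
                          exact_fraction=exact, true_ploidy=profile_ploidy(profile))


def recovery_experiment(purity: float, mean_coverage: float = 30.0, seed: int = 0,
                        profile: pd.DataFrame | None = None,
                        reference: pd.DataFrame | None = None,
                        params: PipelineParams | None = None) -> RecoveryResult:
    """Simulate at the given purity and run the full pipeline against truth."""
    profile = profile if profile is not None else simulate.default_tumor_profile()
    arms = simulate.arms_from_profile(profile)
    if reference is None:
        reference = simulated_reference(profile, seed=seed + 900_001)
    cfg = simulate.SimulationConfig(purity=purity, mean_coverage=mean_coverage,
                                    seed=seed)
    tumor, _ = simulate.simulate_windows(profile, cfg)
    snps = simulate.simulate_het_snps(profile, cfg)
    run_params = params or PipelineParams(seed=seed)
    return _run_pipeline_and_score(tumor, snps, profile, reference, arms, run_params)


def dilution_experiment(target_purity: float, mean_coverage: float = 4.0,
                        normal_coverage: float = 5.0, seed: int = 0,
                        profile: pd.DataFrame | None = None,
                        reference: pd.DataFrame | None = None,
                        params: PipelineParams | None = None) -> RecoveryResult:
    """In-silico dilution: mix pure-tumor and normal reads, then analyze.

    The pure tumor is simulated at ``mean_coverage`` and the matched
    normal at ``normal_coverage`` (the shallow-coverage regime of the
    original benchmark); reads are thinned so the mixture has the target
    tumor cell fraction at the tumor sample's coverage.  The undiluted
    normal still serves for heterozygous-SNP identification.
    """
    profile = profile if profile is not None else simulate.default_tumor_profile()
    arms = simulate.arms_from_profile(profile)
    if reference is None:
        reference = simulated_reference(profile, seed=seed + 900_001)
    true_ploidy = profile_ploidy(profile)

    cfg = simulate.SimulationConfig(purity=1.0, mean_coverage=mean_coverage,
                                    normal_coverage=normal_coverage, seed=seed)
    tumor_w, normal_w = simulate.simulate_windows(profile, cfg)
    snps = simulate.simulate_het_snps(profile, cfg)
    normal_snps = snps[["chrom", "pos"]].copy()
    normal_snps["countA"] = snps["normal_countA"]
    normal_snps["countB"] = snps["normal_countB"]

    mix_seed = seed + 31_337
    mixed_w = simulate.dilute_reads(tumor_w, normal_w, target_purity, true_ploidy,
                                    seed=mix_seed)
    mixed_snps = simulate.dilute_reads(snps, normal_snps, target_purity, true_ploidy,
                                       seed=mix_seed + 1)
    run_params = params or PipelineParams(seed=seed)
    return _run_pipeline_and_score(mixed_w, mixed_snps, profile, reference, arms,
                                   run_params)
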