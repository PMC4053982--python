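"""GC normalization, positional normalization, and 10-kb binning."""

import numpy as np
import pandas as pd
import pytest

from ascn import ingest, normalize, simulate
from conftest import make_bins


def windows_df(counts, gc, start=0):
    counts = np.asarray(counts, dtype=float)
    gc = np.broadcast_to(np.asarray(gc, dtype=float), counts.shape)
    starts = start + np.arange(len(counts)) * 200
    return pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 200,
                         "count": counts, "gc": gc})


class TestGcNormalize:
    def test_uniform_gc_self_normalizes_to_one(self):
        w = windows_df(np.full(500, 10.0), 0.5)
        out = normalize.gc_normalize(w)
        assert np.allclose(out["norm"], 1.0)

    def test_window_divided_by_its_group_mean(self):
        # two GC groups with means 10 and 20; a count of 15 in the second -> 0.75
        counts = np.concatenate([np.full(10, 10.0), np.full(9, 20.0), [15.0]])
        gc = np.concatenate([np.full(10, 0.40), np.full(10, 0.55)])
        out = normalize.gc_normalize(windows_df(counts, gc), min_group=5)
        group2 = out[out["gc"] == 0.55]["norm"]
        assert group2.iloc[-1] == pytest.approx(15.0 / 19.5)
        # check against the exact group mean
        assert out["norm"].iloc[-1] == pytest.approx(15.0 / np.mean(counts[10:]))

    def test_multiplicative_bias_removed_groupwise(self):
        rng = np.random.default_rng(1)
        gc = rng.uniform(0.3, 0.6, size=5000).round(3)
        bias = simulate.default_gc_bias(gc)
        w = windows_df(100.0 * bias, gc)
        out = normalize.gc_normalize(w, min_group=1)
        group = np.floor(out["gc"] / 0.01).astype(int)
        means = out.groupby(group)["norm"].mean()
        assert np.allclose(means, 1.0, atol=1e-9)

    def test_small_group_falls_back_to_global_mean(self):
        counts = np.concatenate([np.full(200, 10.0), [40.0]])
        gc = np.concatenate([np.full(200, 0.45), [0.80]])
        out = normalize.gc_normalize(windows_df(counts, gc), min_group=100)
        global_mean = counts.mean()
        assert out["norm"].iloc[-1] == pytest.approx(40.0 / global_mean)

    def test_missing_gc_gives_missing_value(self):
        w = windows_df(np.full(120, 10.0), 0.5)
        w.loc[0, "gc"] = np.nan
        out = normalize.gc_normalize(w)
        assert np.isnan(out["norm"].iloc[0])


class TestPositionalNormalize:
    def make_ref(self, w, values):
        return pd.DataFrame({"chrom": w["chrom"], "start": w["start"], "end": w["end"],
                             "mean_normalized_count": values})

    def test_unit_reference_is_identity(self):
        w = normalize.gc_normalize(windows_df(np.full(150, 10.0), 0.5))
        ref = self.make_ref(w, np.ones(len(w)))
        out = normalize.positional_normalize(w, ref)
        assert np.allclose(out["ratio"], out["norm"])

    def test_ratio_is_elementwise_division(self):
        w = windows_df(np.full(150, 10.0), 0.5)
        w = normalize.gc_normalize(w)
        values = np.ones(len(w))
        values[3] = 0.75
        w.loc[3, "norm"] = 1.5
        ref = self.make_ref(w, values)
        out = normalize.positional_normalize(w, ref)
        assert out["ratio"].iloc[3] == pytest.approx(2.0)

    def test_missing_reference_propagates(self):
        w = normalize.gc_normalize(windows_df(np.full(150, 10.0), 0.5))
        values = np.ones(len(w))
        values[7] = np.nan
        out = normalize.positional_normalize(w, self.make_ref(w, values))
        assert np.isnan(out["ratio"].iloc[7])

    def test_tiling_mismatch_fails(self):
        w = normalize.gc_normalize(windows_df(np.full(150, 10.0), 0.5))
        ref = self.make_ref(w, np.ones(len(w))).copy()
        ref.loc[2, "start"] = 12345
        with pytest.raises(ValueError, match="mismatch"):
            normalize.positional_normalize(w, ref)


def arms_df(chrom="chr1", p_start=0, cen=20_000, chrom_end=40_000):
    return pd.DataFrame({"chrom": [chrom], "p_start": [p_start],
                         "centromere_start": [cen], "centromere_end": [cen],
                         "chrom_end": [chrom_end]})


class TestBinRatios:
    def windows_with_ratio(self, ratios_per_window):
        w = windows_df(np.full(len(ratios_per_window), 10.0), 0.5)
        w["ratio"] = ratios_per_window
        return w

    def test_bin_mean_and_median_rescale(self):
        # 200 windows = 2 bins per arm x 2 arms; constant ratio rescales to 1
        w = self.windows_with_ratio(np.full(200, 1.2))
        bins = normalize.bin_ratios(w, arms_df(), bin_size=10_000)
        assert len(bins) == 4
        assert np.allclose(bins["ratio"], 1.0)
        assert (bins["n_windows_used"] == 50).all()

    def test_quorum_rule_marks_sparse_bins_missing(self):
        ratios = np.full(200, 1.2)
        ratios[50:80] = np.nan  # second bin keeps 20/50 windows -> below 50%
        bins = normalize.bin_ratios(self.windows_with_ratio(ratios), arms_df())
        assert np.isnan(bins["ratio"].iloc[1])
        assert bins["n_windows_used"].iloc[1] == 20

    def test_bins_never_straddle_centromere(self):
        # centromere at 15 kb: p arm gets bins [0,10k),[10k,15k); q restarts at 15k
        w = self.windows_with_ratio(np.full(200, 1.0))
        bins = normalize.bin_ratios(w, arms_df(cen=15_000), bin_size=10_000)
        p = bins[bins["arm"] == "p"]
        q = bins[bins["arm"] == "q"]
        assert p["end"].max() == 15_000
        assert q["start"].min() == 15_000

    def test_relative_coverage_of_gained_region(self):
        # a quarter of the genome at 1.5x the rest: median anchors the majority at 1
        ratios = np.concatenate([np.full(150, 1.0), np.full(50, 1.5)])
        bins = normalize.bin_ratios(self.windows_with_ratio(ratios), arms_df())
        assert bins["ratio"].iloc[0] == pytest.approx(1.0)
        assert bins["ratio"].iloc[-1] == pytest.approx(1.5)


class TestPipelineInvariants:
    def run_to_bins(self, counts_scale=1.0, seed=20, purity=1.0, profile=None):
        if profile is None:
            mb = 1_000_000
            profile = pd.DataFrame(
                [("chr1", "p", 0, 10 * mb, 2, 1), ("chr1", "q", 10 * mb, 20 * mb, 2, 1)],
                columns=["chrom", "arm", "start", "end", "total_cn", "minor_cn"])
        cfg = simulate.SimulationConfig(purity=purity, mean_coverage=30.0, seed=seed)
        tumor, normal = simulate.simulate_windows(profile, cfg)
        tumor = tumor.copy()
        tumor["count"] = tumor["count"] * counts_scale
        ref = ingest.build_reference([normal])
        normed = normalize.positional_normalize(normalize.gc_normalize(tumor), ref)
        arms = simulate.arms_from_profile(profile)
        return normalize.bin_ratios(normed, arms)

    def test_scale_invariance(self):
        b1 = self.run_to_bins(counts_scale=1.0)
        b7 = self.run_to_bins(counts_scale=7.0)
        ok = b1["ratio"].notna()
        assert np.allclose(b1.loc[ok, "ratio"], b7.loc[ok, "ratio"], rtol=1e-9)

    def test_gc_decorrelated_after_normalization(self):
        mb = 1_000_000
        profile = pd.DataFrame(
            [("chr1", "p", 0, 12 * mb, 2, 1), ("chr1", "q", 12 * mb, 24 * mb, 2, 1)],
            columns=["chrom", "arm", "start", "end", "total_cn", "minor_cn"])
        cfg = simulate.SimulationConfig(purity=1.0, mean_coverage=30.0, seed=21)
        tumor, normal = simulate.simulate_windows(profile, cfg)
        ref = ingest.build_reference([normal])
        normed = normalize.positional_normalize(normalize.gc_normalize(tumor), ref)
        arms = simulate.arms_from_profile(profile)
        bins = normalize.bin_ratios(normed, arms)
        # mean GC per bin, aligned to the arm-relative binning
        gc_bins = []
        for _, a in arms.iterrows():
            for arm_start, arm_end in ((a.p_start, a.centromere_start),
                                       (a.centromere_end, a.chrom_end)):
                sel = tumor[(tumor["start"] >= arm_start) & (tumor["start"] < arm_end)]
                rel = (sel["start"] - arm_start) // 10_000
                gc_bins.append(sel.groupby(rel)["gc"].mean().to_numpy())
        gc_per_bin = np.concatenate(gc_bins)
        ok = bins["ratio"].notna().to_numpy()
        assert len(gc_per_bin) == len(bins)
        r = np.corrcoef(bins.loc[ok, "ratio"], gc_per_bin[ok])[0, 1]
        assert abs(r) < 0.05

    def test_binned_ratio_tracks_mixture_expectation(self):
        # 80% of genome 2m1, 20% 3m1 at purity 0.7: gained region expects
        # (0.7*3 + 0.6) / (0.7*2 + 0.6) = 1.35 relative to the diploid majority
        mb = 1_000_000
        profile = pd.DataFrame(
            [("chr1", "p", 0, 8 * mb, 2, 1), ("chr1", "q", 8 * mb, 16 * mb, 2, 1),
             ("chr2", "p", 0, 8 * mb, 2, 1), ("chr2", "q", 8 * mb, 16 * mb, 3, 1)],
            columns=["chrom", "arm", "start", "end", "total_cn", "minor_cn"])
        bins = self.run_to_bins(profile=profile, purity=0.7, seed=22)
        gained = bins[(bins["chrom"] == "chr2") & (bins["arm"] == "q")]["ratio"]
        neutral = bins[(bins["chrom"] == "chr1")]["ratio"]
        assert neutral.mean() == pytest.approx(1.0, abs=0.02)
        assert gained.mean() == pytest.approx(1.35, abs=0.02)
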