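"""Depth normalization, aggregation, bias correction and sample QC."""

import numpy as np
import pandas as pd
import pytest

from embryocn import (
    CoverageModel,
    aggregate_bins,
    correct_replication_timing,
    normalize_depth,
    qc_sample,
    realize_lineage,
    rebin,
    simulate_bin_counts,
    simulate_repliseq_track,
)
from embryocn.depth import NormalizedCNMatrix, RepliSeqTrack

from conftest import make_bin_counts


class TestRebin:
    def test_sum_of_constituents(self):
        mat = make_bin_counts({"s1": [1, 2, 3, 4, 5]})
        out = rebin(mat, 50_000)
        assert out.counts["s1"].tolist() == [15]
        assert out.bins.iloc[0][["start", "end"]].tolist() == [0, 50_000]

    def test_identity_at_source_size(self):
        mat = make_bin_counts({"s1": [1, 2, 3]})
        out = rebin(mat, 10_000)
        pd.testing.assert_frame_equal(out.counts, mat.counts)

    def test_non_multiple_rejected(self):
        mat = make_bin_counts({"s1": [1, 2, 3]})
        with pytest.raises(ValueError, match="multiple"):
            rebin(mat, 25_000)

    def test_trailing_partial_bin_keeps_true_end(self):
        mat = make_bin_counts({"s1": [1] * 7})
        out = rebin(mat, 50_000)
        assert out.bins["end"].tolist() == [50_000, 70_000]
        assert out.counts["s1"].tolist() == [5, 2]

    def test_low_pass_rebinning_chain(self, genome):
        """10 kb native -> 250 kb working bins for low-pass data."""
        truth = realize_lineage(genome, [])
        counts = simulate_bin_counts(truth, genome, CoverageModel(0.15, seed=0))
        out = rebin(counts, 250_000)
        assert out.bin_size == 250_000
        assert out.counts.to_numpy().sum() == counts.counts.to_numpy().sum()


class TestNormalizeDepth:
    def test_constant_matrix_all_ones(self):
        mat = make_bin_counts({"a": [10] * 20, "b": [30] * 20})
        norm = normalize_depth(mat)
        assert np.allclose(norm.values.to_numpy(), 1.0)
        assert not norm.mask.any()

    def test_low_bin_masked_by_25_80_rule(self):
        base = {f"s{i}": [100] * 10 for i in range(10)}
        for i in range(9):  # bin 0 at 20% of median in 9/10 samples
            base[f"s{i}"][0] = 20
        norm = normalize_depth(make_bin_counts(base))
        assert norm.mask[0]
        assert not norm.mask[1:].any()

    def test_low_bin_in_few_samples_not_masked(self):
        base = {f"s{i}": [100] * 10 for i in range(10)}
        for i in range(7):  # 70% of samples: below the >80% requirement
            base[f"s{i}"][0] = 20
        norm = normalize_depth(make_bin_counts(base))
        assert not norm.mask.any()

    def test_zero_median_sample_dropped(self):
        mat = make_bin_counts({"ok": [10] * 10, "dead": [0] * 10})
        with pytest.warns(UserWarning, match="dead"):
            norm = normalize_depth(mat)
        assert norm.samples == ["ok"]

    def test_all_zero_errors(self):
        mat = make_bin_counts({"a": [0] * 10, "b": [0] * 10})
        with pytest.raises(ValueError, match="no usable samples"):
            normalize_depth(mat)

    def test_median_one_invariant(self, genome):
        truth = realize_lineage(genome, [])
        counts = simulate_bin_counts(truth, genome, CoverageModel(9.45, seed=4))
        norm = normalize_depth(rebin(counts, 50_000))
        for s in norm.samples:
            assert abs(np.median(norm.unmasked(s)) - 1.0) <= 1e-9


class TestAggregateBins:
    def test_all_ones_identity(self):
        norm = normalize_depth(make_bin_counts({"a": [10] * 100, "b": [10] * 100}))
        agg = aggregate_bins(norm, 100_000)
        assert np.allclose(agg.values.to_numpy(), 1.0)

    def test_shared_locus_bias_removed_exactly(self, rng):
        """A bin bias common to all samples cancels in the cross-sample
        median division."""
        bias = np.exp(rng.normal(0, 0.3, 200))
        data = {f"s{i}": np.round(1000 * bias).astype(int) for i in range(6)}
        norm = normalize_depth(make_bin_counts(data))
        agg = aggregate_bins(norm, 50_000)
        v = agg.values.to_numpy()[~agg.mask]
        assert np.allclose(v, v.round(), atol=1e-6)
        assert np.allclose(v, 1.0, atol=1e-6)

    def test_masked_constituents_excluded(self):
        base = {f"s{i}": [100] * 10 for i in range(10)}
        for i in range(9):
            base[f"s{i}"][0] = 20  # bin 0 masked
        norm = normalize_depth(make_bin_counts(base))
        agg = aggregate_bins(norm, 50_000)
        # first large bin averages only bins 1-4 of the untouched sample
        assert np.isclose(agg.values.iloc[0, 9], 1.0)
        assert not agg.mask.any()

    def test_all_masked_large_bin_stays_masked(self):
        base = {f"s{i}": [10] * 10 for i in range(10)}
        for i in range(10):
            base[f"s{i}"] = [1] * 5 + [100] * 5  # whole first 50 kb low
        norm = normalize_depth(make_bin_counts(base))
        agg = aggregate_bins(norm, 50_000)
        assert agg.mask[0] and not agg.mask[1]


class TestReplicationTimingCorrection:
    def _norm(self, values):
        n = len(values)
        bins = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 10_000,
                             "end": (np.arange(n) + 1) * 10_000})
        return NormalizedCNMatrix(
            bins=bins, values=pd.DataFrame({"s": values}),
            mask=np.zeros(n, bool), bin_size=10_000,
        )

    def test_uncorrelated_input_unchanged(self, rng):
        y = 1.0 + rng.normal(0, 0.02, 3000)
        norm = self._norm(y)
        track = RepliSeqTrack(bins=norm.bins, values=rng.normal(0, 1, 3000))
        out = correct_replication_timing(norm, track)
        assert np.allclose(out.values["s"], norm.values["s"], atol=0.02)

    def test_injected_bias_removed(self, rng):
        t = np.sin(np.linspace(0, 20, 3000)) + 0.1 * rng.normal(size=3000)
        y = np.exp(0.2 * t) * (1.0 + rng.normal(0, 0.02, 3000))
        norm = self._norm(y)
        track = RepliSeqTrack(bins=norm.bins, values=t)
        out = correct_replication_timing(norm, track)
        r = np.corrcoef(out.values["s"], t)[0, 1]
        assert abs(r) < 0.05
        assert abs(np.corrcoef(y, t)[0, 1]) > 0.5  # bias was real

    def test_cn_steps_preserved(self, rng):
        t = np.sin(np.linspace(0, 20, 3000))
        cn = np.ones(3000)
        cn[1000:1500] = 1.5  # simulated gain
        y = cn * np.exp(0.2 * t) * (1.0 + rng.normal(0, 0.01, 3000))
        norm = self._norm(y)
        out = correct_replication_timing(norm, RepliSeqTrack(bins=norm.bins, values=t))
        v = out.values["s"].to_numpy()
        ratio = v[1000:1500].mean() / np.concatenate([v[:1000], v[1500:]]).mean()
        assert abs(ratio - 1.5) < 0.05

    def test_constant_track_identity_with_warning(self, rng):
        y = 1.0 + rng.normal(0, 0.02, 500)
        norm = self._norm(y)
        track = RepliSeqTrack(bins=norm.bins, values=np.zeros(500))
        with pytest.warns(UserWarning, match="constant"):
            out = correct_replication_timing(norm, track)
        assert np.allclose(out.values["s"], norm.values["s"])

    def test_end_to_end_bias_removal_on_simulation(self, genome):
        track = simulate_repliseq_track(genome, seed=6)
        truth = realize_lineage(genome, [])
        cov = CoverageModel(9.45, repli_bias_strength=0.25, seed=6)
        counts = simulate_bin_counts(truth, genome, cov, track=track)
        norm = normalize_depth(rebin(counts, 50_000))
        track = RepliSeqTrack(bins=norm.bins, values=track.project(norm.bins))
        out = correct_replication_timing(norm, track)
        for s in ("b1", "b5"):
            before = np.corrcoef(norm.values[s], track.values)[0, 1]
            after = np.corrcoef(out.values[s], track.values)[0, 1]
            assert abs(before) > 0.3
            assert abs(after) < 0.05


class TestRebinProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.integers(0, 1000), min_size=4, max_size=60),
           st.sampled_from([2, 3, 5]))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_rebin_conserves_totals_and_coordinates(self, counts, factor):
        mat = make_bin_counts({"s": counts})
        out = rebin(mat, 10_000 * factor)
        assert out.counts["s"].sum() == sum(counts)
        assert out.bins["end"].iloc[-1] == mat.bins["end"].iloc[-1]
        assert (out.bins["start"] % (10_000 * factor) == 0).all()


class TestSampleQC:
    def _norm_from(self, values):
        n = len(values)
        bins = pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 10_000,
                             "end": (np.arange(n) + 1) * 10_000})
        return NormalizedCNMatrix(bins=bins, values=pd.DataFrame({"s": values}),
                                  mask=np.zeros(n, bool), bin_size=10_000)

    def test_constant_profile_passes(self):
        qc = qc_sample(self._norm_from(np.ones(100)), "s", "low_pass")
        assert qc.mad == 0 and qc.passed

    @pytest.mark.parametrize("platform,expected", [("low_pass", False), ("deep", True)])
    def test_mad_point_two_against_thresholds(self, platform, expected, rng):
        # Laplace noise with MAD exactly ~0.2
        v = 1.0 + 0.2 * np.sign(rng.normal(size=5001)) * rng.exponential(1 / np.log(2), 5001)
        v = 1.0 + (v - 1.0) * (0.2 / np.median(np.abs(v - np.median(v))))
        qc = qc_sample(self._norm_from(v), "s", platform)
        assert abs(qc.mad - 0.2) < 1e-9
        assert qc.passed is expected

    def test_too_few_bins_fail_with_reason(self):
        qc = qc_sample(self._norm_from(np.ones(5)), "s", "deep")
        assert not qc.passed and "usable bins" in qc.reason
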