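"""Generative model: lineage mechanics, count/VAF statistics, determinism."""

import numpy as np
import pandas as pd
import pytest

from embryocn import (
    CoverageModel,
    EventSpec,
    MATERNAL,
    PATERNAL,
    realize_lineage,
    simulate_allelic_depths,
    simulate_bin_counts,
    simulate_edu_image,
    simulate_embryo,
    simulate_repliseq_track,
    toy_genome,
)


def cut_event(cls="acentric_missegregation", chrom="chr1", cut=30_000_000,
              division=1, hap=PATERNAL, **kw):
    return EventSpec(cls, chrom, cut_position=cut, division_index=division,
                     affected_haplotype=hap, **kw)


class TestLineage:
    def test_no_event_identity(self, genome):
        truth = realize_lineage(genome, [])
        t = truth.table()
        assert len(truth.blastomeres) == 8
        assert (t["maternal_cn"] == 1).all() and (t["paternal_cn"] == 1).all()
        assert (t["replication_state"] == "replicated").all()

    def test_acentric_missegregation_reciprocal(self, genome):
        truth = realize_lineage(genome, [cut_event(division=1)])
        t = truth.table()
        distal = t[(t["chrom"] == "chr1") & (t["start"] == 30_000_000)]
        assert distal["paternal_cn"].value_counts().to_dict() == {2: 4, 0: 4}
        proximal = t[(t["chrom"] == "chr1") & (t["start"] == 0)]
        assert (proximal["paternal_cn"] == 1).all()
        assert (t["maternal_cn"] == 1).all()

    def test_bridge_monosomy_homolog_partition(self, genome):
        truth = realize_lineage(
            genome, [cut_event("bridge_monosomy", division=2, hap=MATERNAL)]
        )
        t = truth.table()
        chrom = t[t["chrom"] == "chr1"]
        mono = chrom.groupby("blastomere")["maternal_cn"].max() == 0
        assert mono.sum() == 2  # a division-2 error hits 2 of 8 blastomeres
        keep_pat = chrom[mono[chrom["blastomere"]].to_numpy()]
        assert (keep_pat["paternal_cn"] == 1).all()
        surplus = chrom.groupby("blastomere")["maternal_cn"].min() == 2
        assert surplus.sum() == 2  # sister lineage holds all copies

    def test_conservation_at_division(self, genome):
        """Summed daughter copy number equals twice the mother's per segment."""
        for cls, kw in [
            ("acentric_missegregation", {}),
            ("micronucleus_underreplication", {}),
            ("bridge_monosomy", {}),
            ("bridge_monosomy", {"acentric_fate": "micronucleus"}),
            ("whole_chromosome_missegregation", {"cut": None}),
        ]:
            ev = EventSpec(cls, "chr1", cut_position=kw.pop("cut", 30_000_000),
                           division_index=3, affected_haplotype=PATERNAL, **kw)
            g = toy_genome(seed=0)
            truth = realize_lineage(g, [ev])
            for chrom, length in g.chromosomes:
                pos = np.arange(1, length, 5_000_000)
                m1, p1 = truth.point_mass("b1", chrom, pos)
                m2, p2 = truth.point_mass("b2", chrom, pos)
                np.testing.assert_allclose(m1 + m2, 2.0, err_msg=cls)
                np.testing.assert_allclose(p1 + p2, 2.0, err_msg=cls)

    def test_conflicting_cuts_rejected(self, genome):
        with pytest.raises(ValueError, match="conflicting"):
            realize_lineage(genome, [cut_event(), cut_event(cls="bridge_monosomy")])

    def test_cut_outside_chromosome_rejected(self, genome):
        with pytest.raises(ValueError, match="outside"):
            realize_lineage(genome, [cut_event(cut=10**9)])

    def test_division_index_validation(self):
        with pytest.raises(ValueError, match="division_index"):
            EventSpec("acentric_missegregation", "chr1", cut_position=1000,
                      affected_haplotype=PATERNAL)
        with pytest.raises(ValueError, match="meiotic"):
            EventSpec("meiotic_trisomy", "chr1", division_index=1,
                      affected_haplotype=MATERNAL)

    def test_micronucleus_only_downstream_of_event(self, genome):
        truth = realize_lineage(
            genome, [cut_event("micronucleus_underreplication", division=2)]
        )
        t = truth.table()
        under = t[t["replication_state"] == "underreplicated"]
        assert set(under["blastomere"]) == {"b1", "b2"}
        assert (under["start"] == 30_000_000).all()


class TestBinCounts:
    def test_flat_genome_uniform_counts(self, genome):
        truth = realize_lineage(genome, [])
        cov = CoverageModel(mean_depth=2.0, dispersion=0.0, seed=1)
        counts = simulate_bin_counts(truth, genome, cov)
        # expected 2 haplotypes * depth * bin/read = 2*2*10000/100 = 400
        m = counts.counts["b1"].to_numpy()
        assert abs(m.mean() - 400) / 400 < 0.02
        assert m.std() < 3 * np.sqrt(400)

    def test_mean_scales_with_depth(self, genome):
        truth = realize_lineage(genome, [])
        m1 = simulate_bin_counts(truth, genome, CoverageModel(1.0, seed=2))
        m2 = simulate_bin_counts(truth, genome, CoverageModel(2.0, seed=2))
        r = m2.counts.mean().mean() / m1.counts.mean().mean()
        assert abs(r - 2.0) < 0.05

    def test_underreplicated_half_mass_in_g2(self, genome):
        ev = cut_event("micronucleus_underreplication", division=1)
        truth = realize_lineage(genome, [ev], phase="G2")
        counts = simulate_bin_counts(truth, genome,
                                     CoverageModel(9.45, dispersion=0.0, seed=3))
        bins = counts.bins
        on = (bins["chrom"] == "chr1").to_numpy()
        distal = on & (bins["start"] >= 30_000_000).to_numpy()
        proximal = on & ~ (bins["start"] >= 30_000_000).to_numpy()
        c = counts.counts["b1"].to_numpy()
        # distal mass: paternal micronuclear 1 + maternal replicated 2 = 3
        # proximal mass: 2 + 2 = 4
        assert abs(c[distal].mean() / c[proximal].mean() - 0.75) < 0.02

    def test_fixed_seed_byte_identical(self, genome):
        truth = realize_lineage(genome, [cut_event()])
        a = simulate_bin_counts(truth, genome, CoverageModel(0.15, seed=9))
        b = simulate_bin_counts(truth, genome, CoverageModel(0.15, seed=9))
        pd.testing.assert_frame_equal(a.counts, b.counts)
        d1 = simulate_allelic_depths(truth, genome, CoverageModel(9.45, seed=9))
        d2 = simulate_allelic_depths(truth, genome, CoverageModel(9.45, seed=9))
        pd.testing.assert_frame_equal(d1, d2)


class TestAllelicDepths:
    def test_balanced_heterozygote_vaf_half(self, genome, deep):
        truth = realize_lineage(genome, [])
        d = simulate_allelic_depths(truth, genome, deep)
        vaf = d["alt_count"].sum() / (d["ref_count"] + d["alt_count"]).sum()
        assert abs(vaf - 0.5) < 0.01

    def test_loh_region_vaf_zero(self, genome, deep):
        # distal loss of the 129 (paternal/alt) haplotype: only B6 remains
        truth = realize_lineage(genome, [cut_event(division=1)])
        d = simulate_allelic_depths(truth, genome, deep)
        loser = d[(d["sample"] == "b5") & (d["chrom"] == "chr1")
                  & (d["pos"] >= 30_000_000)]
        assert loser["alt_count"].sum() == 0
        assert loser["ref_count"].sum() > 0

    def test_digyny_paternal_vaf_one_third(self, genome, deep):
        truth = realize_lineage(genome, [EventSpec("digyny")])
        d = simulate_allelic_depths(truth, genome, deep)
        d = d[d["sample"] == "b1"]
        assert len(d) >= 10_000
        vaf = d["alt_count"].sum() / (d["ref_count"] + d["alt_count"]).sum()
        assert abs(vaf - 1 / 3) < 0.01

    def test_nullisomic_region_depth_zero(self, genome, deep):
        ev = cut_event("bridge_monosomy", division=1, hap=MATERNAL)
        truth = realize_lineage(genome, [ev])
        d = simulate_allelic_depths(truth, genome, deep)
        # monosomic daughter keeps 1 paternal copy; maternal reads absent
        mono = d[(d["sample"] == "b1") & (d["chrom"] == "chr1")]
        assert mono["ref_count"].sum() == 0
        assert (mono["alt_count"] >= 0).all()


class TestRepliSeq:
    def test_deterministic(self, genome):
        t1 = simulate_repliseq_track(genome, seed=5)
        t2 = simulate_repliseq_track(genome, seed=5)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_bounded_and_finite(self, genome):
        t = simulate_repliseq_track(genome, seed=5)
        assert np.all(np.isfinite(t.values))
        assert t.values.min() >= -3 and t.values.max() <= 3

    def test_bias_correlation_sign(self, genome):
        track = simulate_repliseq_track(genome, seed=5)
        truth = realize_lineage(genome, [])
        cov = CoverageModel(9.45, dispersion=0.0, repli_bias_strength=0.3, seed=5)
        counts = simulate_bin_counts(truth, genome, cov, track=track)
        r = np.corrcoef(track.values, counts.counts["b1"])[0, 1]
        assert r > 0.5

    def test_simulate_embryo_wraps_emitters(self, genome, deep):
        truth, counts, depths, svs = simulate_embryo(
            genome, [cut_event()], deep, with_svs=True
        )
        assert counts.counts.shape[1] == 8
        assert {"chrom", "pos", "sample", "ref_count", "alt_count"} <= set(depths.columns)
        assert len(svs) > 0


class TestEdUImage:
    def test_masks_roundtrip_geometry(self):
        img = simulate_edu_image()
        assert img["pn_mask"].sum() > img["mn_mask"].sum() > 0
        assert not (img["pn_mask"] & img["mn_mask"]).any()
        y, x, h, w = img["background_region"]
        assert not (img["pn_mask"] | img["mn_mask"])[y:y + h, x:x + w].any()

    def test_overlapping_structures_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            simulate_edu_image(pn=(128, 128, 60), mn=(150, 150, 20))

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            simulate_edu_image(mn=(250, 250, 20))

    def test_null_replication_micronucleus(self):
        img = simulate_edu_image(edu_rate_mn=0.0, noise_sd=0.0)
        bg = float(img["edu"][img["background_region"][0]:, :1].mean())
        mn_mean = float(img["edu"][img["mn_mask"]].mean())
        assert abs(mn_mean - bg) < 1e-6
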