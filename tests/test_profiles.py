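import numpy as np
import pandas as pd
import pytest

from hetkit import io as hio
from hetkit import profiles, regions, synthetic
from hetkit.intervals import GenomicInterval, RegionSet


def make_track(rows, total_mapped=None):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return hio.CoverageTrack(df, total_mapped=total_mapped)


def constant_track(chrom_sizes, value, total_mapped=None):
    return make_track([(c, 0, n, value) for c, n in chrom_sizes.items()],
                      total_mapped=total_mapped)


class TestNormalizePerMillion:
    def test_unit_factor(self):
        t = make_track([("c", 0, 100, 3.0)], total_mapped=1e6)
        out = profiles.normalize_per_million(t)
        np.testing.assert_allclose(out.data["value"], [3.0])

    def test_all_zero(self):
        t = make_track([("c", 0, 100, 0.0)], total_mapped=5e5)
        assert (profiles.normalize_per_million(t).data["value"] == 0).all()

    def test_linearity_in_total(self):
        t1 = make_track([("c", 0, 100, 3.0)], total_mapped=1e6)
        t2 = make_track([("c", 0, 100, 3.0)], total_mapped=2e6)
        v1 = profiles.normalize_per_million(t1).data["value"].iloc[0]
        v2 = profiles.normalize_per_million(t2).data["value"].iloc[0]
        assert v2 == pytest.approx(v1 / 2)

    def test_zero_total_error(self):
        t = make_track([("c", 0, 100, 3.0)], total_mapped=0)
        with pytest.raises(ValueError):
            profiles.normalize_per_million(t)

    def test_value_conservation(self, chip):
        t = chip.tracks["h3k9me2"]
        out = profiles.normalize_per_million(t)
        raw = (t.data["value"] * (t.data["end"] - t.data["start"])).sum()
        norm = (out.data["value"] * (out.data["end"] - out.data["start"])).sum()
        assert norm == pytest.approx(raw * 1e6 / t.total_mapped)


class TestMetaplot:
    sizes = {"c": 100_000}

    def test_constant_track(self):
        track = constant_track(self.sizes, 2.5)
        feats = RegionSet([GenomicInterval("c", 40_000, 50_000, strand="+")])
        mp = profiles.metaplot(track, feats, self.sizes, flank_bp=2000,
                               body_bins=10, flank_bins=4)
        np.testing.assert_allclose(mp.mean, 2.5)

    def test_step_track_hand_computed(self):
        # 10-interval step track; single plus-strand feature [1000, 2000);
        # flank 500 bp in 5 bins (100 bp each), body 10 bins (100 bp each):
        # every metaplot bin aligns with one track interval of value = its index
        rows = [("c", 500 + 100 * i, 600 + 100 * i, float(i)) for i in range(30)]
        track = make_track(rows)
        feats = RegionSet([GenomicInterval("c", 1000, 2000, strand="+")])
        mp = profiles.metaplot(track, feats, {"c": 10_000}, flank_bp=500,
                               body_bins=10, flank_bins=5)
        np.testing.assert_allclose(mp.matrix[0], np.arange(20.0))

    def test_fractional_bins_average_exactly(self):
        # body of 150 bp into 3 bins of 50 bp; track steps at 100
        track = make_track([("c", 0, 100, 1.0), ("c", 100, 1000, 3.0)])
        feats = RegionSet([GenomicInterval("c", 0, 150, strand="+")])
        mp = profiles.metaplot(track, feats, {"c": 1000}, flank_bp=100,
                               body_bins=3, flank_bins=1)
        # bins: flank [-100,0) missing; body [0,50)=1, [50,100)=1, [100,150)=3
        assert np.isnan(mp.matrix[0][0])
        np.testing.assert_allclose(mp.matrix[0][1:4], [1.0, 1.0, 3.0])

    def test_minus_strand_reversed(self):
        track = make_track([("c", 0, 500, 1.0), ("c", 500, 1000, 9.0)])
        plus = RegionSet([GenomicInterval("c", 0, 1000, strand="+")])
        minus = RegionSet([GenomicInterval("c", 0, 1000, strand="-")])
        kw = dict(flank_bp=100, body_bins=10, flank_bins=1)
        mp_p = profiles.metaplot(track, plus, {"c": 1000}, **kw)
        mp_m = profiles.metaplot(track, minus, {"c": 1000}, **kw)
        np.testing.assert_allclose(mp_p.matrix[0], mp_m.matrix[0][::-1],
                                   equal_nan=True)

    def test_double_reverse_is_identity(self):
        track = make_track([("c", i * 100, (i + 1) * 100, float(i)) for i in range(10)])
        feat = RegionSet([GenomicInterval("c", 200, 800, strand="-")])
        kw = dict(flank_bp=200, body_bins=6, flank_bins=2)
        once = profiles.metaplot(track, feat, {"c": 1000}, **kw).matrix[0]
        again = profiles.metaplot(track, feat, {"c": 1000}, **kw).matrix[0]
        np.testing.assert_allclose(once, again, equal_nan=True)

    def test_concatenation_weighted_average(self):
        track = make_track([("c", i * 100, (i + 1) * 100, float(i % 7)) for i in range(100)])
        f1 = RegionSet([GenomicInterval("c", 1000, 3000, strand="+"),
                        GenomicInterval("c", 4000, 4800, strand="+")])
        f2 = RegionSet([GenomicInterval("c", 6000, 9000, strand="+")])
        both = RegionSet(list(f1) + list(f2))
        kw = dict(flank_bp=500, body_bins=8, flank_bins=2)
        sizes = {"c": 10_000}
        m1 = profiles.metaplot(track, f1, sizes, **kw)
        m2 = profiles.metaplot(track, f2, sizes, **kw)
        mb = profiles.metaplot(track, both, sizes, **kw)
        num = np.nansum(m1.matrix, axis=0) + np.nansum(m2.matrix, axis=0)
        den = m1.counts + m2.counts
        np.testing.assert_allclose(mb.mean, num / den)

    def test_empty_features_error(self):
        track = constant_track(self.sizes, 1.0)
        with pytest.raises(ValueError):
            profiles.metaplot(track, RegionSet([]), self.sizes)

    def test_methylation_pooled_ratio(self):
        cyt = pd.DataFrame(
            [("c", 10, "+", "CHG", 2, 10), ("c", 20, "-", "CHG", 8, 10)],
            columns=hio.CX_COLUMNS)
        feats = RegionSet([GenomicInterval("c", 0, 100, strand="+")])
        mp = profiles.metaplot(cyt, feats, {"c": 1000}, flank_bp=100,
                               body_bins=1, flank_bins=1, context="CHG")
        # single body bin pools both cytosines: 10/20
        assert mp.mean[1] == pytest.approx(0.5)
        assert np.isnan(mp.mean[2])  # empty downstream flank

    def test_mutant_chh_below_wildtype_over_tes(self, genome, model, methylomes):
        wt, mut = methylomes
        # flank convergence only holds where the flank is not itself inside
        # another planted region, so restrict to isolated planted TEs
        planted = model.planted_dmrs
        isolated = []
        for te in planted:
            ext_lo = max(0, te.start - 2000)
            ext_hi = min(genome.chrom_sizes[te.chrom], te.end + 2000)
            cov = planted._coverage(te.chrom).overlap_bp(ext_lo, ext_hi)
            if cov == te.length:
                isolated.append(te)
        assert len(isolated) >= 3
        feats = RegionSet(isolated)
        kw = dict(flank_bp=2000, body_bins=20, flank_bins=10, context="CHH")
        mp_wt = profiles.metaplot(wt, feats, genome.chrom_sizes, **kw)
        mp_mut = profiles.metaplot(mut, feats, genome.chrom_sizes, **kw)
        body = slice(10, 30)
        assert np.nanmean(mp_mut.mean[body]) < np.nanmean(mp_wt.mean[body]) - 0.1
        # distal flank bins converge (delta was planted inside TEs only)
        distal = np.r_[0:3, 37:40]
        diff = np.abs(np.nanmean(mp_mut.mean[distal] - mp_wt.mean[distal]))
        assert diff < 0.05


class TestRegionStats:
    def test_single_cytosine_level(self):
        cyt = pd.DataFrame([("c", 50, "+", "CHH", 7, 10)], columns=hio.CX_COLUMNS)
        regs = RegionSet([GenomicInterval("c", 0, 100)])
        table, _ = profiles.region_stats(cyt, regs, {"c": 1000}, context="CHH")
        assert table["value"].iloc[0] == pytest.approx(0.7)

    def test_quartiles_hand_computed(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        track = make_track([("c", i * 100, (i + 1) * 100, v) for i, v in enumerate(vals)])
        regs = RegionSet([GenomicInterval("c", i * 100, (i + 1) * 100) for i in range(5)])
        _, summary = profiles.region_stats(track, regs, {"c": 500})
        assert summary["median"] == 3.0
        assert summary["q1"] == 2.0 and summary["q3"] == 4.0

    def test_uncovered_region_missing_and_counted(self):
        cyt = pd.DataFrame([("c", 50, "+", "CHH", 7, 10)], columns=hio.CX_COLUMNS)
        regs = RegionSet([GenomicInterval("c", 0, 100), GenomicInterval("c", 500, 600)])
        table, summary = profiles.region_stats(cyt, regs, {"c": 1000}, context="CHH")
        assert summary["n_missing"] == 1
        assert np.isnan(table["value"].iloc[1])

    def test_mutant_median_below_wildtype(self, genome, model, methylomes):
        wt, mut = methylomes
        regs = model.planted_dmrs
        _, s_wt = profiles.region_stats(wt, regs, genome.chrom_sizes, context="CHH")
        _, s_mut = profiles.region_stats(mut, regs, genome.chrom_sizes, context="CHH")
        assert s_mut["median"] < s_wt["median"]


class TestH3Normalized:
    sizes = {"c": 1000}

    def test_mark_equals_h3(self):
        h3 = make_track([("c", 0, 1000, 4.0)])
        regs = RegionSet([GenomicInterval("c", 100, 200), GenomicInterval("c", 300, 700)])
        ratios = profiles.h3_normalized_density(h3, h3, regs, self.sizes)
        np.testing.assert_allclose(ratios, 1.0)

    def test_mark_twice_h3(self):
        h3 = make_track([("c", 0, 1000, 4.0)])
        mark = make_track([("c", 0, 1000, 8.0)])
        regs = RegionSet([GenomicInterval("c", 0, 500)])
        np.testing.assert_allclose(
            profiles.h3_normalized_density(mark, h3, regs, self.sizes), 2.0)

    def test_zero_h3_missing(self):
        h3 = make_track([("c", 0, 500, 4.0)])
        mark = make_track([("c", 0, 1000, 8.0)])
        regs = RegionSet([GenomicInterval("c", 600, 700)])
        assert np.isnan(profiles.h3_normalized_density(mark, h3, regs, self.sizes)[0])

    def test_scaled_mark_ratio(self, genome, chip):
        # mutant mark = 0.6x inside planted regions: median ratio(mut)/ratio(wt) ~ 0.6
        regs = genome.long_tes()
        h3 = chip.tracks["h3"]
        mark = chip.tracks["h3k9me2"]
        df = mark.data.copy()
        scaled = np.ones(len(df))
        for i, (chrom, s, e) in enumerate(zip(df["chrom"], df["start"], df["end"])):
            if regs._coverage(chrom).overlap_bp(int(s), int(e)) == (int(e) - int(s)):
                scaled[i] = 0.6
        mut_mark = hio.CoverageTrack(df.assign(value=df["value"] * scaled),
                                     total_mapped=mark.total_mapped)
        r_wt = profiles.h3_normalized_density(mark, h3, regs, genome.chrom_sizes)
        r_mut = profiles.h3_normalized_density(mut_mark, h3, regs, genome.chrom_sizes)
        ratio = np.nanmedian(r_mut / r_wt)
        assert ratio == pytest.approx(0.6, abs=0.05)


class TestMarkAssociation:
    def test_uniform_mark_log2_zero(self, genome):
        track = constant_track(genome.chrom_sizes, 3.0)
        peaks = genome.long_tes()
        controls = regions.shuffle_regions(peaks, genome.chrom_sizes, seed=1, n_sets=3)
        table = profiles.mark_association(peaks, track, controls, genome.chrom_sizes)
        assert table["log2_ratio"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_het_mark_positive_active_negative(self, genome, chip):
        peaks = chip.peaks
        controls = regions.shuffle_regions(peaks, genome.chrom_sizes, seed=2, n_sets=3)
        table = profiles.mark_association(
            peaks, {"h3k9me2": chip.tracks["h3k9me2"], "active": chip.tracks["active"]},
            controls, genome.chrom_sizes).set_index("mark")
        assert table.loc["h3k9me2", "log2_ratio"] > 0.5
        assert table.loc["active", "log2_ratio"] < 0

    def test_empty_peaks_error(self, genome):
        track = constant_track(genome.chrom_sizes, 1.0)
        with pytest.raises(ValueError):
            profiles.mark_association(RegionSet([]), track, [genome.genes],
                                      genome.chrom_sizes)

    def test_invariant_to_per_million_scaling(self, genome, chip):
        peaks = chip.peaks
        controls = regions.shuffle_regions(peaks, genome.chrom_sizes, seed=3, n_sets=2)
        raw = chip.tracks["h3k9me2"]
        norm = profiles.normalize_per_million(raw)
        t_raw = profiles.mark_association(peaks, raw, controls, genome.chrom_sizes)
        t_norm = profiles.mark_association(peaks, norm, controls, genome.chrom_sizes)
        assert t_raw["log2_ratio"].iloc[0] == pytest.approx(
            t_norm["log2_ratio"].iloc[0], rel=1e-9)


class TestTrackCorrelation:
    def test_self_correlation(self, genome, chip):
        res = profiles.track_correlation(chip.tracks["h3k9me2"], chip.tracks["h3k9me2"],
                                         genome.chrom_sizes)
        assert res["pearson"] == pytest.approx(1.0)
        assert res["spearman"] == pytest.approx(1.0)

    def test_noise_null(self, rng):
        sizes = {"c": 1_000_000}
        n = 1000
        starts = np.arange(0, 1_000_000, 1000)
        a = rng.random(n) + 0.1
        b = rng.random(n) + 0.1  # independent
        ta = make_track([("c", s, s + 1000, v) for s, v in zip(starts, a)])
        tb = make_track([("c", s, s + 1000, v) for s, v in zip(starts, b)])
        res = profiles.track_correlation(ta, tb, sizes, bin_size=1000)
        assert abs(res["spearman"]) < 0.1
        assert res["n"] == n

    def test_generator_tracks_highly_correlated(self, genome, chip):
        res = profiles.track_correlation(chip.tracks["agdp1"], chip.tracks["h3k9me2"],
                                         genome.chrom_sizes, bin_size=10_000)
        assert res["pearson"] >= 0.8

    def test_noiseless_generator_r_one(self, genome):
        sim = synthetic.simulate_chip(genome, seed=4, noise_sd=0.0)
        res = profiles.track_correlation(sim.tracks["agdp1"], sim.tracks["h3k9me2"],
                                         genome.chrom_sizes, bin_size=10_000)
        assert res["pearson"] == pytest.approx(1.0, abs=1e-9)
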