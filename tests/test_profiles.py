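"""Signal aggregation, repeat occupancy, grouped t-tests, nearest TSS."""

import numpy as np
import pytest

from triplextad.core import GenomeAssembly, IntervalSet, SignalTrack
from triplextad.profiles import (
    GROUP_NAMES,
    aggregate_signal,
    build_site_grouping,
    conservation_per_bp,
    group_and_compare,
    nearest_tss_targets,
    repeat_occupancy,
    split_repeats_by_class,
)

from conftest import random_interval_set


def random_track(rng, assembly, seg_len=250):
    chroms, starts, ends, values = [], [], [], []
    for c, L in assembly.chromosomes:
        cuts = np.arange(0, L + seg_len, seg_len)
        cuts[-1] = min(cuts[-1], L)
        cuts = np.unique(cuts)
        keep = rng.random(len(cuts) - 1) < 0.7  # leave uncovered holes
        for i in np.flatnonzero(keep):
            chroms.append(c)
            starts.append(int(cuts[i]))
            ends.append(int(cuts[i + 1]))
            values.append(float(rng.normal(0, 2)))
    return SignalTrack.from_arrays(chroms, starts, ends, values)


def track_bitmap(track, assembly):
    maps = {c: np.zeros(l) for c, l in assembly.chromosomes}
    for c, (s, e, v) in track.segments.items():
        for i in range(len(s)):
            maps[c][s[i]:e[i]] = v[i]
    return maps


class TestAggregateSignal:
    def test_zero_track(self, tiny_assembly):
        sites = IntervalSet(["chr1"], [100], [200])
        assert aggregate_signal(sites, SignalTrack())[0] == 0.0

    def test_constant_track_mean_is_constant(self, tiny_assembly):
        track = SignalTrack.from_arrays(
            ["chr1", "chr2"], [0, 0], [100_000, 50_000], [3.5, 3.5])
        rng = np.random.default_rng(3)
        sites = random_interval_set(rng, tiny_assembly, 30)
        assert np.allclose(aggregate_signal(sites, track), 3.5)

    def test_matches_bitmap_oracle(self, tiny_assembly):
        rng = np.random.default_rng(89)
        track = random_track(rng, tiny_assembly)
        maps = track_bitmap(track, tiny_assembly)
        sites = random_interval_set(rng, tiny_assembly, 20)
        means = aggregate_signal(sites, track)
        sums = aggregate_signal(sites, track, statistic="sum")
        for i, site in enumerate(sites):
            seg = maps[site.chrom][site.start:site.end]
            assert means[i] == pytest.approx(seg.mean())
            assert sums[i] == pytest.approx(seg.sum())

    def test_uncovered_bases_count_in_denominator(self):
        track = SignalTrack.from_arrays(["chr1"], [0], [50], [2.0])
        sites = IntervalSet(["chr1"], [0], [100])  # half covered
        assert aggregate_signal(sites, track)[0] == pytest.approx(1.0)

    def test_invariant_under_segment_split(self, tiny_assembly):
        """Splitting one segment into two equal-valued halves changes nothing."""
        whole = SignalTrack.from_arrays(["chr1"], [100], [900], [4.2])
        split = SignalTrack.from_arrays(
            ["chr1", "chr1"], [100, 400], [400, 900], [4.2, 4.2])
        rng = np.random.default_rng(97)
        sites = random_interval_set(rng, tiny_assembly, 40)
        assert np.allclose(aggregate_signal(sites, whole),
                           aggregate_signal(sites, split))

    def test_flank_extends_window(self):
        track = SignalTrack.from_arrays(["chr1"], [0], [300], [1.0])
        sites = IntervalSet(["chr1"], [100], [200])
        assert aggregate_signal(sites, track, flank_bp=50)[0] == pytest.approx(1.0)
        assert aggregate_signal(sites, track, flank_bp=200)[0] < 1.0


class TestRepeatOccupancy:
    def test_examples(self):
        sites = IntervalSet(["chr1"], [0], [100])
        none = {"LINE": IntervalSet.empty()}
        assert repeat_occupancy(sites, none)["LINE"][0] == 0.0
        full = {"SINE": IntervalSet(["chr1"], [0], [100])}
        assert repeat_occupancy(sites, full)["SINE"][0] == 1.0
        half = {"LTR": IntervalSet(["chr1"], [50], [150])}
        assert repeat_occupancy(sites, half)["LTR"][0] == 0.5

    def test_unknown_class_rejected(self):
        sites = IntervalSet(["chr1"], [0], [100])
        with pytest.raises(ValueError, match="unknown repeat"):
            repeat_occupancy(sites, {"ALU": IntervalSet.empty()})

    def test_split_by_class_uses_name_column(self):
        reps = IntervalSet(["chr1"] * 3, [0, 100, 200], [50, 150, 250],
                           names=["SINE", "LINE", "SINE"])
        split = split_repeats_by_class(reps)
        assert set(split) == {"SINE", "LINE"}
        assert len(split["SINE"]) == 2

    def test_matches_bitmap_oracle(self, tiny_assembly):
        rng = np.random.default_rng(101)
        sites = random_interval_set(rng, tiny_assembly, 25)
        reps = random_interval_set(rng, tiny_assembly, 60)
        occ = repeat_occupancy(sites, {"DNA": reps})["DNA"]
        from conftest import bitmap_of
        rep_map = bitmap_of(reps, tiny_assembly)
        for i, site in enumerate(sites):
            frac = rep_map[site.chrom][site.start:site.end].mean()
            assert occ[i] == pytest.approx(frac)


class TestGroupCompare:
    def _setup(self, rng, n=100):
        asm = GenomeAssembly((("chr1", 1_000_000),))
        starts = rng.integers(0, 999_000, n)
        sites = IntervalSet(["chr1"] * n, starts, starts + 500)
        bounds = IntervalSet(["chr1"], [0], [500_000])
        return asm, sites, bounds

    def test_exactly_six_pairs(self):
        rng = np.random.default_rng(103)
        asm, sites, bounds = self._setup(rng)
        values = rng.normal(0, 1, len(sites))
        comp = group_and_compare(sites, bounds, asm, values, 7,
                                 control_values=rng.normal(0, 1, len(sites)))
        assert len(comp.pairs) == 6
        seen = {frozenset((p.group1, p.group2)) for p in comp.pairs}
        assert len(seen) == 6
        assert set(GROUP_NAMES) == set(comp.group_values)

    def test_identical_constant_samples(self):
        rng = np.random.default_rng(107)
        asm, sites, bounds = self._setup(rng)
        values = np.full(len(sites), 2.0)
        comp = group_and_compare(sites, bounds, asm, values, 7,
                                 control_values=np.full(len(sites), 2.0))
        for p in comp.pairs:
            assert p.t_statistic == 0.0 and p.p_value == 1.0

    def test_planted_boundary_uplift_detected(self):
        """Boundary sites at mean 0.6 vs 0.4 elsewhere (sd 0.1): p < 1e-6."""
        rng = np.random.default_rng(109)
        asm = GenomeAssembly((("chr1", 2_000_000),))
        n = 400
        starts = np.concatenate((rng.integers(0, 999_000, n // 2),
                                 rng.integers(1_000_000, 1_999_000, n // 2)))
        sites = IntervalSet(["chr1"] * n, starts, starts + 500)
        bounds = IntervalSet(["chr1"], [0], [1_000_000])
        at = starts < 1_000_000
        values = np.where(at, rng.normal(0.6, 0.1, n), rng.normal(0.4, 0.1, n))
        comp = group_and_compare(sites, bounds, asm, values, 7,
                                 control_values=rng.normal(0.4, 0.1, n))
        pair = comp.pair("at_boundary", "non_boundary")
        assert pair.p_value < 1e-6
        assert pair.mean1 > pair.mean2

    def test_tiny_group_marked_untestable(self):
        rng = np.random.default_rng(113)
        asm = GenomeAssembly((("chr1", 1_000_000),))
        starts = rng.integers(500_000, 999_000, 20)  # none at the boundary
        starts[0] = 1000                             # exactly one at boundary
        sites = IntervalSet(["chr1"] * 20, starts, starts + 100)
        bounds = IntervalSet(["chr1"], [0], [10_000])
        values = rng.normal(0, 1, 20)
        comp = group_and_compare(sites, bounds, asm, values, 7,
                                 control_values=rng.normal(0, 1, 20))
        pair = comp.pair("at_boundary", "non_boundary")
        assert not pair.testable
        assert np.isnan(pair.p_value)
        assert comp.pair("all", "random_control").testable

    def test_control_group_reproducible(self):
        rng = np.random.default_rng(127)
        asm, sites, bounds = self._setup(rng)
        g1 = build_site_grouping(sites, bounds, asm, 55)
        g2 = build_site_grouping(sites, bounds, asm, 55)
        assert g1.random_control == g2.random_control
        assert sorted(g1.random_control.lengths) == sorted(sites.lengths)

    def test_null_pairwise_p_uniform(self):
        """No planted difference: each pair rejects at ~5%."""
        hits = np.zeros(6)
        n_rep = 100
        for r in range(n_rep):
            rng = np.random.default_rng(7000 + r)
            asm, sites, bounds = self._setup(rng, n=80)
            values = rng.normal(0, 1, len(sites))
            comp = group_and_compare(sites, bounds, asm, values, 7,
                                     control_values=rng.normal(0, 1, len(sites)))
            for k, p in enumerate(comp.pairs):
                hits[k] += p.p_value < 0.05
        # "all" overlaps its subsets, so test the independent-sample pairs
        for k, pair in enumerate(comp.pairs):
            if pair.group1 == "all":
                continue
            assert 0.0 <= hits[k] / n_rep <= 0.12


class TestNearestTSS:
    def test_single_gene_always_wins(self):
        sites = IntervalSet(["chr1"], [100], [200])
        tss = IntervalSet(["chr1"], [90_000], [90_001], names=["FOO"])
        assert nearest_tss_targets(sites, tss) == [("FOO", 89_800)]

    def test_tie_breaks_to_smaller_coordinate(self):
        sites = IntervalSet(["chr1"], [100], [200])
        tss = IntervalSet(["chr1", "chr1"], [50, 250], [51, 251],
                          names=["UP", "DOWN"])
        assert nearest_tss_targets(sites, tss) == [("UP", -50)]

    def test_inside_site_distance_zero(self):
        sites = IntervalSet(["chr1"], [100], [200])
        tss = IntervalSet(["chr1"], [150], [151], names=["IN"])
        assert nearest_tss_targets(sites, tss) == [("IN", 0)]

    def test_chromosome_without_tss_unassigned(self):
        sites = IntervalSet(["chr2"], [100], [200])
        tss = IntervalSet(["chr1"], [50], [51], names=["FOO"])
        assert nearest_tss_targets(sites, tss) == [(None, None)]

    def test_empty_tss_raises(self):
        sites = IntervalSet(["chr1"], [100], [200])
        with pytest.raises(ValueError):
            nearest_tss_targets(sites, IntervalSet.empty())

    def test_matches_all_pairs_bruteforce(self, tiny_assembly):
        rng = np.random.default_rng(131)
        sites = random_interval_set(rng, tiny_assembly, 100)
        pos = rng.integers(0, 99_000, 20)
        tss = IntervalSet(["chr1"] * 20, pos, pos + 1,
                          names=[f"G{i:02d}" for i in range(20)])
        got = nearest_tss_targets(sites, tss)
        for i, site in enumerate(sites):
            if site.chrom != "chr1":
                assert got[i] == (None, None)
                continue
            best = min(
                ((g, int(p - site.start) if p < site.start
                  else (int(p - site.end) if p > site.end else 0))
                 for g, p in zip(tss.names, pos)),
                key=lambda t: (abs(t[1]), t[1] + site.start if t[1] < 0 else 0))
            # compare distances only (tie genes may differ in the oracle key)
            assert abs(got[i][1]) == abs(best[1])


def test_conservation_is_mean_per_bp():
    track = SignalTrack.from_arrays(["chr1"], [0], [1000], [1.0])
    sites = IntervalSet(["chr1"] * 2, [0, 500], [100, 700])
    assert np.allclose(conservation_per_bp(sites, track), 1.0)
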