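"""Interval model, I/O and shuffle/overlap primitives against brute force."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from triplextad.core import (
    GenomeAssembly,
    InputError,
    Interval,
    IntervalSet,
    PlacementError,
    SignalTrack,
    complement,
    merge_intervals,
    overlaps_any,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    shuffle_intervals,
    subtract_intervals,
    tad_boundaries,
    total_overlap_bp,
    write_bed,
    write_bedgraph,
)

from conftest import bitmap_of, random_interval_set


class TestChromSizes:
    def test_parse(self, tmp_path):
        p = tmp_path / "g.chrom.sizes"
        p.write_text("chr1\t1000\nchr2\t500\n")
        asm = read_chrom_sizes(p)
        assert asm.names == ["chr1", "chr2"]
        assert asm.total_length == 1500

    @pytest.mark.parametrize("content,fragment", [
        ("", "empty"),
        ("chr1\t0\n", "line 1"),
        ("chr1\t100\nchr1\t200\n", "duplicate"),
        ("chr1\n", "2 columns"),
        ("chr1\tabc\n", "non-integer"),
    ])
    def test_malformed(self, tmp_path, content, fragment):
        p = tmp_path / "bad.sizes"
        p.write_text(content)
        with pytest.raises(InputError, match=fragment):
            read_chrom_sizes(p)


class TestBed:
    def test_basic_parse(self, tmp_path, tiny_assembly):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t20\nchr2\t0\t50\tsiteA\t3.5\n")
        s = read_bed(p, tiny_assembly)
        assert len(s) == 2
        assert list(s)[0] == Interval("chr1", 10, 20)
        assert s.names[1] == "siteA" and s.values[1] == 3.5

    @pytest.mark.parametrize("line", [
        "chr1\t20\t10", "chrX\t10\t20", "chr2\t0\t60000", "chr1\t-5\t20",
    ])
    def test_invalid_rows(self, tmp_path, tiny_assembly, line):
        p = tmp_path / "bad.bed"
        p.write_text(line + "\n")
        with pytest.raises(InputError, match="line 1"):
            read_bed(p, tiny_assembly)

    def test_roundtrip_random(self, tmp_path, tiny_assembly):
        rng = np.random.default_rng(11)
        original = random_interval_set(rng, tiny_assembly, 100)
        p = tmp_path / "rt.bed"
        write_bed(original, p)
        again = read_bed(p, tiny_assembly)
        assert again == original


class TestMerge:
    def test_overlapping_pair(self):
        s = IntervalSet(["chr1", "chr1"], [10, 40], [50, 60])
        m = merge_intervals(s)
        assert list(m) == [Interval("chr1", 10, 60)]

    def test_touching_merged(self):
        s = IntervalSet(["chr1", "chr1"], [10, 50], [50, 80])
        assert list(merge_intervals(s)) == [Interval("chr1", 10, 80)]

    def test_disjoint_unchanged(self):
        s = IntervalSet(["chr1", "chr1", "chr2"], [10, 60, 5], [20, 70, 9])
        assert merge_intervals(s) == s.sort()

    def test_matches_bitmap_oracle(self, tiny_assembly):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = random_interval_set(rng, tiny_assembly, 200)
            merged = merge_intervals(s)
            maps = bitmap_of(s, tiny_assembly)
            assert merged.total_bp == sum(int(m.sum()) for m in maps.values())
            # merged set covers exactly the same bases
            remapped = bitmap_of(merged, tiny_assembly)
            for c in maps:
                assert np.array_equal(maps[c], remapped[c])
            # non-overlapping and sorted
            for chrom, (ms, me) in merged.by_chrom().items():
                assert np.all(me[:-1] < ms[1:])


class TestOverlap:
    def test_examples(self):
        a = IntervalSet(["chr1"], [0], [100])
        assert total_overlap_bp(a, IntervalSet.empty()) == 0
        assert total_overlap_bp(a, a) == 100
        b = IntervalSet(["chr1", "chr1"], [10, 40], [50, 60])
        c = IntervalSet(["chr1"], [30], [45])
        assert total_overlap_bp(b, c) == 15

    def test_symmetric_and_bounded(self, tiny_assembly):
        rng = np.random.default_rng(7)
        a = random_interval_set(rng, tiny_assembly, 80)
        b = random_interval_set(rng, tiny_assembly, 80)
        ab = total_overlap_bp(a, b)
        assert ab == total_overlap_bp(b, a)
        assert ab <= min(merge_intervals(a).total_bp, merge_intervals(b).total_bp)

    def test_matches_bitmap_oracle(self, tiny_assembly):
        rng = np.random.default_rng(13)
        for _ in range(20):
            a = random_interval_set(rng, tiny_assembly, 120)
            b = random_interval_set(rng, tiny_assembly, 120)
            ma, mb = bitmap_of(a, tiny_assembly), bitmap_of(b, tiny_assembly)
            exact = sum(int((ma[c] & mb[c]).sum()) for c in ma)
            assert total_overlap_bp(a, b) == exact

    def test_subtract_and_complement_oracle(self, tiny_assembly):
        rng = np.random.default_rng(17)
        a = random_interval_set(rng, tiny_assembly, 60)
        b = random_interval_set(rng, tiny_assembly, 60)
        ma, mb = bitmap_of(a, tiny_assembly), bitmap_of(b, tiny_assembly)
        diff = bitmap_of(subtract_intervals(a, b), tiny_assembly)
        comp = bitmap_of(complement(a, tiny_assembly), tiny_assembly)
        for c in ma:
            assert np.array_equal(diff[c], ma[c] & ~mb[c])
            assert np.array_equal(comp[c], ~ma[c])


class TestShuffle:
    def test_single_valid_start_is_identity(self):
        asm = GenomeAssembly((("chr1", 500),))
        site = IntervalSet(["chr1"], [0], [500])
        out = shuffle_intervals(site, asm, rng_seed=3)
        assert out == site

    def test_empty_input(self, tiny_assembly):
        assert len(shuffle_intervals(IntervalSet.empty(), tiny_assembly, 1)) == 0

    def test_preserves_length_multiset_and_stays_in_space(self, tiny_assembly):
        rng = np.random.default_rng(23)
        sites = random_interval_set(rng, tiny_assembly, 150)
        exclude = IntervalSet(["chr1"], [20_000], [60_000])
        out = shuffle_intervals(sites, tiny_assembly, 9, exclude=exclude)
        assert sorted(out.lengths) == sorted(sites.lengths)
        assert total_overlap_bp(out, exclude) == 0
        for i in range(len(out)):
            assert out.ends[i] <= tiny_assembly.length_of(out.chroms[i])

    def test_within_tads_never_touches_boundaries(self, tiny_assembly):
        tads = IntervalSet(["chr1", "chr1"], [0, 50_000], [50_000, 100_000])
        bounds = tad_boundaries(tads, 2_000, tiny_assembly)
        allowed = subtract_intervals(tads, bounds)
        sites = IntervalSet(["chr1"] * 50, np.arange(50) * 100,
                            np.arange(50) * 100 + 80)
        out = shuffle_intervals(sites, tiny_assembly, 21,
                                exclude=bounds, within=tads)
        assert total_overlap_bp(out, bounds) == 0
        assert total_overlap_bp(out, allowed) == merge_intervals(out).total_bp

    def test_deterministic_given_seed(self, tiny_assembly):
        rng = np.random.default_rng(29)
        sites = random_interval_set(rng, tiny_assembly, 100)
        assert (shuffle_intervals(sites, tiny_assembly, 77)
                == shuffle_intervals(sites, tiny_assembly, 77))

    def test_site_too_long_raises(self):
        asm = GenomeAssembly((("chr1", 1000),))
        site = IntervalSet(["chr1"], [0], [900])
        within = IntervalSet(["chr1"], [0], [500])
        with pytest.raises(PlacementError):
            shuffle_intervals(site, asm, 1, within=within)

    def test_start_positions_uniform(self, mb_assembly):
        """10k shuffles of one 1 kb site: starts uniform over valid range."""
        site = IntervalSet(["chr1"], [0], [1000])
        starts = np.array([
            int(shuffle_intervals(site, mb_assembly, 1000 + r).starts[0])
            for r in range(10_000)
        ])
        n_valid = 1_000_000 - 1000 + 1
        _, p = stats.kstest(starts / n_valid, "uniform")
        assert p > 0.01

    def test_non_overlapping_mode(self, tiny_assembly):
        sites = IntervalSet(["chr1"] * 40, np.arange(40) * 10,
                            np.arange(40) * 10 + 2000)
        out = shuffle_intervals(sites, tiny_assembly, 5, non_overlapping=True)
        m = merge_intervals(out)
        assert m.total_bp == out.total_bp  # no self-overlap at all


class TestBoundaries:
    def test_basic_window(self):
        tads = IntervalSet(["chr1"], [1000], [5000])
        b = tad_boundaries(tads, 100)
        assert [(iv.start, iv.end) for iv in b] == [(900, 1100), (4900, 5100)]

    def test_clipped_at_zero(self):
        tads = IntervalSet(["chr1"], [0], [5000])
        b = tad_boundaries(tads, 100)
        assert [(iv.start, iv.end) for iv in b] == [(0, 100), (4900, 5100)]

    def test_shared_edge_deduplicated(self):
        tads = IntervalSet(["chr1", "chr1"], [0, 1000], [1000, 2000])
        b = tad_boundaries(tads, 50)
        assert [(iv.start, iv.end) for iv in b] == [
            (0, 50), (950, 1050), (1950, 2050)]

    def test_clipped_at_chrom_end(self, tiny_assembly):
        tads = IntervalSet(["chr2"], [0], [50_000])
        b = tad_boundaries(tads, 100, tiny_assembly)
        assert [(iv.start, iv.end) for iv in b] == [(0, 100), (49_900, 50_000)]


class TestSignalTrack:
    def test_bedgraph_roundtrip_and_sorting(self, tmp_path, tiny_assembly):
        p = tmp_path / "t.bedgraph"
        p.write_text("chr1\t500\t900\t2.5\nchr1\t0\t100\t1\nchr2\t10\t20\t-3\n")
        t = read_bedgraph(p, tiny_assembly)
        s, e, v = t.segments["chr1"]
        assert list(s) == [0, 500] and list(v) == [1.0, 2.5]
        assert t.value_at("chr1", 600) == 2.5
        assert t.value_at("chr1", 200) == 0.0  # uncovered base
        q = tmp_path / "o.bedgraph"
        write_bedgraph(t, q)
        assert read_bedgraph(q).segments.keys() == t.segments.keys()

    def test_overlapping_segments_rejected(self):
        with pytest.raises(InputError, match="overlap"):
            SignalTrack.from_arrays(["chr1", "chr1"], [0, 50], [100, 150], [1, 2])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(data=st.data())
def test_merge_overlap_shuffle_properties(data):
    """Randomized invariants: merge/overlap equal the bitmap oracle and
    shuffling preserves the length multiset inside the genome."""
    asm = GenomeAssembly((("chr1", 20_000), ("chr2", 10_000)))
    intervals = data.draw(st.lists(
        st.tuples(st.sampled_from(["chr1", "chr2"]),
                  st.integers(0, 9_000), st.integers(1, 900)),
        min_size=1, max_size=40))
    iset = IntervalSet([c for c, _, _ in intervals],
                       [s for _, s, _ in intervals],
                       [s + l for _, s, l in intervals])
    maps = bitmap_of(iset, asm)
    merged = merge_intervals(iset)
    assert merged.total_bp == sum(int(m.sum()) for m in maps.values())
    assert total_overlap_bp(iset, merged) == merged.total_bp
    seed = data.draw(st.integers(0, 2**20))
    shuffled = shuffle_intervals(iset, asm, seed)
    assert sorted(shuffled.lengths) == sorted(iset.lengths)
    for i in range(len(shuffled)):
        assert 0 <= shuffled.starts[i]
        assert shuffled.ends[i] <= asm.length_of(shuffled.chroms[i])


def test_overlaps_any_matches_bruteforce(tiny_assembly):
    rng = np.random.default_rng(31)
    sites = random_interval_set(rng, tiny_assembly, 100)
    subject = random_interval_set(rng, tiny_assembly, 50)
    flags = overlaps_any(sites, subject)
    for i, site in enumerate(sites):
        expected = any(
            s.chrom == site.chrom and s.start < site.end and s.end > site.start
            for s in subject)
        assert flags[i] == expected
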