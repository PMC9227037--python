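"""Per-site quantitative profiling and grouped pairwise comparisons.

Sites are scored against stepwise-constant signal tracks (ChIP signal,
per-base conservation) and against repeat-class annotations (LTR, SINE,
LINE, DNA occupancy fractions).  Sites are then partitioned by TAD-boundary
association and compared — all sites, boundary sites, non-boundary sites
and a length-matched random control — with Welch t-tests over all six
group pairs.  A nearest-TSS assignment maps each site to its closest gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    GenomeAssembly,
    IntervalSet,
    SignalTrack,
    merge_intervals,
    overlaps_any,
    per_interval_overlap,
    shuffle_intervals,
)

REPEAT_CLASSES = ("LTR", "SINE", "LINE", "DNA")
GROUP_NAMES = ("all", "at_boundary", "non_boundary", "random_control")


@dataclass
class SiteGrouping:
    """Named site partition: all = at_boundary + non_boundary, plus control."""

    all: IntervalSet
    at_boundary: IntervalSet
    non_boundary: IntervalSet
    random_control: IntervalSet

    def __post_init__(self):
        assert len(self.at_boundary) + len(self.non_boundary) == len(self.all)
        assert len(self.random_control) == len(self.all)


@dataclass
class PairResult:
    group1: str
    group2: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    t_statistic: float
    p_value: float
    testable: bool = True


@dataclass
class GroupComparison:
    """All pairwise Welch t-tests among the four site groups."""

    pairs: list[PairResult]
    group_values: dict[str, np.ndarray]

    def pair(self, g1: str, g2: str) -> PairResult:
        for p in self.pairs:
            if {p.group1, p.group2} == {g1, g2}:
                return p
        raise KeyError(f"no pair ({g1}, {g2})")


def aggregate_signal(sites: IntervalSet, track: SignalTrack,
                     statistic: str = "mean_per_bp",
                     flank_bp: int = 0) -> np.ndarray:
    """Per-site summary of a stepwise signal track.

    ``mean_per_bp`` divides the integrated signal by the site length, with
    uncovered bases contributing 0 to the numerator but counting in the
    denominator; ``sum`` returns the integral.  ``flank_bp`` extends each
    site symmetrically before scoring (clipped at 0).
    """
    if statistic not in ("mean_per_bp", "sum"):
        raise ValueError(f"unknown statistic {statistic!r}")
    starts = np.maximum(sites.starts - flank_bp, 0)
    ends = sites.ends + flank_bp
    out = np.zeros(len(sites), dtype=np.float64)
    chrom_arr = np.asarray(sites.chroms, dtype=object)
    for chrom in dict.fromkeys(sites.chroms):
        idx = np.flatnonzero(chrom_arr == chrom)
        if chrom not in track.segments:
            continue
        ss, se, sv = track.segments[chrom]
        out[idx] = per_interval_overlap(starts[idx], ends[idx], ss, se, weights=sv)
    if statistic == "mean_per_bp":
        out = out / (ends - starts)
    return out


def repeat_occupancy(sites: IntervalSet,
                     repeats_by_class: dict[str, IntervalSet]
                     ) -> dict[str, np.ndarray]:
    """Per-site fraction of site length occupied by each repeat class."""
    unknown = set(repeats_by_class) - set(REPEAT_CLASSES)
    if unknown:
        raise ValueError(f"unknown repeat classes: {sorted(unknown)}")
    lengths = sites.lengths.astype(np.float64)
    chrom_arr = np.asarray(sites.chroms, dtype=object)
    result: dict[str, np.ndarray] = {}
    for cls, repeats in repeats_by_class.items():
        merged = merge_intervals(repeats).by_chrom()
        frac = np.zeros(len(sites), dtype=np.float64)
        for chrom in dict.fromkeys(sites.chroms):
            if chrom not in merged:
                continue
            idx = np.flatnonzero(chrom_arr == chrom)
            rs, re = merged[chrom]
            frac[idx] = per_interval_overlap(
                sites.starts[idx], sites.ends[idx], rs, re
            ).astype(np.float64)
        result[cls] = frac / lengths
    return result


def split_repeats_by_class(repeats: IntervalSet) -> dict[str, IntervalSet]:
    """Split a BED6-style repeat set on its name column (class labels)."""
    if repeats.names is None:
        raise ValueError("repeat intervals lack class names")
    names = np.asarray(repeats.names, dtype=object)
    out = {}
    for cls in REPEAT_CLASSES:
        idx = np.flatnonzero(names == cls)
        if len(idx):
            out[cls] = repeats.take(idx)
    return out


def conservation_per_bp(sites: IntervalSet, cons_track: SignalTrack) -> np.ndarray:
    """Mean conservation score per base over each site."""
    return aggregate_signal(sites, cons_track, statistic="mean_per_bp")


def build_site_grouping(sites: IntervalSet, boundaries: IntervalSet,
                        assembly: GenomeAssembly,
                        rng_seed: int | np.random.Generator) -> SiteGrouping:
    """Partition sites by boundary overlap and draw a matched random control."""
    at = overlaps_any(sites, boundaries)
    control = shuffle_intervals(sites, assembly, rng_seed)
    return SiteGrouping(
        all=sites,
        at_boundary=sites.subset_mask(at),
        non_boundary=sites.subset_mask(~at),
        random_control=control,
    )


def group_and_compare(sites: IntervalSet, boundaries: IntervalSet,
                      assembly: GenomeAssembly,
                      values: np.ndarray,
                      rng_seed: int | np.random.Generator,
                      control_values: np.ndarray | None = None,
                      grouping: SiteGrouping | None = None,
                      value_fn=None) -> GroupComparison:
    """Welch t-tests over the six pairs of the four site groups.

    ``values`` are per-site scores aligned with ``sites``.  Scores for the
    random control are either supplied via ``control_values``, or computed
    by calling ``value_fn(control_sites)`` (required when the score depends
    on genomic position, as for signal or repeat occupancy).  A group pair
    in which either member has fewer than two values is marked untestable
    rather than dropped.
    """
    values = np.asarray(values, dtype=np.float64)
    if len(values) != len(sites):
        raise ValueError("values not aligned with sites")
    if grouping is None:
        grouping = build_site_grouping(sites, boundaries, assembly, rng_seed)
    at = overlaps_any(sites, boundaries)
    if control_values is None:
        if value_fn is None:
            raise ValueError("need control_values or value_fn for the random control")
        control_values = np.asarray(value_fn(grouping.random_control), dtype=np.float64)
    group_values = {
        "all": values,
        "at_boundary": values[at],
        "non_boundary": values[~at],
        "random_control": control_values,
    }
    pairs = []
    names = list(GROUP_NAMES)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            v1, v2 = group_values[names[i]], group_values[names[j]]
            n1, n2 = len(v1), len(v2)
            m1 = float(v1.mean()) if n1 else float("nan")
            m2 = float(v2.mean()) if n2 else float("nan")
            if n1 < 2 or n2 < 2:
                pairs.append(PairResult(names[i], names[j], n1, n2, m1, m2,
                                        float("nan"), float("nan"), testable=False))
                continue
            if np.allclose(v1, v1[0]) and np.allclose(v2, v2[0]) and m1 == m2:
                t, p = 0.0, 1.0  # identical constant samples: no evidence
            else:
                res = stats.ttest_ind(v1, v2, equal_var=False)
                t, p = float(res.statistic), float(res.pvalue)
                if np.isnan(t):
                    t, p = 0.0, 1.0
            pairs.append(PairResult(names[i], names[j], n1, n2, m1, m2, t, p))
    return GroupComparison(pairs=pairs, group_values=group_values)


def nearest_tss_targets(sites: IntervalSet, tss: IntervalSet
                        ) -> list[tuple[str | None, int | None]]:
    """Closest TSS (by gene name) and signed distance for each site.

    Distance is 0 when the TSS lies inside the site, negative when the TSS
    is upstream of the site start, positive when downstream of the site
    end.  Ties break to the smaller TSS coordinate, then lexicographically
    smaller gene name.  Sites on chromosomes without any TSS get
    ``(None, None)``.
    """
    if len(tss) == 0:
        raise ValueError("empty TSS set")
    if tss.names is None:
        raise ValueError("TSS intervals lack gene names")
    by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    chrom_arr = np.asarray(tss.chroms, dtype=object)
    for chrom in dict.fromkeys(tss.chroms):
        idx = np.flatnonzero(chrom_arr == chrom)
        pos = tss.starts[idx]
        genes = [tss.names[i] for i in idx]
        order = sorted(range(len(idx)), key=lambda k: (pos[k], genes[k]))
        by_chrom[chrom] = (pos[np.asarray(order)], [genes[k] for k in order])
    out: list[tuple[str | None, int | None]] = []
    for i in range(len(sites)):
        chrom = sites.chroms[i]
        if chrom not in by_chrom:
            out.append((None, None))
            continue
        pos, genes = by_chrom[chrom]
        s, e = int(sites.starts[i]), int(sites.ends[i])
        dist = np.where(pos < s, pos - s, np.where(pos > e, pos - e, 0))
        absd = np.abs(dist)
        best = int(np.argmin(absd))  # argmin takes first: smaller coord wins ties
        out.append((genes[best], int(dist[best])))
    return out
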