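"""Dynamic boundary gain/loss and A/B compartment-switch classification.

Across the four ordered differentiation stages (ES, MES, CP, CM) each site
is reduced to a binary state per stage — at a TAD boundary or not, in
compartment A or B — giving a 4-tuple pattern.  The 2^4 - 2 = 14
non-constant patterns are the dynamic categories (a gain or loss happened
at least once); the two constant patterns are pooled into a single static
bin.  Observed per-category counts are compared against the mean counts of
randomly repositioned control sites with a chi-square test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    GenomeAssembly,
    IntervalSet,
    ShuffleSpace,
    merge_intervals,
)

STAGE_LABELS = ("ES", "MES", "CP", "CM")


@dataclass(frozen=True)
class DynamicPattern:
    """Binary per-stage state tuple; dynamic iff not constant."""

    pattern: tuple[int, ...]

    @property
    def is_dynamic(self) -> bool:
        return len(set(self.pattern)) > 1

    def __str__(self) -> str:
        return "".join(str(b) for b in self.pattern)


@dataclass
class StageSeries:
    """Ordered per-stage interval annotations (boundaries or compartments).

    For boundary dynamics, ``per_stage`` holds one boundary IntervalSet per
    stage.  For compartment switching, each stage's IntervalSet carries the
    A/B label in its ``names`` column.
    """

    per_stage: list[IntervalSet]
    stage_labels: tuple[str, ...] = STAGE_LABELS

    def __post_init__(self):
        if len(self.per_stage) != len(self.stage_labels):
            raise ValueError(
                f"expected {len(self.stage_labels)} stages, got {len(self.per_stage)}"
            )

    @property
    def n_stages(self) -> int:
        return len(self.per_stage)


@dataclass
class CategoryCounts:
    """Observed vs. expected per-pattern counts and the chi-square result."""

    patterns: list[str]
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float
    n_dynamic_observed: int
    n_static_observed: int
    n_dropped: int = 0
    degenerate: bool = False
    pooled_patterns: list[str] = field(default_factory=list)


def enumerate_dynamic_patterns(n_stages: int) -> list[DynamicPattern]:
    """All non-constant binary state tuples, in lexicographic order.

    For 4 stages this is the 14-category space of boundary gain/loss (or
    compartment-switch) histories.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    out = []
    for bits in itertools.product((0, 1), repeat=n_stages):
        if len(set(bits)) > 1:
            out.append(DynamicPattern(bits))
    return out


def _boundary_states(sites: IntervalSet, series: StageSeries) -> np.ndarray:
    """(n_sites, n_stages) binary matrix: >= 1 bp boundary overlap per stage."""
    states = np.zeros((len(sites), series.n_stages), dtype=np.int8)
    site_by_chrom: dict[str, np.ndarray] = {}
    chrom_arr = np.asarray(sites.chroms, dtype=object)
    for chrom in dict.fromkeys(sites.chroms):
        site_by_chrom[chrom] = np.flatnonzero(chrom_arr == chrom)
    for s, bounds in enumerate(series.per_stage):
        merged = merge_intervals(bounds).by_chrom()
        for chrom, idx in site_by_chrom.items():
            if chrom not in merged:
                continue
            bs, be = merged[chrom]
            qs, qe = sites.starts[idx], sites.ends[idx]
            k = np.searchsorted(be, qs, side="right")
            ok = (k < len(bs)) & (bs[np.minimum(k, len(bs) - 1)] < qe)
            states[idx, s] = ok
    return states


def annotate_site_boundary_dynamics(sites: IntervalSet, series: StageSeries
                                    ) -> list[DynamicPattern]:
    """Per-site boundary presence/absence pattern across the stages.

    State at a stage is 1 iff the site overlaps that stage's boundary set
    by at least one base pair.
    """
    states = _boundary_states(sites, series)
    return [DynamicPattern(tuple(int(b) for b in row)) for row in states]


def _compartment_states(sites: IntervalSet, series: StageSeries
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint compartment state per stage (1 = A); mask of assigned sites.

    A site is dropped (mask False) if its midpoint falls outside every
    compartment at any stage.
    """
    n = len(sites)
    states = np.zeros((n, series.n_stages), dtype=np.int8)
    assigned = np.ones(n, dtype=bool)
    mids = sites.midpoints
    for s, comps in enumerate(series.per_stage):
        if comps.names is None:
            raise ValueError(f"stage {series.stage_labels[s]}: compartments lack A/B labels")
        lookup: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        chrom_arr = np.asarray(comps.chroms, dtype=object)
        labels = np.asarray([1 if x == "A" else 0 for x in comps.names], dtype=np.int8)
        for chrom in dict.fromkeys(comps.chroms):
            mask = chrom_arr == chrom
            cs, ce, cl = comps.starts[mask], comps.ends[mask], labels[mask]
            order = np.argsort(cs, kind="stable")
            lookup[chrom] = (cs[order], ce[order], cl[order])
        for i in range(n):
            chrom = sites.chroms[i]
            if chrom not in lookup:
                assigned[i] = False
                continue
            cs, ce, cl = lookup[chrom]
            j = int(np.searchsorted(cs, mids[i], side="right")) - 1
            if j < 0 or ce[j] <= mids[i]:
                assigned[i] = False
            else:
                states[i, s] = cl[j]
    return states, assigned


def annotate_site_compartment_switch(sites: IntervalSet, series: StageSeries
                                     ) -> tuple[list[DynamicPattern], int]:
    """Per-site A/B pattern (1 = compartment A at midpoint) across stages.

    Returns the patterns of assignable sites and the number of dropped
    sites (midpoint unannotated at some stage).
    """
    states, assigned = _compartment_states(sites, series)
    patterns = [DynamicPattern(tuple(int(b) for b in states[i]))
                for i in np.flatnonzero(assigned)]
    return patterns, int((~assigned).sum())


def _count_patterns(patterns: list[DynamicPattern], n_stages: int
                    ) -> tuple[np.ndarray, int]:
    """Counts over the dynamic categories plus the pooled static count."""
    order = {str(p): k for k, p in enumerate(enumerate_dynamic_patterns(n_stages))}
    counts = np.zeros(len(order), dtype=np.float64)
    static = 0
    for p in patterns:
        if p.is_dynamic:
            counts[order[str(p)]] += 1
        else:
            static += 1
    return counts, static


def chi_square_counts(observed, expected, min_expected: float = 5.0,
                      rescale: bool = True
                      ) -> tuple[float, int, float, list[int], bool]:
    """Chi-square goodness of fit of observed counts against expected.

    Expected counts are rescaled to the observed total (they typically come
    from an average over randomizations); bins with expected below
    ``min_expected`` are pooled into a single rare bin.  Returns
    (chi2, df, p, pooled_bin_indices, degenerate).
    """
    obs = np.asarray(observed, dtype=np.float64)
    exp = np.asarray(expected, dtype=np.float64)
    if obs.shape != exp.shape:
        raise ValueError("observed/expected shape mismatch")
    if obs.sum() == 0 or exp.sum() == 0:
        return 0.0, 0, 1.0, [], True
    if rescale:
        exp = exp * (obs.sum() / exp.sum())
    rare = exp < min_expected
    pooled = [int(i) for i in np.flatnonzero(rare)]
    if rare.any():
        obs_t = np.concatenate((obs[~rare], [obs[rare].sum()]))
        exp_t = np.concatenate((exp[~rare], [exp[rare].sum()]))
        nonzero = exp_t > 0
        obs_t, exp_t = obs_t[nonzero], exp_t[nonzero]
    else:
        obs_t, exp_t = obs, exp
    if len(obs_t) < 2:
        return 0.0, 0, 1.0, pooled, True
    # renormalize after pooling/dropping so totals match exactly
    exp_t = exp_t * (obs_t.sum() / exp_t.sum())
    chi2 = float(((obs_t - exp_t) ** 2 / exp_t).sum())
    df = len(obs_t) - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p, pooled, False


def category_chi_square(
    observed_sites: IntervalSet,
    series: StageSeries,
    assembly: GenomeAssembly,
    n_randomizations: int = 100,
    rng_seed: int = 0,
    mode: str = "boundary",
    include_static: bool = False,
    min_expected: float = 5.0,
) -> CategoryCounts:
    """Chi-square comparison of observed vs. randomized category counts.

    Expected counts are the mean over ``n_randomizations`` random
    repositionings of the sites, rescaled to the observed total.  Bins with
    expected count below ``min_expected`` are pooled into one rare bin
    before the test (classical validity rule); the pre-pooling table is
    kept in ``patterns``/``observed``/``expected``.  ``mode`` selects
    boundary-overlap patterns or compartment-switch patterns; with
    ``include_static`` the pooled static bin enters the chi-square too.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    if mode not in ("boundary", "compartment"):
        raise ValueError(f"unknown mode {mode!r}")

    def classify(iset: IntervalSet) -> tuple[np.ndarray, int, int]:
        if mode == "boundary":
            pats = annotate_site_boundary_dynamics(iset, series)
            dropped = 0
        else:
            pats, dropped = annotate_site_compartment_switch(iset, series)
        counts, static = _count_patterns(pats, series.n_stages)
        return counts, static, dropped

    obs_counts, obs_static, obs_dropped = classify(observed_sites)

    space = ShuffleSpace(assembly)
    lengths = observed_sites.lengths
    exp_counts = np.zeros_like(obs_counts)
    exp_static = 0.0
    for r in range(n_randomizations):
        rng = np.random.default_rng(rng_seed + r)
        chroms, starts = space.place(lengths, rng)
        rand = IntervalSet(chroms, starts, starts + lengths)
        c, s, _ = classify(rand)
        exp_counts += c
        exp_static += s
    exp_counts /= n_randomizations
    exp_static /= n_randomizations

    pattern_labels = [str(p) for p in enumerate_dynamic_patterns(series.n_stages)]
    if include_static:
        obs_vec = np.concatenate((obs_counts, [obs_static]))
        exp_vec = np.concatenate((exp_counts, [exp_static]))
        labels = pattern_labels + ["static"]
    else:
        obs_vec = obs_counts.copy()
        exp_vec = exp_counts.copy()
        labels = list(pattern_labels)

    chi2, df, p, pooled_idx, degenerate = chi_square_counts(
        obs_vec, exp_vec, min_expected=min_expected)
    pooled_labels = [labels[i] for i in pooled_idx]

    return CategoryCounts(
        patterns=pattern_labels,
        observed=obs_counts,
        expected=exp_counts,
        chi2=chi2, df=df, p_value=p,
        n_dynamic_observed=int(obs_counts.sum()),
        n_static_observed=obs_static,
        n_dropped=obs_dropped,
        degenerate=degenerate,
        pooled_patterns=pooled_labels,
    )
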