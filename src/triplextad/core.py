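"""Interval data model, standard-format I/O and shuffle/overlap primitives.

Coordinates are 0-based half-open throughout (BED convention).  All interval
arithmetic is vectorized over per-chromosome numpy arrays; the same merged
sorted representation backs overlap counting, per-interval coverage and
signal aggregation, so every downstream statistic shares one code path that
is cross-checked against a per-base bitmap oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np


class InputError(ValueError):
    """Malformed or invariant-violating input file content."""


class PlacementError(RuntimeError):
    """A site cannot be placed anywhere in the allowed shuffle space."""


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered chromosome name -> length map defining the shuffle space."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise InputError("duplicate chromosome names in assembly")
        for name, length in self.chromosomes:
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise InputError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_lengths", dict(self.chromosomes))

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise InputError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())


@dataclass(frozen=True)
class Interval:
    """Genomic span [start, end) with optional BED-style annotations."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    value: float | None = None
    label: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """A collection of intervals backed by parallel numpy arrays.

    Preserves input order; ``sort()`` returns a copy ordered by
    (chromosome name, start, end).  Optional per-interval ``names`` and
    ``values`` carry BED columns 4-5 (compartment A/B labels and repeat
    class names travel in ``names``).
    """

    def __init__(self, chroms: Sequence[str], starts, ends,
                 names: Sequence[str | None] | None = None,
                 values: Sequence[float | None] | None = None):
        self.chroms = list(chroms)
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends length mismatch")
        if np.any(self.starts < 0) or np.any(self.starts >= self.ends):
            bad = int(np.argmax((self.starts < 0) | (self.starts >= self.ends)))
            raise InputError(
                f"invalid interval {self.chroms[bad]}:"
                f"{self.starts[bad]}-{self.ends[bad]}"
            )
        self.names = list(names) if names is not None else None
        self.values = list(values) if values is not None else None
        self._by_chrom_cache: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_intervals(cls, intervals: Iterable[Interval]) -> "IntervalSet":
        ivs = list(intervals)
        names = [iv.name for iv in ivs]
        values = [iv.value for iv in ivs]
        return cls(
            [iv.chrom for iv in ivs],
            [iv.start for iv in ivs],
            [iv.end for iv in ivs],
            names=names if any(n is not None for n in names) else None,
            values=values if any(v is not None for v in values) else None,
        )

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls([], np.empty(0, np.int64), np.empty(0, np.int64))

    # -- basics -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.chroms)

    def __iter__(self) -> Iterator[Interval]:
        for i in range(len(self)):
            yield Interval(
                self.chroms[i], int(self.starts[i]), int(self.ends[i]),
                name=self.names[i] if self.names else None,
                value=self.values[i] if self.values else None,
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (self.chroms == other.chroms
                and np.array_equal(self.starts, other.starts)
                and np.array_equal(self.ends, other.ends))

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, bp={self.total_bp})"

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def total_bp(self) -> int:
        """Total bases counted with multiplicity (not the union)."""
        return int(self.lengths.sum())

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def sort(self) -> "IntervalSet":
        order = sorted(range(len(self)),
                       key=lambda i: (self.chroms[i], self.starts[i], self.ends[i]))
        return self.take(order)

    def take(self, indices) -> "IntervalSet":
        idx = np.asarray(indices, dtype=np.int64)
        return IntervalSet(
            [self.chroms[i] for i in idx],
            self.starts[idx], self.ends[idx],
            names=[self.names[i] for i in idx] if self.names else None,
            values=[self.values[i] for i in idx] if self.values else None,
        )

    def subset_mask(self, mask: np.ndarray) -> "IntervalSet":
        return self.take(np.flatnonzero(mask))

    def validate(self, assembly: GenomeAssembly) -> "IntervalSet":
        for i, chrom in enumerate(self.chroms):
            if chrom not in assembly:
                raise InputError(f"interval {i}: unknown chromosome {chrom!r}")
            if self.ends[i] > assembly.length_of(chrom):
                raise InputError(
                    f"interval {i}: {chrom}:{self.starts[i]}-{self.ends[i]} "
                    f"extends past chromosome end {assembly.length_of(chrom)}"
                )
        return self

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) sorted by start; cached."""
        if self._by_chrom_cache is None:
            out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            chrom_arr = np.asarray(self.chroms, dtype=object)
            for chrom in dict.fromkeys(self.chroms):
                mask = chrom_arr == chrom
                s, e = self.starts[mask], self.ends[mask]
                order = np.lexsort((e, s))
                out[chrom] = (s[order], e[order])
            self._by_chrom_cache = out
        return self._by_chrom_cache


@dataclass
class SignalTrack:
    """Stepwise-constant per-base signal (bedGraph semantics).

    Segments on one chromosome are non-overlapping and sorted; uncovered
    bases have value 0.
    """

    segments: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_arrays(cls, chroms, starts, ends, values) -> "SignalTrack":
        chroms = np.asarray(chroms, dtype=object)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        if not np.all(np.isfinite(values)):
            raise InputError("non-finite signal value")
        segs = {}
        for chrom in dict.fromkeys(chroms.tolist()):
            mask = chroms == chrom
            s, e, v = starts[mask], ends[mask], values[mask]
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(s >= e):
                raise InputError(f"empty or inverted segment on {chrom}")
            if np.any(e[:-1] > s[1:]):
                raise InputError(f"overlapping segments on {chrom}")
            segs[chrom] = (s, e, v)
        return cls(segs)

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self.segments:
            return 0.0
        s, e, v = self.segments[chrom]
        i = int(np.searchsorted(s, pos, side="right")) - 1
        if i >= 0 and e[i] > pos:
            return float(v[i])
        return 0.0


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> GenomeAssembly:
    """Parse a two-column (name, length) chrom.sizes file."""
    entries: list[tuple[str, int]] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise InputError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
            name, length_s = fields
            try:
                length = int(length_s)
            except ValueError:
                raise InputError(f"{path}: line {lineno}: non-integer length {length_s!r}") from None
            if length <= 0:
                raise InputError(f"{path}: line {lineno}: non-positive length {length}")
            if name in seen:
                raise InputError(f"{path}: line {lineno}: duplicate chromosome {name!r}")
            seen.add(name)
            entries.append((name, length))
    if not entries:
        raise InputError(f"{path}: empty chrom.sizes file")
    return GenomeAssembly(tuple(entries))


def read_bed(path, assembly: GenomeAssembly | None = None) -> IntervalSet:
    """Read BED3+ into an IntervalSet (col 4 -> name, col 5 -> value).

    Columns beyond 5 are dropped.  With an assembly given, coordinates are
    validated against chromosome lengths; intervals extending past a
    chromosome end are an error, not clipped.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str | None] = []
    values: list[float | None] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}: line {lineno}: expected >= 3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise InputError(f"{path}: line {lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise InputError(f"{path}: line {lineno}: invalid span {start}-{end}")
            if assembly is not None:
                if chrom not in assembly:
                    raise InputError(f"{path}: line {lineno}: unknown chromosome {chrom!r}")
                if end > assembly.length_of(chrom):
                    raise InputError(
                        f"{path}: line {lineno}: end {end} exceeds length of {chrom}"
                    )
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            names.append(fields[3] if len(fields) > 3 and fields[3] != "." else None)
            if len(fields) > 4 and fields[4] != ".":
                try:
                    values.append(float(fields[4]))
                except ValueError:
                    values.append(None)
            else:
                values.append(None)
    return IntervalSet(
        chroms, starts, ends,
        names=names if any(n is not None for n in names) else None,
        values=values if any(v is not None for v in values) else None,
    )


def write_bed(iset: IntervalSet, path) -> None:
    """Write BED3/4/5 depending on which annotation columns are present."""
    with open(path, "w") as fh:
        for i in range(len(iset)):
            cols = [iset.chroms[i], str(int(iset.starts[i])), str(int(iset.ends[i]))]
            name = iset.names[i] if iset.names else None
            value = iset.values[i] if iset.values else None
            if name is not None or value is not None:
                cols.append(name if name is not None else ".")
            if value is not None:
                cols.append(format(value, "g"))
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path, assembly: GenomeAssembly | None = None) -> SignalTrack:
    """Read a 4-column bedGraph; accepts unsorted input and sorts internally."""
    chroms, starts, ends, values = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise InputError(f"{path}: line {lineno}: expected 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise InputError(f"{path}: line {lineno}: malformed fields") from None
            if start < 0 or start >= end:
                raise InputError(f"{path}: line {lineno}: invalid span {start}-{end}")
            if assembly is not None and fields[0] not in assembly:
                raise InputError(f"{path}: line {lineno}: unknown chromosome {fields[0]!r}")
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            values.append(value)
    return SignalTrack.from_arrays(chroms, starts, ends, values)


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in track.segments:
            s, e, v = track.segments[chrom]
            for i in range(len(s)):
                # .17g round-trips doubles exactly through the text format
                fh.write(f"{chrom}\t{int(s[i])}\t{int(e[i])}\t{format(float(v[i]), '.17g')}\n")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted-by-start intervals; touching intervals coalesce."""
    if len(starts) == 0:
        return starts, ends
    # cumulative max of ends marks runs of connected intervals
    cummax = np.maximum.accumulate(ends)
    new_block = np.empty(len(starts), dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > cummax[:-1]
    block_id = np.cumsum(new_block) - 1
    n_blocks = block_id[-1] + 1
    merged_starts = starts[new_block]
    merged_ends = np.zeros(n_blocks, dtype=np.int64)
    np.maximum.at(merged_ends, block_id, ends)
    return merged_starts, merged_ends


def merge_intervals(iset: IntervalSet) -> IntervalSet:
    """Union of the input's covered bases as sorted non-overlapping intervals.

    Touching intervals (end == next start) are merged; annotations dropped.
    """
    chroms_out: list[str] = []
    starts_out: list[np.ndarray] = []
    ends_out: list[np.ndarray] = []
    for chrom in sorted(set(iset.chroms)):
        s, e = iset.by_chrom()[chrom]
        ms, me = _merge_arrays(s, e)
        chroms_out.extend([chrom] * len(ms))
        starts_out.append(ms)
        ends_out.append(me)
    if not chroms_out:
        return IntervalSet.empty()
    return IntervalSet(chroms_out, np.concatenate(starts_out), np.concatenate(ends_out))


def per_interval_overlap(q_starts: np.ndarray, q_ends: np.ndarray,
                         s_starts: np.ndarray, s_ends: np.ndarray,
                         weights: np.ndarray | None = None) -> np.ndarray:
    """Per-query overlap with a merged, sorted subject on one chromosome.

    Returns, for each query interval, the number of subject base pairs it
    covers — or, with ``weights`` (one per subject segment), the sum of
    weight x overlap_bp, which is exactly the integral of a stepwise signal
    over the query span.
    """
    nq = len(q_starts)
    if nq == 0 or len(s_starts) == 0:
        return np.zeros(nq, dtype=np.float64 if weights is not None else np.int64)
    seg_len = (s_ends - s_starts).astype(np.float64)
    w = seg_len if weights is None else seg_len * np.asarray(weights, dtype=np.float64)
    cum = np.concatenate(([0.0], np.cumsum(w)))
    lo = np.searchsorted(s_ends, q_starts, side="right")
    hi = np.searchsorted(s_starts, q_ends, side="left")
    out = np.zeros(nq, dtype=np.float64)
    has = hi > lo
    if np.any(has):
        li, hj = lo[has], hi[has]
        total = cum[hj] - cum[li]
        unit_lo = np.ones(li.shape) if weights is None else np.asarray(weights)[li]
        unit_hi = np.ones(li.shape) if weights is None else np.asarray(weights)[hj - 1]
        # clip partial coverage of the first and last overlapped segment
        left_trim = np.maximum(q_starts[has] - s_starts[li], 0)
        right_trim = np.maximum(s_ends[hj - 1] - q_ends[has], 0)
        out[has] = total - left_trim * unit_lo - right_trim * unit_hi
    if weights is None:
        return np.rint(out).astype(np.int64)
    return out


def total_overlap_bp(a: IntervalSet, b: IntervalSet) -> int:
    """Base pairs in the intersection of the unions of ``a`` and ``b``."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    total = 0
    b_chrom = mb.by_chrom()
    for chrom, (qs, qe) in ma.by_chrom().items():
        if chrom not in b_chrom:
            continue
        ss, se = b_chrom[chrom]
        total += int(per_interval_overlap(qs, qe, ss, se).sum())
    return total


def overlaps_any(iset: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Boolean per-interval flag: >= 1 bp overlap with the subject union."""
    msub = merge_intervals(subject).by_chrom()
    flags = np.zeros(len(iset), dtype=bool)
    chrom_arr = np.asarray(iset.chroms, dtype=object)
    for chrom in dict.fromkeys(iset.chroms):
        if chrom not in msub:
            continue
        mask = chrom_arr == chrom
        qs, qe = iset.starts[mask], iset.ends[mask]
        ss, se = msub[chrom]
        k = np.searchsorted(se, qs, side="right")
        ok = (k < len(ss)) & (ss[np.minimum(k, len(ss) - 1)] < qe)
        flags[np.flatnonzero(mask)] = ok
    return flags


def complement(iset: IntervalSet, assembly: GenomeAssembly) -> IntervalSet:
    """Assembly minus the union of ``iset``."""
    merged = merge_intervals(iset).by_chrom()
    chroms, starts, ends = [], [], []
    for chrom, length in assembly.chromosomes:
        if chrom in merged:
            s, e = merged[chrom]
            gaps_start = np.concatenate(([0], e))
            gaps_end = np.concatenate((s, [length]))
            keep = gaps_start < gaps_end
            for gs, ge in zip(gaps_start[keep], gaps_end[keep]):
                chroms.append(chrom)
                starts.append(int(gs))
                ends.append(int(ge))
        else:
            chroms.append(chrom)
            starts.append(0)
            ends.append(length)
    if not chroms:
        return IntervalSet.empty()
    return IntervalSet(chroms, starts, ends)


def intersect_sets(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Intervals covering exactly the bases in union(a) AND union(b)."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    b_chrom = mb.by_chrom()
    chroms, starts, ends = [], [], []
    for chrom, (qs, qe) in ma.by_chrom().items():
        if chrom not in b_chrom:
            continue
        ss, se = b_chrom[chrom]
        lo = np.searchsorted(se, qs, side="right")
        hi = np.searchsorted(ss, qe, side="left")
        for i in range(len(qs)):
            for j in range(lo[i], hi[i]):
                s = max(qs[i], ss[j])
                e = min(qe[i], se[j])
                if s < e:
                    chroms.append(chrom)
                    starts.append(int(s))
                    ends.append(int(e))
    if not chroms:
        return IntervalSet.empty()
    return IntervalSet(chroms, starts, ends)


# ---------------------------------------------------------------------------
# Shuffle primitive
# ---------------------------------------------------------------------------

class ShuffleSpace:
    """Precomputed allowed spans for repeated length-preserving shuffles.

    The allowed space is the assembly (or ``within`` if given) minus
    ``exclude``.  A placement start is drawn uniformly over *all* valid
    start positions across spans, so a span's selection probability is
    proportional to its number of valid starts for the site length.
    """

    def __init__(self, assembly: GenomeAssembly,
                 exclude: IntervalSet | None = None,
                 within: IntervalSet | None = None):
        if within is not None:
            space = merge_intervals(within)
            if exclude is not None:
                excl = merge_intervals(exclude)
                space = _subtract(space, excl)
        elif exclude is not None:
            space = complement(exclude, assembly)
        else:
            space = IntervalSet(
                assembly.names,
                np.zeros(len(assembly.names), np.int64),
                np.array([assembly.length_of(c) for c in assembly.names], np.int64),
            )
        space = space.sort()
        self.span_chroms = list(space.chroms)
        self.span_starts = space.starts
        self.span_lengths = space.lengths

    def place(self, lengths: np.ndarray, rng: np.random.Generator
              ) -> tuple[list[str], np.ndarray]:
        """Place sites of the given lengths; returns (chroms, starts)."""
        lengths = np.asarray(lengths, dtype=np.int64)
        n = len(lengths)
        out_chrom_idx = np.zeros(n, dtype=np.int64)
        out_starts = np.zeros(n, dtype=np.int64)
        # process unique lengths in sorted order for seed-stable determinism
        for L in np.unique(lengths):
            idx = np.flatnonzero(lengths == L)
            valid = np.maximum(self.span_lengths - L + 1, 0)
            total = int(valid.sum())
            if total == 0:
                raise PlacementError(
                    f"site of length {L} does not fit in any allowed span"
                )
            cum = np.cumsum(valid)
            draws = rng.integers(0, total, size=len(idx))
            span = np.searchsorted(cum, draws, side="right")
            offset = draws - (cum[span] - valid[span])
            out_chrom_idx[idx] = span
            out_starts[idx] = self.span_starts[span] + offset
        chroms = [self.span_chroms[i] for i in out_chrom_idx]
        return chroms, out_starts


def _subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """union(a) minus union(b); both inputs already merged."""
    b_chrom = b.by_chrom()
    chroms, starts, ends = [], [], []
    for chrom, (qs, qe) in a.by_chrom().items():
        if chrom not in b_chrom:
            for s, e in zip(qs, qe):
                chroms.append(chrom)
                starts.append(int(s))
                ends.append(int(e))
            continue
        ss, se = b_chrom[chrom]
        for s, e in zip(qs, qe):
            cur = int(s)
            lo = np.searchsorted(se, s, side="right")
            hi = np.searchsorted(ss, e, side="left")
            for j in range(lo, hi):
                if ss[j] > cur:
                    chroms.append(chrom)
                    starts.append(cur)
                    ends.append(int(ss[j]))
                cur = max(cur, int(se[j]))
            if cur < e:
                chroms.append(chrom)
                starts.append(cur)
                ends.append(int(e))
    if not chroms:
        return IntervalSet.empty()
    return IntervalSet(chroms, starts, ends)


def subtract_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases covered by ``a`` but not ``b``, as merged intervals."""
    return _subtract(merge_intervals(a), merge_intervals(b))


def shuffle_intervals(sites: IntervalSet, assembly: GenomeAssembly,
                      rng_seed: int | np.random.Generator,
                      exclude: IntervalSet | None = None,
                      within: IntervalSet | None = None,
                      non_overlapping: bool = False,
                      max_tries: int = 1000) -> IntervalSet:
    """Length-preserving random repositioning of sites within the genome.

    Each output interval keeps its input length and lands fully inside the
    allowed space (assembly minus ``exclude``, intersected with ``within``
    if given).  Placement is uniform over valid start positions, so
    chromosomes/spans are chosen proportional to how many starts they admit.
    By default shuffled sites may overlap one another; ``non_overlapping``
    switches to rejection sampling.  Deterministic given the seed.
    """
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    if len(sites) == 0:
        return IntervalSet.empty()
    space = ShuffleSpace(assembly, exclude=exclude, within=within)
    lengths = sites.lengths
    chroms, starts = space.place(lengths, rng)
    if non_overlapping:
        for _ in range(max_tries):
            placed = IntervalSet(chroms, starts, starts + lengths)
            clash = _self_overlap_mask(placed)
            if not clash.any():
                break
            idx = np.flatnonzero(clash)
            new_chroms, new_starts = space.place(lengths[idx], rng)
            for k, i in enumerate(idx):
                chroms[i] = new_chroms[k]
                starts[i] = new_starts[k]
        else:
            raise PlacementError("could not place sites without overlap")
    return IntervalSet(chroms, starts, starts + lengths)


def _self_overlap_mask(iset: IntervalSet) -> np.ndarray:
    """Mark intervals overlapping an earlier-sorting interval of the set."""
    mask = np.zeros(len(iset), dtype=bool)
    order = sorted(range(len(iset)),
                   key=lambda i: (iset.chroms[i], int(iset.starts[i])))
    prev_chrom, prev_end = None, -1
    for i in order:
        if iset.chroms[i] == prev_chrom and iset.starts[i] < prev_end:
            mask[i] = True
        else:
            prev_chrom = iset.chroms[i]
            prev_end = int(iset.ends[i])
    return mask


def tad_boundaries(tads: IntervalSet, flank_bp: int,
                   assembly: GenomeAssembly | None = None) -> IntervalSet:
    """Boundary windows [edge - flank, edge + flank) around every TAD edge.

    Edges shared by adjacent TADs are deduplicated; windows are clipped to
    [0, chromosome length) and the result is merged.  The flank width is an
    analysis parameter, not a measured quantity.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    chroms, starts, ends = [], [], []
    for chrom, (s, e) in tads.by_chrom().items():
        edges = np.unique(np.concatenate((s, e)))
        limit = assembly.length_of(chrom) if assembly is not None else None
        for edge in edges:
            lo = max(int(edge) - flank_bp, 0)
            hi = int(edge) + flank_bp
            if limit is not None:
                hi = min(hi, limit)
            if lo < hi:
                chroms.append(chrom)
                starts.append(lo)
                ends.append(hi)
    if not chroms:
        return IntervalSet.empty()
    return merge_intervals(IntervalSet(chroms, starts, ends))
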