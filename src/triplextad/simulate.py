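"""Seeded synthetic-data generator with planted, parameterized structure.

Emulates the input bundle of the triplex-site 3D-genome analysis: a small
multi-chromosome genome; four ordered stages (ES, MES, CP, CM) of TAD
partitions with controlled boundary turnover; A/B compartment blocks with a
controlled fraction of switching blocks; triplex-like sites placed with a
tunable enrichment factor at CP-stage TAD boundaries; a ChIP-like signal
track with peaks planted over a fraction of sites; a conservation-like
track uplifted at boundary-associated sites; four repeat classes with
class-specific enrichment or depletion inside sites; and evenly spaced TSS
points.  Every planted parameter is recoverable by the corresponding
pipeline stage, which is the module's reason to exist.

All randomness flows from one seed through fixed per-component offsets, so
each component is independently reproducible and the whole bundle is
byte-identical across runs with the same config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    GenomeAssembly,
    InputError,
    IntervalSet,
    ShuffleSpace,
    SignalTrack,
    intersect_sets,
    merge_intervals,
    overlaps_any,
    tad_boundaries,
    write_bed,
    write_bedgraph,
)
from .dynamics import STAGE_LABELS, StageSeries
from .profiles import REPEAT_CLASSES

# fixed per-component seed offsets (stream splitting)
_STREAM = {"tads": 1, "compartments": 2, "sites": 3,
           "ctcf": 4, "cons": 5, "repeats": 6, "tss": 7}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic bundle; defaults define the study conditions.

    Lengths in bp.  ``boundary_enrichment`` is the relative placement
    density of sites inside CP-stage boundary windows (1 = uniform) and
    ``gap_depletion`` the relative density in unorganized regions outside
    TADs (1 = uniform); ``compartment_switch_rate`` is the fraction of
    compartment blocks that switch label at least once across the stages;
    ``boundary_turnover`` is the per-transition probability that an
    internal TAD boundary is lost (and replaced elsewhere).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 10_000_000
    tad_mean_length: int = 800_000
    tad_gap_prob: float = 1.0
    tad_gap_length: int = 200_000
    boundary_flank: int = 40_000
    boundary_turnover: float = 0.2
    compartment_block_length: int = 500_000
    compartment_switch_rate: float = 0.3
    n_sites: int = 1000
    site_length: int = 1000
    boundary_enrichment: float = 10.0
    gap_depletion: float = 0.1
    signal_site_fraction: float = 0.5
    signal_peak_height: float = 10.0
    signal_bin: int = 1000
    cons_bin: int = 500
    cons_base_mean: float = 0.4
    cons_sd: float = 0.1
    cons_boundary_shift: float = 0.2
    repeat_density: dict = field(default_factory=lambda: {
        "LTR": 0.05, "SINE": 0.08, "LINE": 0.15, "DNA": 0.03})
    repeat_length: dict = field(default_factory=lambda: {
        "LTR": 500, "SINE": 300, "LINE": 5000, "DNA": 800})
    repeat_site_factor: dict = field(default_factory=lambda: {
        "LTR": 5.0, "SINE": 5.0, "LINE": 0.2, "DNA": 0.2})
    tss_spacing: int = 100_000

    def __post_init__(self):
        for p in (self.boundary_turnover, self.compartment_switch_rate,
                  self.signal_site_fraction, self.tad_gap_prob):
            if not 0.0 <= p <= 1.0:
                raise InputError(f"probability out of [0,1]: {p}")
        if self.boundary_enrichment < 1.0:
            raise InputError("boundary_enrichment must be >= 1")
        if self.gap_depletion <= 0.0:
            raise InputError("gap_depletion must be positive")
        if self.chrom_length < 2 * self.tad_mean_length:
            raise InputError("chrom_length must be >= 2 * tad_mean_length")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Bundle:
    """In-memory synthetic input bundle."""

    config: SimulationConfig
    assembly: GenomeAssembly
    tads: StageSeries
    compartments: StageSeries
    sites: IntervalSet
    ctcf: SignalTrack
    cons: SignalTrack
    repeats: IntervalSet
    tss: IntervalSet

    def boundaries(self, stage: str) -> IntervalSet:
        idx = list(STAGE_LABELS).index(stage)
        return tad_boundaries(self.tads.per_stage[idx],
                              self.config.boundary_flank, self.assembly)


# ---------------------------------------------------------------------------
# Genome, TAD stages and compartments
# ---------------------------------------------------------------------------

def _tile_tads(rng: np.random.Generator, config: SimulationConfig
               ) -> list[tuple[int, int]]:
    """Stage-1 TAD intervals along one chromosome.

    TAD lengths ~ exponential around the mean, truncated to [mean/4,
    4*mean]; before each TAD an unorganized gap of exponential length is
    inserted with probability ``tad_gap_prob`` (1 by default: TAD callers
    leave an unorganized region between adjacent domains), so TADs cover
    most but not all of the chromosome, as real TAD calls do.
    """
    mean_len = config.tad_mean_length
    lo, hi = mean_len // 4, mean_len * 4
    L = config.chrom_length
    tads: list[tuple[int, int]] = []
    pos = 0
    while True:
        if tads and rng.random() < config.tad_gap_prob:
            g = config.tad_gap_length
            pos += int(np.clip(rng.exponential(g), g // 2, g * 2))
        length = int(np.clip(rng.exponential(mean_len), lo, hi))
        end = min(pos + length, L)
        if end - pos < lo:
            break
        tads.append((pos, end))
        pos = end
        if pos >= L - lo:
            break
    return tads


def _turnover_step(rng: np.random.Generator, tads: list[tuple[int, int]],
                   config: SimulationConfig) -> list[tuple[int, int]]:
    """One stage transition: merge adjacent TADs, split others to compensate.

    Each junction between consecutive TADs is lost (the pair merges,
    absorbing any gap) with probability ``boundary_turnover``; the same
    number of new boundaries is created by splitting randomly chosen TADs
    at uniform interior points.  A split re-inserts an unorganized gap with
    probability ``tad_gap_prob`` so the genome's TAD-covered share stays
    stationary across stages instead of drifting up as merges swallow
    gaps.  TAD count stays constant.
    """
    min_len = config.tad_mean_length // 4
    tads = list(tads)
    n_merged = 0
    for i in range(len(tads) - 1, 0, -1):
        if rng.random() < config.boundary_turnover:
            tads[i - 1] = (tads[i - 1][0], tads[i][1])
            del tads[i]
            n_merged += 1
    for _ in range(n_merged):
        gl = 0
        if rng.random() < config.tad_gap_prob:
            g = config.tad_gap_length
            gl = int(np.clip(rng.exponential(g), g // 2, g * 2))
        candidates = [j for j, (s, e) in enumerate(tads)
                      if e - s >= 2 * min_len + gl]
        if not candidates:
            gl = 0
            candidates = [j for j, (s, e) in enumerate(tads)
                          if e - s >= 2 * min_len]
            if not candidates:
                break
        j = candidates[int(rng.integers(0, len(candidates)))]
        s, e = tads[j]
        cut = int(rng.integers(s + min_len, e - min_len - gl + 1))
        tads[j: j + 1] = [(s, cut), (cut + gl, e)]
    return tads


def simulate_genome_and_stages(config: SimulationConfig
                               ) -> tuple[GenomeAssembly, StageSeries, StageSeries]:
    """Genome, four-stage TAD partitions and four-stage A/B compartments.

    Stage-1 TADs cover each chromosome up to occasional unorganized gaps;
    at each later stage every internal boundary is lost with probability
    ``boundary_turnover`` (the flanking TADs merge) and a compensating
    boundary appears by splitting a random TAD, keeping the TAD count
    constant (memoryless Markov dynamics over stages).  Compartment blocks
    alternate A/B at stage 1; a ``compartment_switch_rate`` fraction of
    blocks flip their label at one or more randomly chosen stage
    transitions.
    """
    assembly = GenomeAssembly(tuple(
        (f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)
    ))
    rng = np.random.default_rng(config.seed + _STREAM["tads"])
    min_len = config.tad_mean_length // 4

    per_chrom: dict[str, list[tuple[int, int]]] = {
        c: _tile_tads(rng, config) for c in assembly.names
    }
    stage_tads: list[IntervalSet] = []
    for s in range(len(STAGE_LABELS)):
        if s > 0:
            for chrom in assembly.names:
                per_chrom[chrom] = _turnover_step(rng, per_chrom[chrom], config)
        chroms, starts, ends = [], [], []
        for chrom in assembly.names:
            for t_start, t_end in per_chrom[chrom]:
                chroms.append(chrom)
                starts.append(t_start)
                ends.append(t_end)
        stage_tads.append(IntervalSet(chroms, starts, ends))
    tads = StageSeries(stage_tads)

    rng_c = np.random.default_rng(config.seed + _STREAM["compartments"])
    block = config.compartment_block_length
    chroms, starts, ends, base_labels = [], [], [], []
    for chrom in assembly.names:
        cuts = list(range(0, config.chrom_length, block)) + [config.chrom_length]
        for k in range(len(cuts) - 1):
            if cuts[k] < cuts[k + 1]:
                chroms.append(chrom)
                starts.append(cuts[k])
                ends.append(cuts[k + 1])
                base_labels.append(k % 2)  # alternate A(1)/B(0)
    n_blocks = len(chroms)
    base = np.asarray(base_labels, dtype=np.int8)
    switcher = rng_c.random(n_blocks) < config.compartment_switch_rate
    n_transitions = len(STAGE_LABELS) - 1
    # each switching block flips at a random non-empty subset of transitions
    flips = np.zeros((n_blocks, n_transitions), dtype=bool)
    for i in np.flatnonzero(switcher):
        sub = rng_c.integers(1, 2 ** n_transitions)
        flips[i] = [(sub >> t) & 1 for t in range(n_transitions)]
    stage_comps: list[IntervalSet] = []
    state = base.copy()
    for s in range(len(STAGE_LABELS)):
        if s > 0:
            state = state ^ flips[:, s - 1].astype(np.int8)
        labels = ["A" if b else "B" for b in state]
        stage_comps.append(IntervalSet(chroms, starts, ends, names=labels))
    return assembly, tads, StageSeries(stage_comps)


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

def simulate_sites(config: SimulationConfig, assembly: GenomeAssembly,
                   boundaries: IntervalSet,
                   tads: IntervalSet | None = None) -> IntervalSet:
    """Place sites with planted density contrasts over three genome strata.

    Strata: boundary windows inside TAD territory (relative density
    ``boundary_enrichment``), unorganized gaps outside TADs (relative
    density ``gap_depletion``) and TAD interiors (density 1).  A site
    falls in stratum ``k`` with probability proportional to
    density_k x bp_share_k and is placed uniformly over valid starts
    within it.  With both factors equal to 1 placement is uniform
    genome-wide; without ``tads`` the strata reduce to boundary windows
    versus the rest of the genome and only the boundary contrast is
    planted.
    """
    if config.n_sites == 0:
        return IntervalSet.empty()
    rng = np.random.default_rng(config.seed + _STREAM["sites"])
    lengths = np.full(config.n_sites, config.site_length, dtype=np.int64)
    total = assembly.total_length

    neutral = config.boundary_enrichment == 1.0 and (
        tads is None or config.gap_depletion == 1.0)
    if neutral:
        # exactly uniform: one placement space, no stratum borders
        c, s = ShuffleSpace(assembly).place(lengths, rng)
        return IntervalSet(c, s, s + lengths)

    strata: list[tuple[float, dict]] = []  # (weight, ShuffleSpace kwargs)
    if tads is not None and len(tads):
        covered = merge_intervals(tads)
        bound_space = intersect_sets(boundaries, covered)
        gap_bp = total - covered.total_bp
        rest_kwargs = ({"within": covered, "exclude": boundaries}
                       if len(bound_space) else {"within": covered})
    else:
        covered = None
        bound_space = merge_intervals(boundaries) if len(boundaries) else boundaries
        gap_bp = 0
        rest_kwargs = {"exclude": boundaries} if len(bound_space) else {}
    bound_bp = bound_space.total_bp if len(bound_space) else 0
    rest_bp = total - bound_bp - gap_bp
    if bound_bp:
        strata.append((config.boundary_enrichment * bound_bp,
                       {"within": bound_space}))
    if gap_bp:
        strata.append((config.gap_depletion * gap_bp,
                       {"exclude": covered}))
    strata.append((float(rest_bp), rest_kwargs))

    weights = np.asarray([w for w, _ in strata])
    probs = weights / weights.sum()
    assign = rng.choice(len(strata), size=config.n_sites, p=probs)
    chroms: list[str] = [""] * config.n_sites
    starts = np.zeros(config.n_sites, dtype=np.int64)
    for k, (_, kwargs) in enumerate(strata):
        idx = np.flatnonzero(assign == k)
        if len(idx) == 0:
            continue
        space = ShuffleSpace(assembly, **kwargs)
        c, s = space.place(lengths[idx], rng)
        for j, i in enumerate(idx):
            chroms[i] = c[j]
            starts[i] = s[j]
    return IntervalSet(chroms, starts, starts + lengths)


# ---------------------------------------------------------------------------
# Tracks, repeats and TSS
# ---------------------------------------------------------------------------

def _binned_track(assembly: GenomeAssembly, bin_size: int, values_fn
                  ) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    chroms, starts, ends, values = [], [], [], []
    for chrom, length in assembly.chromosomes:
        cuts = np.arange(0, length + bin_size, bin_size)
        cuts[-1] = min(cuts[-1], length)
        cuts = np.unique(cuts)
        s, e = cuts[:-1], cuts[1:]
        chroms.extend([chrom] * len(s))
        starts.append(s)
        ends.append(e)
        values.append(values_fn(chrom, s, e))
    return (chroms, np.concatenate(starts), np.concatenate(ends),
            np.concatenate(values))


def _add_over_sites(chroms, starts, ends, values, sites: IntervalSet,
                    amount: float, cap: float | None = None) -> None:
    """Add ``amount`` to every bin overlapping a site (in place)."""
    merged = merge_intervals(sites).by_chrom()
    chrom_arr = np.asarray(chroms, dtype=object)
    for chrom, (ss, se) in merged.items():
        idx = np.flatnonzero(chrom_arr == chrom)
        if len(idx) == 0:
            continue
        bs, be = starts[idx], ends[idx]
        k = np.searchsorted(se, bs, side="right")
        hit = (k < len(ss)) & (ss[np.minimum(k, len(ss) - 1)] < be)
        values[idx[hit]] += amount
    if cap is not None:
        np.minimum(values, cap, out=values)


def simulate_tracks_and_annotations(
    config: SimulationConfig, assembly: GenomeAssembly,
    sites: IntervalSet, boundaries: IntervalSet,
) -> tuple[SignalTrack, SignalTrack, IntervalSet, IntervalSet]:
    """CTCF-like signal, conservation track, repeat annotation and TSS points.

    The signal track is exponential(mean 1) noise with a peak of
    ``signal_peak_height`` added over a ``signal_site_fraction`` random
    subset of sites.  The conservation track is clipped-normal noise with
    mean ``cons_base_mean``, uplifted by ``cons_boundary_shift`` over
    boundary-overlapping sites.  Repeats of each class are placed so their
    probability of overlapping a site is scaled by the class factor
    (LTR/SINE enriched, LINE/DNA depleted by default).
    """
    rng_sig = np.random.default_rng(config.seed + _STREAM["ctcf"])
    chroms, starts, ends, values = _binned_track(
        assembly, config.signal_bin,
        lambda c, s, e: rng_sig.exponential(1.0, len(s)))
    n_peak = int(round(config.signal_site_fraction * len(sites)))
    if n_peak and config.signal_peak_height != 0:
        chosen = rng_sig.choice(len(sites), size=n_peak, replace=False)
        _add_over_sites(chroms, starts, ends, values, sites.take(np.sort(chosen)),
                        config.signal_peak_height)
    ctcf = SignalTrack.from_arrays(chroms, starts, ends, values)

    rng_cons = np.random.default_rng(config.seed + _STREAM["cons"])
    c2, s2, e2, v2 = _binned_track(
        assembly, config.cons_bin,
        lambda c, s, e: np.clip(
            rng_cons.normal(config.cons_base_mean, config.cons_sd, len(s)), 0.0, 1.0))
    if config.cons_boundary_shift != 0 and len(sites):
        at_boundary = sites.subset_mask(overlaps_any(sites, boundaries))
        if len(at_boundary):
            _add_over_sites(c2, s2, e2, v2, at_boundary,
                            config.cons_boundary_shift, cap=1.0)
    cons = SignalTrack.from_arrays(c2, s2, e2, v2)

    rng_rep = np.random.default_rng(config.seed + _STREAM["repeats"])
    rep_chroms, rep_starts, rep_ends, rep_names = [], [], [], []
    for cls in REPEAT_CLASSES:
        density = config.repeat_density.get(cls, 0.0)
        rep_len = int(config.repeat_length.get(cls, 300))
        factor = config.repeat_site_factor.get(cls, 1.0)
        n_rep = int(round(density * assembly.total_length / rep_len))
        if n_rep == 0:
            continue
        # the site-overlap probability of a uniformly placed repeat is the
        # share of start positions within rep_len-1 of a site; scaling that
        # share by the class factor makes factor = 1 exactly neutral
        if len(sites):
            windows = merge_intervals(IntervalSet(
                sites.chroms,
                np.maximum(sites.starts - rep_len + 1, 0),
                sites.ends))
            w = windows.total_bp / assembly.total_length
        else:
            w = 0.0
        p_in = factor * w / (factor * w + (1.0 - w)) if w > 0 else 0.0
        hits = rng_rep.random(n_rep) < p_in
        # overlapping repeats: anchored to a random site with a uniform
        # offset over the start positions that touch it
        for _ in range(int(hits.sum())):
            i = int(rng_rep.integers(0, len(sites)))
            lo = max(int(sites.starts[i]) - rep_len + 1, 0)
            hi = min(int(sites.ends[i]) - 1,
                     assembly.length_of(sites.chroms[i]) - rep_len)
            start = int(rng_rep.integers(lo, max(hi, lo) + 1))
            rep_chroms.append(sites.chroms[i])
            rep_starts.append(start)
            rep_ends.append(start + rep_len)
            rep_names.append(cls)
        # non-overlapping repeats avoid the overlap windows entirely
        n_out = int((~hits).sum())
        if n_out:
            space = (ShuffleSpace(assembly, exclude=windows) if w > 0
                     else ShuffleSpace(assembly))
            c, s = space.place(np.full(n_out, rep_len, dtype=np.int64), rng_rep)
            rep_chroms.extend(c)
            rep_starts.extend(int(x) for x in s)
            rep_ends.extend(int(x) + rep_len for x in s)
            rep_names.extend([cls] * n_out)
    repeats = (IntervalSet(rep_chroms, rep_starts, rep_ends, names=rep_names)
               if rep_chroms else IntervalSet.empty())

    rng_tss = np.random.default_rng(config.seed + _STREAM["tss"])
    t_chroms, t_pos, t_names = [], [], []
    gene_i = 0
    for chrom, length in assembly.chromosomes:
        for anchor in range(config.tss_spacing // 2, length, config.tss_spacing):
            jitter = int(rng_tss.integers(-config.tss_spacing // 4,
                                          config.tss_spacing // 4 + 1))
            pos = int(np.clip(anchor + jitter, 0, length - 1))
            t_chroms.append(chrom)
            t_pos.append(pos)
            t_names.append(f"GENE{gene_i:05d}")
            gene_i += 1
    tss = IntervalSet(t_chroms, np.asarray(t_pos),
                      np.asarray(t_pos) + 1, names=t_names)
    return ctcf, cons, repeats, tss


# ---------------------------------------------------------------------------
# Bundle assembly and on-disk layout
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig) -> Bundle:
    """Generate the full input bundle in memory.

    Site placement, signal peaks, conservation uplift and repeat
    enrichment are all planted relative to the CP-stage boundary windows,
    matching the stage the downstream profiling analyses.
    """
    assembly, tads, comps = simulate_genome_and_stages(config)
    cp_idx = list(STAGE_LABELS).index("CP")
    cp_boundaries = tad_boundaries(tads.per_stage[cp_idx],
                                   config.boundary_flank, assembly)
    sites = simulate_sites(config, assembly, cp_boundaries,
                           tads=tads.per_stage[cp_idx])
    ctcf, cons, repeats, tss = simulate_tracks_and_annotations(
        config, assembly, sites, cp_boundaries)
    return Bundle(config=config, assembly=assembly, tads=tads,
                  compartments=comps, sites=sites, ctcf=ctcf, cons=cons,
                  repeats=repeats, tss=tss)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_bundle(bundle: Bundle, outdir) -> dict:
    """Write the bundle to a directory; returns the manifest dict.

    Layout: genome.chrom.sizes, tads_{es,mes,cp,cm}.bed,
    compartments_{stage}.bed (BED4 with A/B), sites.bed, ctcf.bedgraph,
    cons.bedgraph, repeats.bed (BED4, name = class), tss.bed and
    manifest.json with the config echo and per-file sha256 checksums.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    p = outdir / "genome.chrom.sizes"
    with open(p, "w") as fh:
        for name, length in bundle.assembly.chromosomes:
            fh.write(f"{name}\t{length}\n")
    files["genome"] = p

    for s, label in enumerate(STAGE_LABELS):
        p = outdir / f"tads_{label.lower()}.bed"
        write_bed(bundle.tads.per_stage[s], p)
        files[f"tads_{label.lower()}"] = p
        p = outdir / f"compartments_{label.lower()}.bed"
        write_bed(bundle.compartments.per_stage[s], p)
        files[f"compartments_{label.lower()}"] = p

    for key, obj in (("sites", bundle.sites), ("repeats", bundle.repeats),
                     ("tss", bundle.tss)):
        p = outdir / f"{key}.bed"
        write_bed(obj, p)
        files[key] = p
    for key, track in (("ctcf", bundle.ctcf), ("cons", bundle.cons)):
        p = outdir / f"{key}.bedgraph"
        write_bedgraph(track, p)
        files[key] = p

    manifest = {
        "config": bundle.config.to_dict(),
        "files": {k: v.name for k, v in files.items()},
        "checksums": {k: _sha256(v) for k, v in files.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
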