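# Methods

This note records the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Coverage-enrichment test

The statistic is the base-pair overlap between the union of the sites and
the union of the region set.  The null model repositions each site
independently and uniformly over the genome's valid start positions,
preserving the multiset of site lengths; chromosomes (and, when an
exclusion or restriction set is given, allowed spans) are selected with
probability proportional to their number of valid starts, which makes the
placement exactly uniform over placements rather than uniform over
chromosomes.  Shuffled sites may overlap one another by default — the
observed and null draws are then exchangeable whenever the observed sites
come from the same placement process, which is what makes the test's
type-I rate nominal in the calibration runs; a `non_overlapping` option
switches to rejection sampling for users whose observed intervals are
guaranteed disjoint.

Both a fitted-normal p-value (sample mean and n−1 sd of the null
coverages, one-sided upper tail by default) and the rank-based empirical
p-value `(1 + #{null ≥ obs})/(n + 1)` are always reported.  The normal fit
is the headline number and extrapolates beyond the resolution of the
shuffle count; the empirical value is bounded below by `1/(n + 1)` and is
authoritative whenever the null is degenerate (sd = 0, e.g. regions
covering the whole genome), in which case the normal-fit p is reported as
1.0 (obs = mean) or 0.0 with a degenerate flag.  Default `n_shuffles` is
1000; replicate *r* always uses seed + *r*.

## Positional profile and KS test

Each TAD is partitioned into `n_bins = 10` contiguous bins; the remainder
of the integer division goes one base each to the first `length mod 10`
bins so the bins tile the TAD exactly.  TADs shorter than `n_bins` are
skipped and counted.  Occupancy is per-base (fraction of bin length
covered by the merged sites), not per-midpoint, so bin size differences
across TADs do not bias the profile; the mean and SEM are taken across
TADs per bin index.  The profile is reported left-to-right (unfolded) by
default because the folded and unfolded versions are equivalent in
expectation for a symmetric preference; `fold=True` averages mirror bins
onto a distance-from-nearer-boundary axis.

The randomized control repositions only the boundary-overlapping sites,
uniformly into the TAD interiors (TADs minus boundary windows); interior
sites keep their positions.  The per-site KS statistic uses the site
midpoint's relative position within its host TAD folded to [0, 0.5]; TADs
are used as called (not merged), since adjacent TADs sharing an edge must
keep separate identities for the fold to be meaningful.  The two-sample
KS test uses the exact p-value when either sample has fewer than 25
values, the asymptotic one otherwise.  Note the control is *not*
exchangeable with uniform sites (it excludes boundary windows by
construction); the KS calibration property is therefore stated for two
samples from the same distribution, which is the test's actual null.

## Dynamic-event classification

Stage states are binary: boundary state is ≥1 bp overlap with that
stage's boundary windows (boundaries are narrow targets), compartment
state is the A/B label at the site midpoint (compartments are broad
partitions; a site whose midpoint is unannotated at any stage is dropped
and counted).  The 2⁴ − 2 = 14 non-constant tuples are the dynamic
categories; the two constant tuples pool into a static bin that is
reported but excluded from the chi-square by default (`include_static`
reverses this).  Expected counts are the mean over `n_randomizations`
(default 100) uniform repositionings, rescaled to the observed total;
bins with expected < 5 are pooled into one rare bin before the test
(classical validity rule) and the pre-pooling table is always emitted.
The chi-square arithmetic matches `scipy.stats.chisquare` to 1e-10 on
fixed count vectors.

## Site profiling

Signal aggregation is mean-per-bp over the site extent with no flanking
window by default (`flank_bp` extends sites symmetrically); bases not
covered by any bedGraph segment contribute 0 to the numerator but count
in the denominator.  Repeat occupancy is overlap bp divided by site
length, per class (LTR, SINE, LINE, DNA).  Groups are {all, at-boundary,
non-boundary, random-control}, giving six pairwise Welch t-tests
(unequal-variance; robust default where the test family was unspecified).
No multiple-testing correction is applied; all six raw p-values are
emitted for downstream correction.  Note the "all" group shares members
with its two subsets, so those three pairs are not independent samples;
the independent contrasts are at-boundary vs non-boundary and each group
vs the control.  Nearest-TSS assignment minimizes the distance from the
site span to the TSS point (0 inside the site, signed outside), breaking
ties toward the smaller coordinate and then the lexicographically smaller
gene name; the gene table is written as TSV for external GO tools.

## Synthetic-data generator

The generator's defaults are the study conditions the pipeline is
validated under: 2 chromosomes × 10 Mb; TAD lengths exponential with mean
800 kb truncated to [200 kb, 3.2 Mb]; an unorganized gap (exponential,
mean 200 kb, truncated to [100 kb, 400 kb]) between adjacent TADs, so
TADs cover roughly 80% of the genome as real TAD calls do; boundary
windows of ±40 kb; four stages with per-transition boundary turnover 0.2
implemented as merge-adjacent-TADs / split-a-random-TAD (splits re-insert
gaps at the stage-1 rate so the TAD-covered share is stationary across
stages — without this, merges monotonically absorb gaps and the planted
TAD-level signal drifts away); 500 kb compartment blocks alternating A/B
with 30% of blocks switching label at one or more random transitions
(the switch rate is the fraction of ever-switching blocks, so the planted
rate is directly the recoverable dynamic fraction); 1000 sites of 1 kb.

Sites are placed over three strata — boundary windows within TAD
territory (relative density `boundary_enrichment = 10`), gaps outside
TADs (relative density `gap_depletion = 0.1`), TAD interiors (density 1)
— with stratum probability proportional to density × bp share and uniform
placement within the stratum.  Planting boundary sites in the in-TAD part
of boundary windows matches the geometry of real data, where
boundary-proximal sites lie at TAD edges; the gap depletion emulates the
scarcity of mapped sites in unorganized/unmappable regions and is what
makes TAD-level enrichment a planted signal distinct from the boundary
signal.  A fully neutral configuration (both factors 1) short-circuits to
a single uniform placement space, because the stratified scheme's
no-straddling constraint is measurably non-uniform for fine-grained
statistics (it made the null chi-square conservative).

Tracks: the ChIP-like track is exponential(mean 1) noise in 1 kb bins
with a peak of height 10 added over a random 50% of sites; the
conservation-like track is normal(0.4, 0.1) clipped to [0, 1] in 500 bp
bins, uplifted by 0.2 (capped at 1) over boundary-overlapping sites — so
the planted group contrast is 0.6 vs 0.4 with sd 0.1.  Repeats per class
are placed so that a repeat's probability of overlapping a site equals
the uniform-placement probability scaled by the class factor (LTR/SINE
5×, LINE/DNA 0.2×; factor 1 is exactly neutral); overlapping repeats are
anchored to a uniformly chosen site, the rest are placed outside the
overlap windows.  TSS points sit every ~100 kb with ±25 kb jitter.

All randomness flows from one seed through fixed per-component offsets
(tads +1, compartments +2, sites +3, ctcf +4, cons +5, repeats +6,
tss +7), so components are independently reproducible and bundle files
are byte-identical across runs.

What the generator does **not** emulate: sequence content (no FASTA, so
no GC or mappability structure), distance-dependent Hi-C contact
structure, correlated placement of CTCF peaks at boundaries independent
of sites, nested/overlapping TAD hierarchies, chromosome-specific
biology, or clustering of sites beyond the boundary/gap strata.  Passing
tests therefore demonstrate that the statistics recover planted effects
of realistic magnitude under an idealized placement model — not that
real-data confounders (GC-matched nulls, assembly gaps) are handled;
for real data the `exclude` option should carry assembly gaps.

## Numerical and degenerate-input choices

* Coordinates 0-based half-open throughout; intervals past a chromosome
  end are input errors, never clipped silently (boundary windows are the
  one construct that is clipped, by definition).
* Merging coalesces touching intervals (end == next start).
* A site longer than every allowed span raises a placement error naming
  the length; `within_tad_randomization` inherits this.
* Identical constant value samples in a t-test report t = 0, p = 1
  (no evidence of difference) instead of scipy's NaN; groups with n < 2
  are marked untestable rather than dropped.
* Degenerate chi-square tables (no dynamic site observed or expected, or
  fewer than two bins after pooling) report chi2 = 0, p = 1 with a flag.
* bedGraph floats are written with `.17g` so tracks round-trip exactly
  through the text format.

## Problem sizes used in validation

The test suite and acceptance script run the default bundle (20 Mb, 1000
sites) for power checks, 300-site bundles for the 100-replicate
calibration loops, 200 shuffles per enrichment test (the extreme planted
signals do not need the full 1000), and 30–50 randomizations per
chi-square.  These sizes give the calibration bands quoted in the tests
while keeping any single test file in the seconds range.
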