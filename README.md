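# triplextad

Statistical toolkit linking a set of genomic intervals — typically the
RNA–DNA triplex-forming sites of a lncRNA mapped by DBD-Capture-Seq — to
features of 3D genome organization: topologically associating domains
(TADs), their boundaries, and A/B compartments called at four ordered
stages of cardiac differentiation (ES, MES, CP, CM).

It is aimed at regulatory-genomics analysts who have interval calls in BED
form (sites, per-stage TADs, compartment labels, repeats, TSS) plus signal
tracks in bedGraph form (ChIP signal, phastCons conservation) and want
reproducible, seeded answers to:

* Are the sites **enriched** in TADs or TAD boundaries beyond chance?
* Do sites **prefer boundary-proximal positions** within TADs?
* Do sites sit in regions with **dynamic boundary gain/loss** or
  **A/B compartment switching** across stages?
* Are sites distinguished by **CTCF signal, repeat-class occupancy
  (LTR/SINE/LINE/DNA), or conservation**, split by boundary association?

## The statistics

**Shuffle-null coverage enrichment.** For sites *S* and regions *R*, the
observed statistic is the base-pair overlap `|union(S) ∩ union(R)|`.  The
null repositions every site uniformly at random in the genome (lengths
preserved), `n` times (default 1000).  A normal distribution N(μ̂, σ̂²) is
fitted to the null coverages; the headline p-value is the upper-tail
survival at z = (obs − μ̂)/σ̂, and the rank-based empirical p-value
`(1 + #{null ≥ obs})/(n + 1)` is reported alongside.

**Positional preference.** Each TAD is divided into 10 contiguous bins of
equal length; per bin index, the fraction of bin length occupied by sites
is averaged over TADs (± SEM).  Boundary-overlapping sites are then
repositioned strictly into TAD interiors, and a two-sample
Kolmogorov–Smirnov test compares the folded boundary-distance values
(site midpoint position within its TAD, folded to [0, 0.5]) of observed
versus randomized sites.

**Dynamic-event classification.** A site's state at each stage is binary
(overlaps that stage's boundary set, or lies in compartment A at its
midpoint).  The 2⁴ − 2 = 14 non-constant state tuples are the dynamic
categories; constant tuples pool into a static bin.  Observed category
counts are compared to the mean counts of uniformly repositioned control
sites with a chi-square test (expected rescaled to the observed total,
low-expectation bins pooled).

**Site profiling.** Per-site mean signal per bp, per-class repeat
occupancy fraction, and mean conservation per bp are computed over
{all, at-boundary, non-boundary, random-control} site groups and compared
with Welch t-tests over all six group pairs; nearest-TSS assignment maps
each site to its closest gene.

A seeded synthetic-data generator (`triplextad.simulate`) produces a full
input bundle with planted, parameterized versions of every one of these
signals, so the whole pipeline is verifiable end-to-end without any
external downloads.

## Worked example

Simulate the default bundle (2 × 10 Mb chromosomes, four TAD stages with
20% boundary turnover per transition, 1000 sites of 1 kb planted with
10× density at CP-stage boundaries) and run the full analysis:

```bash
triplextad simulate --seed 7 --out bundle/
triplextad run-all --bundle bundle/ --out results/ --seed 7 --n-shuffles 1000
triplextad report --report results/report.json
```

prints

```
triplextad report (version 0.1.0)
  enrichment[tads]: observed=914173 bp, null=780067.0±12551.8, z=10.68, p=6.04e-27 (empirical 0.000999)
  enrichment[boundaries]: observed=506995 bp, null=173372.0±11752.8, z=28.39, p=1.48e-177 (empirical 0.000999)
  positional: KS D=0.4281 p=1.03e-82 over 23 TADs
  boundary_dynamics: chi2=158.76 df=7 p=5.85e-31
  compartment_switching: chi2=48.93 df=9 p=1.71e-07
```

Reading this: the 1000 sites cover 507.0 kb of boundary windows where
random placement covers 173.4 ± 11.8 kb, a 28σ excess (the planted 10×
boundary enrichment); TAD coverage is likewise enriched (sites avoid
unorganized inter-TAD regions); the KS statistic D = 0.43 shows the strong
boundary-proximal positional skew; and both dynamic-event classifications
differ from the uniform control because boundary-planted sites
preferentially occupy regions whose boundary status changes across stages.
`results/` also holds TSV tables (bin profile, category counts, per-site
values, pairwise t-tests, target genes) and the diffable `report.json`.

Every stage is also exposed as its own subcommand (`enrich`, `tadbins`,
`dynamics`, `profile`) over plain BED/bedGraph/chrom.sizes inputs, and as
library functions (`triplextad.permutation_coverage_enrichment`, …).

## Conventions

* Coordinates are 0-based, half-open (BED) everywhere, including reports.
* Boundary windows are `edge ± flank` with `flank = 40000` bp by default
  (a typical Hi-C bin scale); the flank is a visible parameter in every
  command and is echoed into reports.
* A single integer seed controls each command; shuffle replicate *r* uses
  `seed + r`, so any replicate is independently reproducible.
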