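"""Orchestration of the full analysis over an on-disk input bundle.

``run_all`` loads a bundle directory (as written by the simulator, or
assembled from real BED/bedGraph files with the same layout), runs every
stage — coverage enrichment in TADs and in boundaries, the 10-bin
positional profile with its KS test, boundary-dynamics and
compartment-switch chi-square classification, and signal/repeat/
conservation profiling with pairwise t-tests plus nearest-TSS targets —
and writes a machine-readable JSON report together with TSV tables.
Timestamps and hostnames are kept out of the report body so reports are
byte-diffable across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    IntervalSet,
    overlaps_any,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    tad_boundaries,
)
from .dynamics import STAGE_LABELS, StageSeries, category_chi_square
from .enrichment import permutation_coverage_enrichment
from .positional import bin_occupancy, positional_ks_test, within_tad_randomization
from .profiles import (
    aggregate_signal,
    build_site_grouping,
    conservation_per_bp,
    group_and_compare,
    nearest_tss_targets,
    repeat_occupancy,
    split_repeats_by_class,
)

log = logging.getLogger("triplextad")

DEFAULTS = {
    "n_shuffles": 1000,
    "n_randomizations": 100,
    "boundary_flank": 40_000,
    "n_bins": 10,
    "analysis_stage": "CP",
    "seed": 0,
    "fold_bins": False,
    "include_static": False,
    "non_overlapping_shuffle": False,
}


def load_bundle_dir(bundle_dir) -> dict:
    """Read a bundle directory into in-memory objects."""
    d = Path(bundle_dir)
    assembly = read_chrom_sizes(d / "genome.chrom.sizes")
    tads = StageSeries([
        read_bed(d / f"tads_{s.lower()}.bed", assembly) for s in STAGE_LABELS
    ])
    comp_files = [d / f"compartments_{s.lower()}.bed" for s in STAGE_LABELS]
    comps = (StageSeries([read_bed(p, assembly) for p in comp_files])
             if all(p.exists() for p in comp_files) else None)
    out = {
        "assembly": assembly,
        "tads": tads,
        "compartments": comps,
        "sites": read_bed(d / "sites.bed", assembly),
        "ctcf": read_bedgraph(d / "ctcf.bedgraph", assembly) if (d / "ctcf.bedgraph").exists() else None,
        "cons": read_bedgraph(d / "cons.bedgraph", assembly) if (d / "cons.bedgraph").exists() else None,
        "repeats": read_bed(d / "repeats.bed", assembly) if (d / "repeats.bed").exists() else None,
        "tss": read_bed(d / "tss.bed", assembly) if (d / "tss.bed").exists() else None,
    }
    return out


def _checksum_inputs(bundle_dir) -> dict[str, str]:
    out = {}
    for p in sorted(Path(bundle_dir).glob("*")):
        if p.is_file() and p.name != "manifest.json":
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def _enrichment_block(res) -> dict:
    return res.to_dict(include_null=False)


def _pairs_frame(comparison) -> pd.DataFrame:
    return pd.DataFrame([{
        "group1": p.group1, "group2": p.group2,
        "n1": p.n1, "n2": p.n2, "mean1": p.mean1, "mean2": p.mean2,
        "t_statistic": p.t_statistic, "p_value": p.p_value,
        "testable": p.testable,
    } for p in comparison.pairs])


def run_all(bundle_dir, outdir, **overrides) -> dict:
    """Run every analysis stage on a bundle; returns the report dict.

    Keyword overrides replace entries of ``DEFAULTS`` (n_shuffles,
    n_randomizations, boundary_flank, n_bins, analysis_stage, seed,
    fold_bins, include_static).
    """
    params = {**DEFAULTS, **overrides}
    unknown = set(overrides) - set(DEFAULTS)
    if unknown:
        raise ValueError(f"unknown parameters: {sorted(unknown)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(params["seed"])
    flank = int(params["boundary_flank"])
    stage = params["analysis_stage"]
    stage_idx = list(STAGE_LABELS).index(stage)

    log.info("loading bundle from %s", bundle_dir)
    data = load_bundle_dir(bundle_dir)
    assembly = data["assembly"]
    sites = data["sites"]
    tads_stage = data["tads"].per_stage[stage_idx]
    boundaries = tad_boundaries(tads_stage, flank, assembly)
    log.info("stage %s: %d TADs, %d boundary windows, %d sites; flank=%d",
             stage, len(tads_stage), len(boundaries), len(sites), flank)

    report: dict = {
        "version": __version__,
        "parameters": params,
        "input_checksums": _checksum_inputs(bundle_dir),
        "stages": {},
    }

    # 1. coverage enrichment in TADs and in boundary windows
    n_shuffles = int(params["n_shuffles"])
    log.info("enrichment: n_shuffles=%d seed=%d", n_shuffles, seed)
    enr_tads = permutation_coverage_enrichment(
        sites, tads_stage, assembly, n_shuffles=n_shuffles, rng_seed=seed)
    enr_bounds = permutation_coverage_enrichment(
        sites, boundaries, assembly, n_shuffles=n_shuffles, rng_seed=seed)
    report["stages"]["enrichment"] = {
        "tads": _enrichment_block(enr_tads),
        "boundaries": _enrichment_block(enr_bounds),
    }

    # 2. positional profile and KS against within-TAD randomized control
    n_bins = int(params["n_bins"])
    fold = bool(params["fold_bins"])
    profile_obs = bin_occupancy(sites, tads_stage, n_bins, fold=fold)
    randomized = within_tad_randomization(sites, tads_stage, boundaries,
                                          seed, assembly)
    profile_rnd = bin_occupancy(randomized, tads_stage, n_bins, fold=fold)
    ks_d, ks_p, ks_info = positional_ks_test(sites, randomized, tads_stage, n_bins)
    pd.DataFrame({
        "bin": np.arange(1, profile_obs.n_bins + 1),
        "mean_fraction": profile_obs.mean_fraction,
        "sem": profile_obs.sem,
        "random_mean_fraction": profile_rnd.mean_fraction,
        "random_sem": profile_rnd.sem,
    }).to_csv(outdir / "tad_bin_profile.tsv", sep="\t", index=False)
    report["stages"]["positional"] = {
        "n_bins": profile_obs.n_bins,
        "n_tads": profile_obs.n_tads,
        "n_tads_skipped": profile_obs.n_skipped,
        "mean_fraction": profile_obs.mean_fraction.tolist(),
        "sem": profile_obs.sem.tolist(),
        "random_mean_fraction": profile_rnd.mean_fraction.tolist(),
        "random_sem": profile_rnd.sem.tolist(),
        "ks_D": ks_d,
        "ks_p_value": ks_p,
        **ks_info,
    }

    # 3. dynamic-event classification (boundary gain/loss; A/B switching)
    n_rand = int(params["n_randomizations"])
    include_static = bool(params["include_static"])
    bound_series = StageSeries([
        tad_boundaries(t, flank, assembly) for t in data["tads"].per_stage])
    cc_bound = category_chi_square(
        sites, bound_series, assembly, n_randomizations=n_rand,
        rng_seed=seed, mode="boundary", include_static=include_static)
    blocks = {"boundary_dynamics": cc_bound}
    if data["compartments"] is not None:
        cc_comp = category_chi_square(
            sites, data["compartments"], assembly, n_randomizations=n_rand,
            rng_seed=seed, mode="compartment", include_static=include_static)
        blocks["compartment_switching"] = cc_comp
    for key, cc in blocks.items():
        pd.DataFrame({
            "pattern": cc.patterns,
            "observed": cc.observed,
            "expected": cc.expected,
        }).to_csv(outdir / f"{key}_counts.tsv", sep="\t", index=False)
        report["stages"][key] = {
            "chi2": cc.chi2, "df": cc.df, "p_value": cc.p_value,
            "n_dynamic_observed": cc.n_dynamic_observed,
            "n_static_observed": cc.n_static_observed,
            "n_dropped": cc.n_dropped,
            "degenerate": cc.degenerate,
            "pooled_patterns": cc.pooled_patterns,
            "observed": cc.observed.tolist(),
            "expected": cc.expected.tolist(),
            "patterns": cc.patterns,
        }

    # 4. per-site profiling against tracks and repeats, grouped t-tests
    grouping = build_site_grouping(sites, boundaries, assembly, seed)
    per_site = pd.DataFrame({
        "chrom": sites.chroms,
        "start": sites.starts,
        "end": sites.ends,
        "at_boundary": overlaps_any(sites, boundaries),
    })

    profile_block = {}
    if data["ctcf"] is not None:
        vals = aggregate_signal(sites, data["ctcf"])
        comp = group_and_compare(
            sites, boundaries, assembly, vals, seed, grouping=grouping,
            value_fn=lambda s: aggregate_signal(s, data["ctcf"]))
        _pairs_frame(comp).to_csv(outdir / "ctcf_signal_tests.tsv",
                                  sep="\t", index=False)
        per_site["ctcf_mean"] = vals
        profile_block["ctcf_signal"] = _pairs_frame(comp).to_dict("records")
    if data["cons"] is not None:
        vals = conservation_per_bp(sites, data["cons"])
        comp = group_and_compare(
            sites, boundaries, assembly, vals, seed, grouping=grouping,
            value_fn=lambda s: conservation_per_bp(s, data["cons"]))
        _pairs_frame(comp).to_csv(outdir / "conservation_tests.tsv",
                                  sep="\t", index=False)
        per_site["cons_mean"] = vals
        profile_block["conservation"] = _pairs_frame(comp).to_dict("records")
    if data["repeats"] is not None:
        by_class = split_repeats_by_class(data["repeats"])
        occ = repeat_occupancy(sites, by_class)
        rep_block = {}
        for cls, vals in occ.items():
            comp = group_and_compare(
                sites, boundaries, assembly, vals, seed, grouping=grouping,
                value_fn=lambda s, c=cls: repeat_occupancy(s, {c: by_class[c]})[c])
            _pairs_frame(comp).to_csv(
                outdir / f"repeat_{cls}_tests.tsv", sep="\t", index=False)
            per_site[f"repeat_{cls}_fraction"] = vals
            rep_block[cls] = _pairs_frame(comp).to_dict("records")
        profile_block["repeats"] = rep_block
    if data["tss"] is not None:
        targets = nearest_tss_targets(sites, data["tss"])
        tgt = pd.DataFrame({
            "chrom": sites.chroms,
            "start": sites.starts,
            "end": sites.ends,
            "gene": [g for g, _ in targets],
            "distance": [d for _, d in targets],
        })
        tgt.to_csv(outdir / "target_genes.tsv", sep="\t", index=False)
        profile_block["n_target_genes"] = int(
            tgt["gene"].dropna().nunique())
    report["stages"]["profiles"] = profile_block
    per_site.to_csv(outdir / "per_site_values.tsv", sep="\t", index=False)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    log.info("report written to %s", outdir / "report.json")
    return report
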