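"""End-to-end orchestration: from a directory of per-island inputs to the
island x metrics table and the statistical layer.

Expected directory layout (what :func:`isledv.simulate.build_archipelago`
writes, and what a real study would be arranged into):

    islands.csv            sample,island,area_km2,group
    <sample>.vcf           all-sites VCF, one individual
    <sample>.final.txt     MSMC2 scaled trajectory
    melt.vcf               combined MELT-style ERV calls, one column/sample
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import demography, diversity_metrics, erv, roh, stats
from .genotype_io import FilterConfig, FilterStats


@dataclass
class PipelineConfig:
    filters: FilterConfig = field(default_factory=FilterConfig)
    window_bp: int = diversity_metrics.DEFAULT_WINDOW_BP
    min_genotyped_fraction: float = 0.8
    erv_filters: erv.ERVFilterConfig = field(default_factory=erv.ERVFilterConfig)
    scaling: demography.ScalingParams = field(default_factory=demography.ScalingParams)
    horizon_years: float = 200_000.0
    skip_first_epoch: bool = False


@dataclass
class PipelineResult:
    table: pd.DataFrame
    regressions: Dict[str, stats.RegressionFit]
    correlations: pd.DataFrame
    lasso: Optional[stats.LassoFit]
    filter_stats: Dict[str, FilterStats]


def _chrom_lengths_from_vcf(path: str) -> Dict[str, int]:
    from cyvcf2 import VCF

    v = VCF(path)
    return dict(zip(v.seqnames, v.seqlens))


def run_pipeline(
    sim_dir: str,
    cfg: PipelineConfig = PipelineConfig(),
    responses: Sequence[str] = ("genome_het", "het_sd", "recent_ne", "harmonic_ne", "roh_total_bp", "erv_hom_nonref"),
    run_lasso: bool = True,
) -> PipelineResult:
    """Run every stage on a study directory and fit the statistics layer."""
    meta = pd.read_csv(os.path.join(sim_dir, "islands.csv"))
    islands = [
        stats.IslandRecord(r["sample"], r["island"], float(r["area_km2"]), str(r.get("group", "")))
        for _, r in meta.iterrows()
    ]

    het_summaries: Dict[str, diversity_metrics.HetSummary] = {}
    roh_summaries: Dict[str, roh.ROHSummary] = {}
    ne_summaries: Dict[str, demography.NeSummary] = {}
    filter_stats: Dict[str, FilterStats] = {}
    for rec in islands:
        vcf_path = os.path.join(sim_dir, f"{rec.sample}.vcf")
        fstats = FilterStats()
        windows = diversity_metrics.tally_vcf(
            vcf_path,
            _chrom_lengths_from_vcf(vcf_path),
            cfg.filters,
            cfg.window_bp,
            stats=fstats,
        )
        filter_stats[rec.sample] = fstats
        het_summaries[rec.sample] = diversity_metrics.summarize_heterozygosity(
            windows, rec.sample, cfg.min_genotyped_fraction
        )
        calls = roh.call_roh_windows(windows, cfg.min_genotyped_fraction)
        segments = roh.merge_segments(calls)
        roh_summaries[rec.sample] = roh.summarize_roh(
            segments, het_summaries[rec.sample].n_genotyped, rec.sample, cfg.window_bp
        )
        msmc_path = os.path.join(sim_dir, f"{rec.sample}.final.txt")
        if os.path.exists(msmc_path):
            traj = demography.unscale(demography.read_msmc(msmc_path), cfg.scaling)
            ne_summaries[rec.sample] = demography.summarize_ne(
                traj, rec.sample, cfg.horizon_years, cfg.skip_first_epoch
            )

    erv_summaries: Dict[str, erv.ERVSummary] = {}
    melt_path = os.path.join(sim_dir, "melt.vcf")
    if os.path.exists(melt_path):
        calls, samples = erv.read_erv_vcf(melt_path)
        calls = erv.resolve_overlaps(calls, cfg.erv_filters.overlap_radius)
        calls = erv.filter_calls(calls, cfg.erv_filters)
        for rec in islands:
            if rec.sample in samples:
                erv_summaries[rec.sample] = erv.count_hom_nonref(calls, rec.sample, samples)

    table = stats.assemble_table(islands, het_summaries, roh_summaries, erv_summaries, ne_summaries)
    regressions: Dict[str, stats.RegressionFit] = {}
    for response in responses:
        if response in table.columns and table[response].notna().sum() >= 3:
            fit, _ = stats.simple_regression(table, response)
            regressions[response] = fit
    corr, _undef = stats.correlation_matrix(table)
    lasso_fit = None
    if run_lasso:
        try:
            lasso_fit = stats.lasso_select(table, response="log10_area")
        except ValueError:
            lasso_fit = None
    return PipelineResult(table, regressions, corr, lasso_fit, filter_stats)
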