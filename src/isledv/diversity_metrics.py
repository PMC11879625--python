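"""Per-individual heterozygosity: genome-wide, per-window, and its variability.

Observed heterozygosity is the fraction of an individual's genotyped sites
(variant and invariant) that are heterozygous; under neutrality it estimates
theta = 4*Ne*mu.  The genome is tiled into fixed-width windows (default
25 kbp) both to feed the ROH caller and to measure how variable
heterozygosity is along the genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .genotype_io import (
    FilterConfig,
    FilterStats,
    Genotype,
    GenotypeSite,
    _CY_HET,
    _CY_UNKNOWN,
)

DEFAULT_WINDOW_BP = 25_000


@dataclass
class GenomeWindow:
    """A fixed-width genomic interval (0-based half-open) with per-sample
    genotyped/heterozygous site counts for one individual."""

    chrom: str
    start: int
    end: int
    width: int  # nominal tiling width; end - start < width flags a partial window
    n_genotyped: int = 0
    n_het: int = 0

    @property
    def is_partial(self) -> bool:
        return self.end - self.start < self.width

    @property
    def het(self) -> Optional[float]:
        if self.n_genotyped == 0:
            return None
        return self.n_het / self.n_genotyped


@dataclass
class HetSummary:
    sample: str
    genome_het: float
    het_sd: Optional[float]
    het_cv: Optional[float]
    n_windows_used: int
    n_genotyped: int
    n_het: int


def make_windows(chrom_lengths: Dict[str, int], width: int = DEFAULT_WINDOW_BP) -> List[GenomeWindow]:
    """Tile each chromosome from 0 with non-overlapping windows of ``width``;
    a trailing partial window is retained (flagged via ``is_partial``)."""
    if width <= 0:
        raise ValueError("window width must be positive")
    windows: List[GenomeWindow] = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        for start in range(0, length, width):
            windows.append(GenomeWindow(chrom, start, min(start + width, length), width))
    return windows


def _window_index(windows: List[GenomeWindow]) -> Dict[str, Tuple[int, int, int]]:
    """chrom -> (first index in list, n windows, width)."""
    idx: Dict[str, Tuple[int, int, int]] = {}
    for i, w in enumerate(windows):
        if w.chrom not in idx:
            idx[w.chrom] = (i, 0, w.width)
        first, n, width = idx[w.chrom]
        idx[w.chrom] = (first, n + 1, width)
    return idx


def tally_windows(
    sites: Iterable[GenotypeSite],
    windows: List[GenomeWindow],
    sample_index: int = 0,
) -> List[GenomeWindow]:
    """Fill ``n_genotyped``/``n_het`` for one sample from a sorted site stream.

    Each genotyped site increments exactly one window; heterozygous sites
    increment both counters.  Sites beyond the tiled chromosome extent raise.
    """
    idx = _window_index(windows)
    for site in sites:
        call = site.per_sample[sample_index]
        if call.genotype == Genotype.MISSING:
            continue
        if site.chrom not in idx:
            raise ValueError(f"site on untiled chromosome {site.chrom!r}")
        first, n, width = idx[site.chrom]
        k = (site.pos - 1) // width
        if k >= n or site.pos - 1 >= windows[first + n - 1].end:
            raise ValueError(
                f"site {site.chrom}:{site.pos} beyond chromosome tiling"
            )
        w = windows[first + k]
        w.n_genotyped += 1
        if call.genotype == Genotype.HET:
            w.n_het += 1
    return windows


def genome_heterozygosity(windows: Iterable[GenomeWindow]) -> float:
    """Genome-wide observed heterozygosity: total het sites over total
    genotyped sites, partial windows included."""
    n_gt = sum(w.n_genotyped for w in windows)
    n_het = sum(w.n_het for w in windows)
    if n_gt == 0:
        raise ValueError("no genotyped sites: heterozygosity undefined")
    return n_het / n_gt


def heterozygosity_variability(
    windows: Iterable[GenomeWindow],
    min_genotyped_fraction: float = 0.8,
    statistic: str = "sd",
) -> float:
    """Variability of per-window heterozygosity.

    Uses full-width windows with at least ``min_genotyped_fraction`` of their
    span genotyped (the same support rule the ROH caller applies), and the
    sample standard deviation (n-1 denominator) of window het; ``statistic``
    may be ``"cv"`` for the coefficient of variation instead.
    """
    vals = [
        w.n_het / w.n_genotyped
        for w in windows
        if not w.is_partial and w.n_genotyped >= min_genotyped_fraction * w.width
    ]
    if len(vals) < 2:
        raise ValueError("fewer than 2 qualifying windows: variability undefined")
    sd = float(np.std(vals, ddof=1))
    if statistic == "sd":
        return sd
    if statistic == "cv":
        m = float(np.mean(vals))
        if m == 0:
            raise ValueError("mean window het is 0: CV undefined")
        return sd / m
    raise ValueError(f"unknown statistic {statistic!r}")


def summarize_heterozygosity(
    windows: List[GenomeWindow],
    sample: str,
    min_genotyped_fraction: float = 0.8,
) -> HetSummary:
    n_gt = sum(w.n_genotyped for w in windows)
    n_het = sum(w.n_het for w in windows)
    gh = genome_heterozygosity(windows)
    try:
        sd = heterozygosity_variability(windows, min_genotyped_fraction, "sd")
        cv = heterozygosity_variability(windows, min_genotyped_fraction, "cv")
    except ValueError:
        sd = cv = None
    n_used = sum(
        1
        for w in windows
        if not w.is_partial and w.n_genotyped >= min_genotyped_fraction * w.width
    )
    return HetSummary(sample, gh, sd, cv, n_used, n_gt, n_het)


def write_windows_tsv(windows: List[GenomeWindow], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_genotyped\tn_het\thet\n")
        for w in windows:
            het = "" if w.het is None else f"{w.het:.6g}"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_genotyped}\t{w.n_het}\t{het}\n")


# ---------------------------------------------------------------------------
# Fast single-pass path: VCF -> filtered window tallies
# ---------------------------------------------------------------------------


def tally_vcf(
    vcf_path: str,
    chrom_lengths: Dict[str, int],
    cfg: FilterConfig = FilterConfig(),
    width: int = DEFAULT_WINDOW_BP,
    sample_index: int = 0,
    stats: Optional[FilterStats] = None,
) -> List[GenomeWindow]:
    """Stream a single-sample all-sites VCF straight into filtered window
    tallies, without materialising per-site objects.

    Applies the same site/genotype rules as
    :func:`isledv.genotype_io.apply_filters` (for a one-sample file the
    site mean DP is that sample's DP).  Intended for the per-island files of
    this study design — one sequenced individual per island.
    """
    from cyvcf2 import VCF

    if stats is None:
        stats = FilterStats()
    windows = make_windows(chrom_lengths, width)
    idx = _window_index(windows)
    counts: Dict[str, np.ndarray] = {}
    for chrom, (first, n, _) in idx.items():
        counts[chrom] = np.zeros((n, 2), dtype=np.int64)
    min_q, min_gq, min_dp, max_mdp = (
        cfg.min_site_qual,
        cfg.min_gq,
        cfg.min_dp,
        cfg.max_mean_dp,
    )
    i = sample_index
    for rec in VCF(vcf_path):
        stats.n_sites_seen += 1
        q = rec.QUAL
        if q is not None and q < min_q:
            stats.dropped_site_qual += 1
            continue
        gt = rec.gt_types[i]
        dp_arr = rec.format("DP")
        dp = int(dp_arr[i][0]) if dp_arr is not None else -1
        if gt != _CY_UNKNOWN and dp > max_mdp:
            stats.dropped_mean_dp += 1
            continue
        stats.n_sites_kept += 1
        if gt == _CY_UNKNOWN:
            continue
        gq = rec.gt_quals[i]
        if gq < min_gq:
            stats.masked_gq += 1
            continue
        if dp < min_dp:
            stats.masked_dp += 1
            continue
        c = counts[rec.CHROM]
        c[(rec.POS - 1) // width, 0] += 1
        if gt == _CY_HET:
            c[(rec.POS - 1) // width, 1] += 1
    for chrom, (first, n, _) in idx.items():
        for k in range(n):
            windows[first + k].n_genotyped = int(counts[chrom][k, 0])
            windows[first + k].n_het = int(counts[chrom][k, 1])
    return windows


def windows_from_arrays(
    chrom_lengths: Dict[str, int],
    genotyped_pos: Dict[str, np.ndarray],
    het_pos: Dict[str, np.ndarray],
    width: int = DEFAULT_WINDOW_BP,
) -> List[GenomeWindow]:
    """Build tallied windows from per-chromosome 0-based position arrays of
    genotyped and heterozygous sites (the synthetic generator's native
    representation; avoids a VCF round trip for large simulated genomes)."""
    windows = make_windows(chrom_lengths, width)
    idx = _window_index(windows)
    for chrom, (first, n, _) in idx.items():
        gpos = np.asarray(genotyped_pos.get(chrom, np.empty(0, dtype=np.int64)))
        hpos = np.asarray(het_pos.get(chrom, np.empty(0, dtype=np.int64)))
        gcnt = np.bincount(gpos // width, minlength=n) if gpos.size else np.zeros(n, int)
        hcnt = np.bincount(hpos // width, minlength=n) if hpos.size else np.zeros(n, int)
        if gcnt.size > n or hcnt.size > n:
            raise ValueError(f"positions beyond tiling on {chrom!r}")
        for k in range(n):
            windows[first + k].n_genotyped = int(gcnt[k])
            windows[first + k].n_het = int(hcnt[k])
    return windows
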